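# elbench

**Synthetic cryo-EM benchmark for conformational-heterogeneity methods.**

Biomolecular machines such as the ribosome move through continuous
conformational changes, and at thermal equilibrium the probability of
observing a conformation of energy *E* is set by the Boltzmann factor
exp(−*E*/*kT*).  A growing family of data-analytical tools (variational
autoencoders, linear subspace methods, manifold embeddings, multi-body
refinement) tries to recover this conformational energy landscape from
single-particle cryo-EM images.  Assessing how faithfully each tool does so
requires data whose landscape is known exactly.

`elbench` provides both halves of such a benchmark:

1. **Simulator** — a two-coordinate ground-truth energy landscape
   (12 Gaussian wells of uneven depth on a 3 × 4 grid over [0, 1]²) acting
   on a ribosome-like two-body phantom: a fixed large subunit (LSU) and a
   small subunit (SSU) that rotates rigidly about two orthogonal axes in a
   ratchet-like fashion, the two rotation angles being the conformational
   coordinates.  Conformations are drawn exactly from the Boltzmann
   distribution p(**c**) ∝ exp(−E(**c**)/kT); particles are projected
   analytically in uniform (or fixed) orientations and white Gaussian noise
   is calibrated so that Var(signal)/Var(noise) = SNR (1 by default).
   Output: an MRCS image stack plus Relion-dialect STAR (and CSV) metadata
   carrying the ground-truth orientations, coordinates and well labels.

2. **Evaluation suite** — scores any per-particle low-dimensional embedding
   against the ground truth with the nearest-center procedure: per-well
   centers are the class means, each particle is assigned to the nearest
   center (squared Euclidean), and

   Recall(n) = TP(n)/P(n),  Accuracy = Σₙ Recall(n)/n  (n = 12 wells),

   reported in percent together with the standard deviation of the 12
   recalls.  The suite also builds occupancy maps (2-D histograms of the
   embedding), Boltzmann-inverted energy landscapes E = −kT ln p, and
   "data lineage" colorings (each particle colored by its true well).

A `reference_embed` module supplies in-house embeddings — the ground-truth
oracle and an image-space PCA for fixed-view stacks — plus controlled
distortions (noise, affine, shuffle, collapse) so the whole pipeline runs
end-to-end without any external heterogeneity software.

## Worked example

```python
import numpy as np
from elbench import generate_dataset, evaluate_embedding
from elbench.landscape import default_landscape
from elbench.phantom import build_default_phantom
from elbench.reference_embed import embed_oracle, distort, DistortionSpec

landscape = default_landscape()                      # 12 wells, 3 x 4 grid
phantom = build_default_phantom(box_size=64, voxel_size=3.0)
stack = generate_dataset(landscape, phantom, n=2000, snr_target=1.0, seed=7)
labels = np.array([m.well_label for m in stack.metadata])

emb = embed_oracle(stack.metadata)                   # the ideal method
print(evaluate_embedding(emb, labels).accuracy)      # 99.47

noisy = distort(emb, DistortionSpec(kind="noise", magnitude=1.0, seed=1))
report = evaluate_embedding(noisy, labels)
print(report.accuracy, report.recall_std)            # 30.66 12.57
```

The oracle embedding (the true conformational coordinates) scores 99.47 %
balanced accuracy — a fraction of particles lies in the weakly occupied
background between wells, where finite-sample jitter of the class means can
flip assignments near basin boundaries.  Adding embedding noise of one data
standard deviation intermixes the basins and accuracy collapses to 30.66 %
with a much larger recall spread (12.57 %), the qualitative failure mode of
a poor heterogeneity method.

The same workflow from the shell:

```bash
elbench simulate --n 2000 --snr 1.0 --seed 7 --out stack.mrcs --meta particles.star
elbench embed --stack stack.mrcs --meta particles.star --method oracle --out emb.csv
elbench distort --embedding emb.csv --kind noise --magnitude 1.0 --seed 1 --out emb2.csv
elbench evaluate --embedding emb2.csv --meta particles.star --out report.json
```

## Layout

- `elbench.landscape` — wells, Boltzmann occupancy, exact rejection sampling, basin labels
- `elbench.phantom` — Gaussian-blob two-body model, rigid SSU rotation, volume rendering
- `elbench.imaging` — analytic projection, SNR calibration, noise, dataset generation
- `elbench.evaluation` — recall/accuracy, occupancy maps, energy inversion, lineage
- `elbench.reference_embed` — oracle/PCA embeddings and controlled distortions
- `elbench.io`, `elbench.cli`, `elbench.config` — MRC/STAR/JSON I/O, YAML config, `elbench` CLI

See `docs/methods.md` for the model, parameter choices and limitations.
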