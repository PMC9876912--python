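# Methods

## Ground-truth energy landscape

The landscape is a sum of negative isotropic Gaussian wells on a flat
background over the unit square of conformational coordinates
**c** = (cc1, cc2):

E(**c**) = E₀ − Σᵢ dᵢ · exp(−‖**c** − **μ**ᵢ‖² / 2wᵢ²),   energies in kT.

This form is smooth and analytic, and reproduces the qualitative picture of
a multi-well conformational landscape with minima of uneven depth.  The
default configuration has 12 wells on a regular 3 × 4 grid:

- columns (cc1): 0.1275, 0.3775, 0.6275, 0.8775 (spacing 0.25)
- rows (cc2): 0.1675, 0.4975, 0.8275 (spacing 0.33)
- depths (kT, raster order, bottom row first): 2.0, 3.5, 2.5, 4.0, 3.0,
  2.2, 4.5, 2.8, 3.8, 2.4, 3.2, 4.2
- width w = 0.035 for every well; kT = 1; background E₀ = 0.

The grid coordinates are deliberately offset from the "centered" lattice
(1/8, 3/8, … × 1/6, 1/2, 5/6): midpoint discretization of the occupancy
(below) would otherwise place every well center exactly on a cell boundary
at even grid resolutions, where mirror-symmetric cells are equal to the
last floating-point bit and the density has no *strict* local maximum
there.  With the offsets, the lattice density has exactly 12 strict maxima
at all resolutions in practical use (verified at 64–256).

Width 0.035 makes wells well-separated (7 widths apart) yet leaves real
occupancy in the inter-well background (~29 % of the Boltzmann mass),
mimicking a continuous landscape rather than a discrete mixture.  Depths
span 2–4.5 kT so basin occupancies vary by an order of magnitude.

**Occupancy** is p(**c**) ∝ exp(−E/kT), discretized by the midpoint rule on
an n × n lattice and normalized to unit total mass (to 10⁻¹²).

**Sampling** is plain rejection sampling: uniform proposals over the
domain, envelope equal to the global maximum of the Boltzmann weight.  The
maximum has no closed form for a Gaussian mixture, so it is located by
multi-start bounded L-BFGS (one start per well center plus the best cell of
a 256² lattice) and inflated by a 10⁻⁹ relative safety margin.  Rejection
sampling is exact (no burn-in or autocorrelation); batch sizes adapt to the
observed acceptance rate.  All randomness flows through
`numpy.random.default_rng(seed)`, so outputs are bit-reproducible.

**Ground-truth labels** use the nearest-well-center rule (Euclidean), i.e.
Voronoi basins of the 12 centers, ties to the lowest id.  Every sampled
conformation, including background points, carries the label of its basin.

## Two-body phantom

The molecule is an analytic Gaussian-blob mixture in two rigid bodies: a
6-blob LSU filling roughly the lower half of the box and a 4-blob SSU above
it.  The SSU rotates rigidly about a pivot at the subunit interface through
two orthogonal axes (x and y), with angles linear in the conformational
coordinates: α = α_max(2·cc1 − 1), β = β_max(2·cc2 − 1), α_max = β_max =
10° by default — the magnitude of ribosomal ratchet-like intersubunit
rotations.  Rotations compose as R(axis2, β)·R(axis1, α) (axis1 first); at
≤10° the commutator correction is second-order and the order is simply
fixed and documented.

Rotating *blob parameters* rather than resampling a voxel grid keeps the
analytic mass Σ aᵢ(2π)^{3/2}σᵢ³ exactly conformation-independent and avoids
interpolation artifacts entirely.  Densities are evaluated on the grid as
outer products of 1-D Gaussians (exact, fast).  Gaussians are *not*
truncated: voxelized mass therefore agrees with the analytic mass to ≈0.02 %
(edge tails), and "fixed LSU" is exact at the blob level while rendered
voxels far from the SSU agree across conformations to < 10⁻¹⁵ of the peak
density (tails below that remain conformation-dependent in the last bits —
a deliberate consequence of untruncated analytic evaluation).

Conventions: volumes are (z, y, x)-indexed, origin at the box center,
right-handed axes, angles counter-clockwise looking down the axis; box 64
voxels at 3 Å/voxel by default.

## Image formation

A 3-D Gaussian blob of amplitude a and width σ projects along any axis to a
2-D Gaussian of the same σ and amplitude aσ√(2π), so projections are
analytic too.  Orientations follow the Relion ZYZ convention: the matrix
A(rot, tilt, psi) = R_z(psi)·R_y(tilt)·R_z(rot) maps reference coordinates
into the projection frame and the image is the line integral along the new
z.  Uniform orientations are Haar samples via normalized random quaternions;
a fixed-view mode exists for methods (such as the built-in PCA) that cannot
disentangle pose from conformation.

**Noise** is additive white Gaussian.  The stack-wide SNR is defined as
pooled signal variance over noise variance across every pixel of every
frame (a circular-mask variant is selectable), and a single σ_noise =
√(Var(signal)/SNR) is computed from the noise-free pass so noise is
stationary across conformations.  Per-particle noise streams derive from
(seed, index), making generation order-independent and parallelizable.
An optional phase CTF (defocus + amplitude contrast, multiplied in Fourier
space, defocus recorded per particle) is available but off by default.

The default SNR target is 1, the noise level of the benchmark dataset this
simulator emulates; full-scale stacks (10⁶–10⁷ particles) are supported by
the API, while tests and the acceptance script use 10²–10⁵ so they complete
in minutes on one CPU.

## Evaluation

Given an embedding (n × d, d = 2 typically) and true labels 1..12:

1. center of well n = mean of its particles' embedding coordinates;
2. each particle → label of the nearest center (squared Euclidean, ties to
   the lowest id);
3. Recall(n) = TP(n)/P(n);
4. Accuracy = mean recall × 100, with the standard deviation of the 12
   recalls (population convention by default, ddof switchable).

The procedure is invariant under rotation + isotropic scaling + translation
of the embedding, but *not* under anisotropic affine maps — class means
transform affinely, yet nearest-center boundaries do not, which is exactly
why the metric punishes methods that stretch or fold the landscape.

Occupancy maps are 2-D histograms over the data range; the energy surface
is E = −kT ln p shifted to min 0, with bins under a floor count (default 1)
masked rather than extrapolated — the data say nothing about unvisited
states, and pseudo-counts would invent energies for them.  Lineage tables
color each particle by its true well through a fixed 12-color palette.

On the default landscape, inverting the occupancy of 10⁵ ground-truth
samples on a 40 × 40 grid recovers the generator energy with Pearson
r ≈ 0.97 at bin centers; the residual decorrelation is discretization
(bin-averaged Boltzmann weights act as a soft minimum over each bin, while
the reference energy is evaluated at the bin center).

### Exactness regimes

With continuous Boltzmann sampling, ~29 % of default-landscape particles
lie in the inter-well background.  The class means of a ground-truth
embedding then deviate from the true well centers by O(n_well^{-1/2}),
assignment boundaries shift accordingly, and a small fraction of
boundary-adjacent particles flips: the oracle embedding scores ≈ 99.5–99.9 %
rather than exactly 100 %.  Exact 100 %/0 % is the property of the
*separable* regime — wells ≥ 8 widths apart with negligible background
occupancy (e.g. width 0.02 with depths 10–12.5 kT on the same grid), where
the tests assert it exactly.  Chance level for a 12-class balanced problem
is 100/12 ≈ 8.33 %, which shuffled embeddings reproduce within sampling
error.

## Reference embeddings and distortions

`embed_oracle` returns the true conformational coordinates — the ideal
heterogeneity method and the fixed point of the evaluation.  `embed_pca`
computes image-space PCA scores (SVD of mean-centered flattened images,
component signs fixed by the largest loading) and refuses mixed-orientation
stacks: separating pose from conformation is precisely the problem the
benchmarked tools exist to solve, and silent conflation would make the
baseline meaningless.  Distortions emulate observed failure modes: noise
(basin intermixing), affine (anisotropic stretching), shuffle (uninformative
labels, chance level), collapse (loss of a conformational coordinate; the
expected accuracy is computed at run time from the occupancy lattice and
the collapsed centers, ≈ 1/3 of the full accuracy on the 3 × 4 grid since
same-column wells become indistinguishable).

## File formats

MRC2014 mode-2 stacks (little-endian float32, nz = particle count, pixel
size in the cell header, deterministic byte-identical output) and
Relion-dialect STAR metadata (`_rlnImageName`, `_rlnAngleRot/Tilt/Psi` plus
namespaced `_elbCc1`, `_elbCc2`, `_elbWellLabel` columns; fixed float
formatting; CSV mirror) are written by compact readers/writers in
`elbench.io` and cross-checked in the tests against gemmi as an independent
reader.  Benchmark reports serialize to JSON with per-well P/TP/recall and
percent-scale accuracy and recall spread.

## What the synthetic data does and does not show

The generator emulates Boltzmann-distributed conformational heterogeneity,
known orientations, and stationary white noise at a controlled SNR.  It
omits CTF by default, structural/solvent noise, orientation bias, flexible
(non-rigid) deformation, and realistic molecular density.  Passing the
benchmark therefore demonstrates that an analysis method can recover a
two-dimensional landscape from idealized images under known poses — not
that it is robust to the full complexity of experimental cryo-EM data.

## Known limitations

- Landscapes are strictly two-dimensional; evaluation accepts d-dimensional
  embeddings but occupancy/energy maps require d = 2.
- The rejection sampler's acceptance rate decays with the deepest well's
  Boltzmann weight (~e^{d_max}); for wells much deeper than ~30 kT an
  importance or mixture proposal would be needed.
- PCA is a fixed-view baseline only, by design.
- The recall-spread convention (population vs sample) changes Table-style
  spread values by √(12/11) ≈ 4.4 %; both are available, population is the
  default.
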