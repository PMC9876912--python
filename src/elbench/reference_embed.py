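"""In-house embeddings and controlled distortions.

External heterogeneity methods are out of scope, but the evaluation suite
must be exercisable end-to-end.  This module provides:

- the oracle embedding (ground-truth conformational coordinates — the
  ideal heterogeneity method);
- an image-space PCA embedding for fixed-orientation stacks;
- parametric distortions (noise, affine, shuffle, collapse) that mimic the
  failure modes real methods show — mixed basins, anisotropic stretching,
  lost conformational coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import ParticleStack

__all__ = ["DistortionSpec", "embed_oracle", "embed_pca", "distort"]

_KINDS = ("identity", "noise", "affine", "shuffle", "collapse")


@dataclass(frozen=True)
class DistortionSpec:
    """A named distortion of an embedding.

    kind: one of identity / noise / affine / shuffle / collapse.
    magnitude: distortion strength (>= 0); magnitude 0 leaves noise and
    affine distortions as the identity.
    """

    kind: str
    magnitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown distortion kind {self.kind!r}; expected one of {_KINDS}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")


def embed_oracle(metadata) -> np.ndarray:
    """The ideal embedding: each particle's true (cc1, cc2) coordinates.

    ``metadata`` is a sequence of particle metadata records (anything with
    a ``cc`` attribute) or a DataFrame with cc1/cc2 columns.
    """
    if hasattr(metadata, "columns"):
        return metadata[["cc1", "cc2"]].to_numpy(dtype=float)
    return np.array([m.cc for m in metadata], dtype=float)


def embed_pca(stack: ParticleStack, n_components: int = 2) -> np.ndarray:
    """Image-space PCA scores for a fixed-orientation stack.

    Images are flattened and mean-centered; scores on the leading
    principal axes are returned.  The sign of each component is fixed by
    making its largest-magnitude loading positive.

    PCA on images from mixed viewing directions conflates pose with
    conformation — that disentanglement is precisely the problem the
    benchmarked heterogeneity tools exist to solve — so mixed-orientation
    stacks are rejected.
    """
    eulers = np.array([m.euler for m in stack.metadata])
    if not np.allclose(eulers, eulers[0], atol=1e-9):
        raise ValueError(
            "embed_pca requires a fixed-orientation stack; mixed views conflate pose and conformation"
        )
    n = stack.n_particles
    if n < n_components:
        raise ValueError("need at least n_components particles")
    x = stack.images.reshape(n, -1).astype(float)
    x -= x.mean(axis=0)
    # economy SVD of the centered data matrix == covariance eigendecomposition
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    comps = vt[:n_components]
    flip = np.sign(comps[np.arange(n_components), np.argmax(np.abs(comps), axis=1)])
    comps = comps * flip[:, None]
    return x @ comps.T


def distort(embedding, spec: DistortionSpec) -> np.ndarray:
    """Apply a controlled distortion to an embedding (deterministic per seed).

    - identity: copy.
    - noise: add i.i.d. Gaussian noise, sd = magnitude x per-dimension sd.
    - affine: random rotation composed with an anisotropic scaling of
      condition number (1 + magnitude).
    - shuffle: permute the rows (labels become uninformative).
    - collapse: keep only the first dimension (a method that lost a
      conformational coordinate).
    """
    coords = np.array(embedding, dtype=float, copy=True)
    if coords.ndim == 1:
        coords = coords[:, None]
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "identity":
        return coords
    if spec.kind == "noise":
        if spec.magnitude == 0:
            return coords
        sd = coords.std(axis=0)
        return coords + rng.normal(0.0, 1.0, coords.shape) * (spec.magnitude * sd)
    if spec.kind == "affine":
        if spec.magnitude == 0:
            return coords
        d = coords.shape[1]
        q, _ = np.linalg.qr(rng.normal(size=(d, d)))
        scales = np.linspace(1.0, 1.0 + spec.magnitude, d)
        center = coords.mean(axis=0)
        return (coords - center) @ (q @ np.diag(scales) @ q.T) + center
    if spec.kind == "shuffle":
        return coords[rng.permutation(coords.shape[0])]
    if spec.kind == "collapse":
        return coords[:, :1]
    raise ValueError(f"unknown distortion kind {spec.kind!r}")
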