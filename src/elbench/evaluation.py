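"""Scoring a recovered conformational embedding against ground truth.

A heterogeneity method returns per-particle low-dimensional coordinates
(an embedding).  The benchmark scores it with a nearest-center procedure:

1. the center of each ground-truth energy minimum is the mean of the
   embedding points carrying that true label;
2. every particle is assigned to the center at minimal squared Euclidean
   distance;
3. per-well Recall(n) = TP(n) / P(n) — the fraction of well n's particles
   assigned back to well n;
4. balanced Accuracy = unweighted mean of the per-well recalls, reported
   in percent together with the standard deviation of the recalls.

The module also converts embeddings into occupancy maps (2-D histograms)
and Boltzmann-inverted energy landscapes E = -kT ln p, and produces
lineage colorings (each particle colored by its ground-truth well).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RecallTable",
    "BenchmarkReport",
    "OccupancyMap",
    "well_centers",
    "assign_nearest_center",
    "recall_per_well",
    "accuracy",
    "evaluate_embedding",
    "occupancy_map",
    "energy_from_occupancy",
    "lineage_map",
    "LINEAGE_PALETTE",
]

#: fixed 12-color lineage palette (hex), indexed by well id - 1
LINEAGE_PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728",
    "#9467bd", "#8c564b", "#e377c2", "#7f7f7f",
    "#bcbd22", "#17becf", "#aec7e8", "#ffbb78",
)


@dataclass(frozen=True)
class RecallTable:
    """Per-well positive counts, true-positive counts and recalls."""

    well_ids: np.ndarray  # (k,) int
    positives: np.ndarray  # P(n)
    true_positives: np.ndarray  # TP(n)

    def __post_init__(self) -> None:
        if np.any(self.true_positives > self.positives) or np.any(self.true_positives < 0):
            raise ValueError("require 0 <= TP(n) <= P(n)")

    @property
    def recall(self) -> np.ndarray:
        return self.true_positives / self.positives


@dataclass(frozen=True)
class BenchmarkReport:
    """Benchmark summary: recall table plus accuracy statistics in percent."""

    recall_table: RecallTable
    accuracy: float  # %
    recall_std: float  # %


@dataclass(frozen=True)
class OccupancyMap:
    """2-D histogram of an embedding: counts, probabilities and bin edges."""

    counts: np.ndarray  # (n_bins, n_bins), rows index dim2
    edges1: np.ndarray
    edges2: np.ndarray

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def _as_embedding(coords) -> np.ndarray:
    c = np.asarray(coords, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if not np.all(np.isfinite(c)):
        raise ValueError("embedding contains non-finite entries")
    return c


def well_centers(embedding, true_labels, n_wells: int = 12) -> np.ndarray:
    """Per-well centers: the mean embedding point of each true class.

    Returns an (n_wells, d) array ordered by well id 1..n_wells.  Raises
    if any well has no particles (its center is undefined).
    """
    coords = _as_embedding(embedding)
    labels = np.asarray(true_labels, dtype=int)
    centers = np.empty((n_wells, coords.shape[1]))
    for k in range(1, n_wells + 1):
        sel = labels == k
        if not sel.any():
            raise ValueError(f"well {k} has no particles; center undefined")
        centers[k - 1] = coords[sel].mean(axis=0)
    return centers


def assign_nearest_center(embedding, centers) -> np.ndarray:
    """Label each particle with its nearest center (squared Euclidean).

    Ties break toward the lowest well id.  Returns 1-based labels.
    """
    coords = _as_embedding(embedding)
    ctr = np.atleast_2d(np.asarray(centers, dtype=float))
    if ctr.shape[0] < 1:
        raise ValueError("need at least one center")
    d2 = ((coords[:, None, :] - ctr[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1) + 1  # argmin -> first (lowest id) on ties


def recall_per_well(true_labels, predicted_labels, n_wells: int = 12) -> RecallTable:
    """Recall(n) = TP(n) / P(n) for every well n.

    P(n) counts particles whose true label is n; TP(n) counts those also
    predicted as n.  Every well must occur among the true labels.
    """
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label arrays must have equal length")
    ids = np.arange(1, n_wells + 1)
    positives = np.array([(t == k).sum() for k in ids])
    if np.any(positives == 0):
        missing = ids[positives == 0]
        raise ValueError(f"recall undefined: wells {missing.tolist()} have P(n) = 0")
    tps = np.array([((t == k) & (p == k)).sum() for k in ids])
    return RecallTable(well_ids=ids, positives=positives, true_positives=tps)


def accuracy(recall_table: RecallTable, ddof: int = 0) -> tuple[float, float]:
    """Balanced accuracy and recall spread, both in percent.

    Accuracy is the unweighted mean of the per-well recalls x 100; the
    spread is the standard deviation of the recalls x 100 (population
    convention by default; pass ``ddof=1`` for the sample convention).
    """
    r = recall_table.recall
    return float(r.mean() * 100.0), float(r.std(ddof=ddof) * 100.0)


def evaluate_embedding(embedding, true_labels, n_wells: int = 12, ddof: int = 0) -> BenchmarkReport:
    """Full nearest-center benchmark: centers -> assignment -> recall -> accuracy."""
    centers = well_centers(embedding, true_labels, n_wells)
    predicted = assign_nearest_center(embedding, centers)
    table = recall_per_well(true_labels, predicted, n_wells)
    acc, std = accuracy(table, ddof=ddof)
    return BenchmarkReport(recall_table=table, accuracy=acc, recall_std=std)


def occupancy_map(embedding, n_bins: int = 40) -> OccupancyMap:
    """2-D occupancy histogram of a d = 2 embedding over its data range."""
    coords = _as_embedding(embedding)
    if coords.shape[1] != 2:
        raise ValueError("occupancy maps require a 2-D embedding")
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    counts, e1, e2 = np.histogram2d(coords[:, 0], coords[:, 1], bins=n_bins)
    # transpose so rows index dim2 (image convention), columns dim1
    return OccupancyMap(counts=counts.T, edges1=e1, edges2=e2)


def energy_from_occupancy(occ: OccupancyMap, kT: float = 1.0, floor_count: int = 1) -> np.ndarray:
    """Boltzmann-inverted energy surface E = -kT ln p, min shifted to 0.

    Bins with fewer than ``floor_count`` particles are masked (NaN) rather
    than extrapolated: the data say nothing about unvisited states.
    """
    if floor_count < 1:
        raise ValueError("floor_count must be >= 1")
    counts = occ.counts
    valid = counts >= floor_count
    if not valid.any():
        raise ValueError("all bins below floor_count; energy undefined")
    p = occ.probabilities
    energy = np.full(counts.shape, np.nan)
    energy[valid] = -kT * np.log(p[valid])
    energy[valid] -= np.nanmin(energy[valid])
    return energy


def lineage_map(embedding, true_labels) -> "pandas.DataFrame":  # noqa: F821
    """Per-particle lineage table: coordinates, well label, fixed color.

    Each ground-truth energy minimum keeps a unique color from the fixed
    12-color palette, so plotting the table shows how a method mixes or
    preserves the basins.
    """
    import pandas as pd

    coords = _as_embedding(embedding)
    labels = np.asarray(true_labels, dtype=int)
    if labels.min() < 1 or labels.max() > len(LINEAGE_PALETTE):
        raise ValueError("labels must lie in 1..12")
    df = pd.DataFrame(coords, columns=[f"dim{i + 1}" for i in range(coords.shape[1])])
    df["well_label"] = labels
    df["color_id"] = labels
    df["color"] = [LINEAGE_PALETTE[k - 1] for k in labels]
    return df


def plot_lineage(df, path, dims=("dim1", "dim2")) -> None:
    """Scatter the lineage table to a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(df[dims[0]], df[dims[1]], c=df["color"], s=2, linewidths=0)
    ax.set_xlabel(dims[0])
    ax.set_ylabel(dims[1])
    ax.set_title("data lineage (color = ground-truth energy minimum)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
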