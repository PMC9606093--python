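"""Histogramming, maximum-entropy (Kapur) thresholding, masks, slab projections.

Hyperdense (HD) particles are segmented from a density volume by a single
global threshold chosen to maximise the sum of the Shannon entropies of the
two classes it induces on the grey-level histogram (Kapur's maximum-entropy
criterion).  The threshold is computed per volume of interest, so local
contrast differences between tissue locations do not bias the split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Literal

import numpy as np

from .volume import DegenerateHistogramError, VoxelVolume

__all__ = [
    "Histogram",
    "BinaryMask",
    "build_histogram",
    "kapur_threshold",
    "apply_threshold",
    "slab_projection",
]


@dataclass
class Histogram:
    """Uniform-bin intensity histogram.

    ``bin_edges`` has length ``B + 1`` (strictly increasing); ``counts`` has
    length ``B`` and sums to the number of voxels histogrammed.  ``degenerate``
    flags a constant input (all mass in one bin support).
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("bin_edges must have length len(counts) + 1")

    @property
    def n_bins(self) -> int:
        return len(self.counts)


@dataclass
class BinaryMask:
    """Boolean foreground mask aligned with a source volume.

    Polarity: True marks hyperdense voxels (value strictly above threshold).
    """

    values: np.ndarray
    voxel_size: float
    threshold: float | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("mask must be 3-D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def foreground_count(self) -> int:
        return int(self.values.sum())


def build_histogram(volume: VoxelVolume | np.ndarray, n_bins: int = 256) -> Histogram:
    """Histogram a volume into uniform bins spanning [min, max].

    The top edge is inclusive (numpy convention).  A constant volume yields a
    single-support histogram flagged ``degenerate``.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    values = volume.values if isinstance(volume, VoxelVolume) else np.asarray(volume)
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        # widen artificially so edges stay strictly increasing
        edges = np.linspace(lo - 0.5, hi + 0.5, n_bins + 1)
        counts = np.zeros(n_bins, dtype=np.int64)
        counts[n_bins // 2] = values.size
        return Histogram(edges, counts, degenerate=True)
    counts, edges = np.histogram(values.ravel(), bins=n_bins, range=(lo, hi))
    return Histogram(edges, counts.astype(np.int64))


def kapur_threshold(hist: Histogram) -> float:
    """Maximum-entropy threshold of Kapur, Sahoo & Wong.

    For a candidate boundary after bin ``t`` let ``P0 = sum_{i<=t} p_i`` and
    ``P1 = 1 - P0``.  The boundary maximising

        H0 + H1 = -sum_{i<=t} (p_i/P0) ln(p_i/P0) - sum_{i>t} (p_i/P1) ln(p_i/P1)

    is returned as the corresponding bin edge (density units).  Candidates with
    an empty class are skipped; ``0·ln 0 = 0``.  Ties within 1e-12 resolve to
    the lowest boundary, so the result is deterministic.
    """
    counts = np.asarray(hist.counts, dtype=float)
    if hist.degenerate or int(np.count_nonzero(counts)) < 2:
        raise DegenerateHistogramError(
            "histogram needs >= 2 occupied bins for entropy thresholding"
        )
    p = counts / counts.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    P0 = np.cumsum(p)[:-1]          # boundary after bin t, t = 0 .. B-2
    A0 = np.cumsum(plogp)[:-1]      # sum_{i<=t} p ln p
    P1 = 1.0 - P0
    A1 = plogp.sum() - A0
    valid = (P0 > 0) & (P1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        psi = np.log(P0) + np.log(P1) - A0 / P0 - A1 / P1
    psi = np.where(valid, psi, -np.inf)
    best = float(np.max(psi))
    t_star = int(np.flatnonzero(psi >= best - 1e-12)[0])
    return float(hist.bin_edges[t_star + 1])


def apply_threshold(volume: VoxelVolume, threshold: float) -> BinaryMask:
    """Binarise a volume: foreground (hyperdense) iff value > threshold."""
    return BinaryMask(
        values=volume.values > threshold,
        voxel_size=volume.voxel_size,
        threshold=float(threshold),
        meta=dict(volume.meta),
    )


def slab_projection(
    volume: VoxelVolume,
    axis: int,
    start: int,
    count: int,
    mode: Literal["sum", "max"] = "sum",
) -> np.ndarray:
    """Project a slab of ``count`` consecutive slices into one 2-D image.

    ``mode='sum'`` reproduces the summed z-projection used for MIP-style
    overview maps of 20–100 consecutive CT slices; ``mode='max'`` takes the
    per-pixel maximum instead.
    """
    n = volume.shape[axis]
    if count < 1 or start < 0 or start + count > n:
        raise IndexError(
            f"slab [{start}, {start + count}) out of bounds for axis of length {n}"
        )
    slicer: list[slice] = [slice(None)] * 3
    slicer[axis] = slice(start, start + count)
    slab = volume.values[tuple(slicer)]
    if mode == "sum":
        return slab.sum(axis=axis)
    if mode == "max":
        return slab.max(axis=axis)
    raise ValueError(f"unknown projection mode {mode!r}")
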