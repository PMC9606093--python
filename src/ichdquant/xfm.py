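"""X-ray fluorescence microscopy quantification: mean intracellular elemental
density per cell and ICHD-vs-normal class comparison.

Inputs are calibrated 2-D elemental area-density maps (ng/mm²) and a labeled
cell mask whose labels carry a class (normal or ICHD-bearing).  Cell
segmentation itself is an input — in the original workflow intracellular
areas were selected manually — so this module only measures and compares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Literal

import numpy as np
import pandas as pd

from . import stats as _stats

__all__ = [
    "ELEMENTS",
    "ElementalMap",
    "CellMask",
    "mean_intracellular_density",
    "colocalization_overlay",
    "run_xfm_analysis",
]

ELEMENTS = ("K", "S", "P", "Zn", "Fe", "Cu", "Ca", "Br")

CellClass = Literal["normal", "ichd"]


@dataclass
class ElementalMap:
    """Calibrated 2-D area-density map for one element, in ng/mm²."""

    values: np.ndarray
    element: str
    pixel_size_um: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("elemental map must be 2-D")
        if self.element not in ELEMENTS:
            raise ValueError(f"unknown element {self.element!r}; expected one of {ELEMENTS}")
        if np.any(self.values < 0):
            raise ValueError("area densities must be >= 0")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")


@dataclass
class CellMask:
    """Labeled intracellular regions aligned with the elemental maps.

    ``labels`` holds positive integers (0 = background); ``classes`` maps every
    label to 'normal' or 'ichd'.
    """

    labels: np.ndarray
    classes: dict[int, CellClass]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("cell mask must be 2-D")
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        missing = present - set(self.classes)
        if missing:
            raise ValueError(f"labels without a class: {sorted(missing)}")
        for lab, cls in self.classes.items():
            if cls not in ("normal", "ichd"):
                raise ValueError(f"label {lab}: class must be 'normal' or 'ichd'")

    @property
    def label_ids(self) -> list[int]:
        return sorted(set(int(v) for v in np.unique(self.labels)) - {0})


def mean_intracellular_density(emap: ElementalMap, mask: CellMask) -> pd.DataFrame:
    """Arithmetic mean map value over each cell's pixels.

    Zero-density pixels are included (no censoring).  Returns one row per cell:
    ``cell_id, cell_class, element, n_pixels, mean_density``.
    """
    if emap.values.shape != mask.labels.shape:
        raise ValueError(
            f"map shape {emap.values.shape} != mask shape {mask.labels.shape}"
        )
    labs = mask.labels.ravel()
    vals = emap.values.ravel()
    fg = labs > 0
    n_max = int(labs.max()) if fg.any() else 0
    counts = np.bincount(labs[fg], minlength=n_max + 1)
    sums = np.bincount(labs[fg], weights=vals[fg], minlength=n_max + 1)
    rows = []
    for lab in mask.label_ids:
        if counts[lab] == 0:
            raise ValueError(f"cell label {lab} has no pixels in the mask")
        rows.append(
            dict(
                cell_id=lab,
                cell_class=mask.classes[lab],
                element=emap.element,
                n_pixels=int(counts[lab]),
                mean_density=float(sums[lab] / counts[lab]),
            )
        )
    return pd.DataFrame(rows, columns=["cell_id", "cell_class", "element",
                                       "n_pixels", "mean_density"])


def _minmax(a: np.ndarray) -> np.ndarray:
    lo, hi = float(a.min()), float(a.max())
    if hi == lo:
        import warnings

        warnings.warn("constant map normalised to zeros in overlay", stacklevel=3)
        return np.zeros_like(a, dtype=float)
    return (a - lo) / (hi - lo)


def colocalization_overlay(map_a: ElementalMap, map_b: ElementalMap) -> np.ndarray:
    """Two-channel min-max-normalised composite (H, W, 2), purely presentational.

    Channel 0 is map_a, channel 1 is map_b (e.g. P, S or Ca superimposed on
    Fe); swapping the inputs swaps the channels.
    """
    if map_a.values.shape != map_b.values.shape:
        raise ValueError("overlay inputs must share a shape")
    return np.stack([_minmax(map_a.values), _minmax(map_b.values)], axis=-1)


def run_xfm_analysis(
    maps: dict[str, ElementalMap] | list[ElementalMap],
    mask: CellMask,
) -> tuple[pd.DataFrame, dict[str, _stats.WilcoxonResult]]:
    """Per-cell means for every element plus per-element class comparison.

    Returns the stacked per-cell table (labels × elements rows) and one
    two-sided Wilcoxon result per element (ICHD-bearing vs normal cells, raw
    p, no multiplicity correction).  Elements with a class absent are skipped
    by the comparison; if the mask itself lacks a class the comparison table
    is empty and only the means are returned.
    """
    map_list = list(maps.values()) if isinstance(maps, dict) else list(maps)
    if not map_list:
        raise ValueError("need at least one elemental map")
    tables = [mean_intracellular_density(m, mask) for m in map_list]
    cell_means = pd.concat(tables, ignore_index=True)
    classes = set(mask.classes.values())
    if classes >= {"normal", "ichd"}:
        comparisons = _stats.xfm_group_compare(cell_means)
    else:
        comparisons = {}
    return cell_means, comparisons
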