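"""Group-level inference: one-way ANOVA, Tukey–Kramer post hoc, Wilcoxon tests.

The study design compares four animal groups (WT-saline, WT-LY, TG-saline,
TG-LY) within each of four brain regions (dCTX, dHIP, vCTX, vHIP) on per-VOI
measurements (hyperdense load, population sizes, proportions) by one-way
ANOVA followed by a Tukey–Kramer studentized-range post hoc that supports
unequal group sizes.  Intracellular elemental densities (ICHD-bearing vs
normal cells) are compared per element by an unpaired two-sided two-sample
Wilcoxon rank-sum test, exact for small tie-free samples.

The unit of analysis is the VOI, not the animal; an animal-mean aggregation
mode is provided because per-VOI analysis pseudo-replicates animals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GROUPS",
    "REGIONS",
    "AnovaResult",
    "PosthocResult",
    "PairComparison",
    "WilcoxonResult",
    "one_way_anova",
    "tukey_kramer",
    "wilcoxon_rank_sum",
    "compare_regions",
    "xfm_group_compare",
]

GROUPS = ("WT-saline", "WT-LY", "TG-saline", "TG-LY")
REGIONS = ("dCTX", "dHIP", "vCTX", "vHIP")


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: np.ndarray
    group_ns: np.ndarray
    degenerate: bool = False


@dataclass
class PairComparison:
    pair: tuple[int, int]
    mean_diff: float
    se: float
    q: float
    p_adj: float
    significant: bool


@dataclass
class PosthocResult:
    comparisons: list[PairComparison]
    k: int
    df_within: int
    alpha: float
    degenerate: bool = False

    def significant_pairs(self) -> list[tuple[int, int]]:
        return [c.pair for c in self.comparisons if c.significant]


@dataclass
class WilcoxonResult:
    u_statistic: float
    n1: int
    n2: int
    p_value: float
    method: Literal["exact", "normal-approx-with-tie-correction"]


def _as_groups(samples: Sequence[Sequence[float]]) -> list[np.ndarray]:
    groups = [np.asarray(g, dtype=float).ravel() for g in samples]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs n >= 2")
        if not np.all(np.isfinite(g)):
            raise ValueError("non-finite values in a group")
    return groups


def one_way_anova(samples: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA.

    Degenerate inputs are flagged rather than raising: all values identical
    gives F = 0, p = 1; zero within-group variance with unequal means gives
    the p -> 0 limit.
    """
    groups = _as_groups(samples)
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    n = int(ns.sum())
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(np.sum((g - g.mean()) ** 2) for g in groups))
    df_b, df_w = k - 1, n - k
    if df_w < 1:
        raise ValueError("total n must exceed the number of groups")
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, df_b, df_w, 1.0, means, ns, degenerate=True)
        return AnovaResult(np.inf, df_b, df_w, 0.0, means, ns, degenerate=True)
    f = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), df_b, df_w, p, means, ns)


def tukey_kramer(samples: Sequence[Sequence[float]], alpha: float = 0.05) -> PosthocResult:
    """Tukey–Kramer all-pairs post hoc on the studentized range.

    For unequal n the Kramer standard error is
    ``SE_ij = sqrt(MSW/2 * (1/n_i + 1/n_j))``; ``q_ij = |m_i - m_j| / SE_ij``
    is referred to the studentized-range distribution with (k, df_within).
    """
    groups = _as_groups(samples)
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    n = int(ns.sum())
    means = np.array([g.mean() for g in groups])
    df_w = n - k
    ssw = float(sum(np.sum((g - g.mean()) ** 2) for g in groups))
    pairs = list(itertools.combinations(range(k), 2))
    if ssw == 0.0:
        comps = [
            PairComparison(p, float(means[p[1]] - means[p[0]]), 0.0,
                           np.inf if means[p[0]] != means[p[1]] else 0.0,
                           0.0 if means[p[0]] != means[p[1]] else 1.0,
                           means[p[0]] != means[p[1]])
            for p in pairs
        ]
        return PosthocResult(comps, k, df_w, alpha, degenerate=True)
    msw = ssw / df_w
    qs = np.empty(len(pairs))
    ses = np.empty(len(pairs))
    diffs = np.empty(len(pairs))
    for idx, (i, j) in enumerate(pairs):
        se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        diffs[idx] = means[j] - means[i]
        ses[idx] = se
        qs[idx] = abs(diffs[idx]) / se
    p_adj = np.clip(sps.studentized_range.sf(qs, k, df_w), 0.0, 1.0)
    comps = [
        PairComparison(pairs[idx], float(diffs[idx]), float(ses[idx]),
                       float(qs[idx]), float(p_adj[idx]), bool(p_adj[idx] < alpha))
        for idx in range(len(pairs))
    ]
    return PosthocResult(comps, k, df_w, alpha)


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["auto", "exact", "approx"] = "auto",
) -> WilcoxonResult:
    """Unpaired two-sided two-sample Wilcoxon (Mann–Whitney U) test.

    ``mode='auto'`` uses the exact null distribution of U when
    ``n1 + n2 <= 20`` and the pooled data are tie-free, otherwise the normal
    approximation with tie and continuity corrections.  Two-sided
    p = min(1, 2·min-tail) in the exact case.
    """
    xa = np.asarray(x, dtype=float).ravel()
    ya = np.asarray(y, dtype=float).ravel()
    if len(xa) == 0 or len(ya) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([xa, ya])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if mode == "auto":
        use_exact = (len(xa) + len(ya) <= 20) and not has_ties
    elif mode == "exact":
        use_exact = True
    else:
        use_exact = False
    method = "exact" if use_exact else "asymptotic"
    res = sps.mannwhitneyu(xa, ya, alternative="two-sided", method=method,
                           use_continuity=True)
    return WilcoxonResult(
        u_statistic=float(res.statistic),
        n1=len(xa),
        n2=len(ya),
        p_value=float(min(1.0, res.pvalue)),
        method="exact" if use_exact else "normal-approx-with-tie-correction",
    )


@dataclass
class RegionReport:
    region: str
    measurement: str
    groups: list[str]
    anova: AnovaResult | None
    posthoc: PosthocResult | None
    significant_pairs: list[tuple[str, str]] = field(default_factory=list)
    skipped: str | None = None

    def to_rows(self) -> list[dict[str, Any]]:
        rows: list[dict[str, Any]] = []
        if self.anova is None or self.posthoc is None:
            return rows
        for c in self.posthoc.comparisons:
            gi, gj = self.groups[c.pair[0]], self.groups[c.pair[1]]
            rows.append(dict(
                region=self.region, measurement=self.measurement,
                F=self.anova.f_statistic, df1=self.anova.df_between,
                df2=self.anova.df_within, p=self.anova.p_value,
                pair=f"{gi} vs {gj}", mean_diff=c.mean_diff, q=c.q,
                p_adj=c.p_adj, flag=int(c.significant),
            ))
        return rows


def compare_regions(
    table: pd.DataFrame,
    measurement: str = "value",
    alpha: float = 0.05,
    unit: Literal["voi", "animal"] = "voi",
) -> dict[str, RegionReport]:
    """Per-region four-group ANOVA + Tukey–Kramer on a study table.

    ``table`` needs columns ``group``, ``region`` and the measurement column
    (plus ``animal_id`` for ``unit='animal'``, which averages VOIs within an
    animal first).  Regions with fewer than two groups of n >= 2 are skipped
    with a note in the report.
    """
    required = {"group", "region", measurement}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"study table missing columns: {sorted(missing)}")
    bad_groups = set(table["group"]) - set(GROUPS)
    bad_regions = set(table["region"]) - set(REGIONS)
    if bad_groups:
        raise ValueError(f"unknown group labels: {sorted(bad_groups)}")
    if bad_regions:
        raise ValueError(f"unknown region labels: {sorted(bad_regions)}")
    reports: dict[str, RegionReport] = {}
    for region in REGIONS:
        sub = table[table["region"] == region]
        if sub.empty:
            continue
        if unit == "animal":
            sub = (sub.groupby(["group", "animal_id"], as_index=False)[measurement]
                   .mean())
        present = [g for g in GROUPS if (sub["group"] == g).sum() >= 2]
        if len(present) < 2:
            reports[region] = RegionReport(
                region, measurement, present, None, None,
                skipped="fewer than 2 groups with n >= 2",
            )
            continue
        samples = [sub.loc[sub["group"] == g, measurement].to_numpy() for g in present]
        anova = one_way_anova(samples)
        posthoc = tukey_kramer(samples, alpha=alpha)
        sig = [(present[i], present[j]) for (i, j) in posthoc.significant_pairs()]
        reports[region] = RegionReport(region, measurement, present, anova, posthoc, sig)
    return reports


def region_report_frame(reports: dict[str, RegionReport]) -> pd.DataFrame:
    """Flatten per-region reports into the CSV layout
    region,measurement,F,df1,df2,p,pair,mean_diff,q,p_adj,flag."""
    rows: list[dict[str, Any]] = []
    for rep in reports.values():
        rows.extend(rep.to_rows())
    cols = ["region", "measurement", "F", "df1", "df2", "p",
            "pair", "mean_diff", "q", "p_adj", "flag"]
    return pd.DataFrame(rows, columns=cols)


def xfm_group_compare(
    cell_means: pd.DataFrame,
    value_col: str = "mean_density",
) -> dict[str, WilcoxonResult]:
    """Per-element Wilcoxon comparison of ICHD-bearing vs normal cells.

    ``cell_means`` needs columns ``element``, ``cell_class`` (normal | ichd)
    and the value column of per-cell mean densities (ng/mm²).  One raw
    two-sided p per element, no multiplicity correction.  Elements missing a
    class are skipped.
    """
    required = {"element", "cell_class", value_col}
    missing = required - set(cell_means.columns)
    if missing:
        raise ValueError(f"cell-means table missing columns: {sorted(missing)}")
    out: dict[str, WilcoxonResult] = {}
    for element, sub in cell_means.groupby("element", sort=True):
        ichd = sub.loc[sub["cell_class"] == "ichd", value_col].to_numpy()
        normal = sub.loc[sub["cell_class"] == "normal", value_col].to_numpy()
        if len(ichd) == 0 or len(normal) == 0:
            continue
        out[str(element)] = wilcoxon_rank_sum(ichd, normal)
    return out
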