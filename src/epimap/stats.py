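"""Group comparisons, correlations, and perfusate statistics.

The group test is an exact two-sided Mann-Whitney U: with small samples
(n1 + n2 <= 14) the permutation null is enumerated over all
C(n1 + n2, n1) group assignments of the pooled observed values (ties kept,
half-counts in U), and the two-sided p is twice the smaller tail
probability, capped at 1. With n = 4 vs 4 this yields the familiar ladder
2/70, 4/70, 8/70, 14/70, 24/70, ... for U = 0, 1, 2, 3, 4. Larger samples
fall back to the tie-corrected normal approximation with continuity
correction.

Pearson correlations are graded weak (|r| < 0.3), moderate
(0.3 <= |r| < 0.7), or strong (|r| >= 0.7). Lactate trends are the slope
between the first and last arterial sample after reperfusion (uM/min). No
multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import PairingError, ParameterError
from .recording import PerfusateSample
from .substrate import HeartSummary

EXACT_LIMIT = 14  # pooled size up to which the permutation null is enumerated


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float
    p_two_sided: float
    method: str  # exact | normal_approx
    n1: int
    n2: int


@dataclass(frozen=True)
class GroupComparison:
    """One Table-style row: medians (ranges) per group plus the exact U test."""

    parameter: str
    ventricle: str
    group1_median: float
    group1_range: tuple[float, float]
    group2_median: float
    group2_range: tuple[float, float]
    u_statistic: float
    p_two_sided: float
    method: str


@dataclass(frozen=True)
class CorrelationEntry:
    var_x: str
    var_y: str
    r: float
    p_two_sided: float
    strength: Optional[str]  # weak | moderate | strong; None if undefined
    n: int = 0
    significant: bool = False


@dataclass(frozen=True)
class LactateTrend:
    heart_id: str
    slope_um_min: float
    first_sample: tuple[float, float]  # (time_min, mmol/l)
    last_sample: tuple[float, float]


@dataclass(frozen=True)
class RegionComparison:
    parameter: str
    groups: dict
    f_statistic: float
    p_value: float


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U = #{(x in a, y in b): y < x} + 1/2 per tie."""
    a = a[:, None]
    b = b[None, :]
    return float(np.sum(b < a) + 0.5 * np.sum(b == a))


def exact_mann_whitney(a: Sequence[float], b: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test, exact for pooled sizes <= 14.

    The exact two-sided p doubles the smaller of P(U <= U_obs) and
    P(U >= U_obs) over the full enumeration of group assignments of the
    pooled (possibly tied) values, capped at 1.
    """
    a = np.asarray(list(a), float)
    b = np.asarray(list(b), float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    u_obs = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    n = n1 + n2
    if n <= EXACT_LIMIT:
        idx = np.arange(n)
        us = []
        for comb in combinations(idx, n1):
            sel = np.zeros(n, bool)
            sel[list(comb)] = True
            us.append(_u_statistic(pooled[sel], pooled[~sel]))
        us = np.asarray(us)
        total = us.size
        eps = 1e-9
        p_low = np.count_nonzero(us <= u_obs + eps) / total
        p_high = np.count_nonzero(us >= u_obs - eps) / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        return MannWhitneyResult(u_obs, p, "exact", n1, n2)
    # tie-corrected normal approximation with continuity correction
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return MannWhitneyResult(u_obs, 1.0, "normal_approx", n1, n2)
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
    return MannWhitneyResult(u_obs, p, "normal_approx", n1, n2)


def classify_strength(r: float) -> str:
    """Correlation strength grade on |r|: <0.3 weak, <0.7 moderate, else strong."""
    a = abs(r)
    if a < 0.3:
        return "weak"
    if a < 0.7:
        return "moderate"
    return "strong"


def pearson_correlation(
    x: Sequence[float], y: Sequence[float],
    var_x: str = "x", var_y: str = "y",
    alpha: float = 0.05,
) -> CorrelationEntry:
    """Pearson r with a two-sided t-based p and a strength grade.

    Zero-variance input yields an entry with NaN r and no strength grade
    (reported missing rather than raised).
    """
    x = np.asarray(list(x), float)
    y = np.asarray(list(y), float)
    if x.size != y.size:
        raise ParameterError("x and y must have equal length")
    if x.size < 3:
        raise ParameterError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationEntry(var_x, var_y, float("nan"), float("nan"),
                                None, int(x.size), False)
    res = sps.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    return CorrelationEntry(var_x, var_y, r, p, classify_strength(r),
                            int(x.size), p <= alpha)


def lactate_trend(series: Sequence[PerfusateSample]) -> LactateTrend:
    """Slope (uM/min) between the first and last arterial sample.

    Venous samples are ignored; intermediate arterial samples do not affect
    the result.
    """
    arterial = sorted((s for s in series if s.site == "arterial"),
                      key=lambda s: s.time_min)
    if len(arterial) < 2:
        raise ParameterError("need >= 2 arterial samples")
    first, last = arterial[0], arterial[-1]
    slope = (last.lactate_mmol_l - first.lactate_mmol_l) / (
        last.time_min - first.time_min) * 1000.0
    return LactateTrend(
        heart_id=first.heart_id,
        slope_um_min=float(slope),
        first_sample=(first.time_min, first.lactate_mmol_l),
        last_sample=(last.time_min, last.lactate_mmol_l),
    )


def av_lactate_difference(
    arterial: Sequence[PerfusateSample], venous: Sequence[PerfusateSample]
) -> list[tuple[float, float]]:
    """Arteriovenous lactate difference (arterial - venous) per time point."""
    art = sorted(arterial, key=lambda s: s.time_min)
    ven = sorted(venous, key=lambda s: s.time_min)
    if len(art) != len(ven) or any(
        a.time_min != v.time_min for a, v in zip(art, ven)
    ):
        raise PairingError("arterial and venous series have mismatched times")
    return [(a.time_min, a.lactate_mmol_l - v.lactate_mmol_l)
            for a, v in zip(art, ven)]


def unpaired_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Pooled-variance two-sample t test (t, two-sided p)."""
    a = np.asarray(list(a), float)
    b = np.asarray(list(b), float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("need n >= 2 per group")
    if np.ptp(np.concatenate([a, b])) == 0:
        raise ParameterError("zero pooled variance")
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def one_way_anova(groups: dict) -> RegionComparison:
    """Classical one-way ANOVA across labelled groups (e.g. regions)."""
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ParameterError("need >= 2 groups with n >= 2 each")
    arrays = [np.asarray(list(v), float) for v in groups.values()]
    if all(np.ptp(arr) == 0 for arr in arrays) and np.ptp(np.concatenate(arrays)) == 0:
        raise ParameterError("degenerate: all values identical")
    f, p = sps.f_oneway(*arrays)
    return RegionComparison(parameter="", groups=dict(groups),
                            f_statistic=float(f), p_value=float(p))


#: (column on HeartSummary, report label, sign for display)
_TABLE_PARAMS = [
    ("n_potentials", "Number of potentials", 1.0),
    ("median_voltage_mv", "Voltage (mV)", 1.0),
    ("pct_low_voltage", "Low voltage (%)", 1.0),
    ("median_slope_v_s", "Slope (-V/s)", -1.0),
    ("median_cv_cm_s", "Conduction velocity (cm/s)", 1.0),
    ("pct_block", "Conduction block (%)", 1.0),
]


def group_compare_table(
    summaries: Sequence[HeartSummary], groups: dict
) -> tuple[list[GroupComparison], pd.DataFrame]:
    """Per-parameter, per-ventricle group comparison with exact U tests.

    ``groups`` maps heart_id -> 'group1' | 'group2'. Slope rows are
    reported as magnitudes (the internal sign convention is negative).
    """
    comparisons: list[GroupComparison] = []
    for ventricle in ("RV", "LV"):
        vs = [s for s in summaries if s.ventricle == ventricle]
        for attr, label, sign in _TABLE_PARAMS:
            g1 = [sign * getattr(s, attr) for s in vs if groups[s.heart_id] == "group1"]
            g2 = [sign * getattr(s, attr) for s in vs if groups[s.heart_id] == "group2"]
            g1 = [v for v in g1 if np.isfinite(v)]
            g2 = [v for v in g2 if np.isfinite(v)]
            if not g1 or not g2:
                continue
            mw = exact_mann_whitney(g1, g2)
            comparisons.append(
                GroupComparison(
                    parameter=label,
                    ventricle=ventricle,
                    group1_median=float(np.median(g1)),
                    group1_range=(float(min(g1)), float(max(g1))),
                    group2_median=float(np.median(g2)),
                    group2_range=(float(min(g2)), float(max(g2))),
                    u_statistic=mw.u_statistic,
                    p_two_sided=mw.p_two_sided,
                    method=mw.method,
                )
            )
    df = pd.DataFrame(
        {
            "ventricle": c.ventricle,
            "parameter": c.parameter,
            "group1": f"{c.group1_median:.1f} ({c.group1_range[0]:.1f}-{c.group1_range[1]:.1f})",
            "group2": f"{c.group2_median:.1f} ({c.group2_range[0]:.1f}-{c.group2_range[1]:.1f})",
            "U": c.u_statistic,
            "p": round(c.p_two_sided, 3),
            "method": c.method,
        }
        for c in comparisons
    )
    return comparisons, df


def correlation_matrix(
    variables: pd.DataFrame, alpha: float = 0.05
) -> tuple[list[CorrelationEntry], pd.DataFrame]:
    """All pairwise Pearson correlations of per-heart variables.

    ``variables``: one row per heart, numeric columns only. Pairs with a
    zero-variance member are skipped. Returns the entries and the symmetric
    r matrix (diagonal 1).
    """
    if len(variables) < 3:
        raise ParameterError("need >= 3 hearts with complete variables")
    cols = list(variables.columns)
    rmat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    entries: list[CorrelationEntry] = []
    for i, x in enumerate(cols):
        for y in cols[i + 1:]:
            sub = variables[[x, y]].dropna()
            if len(sub) < 3:
                continue
            entry = pearson_correlation(sub[x], sub[y], x, y, alpha)
            if entry.strength is None:
                continue
            entries.append(entry)
            rmat.loc[x, y] = rmat.loc[y, x] = entry.r
    return entries, rmat


def render_correlation_matrix(rmat: pd.DataFrame, path) -> None:
    """Render the correlation matrix as a colour-coded grid."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.45 * len(rmat) + 2,) * 2)
    im = ax.imshow(rmat.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(rmat)), rmat.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(rmat)), rmat.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
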