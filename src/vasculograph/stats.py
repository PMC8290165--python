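"""Normality-gated two-group comparison of network metrics.

Each metric is tested for normality in both groups with a one-sample
Kolmogorov-Smirnov test against a normal with estimated mean/SD (the
Lilliefors correction, since the population parameters are unknown). If
both groups look normal at α = 0.05 the groups are compared with a
two-sided Student's t-test (equal variances by default, Welch available)
and summarized as mean ± SD; otherwise with a two-sided Mann-Whitney U test
and summarized as median (25th–75th IQR). No multiple-testing correction is
applied across metrics; the report notes this.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .volume import warn

__all__ = [
    "test_normality",
    "compare_groups",
    "batch_compare",
    "GroupComparisonResult",
    "DEFAULT_METRICS",
]

ALPHA = 0.05
DEFAULT_METRICS = ("cc", "nse", "apl")


def test_normality(sample) -> tuple[float, float, bool]:
    """Lilliefors-corrected KS normality test → (statistic, p, is_normal).

    ``is_normal`` is ``p ≥ 0.05``. A constant sample has no defined SD and
    is reported non-normal with a warning.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("normality test needs at least 3 observations")
    if np.ptp(x) < 1e-15 or np.std(x, ddof=1) < 1e-15:
        warn("constant sample: degenerate SD, treated as non-normal")
        return float("nan"), 0.0, False
    stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    return float(stat), float(p), bool(p >= ALPHA)


@dataclass
class GroupComparisonResult:
    """Two-group comparison of one metric, in the reporting convention of
    normality-gated studies: mean ± SD with Student's t when both groups are
    normal, otherwise median (IQR) with Mann-Whitney U."""

    metric_name: str
    group_labels: tuple[str, str]
    summaries: tuple[str, str]
    group_means: tuple[float, float]
    test_used: str  # students_t | mann_whitney_u
    statistic: float
    p_value: float
    alpha: float = ALPHA
    normal: tuple[bool, bool] = (True, True)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _summary(x: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{np.mean(x):.4g} ± {np.std(x, ddof=1):.4g}"
    q25, q50, q75 = np.percentile(x, [25, 50, 75])
    return f"{q50:.4g} ({q25:.4g}~{q75:.4g})"


def compare_groups(
    a,
    b,
    group_labels: tuple[str, str] = ("group_a", "group_b"),
    metric_name: str = "",
    equal_var: bool = True,
) -> GroupComparisonResult:
    """Two-sided two-group test, gated on normality of both samples."""
    xa, xb = np.asarray(a, float), np.asarray(b, float)
    if xa.size < 3 or xb.size < 3:
        raise ValueError("each group needs at least 3 observations")
    _, _, norm_a = test_normality(xa)
    _, _, norm_b = test_normality(xb)
    if norm_a and norm_b:
        stat, p = sps.ttest_ind(xa, xb, equal_var=equal_var)
        test_used = "students_t" if equal_var else "welch_t"
    else:
        stat, p = sps.mannwhitneyu(xa, xb, alternative="two-sided")
        test_used = "mann_whitney_u"
    return GroupComparisonResult(
        metric_name=metric_name,
        group_labels=tuple(group_labels),
        summaries=(_summary(xa, norm_a and norm_b), _summary(xb, norm_a and norm_b)),
        group_means=(float(np.mean(xa)), float(np.mean(xb))),
        test_used=test_used,
        statistic=float(stat),
        p_value=float(p),
        normal=(norm_a, norm_b),
    )


def batch_compare(
    table: pd.DataFrame,
    group_col: str = "group",
    metrics: tuple[str, ...] = DEFAULT_METRICS,
    equal_var: bool = True,
) -> list[GroupComparisonResult]:
    """One comparison per metric column of a tidy per-specimen table."""
    groups = sorted(table[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    missing = [m for m in metrics if m not in table.columns]
    if missing:
        raise ValueError(f"missing metric column(s): {missing}")
    ga = table[table[group_col] == groups[0]]
    gb = table[table[group_col] == groups[1]]
    return [
        compare_groups(
            ga[m].to_numpy(),
            gb[m].to_numpy(),
            group_labels=(str(groups[0]), str(groups[1])),
            metric_name=m,
            equal_var=equal_var,
        )
        for m in metrics
    ]


def results_table(results: list[GroupComparisonResult]) -> pd.DataFrame:
    """Comparison results as a two-row-header style table (value, value, P)."""
    rows = []
    for r in results:
        rows.append(
            {
                "metric": r.metric_name,
                r.group_labels[0]: r.summaries[0],
                r.group_labels[1]: r.summaries[1],
                "test": r.test_used,
                "P": f"{r.p_value:.4g}",
            }
        )
    return pd.DataFrame(rows)


def format_report(results: list[GroupComparisonResult]) -> str:
    table = results_table(results).to_string(index=False)
    return table + "\nNote: no multiple-testing correction applied across metrics."


def write_results(results: list[GroupComparisonResult], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([r.to_dict() for r in results], indent=2, sort_keys=True)
    )
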