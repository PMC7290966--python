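"""Group-comparison statistics for cohort-level model parameters.

Thin, validated wrappers over scipy/statsmodels implementing the
comparison battery used on per-subject outcomes (Tc, T*, best Mantel r,
direct SC-FC r, dimensionality): Welch two-sample t, paired t, one-way
ANOVA, and Benjamini-Hochberg FDR adjustment. All p-values are
two-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparisonResult",
    "welch_t_test",
    "paired_t_test",
    "one_way_anova",
    "fdr_adjust",
    "posthoc_vs_control",
]


@dataclass(frozen=True)
class GroupComparisonResult:
    statistic: float
    df: float | tuple[float, float]
    p_two_tailed: float
    comparison_label: str = ""
    adjusted_p: float | None = None

    def with_adjusted(self, adj: float) -> "GroupComparisonResult":
        return GroupComparisonResult(
            statistic=self.statistic,
            df=self.df,
            p_two_tailed=self.p_two_tailed,
            comparison_label=self.comparison_label,
            adjusted_p=float(adj),
        )


def _clean(sample, name: str) -> np.ndarray:
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError(f"{name} must be a 1-D sample with n >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def welch_t_test(x, y, label: str = "") -> GroupComparisonResult:
    """Welch two-sample t-test (unequal variances, Satterthwaite df)."""
    x, y = _clean(x, "x"), _clean(y, "y")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    return GroupComparisonResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_two_tailed=float(res.pvalue),
        comparison_label=label,
    )


def paired_t_test(x, y, label: str = "") -> GroupComparisonResult:
    """Paired t-test: one-sample t on the index-paired differences."""
    x, y = _clean(x, "x"), _clean(y, "y")
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    d = x - y
    if d.var(ddof=1) == 0:
        raise ValueError("paired differences have zero variance")
    res = stats.ttest_rel(x, y)
    return GroupComparisonResult(
        statistic=float(res.statistic),
        df=float(x.size - 1),
        p_two_tailed=float(res.pvalue),
        comparison_label=label,
    )


def one_way_anova(groups: list, label: str = "") -> GroupComparisonResult:
    """One-way ANOVA: F = MS_between / MS_within, df = (k-1, n-k)."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    gs = [_clean(g, f"group {i}") for i, g in enumerate(groups)]
    if all(g.var(ddof=1) == 0 for g in gs):
        raise ValueError("every group has zero within-group variance")
    res = stats.f_oneway(*gs)
    k = len(gs)
    n_total = sum(g.size for g in gs)
    return GroupComparisonResult(
        statistic=float(res.statistic),
        df=(float(k - 1), float(n_total - k)),
        p_two_tailed=float(res.pvalue),
        comparison_label=label,
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def posthoc_vs_control(
    control, patient_groups: dict[str, np.ndarray]
) -> list[GroupComparisonResult]:
    """Pairwise Welch t of each patient group against the control group.

    The family for FDR adjustment is the set of group-vs-control
    contrasts; adjusted p-values are attached to each result.
    """
    if not patient_groups:
        raise ValueError("no patient groups supplied")
    results = [
        welch_t_test(control, sample, label=f"HC_vs_{name}")
        for name, sample in patient_groups.items()
    ]
    adj = fdr_adjust([r.p_two_tailed for r in results])
    return [r.with_adjusted(a) for r, a in zip(results, adj)]
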