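"""Normality-gated group comparisons and fold-change summaries.

The comparison scheme mirrors common practice in functional immunology:
every group is first screened with the Shapiro-Wilk test at alpha = 0.05;
if all groups look Gaussian the comparison is parametric (Student's t for
two groups, one-way ANOVA with a Tukey HSD post hoc for three or more),
otherwise a Mann-Whitney U test is used.  If *any* group fails normality
the whole comparison goes nonparametric — the conservative reading of a
per-comparison gate.  All tests are two-sided with significance declared
at p < 0.05.

The module owns the gating, orchestration and reporting; the test
internals are delegated to scipy.stats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "normality_gate",
    "compare_two",
    "compare_many",
    "fold_change",
]

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class GroupSummary:
    name: str
    n: int
    mean: float
    median: float
    sd: float
    sem: float


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one group comparison.

    ``gate`` records whether the parametric or nonparametric route was
    taken; ``posthoc`` (multi-group only) holds the pairwise Tukey table
    with both adjusted and unadjusted p-values.
    """

    test_name: str
    statistic: float
    p_value: float
    groups: tuple[GroupSummary, ...]
    alpha: float
    significant: bool
    gate: str
    posthoc: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value out of [0, 1]: {self.p_value}")


def _summarize(name: str, x: np.ndarray) -> GroupSummary:
    n = len(x)
    sd = float(np.std(x, ddof=1)) if n >= 2 else float("nan")
    return GroupSummary(
        name=name,
        n=n,
        mean=float(np.mean(x)),
        median=float(np.median(x)),
        sd=sd,
        sem=sd / np.sqrt(n) if n >= 2 else float("nan"),
    )


def _clean(samples) -> list[np.ndarray]:
    out = []
    for s in samples:
        x = np.asarray(s, dtype=float)
        if x.size == 0:
            raise ValidationError("empty group")
        out.append(x)
    return out


def normality_gate(samples, alpha: float = ALPHA_DEFAULT) -> str:
    """'parametric' iff every group passes Shapiro-Wilk at ``alpha``.

    Groups with fewer than three observations cannot be screened; the
    comparison then falls back to nonparametric with a warning.
    """
    groups = _clean(samples)
    for x in groups:
        if len(x) < 3:
            warnings.warn(
                "group with n < 3 cannot be tested for normality; "
                "falling back to nonparametric",
                stacklevel=2,
            )
            return "nonparametric"
    for x in groups:
        if np.ptp(x) == 0:
            return "nonparametric"  # Shapiro-Wilk undefined for constant data
        if stats.shapiro(x).pvalue < alpha:
            return "nonparametric"
    return "parametric"


def compare_two(
    a,
    b,
    gate: str | None = None,
    paired: bool = False,
    alpha: float = ALPHA_DEFAULT,
) -> ComparisonResult:
    """Two-group comparison: Student's t (parametric) or Mann-Whitney U.

    ``gate`` may carry a precomputed :func:`normality_gate` result;
    when omitted the gate is evaluated here.  Paired data use the paired t
    or Wilcoxon signed-rank test.
    """
    xa, xb = _clean([a, b])
    if paired and len(xa) != len(xb):
        raise ValidationError("paired comparison needs equal group sizes")
    route = gate or normality_gate([xa, xb], alpha=alpha)
    if route not in ("parametric", "nonparametric"):
        raise ValueError(f"gate must be 'parametric' or 'nonparametric', got {route!r}")

    if route == "parametric":
        if paired:
            res = stats.ttest_rel(xa, xb)
            name = "paired t-test"
        else:
            res = stats.ttest_ind(xa, xb)
            name = "Student's t-test"
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        if paired:
            res = stats.wilcoxon(xa, xb)
            name = "Wilcoxon signed-rank"
        else:
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            name = "Mann-Whitney U"
        statistic, p = float(res.statistic), float(res.pvalue)

    return ComparisonResult(
        test_name=name,
        statistic=statistic,
        p_value=p,
        groups=(_summarize("a", xa), _summarize("b", xb)),
        alpha=alpha,
        significant=p < alpha,
        gate=route,
    )


def compare_many(
    groups,
    names: list[str] | None = None,
    alpha: float = ALPHA_DEFAULT,
) -> ComparisonResult:
    """One-way ANOVA with a Tukey HSD post hoc over three or more groups.

    The post hoc table reports, per pair, the mean difference, the
    Tukey-adjusted p-value and the unadjusted pooled-variance t-test
    p-value (the adjusted value can never be smaller).
    """
    xs = _clean(groups)
    if len(xs) < 3:
        raise ValidationError(
            "compare_many needs >= 3 groups; use compare_two for two"
        )
    names = names or [f"g{i}" for i in range(len(xs))]
    if len(names) != len(xs):
        raise ValidationError("names must match the number of groups")
    if all(np.ptp(x) == 0 for x in xs) and len({float(x[0]) for x in xs}) == 1:
        raise ValidationError("degenerate input: all groups constant and equal")

    f_res = stats.f_oneway(*xs)
    if not np.isfinite(f_res.pvalue):
        raise ValidationError("ANOVA undefined for these groups (zero variance?)")

    # Tukey HSD plus unadjusted pairwise p from the same pooled error.
    n_total = sum(len(x) for x in xs)
    k = len(xs)
    grand_means = [float(np.mean(x)) for x in xs]
    df_err = n_total - k
    mse = sum(np.sum((x - m) ** 2) for x, m in zip(xs, grand_means)) / df_err

    tukey = stats.tukey_hsd(*xs)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = grand_means[i] - grand_means[j]
            se = np.sqrt(mse * (1.0 / len(xs[i]) + 1.0 / len(xs[j])))
            t_stat = diff / se if se > 0 else np.inf
            p_unadj = 2.0 * stats.t.sf(abs(t_stat), df_err)
            rows.append(
                {
                    "group1": names[i],
                    "group2": names[j],
                    "mean_diff": diff,
                    "p_adj": float(tukey.pvalue[i, j]),
                    "p_unadj": float(p_unadj),
                }
            )
    posthoc = pd.DataFrame(rows)

    return ComparisonResult(
        test_name="one-way ANOVA + Tukey HSD",
        statistic=float(f_res.statistic),
        p_value=float(f_res.pvalue),
        groups=tuple(_summarize(n, x) for n, x in zip(names, xs)),
        alpha=alpha,
        significant=float(f_res.pvalue) < alpha,
        gate="parametric",
        posthoc=posthoc,
    )


def fold_change(numerator, denominator) -> float:
    """Ratio of group means for normalized quantities (e.g. glycogen per
    protein).  The denominator group mean must be positive."""
    num, den = _clean([numerator, denominator])
    den_mean = float(np.mean(den))
    if den_mean <= 0:
        raise ValidationError("denominator group mean must be positive")
    return float(np.mean(num)) / den_mean
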