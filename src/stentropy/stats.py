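"""Group statistics on E_d: ANOVA, Welch pairwise tests, Lilliefors normality.

The comparison protocol: a one-way ANOVA across rhythm groups, followed by
post-hoc two-tailed unpaired t-tests that do not assume equal variance
(Welch), declared significant below a Bonferroni-corrected critical value of
0.0125 (alpha 0.05).  Normality of each group is checked with the Lilliefors
test; its p-value is obtained by seeded Monte-Carlo simulation of the null
(normal samples with estimated mean/sd) rather than truncated lookup tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

CORRECTED_CRITICAL = 0.0125
DEFAULT_MC_REPLICATES = 10_000


@dataclass
class PairResult:
    t: float
    p: float
    significant: bool


@dataclass
class GroupComparison:
    groups: dict[str, np.ndarray]
    anova_f: float
    anova_p: float
    pairwise: dict[tuple[str, str], PairResult]
    corrected_critical: float
    normality: dict[str, tuple[float, float]]
    excluded: list[str] = field(default_factory=list)


def welch_ttest(a, b) -> tuple[float, float]:
    """Two-tailed unpaired t-test without the equal-variance assumption."""
    t, p = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(t), float(p)


def _lilliefors_stat(x: np.ndarray) -> float:
    n = x.size
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_plus = (i / n - cdf).max()
    d_minus = (cdf - (i - 1) / n).max()
    return float(max(d_plus, d_minus))


def _lilliefors_null_table(
    n: int, replicates: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo null distribution of the Lilliefors statistic at sample
    size n (statistic is location/scale free, so standard normals suffice)."""
    x = rng.standard_normal((replicates, n))
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
    x.sort(axis=1)
    cdf = sps.norm.cdf(x)
    i = np.arange(1, n + 1)
    d_plus = (i / n - cdf).max(axis=1)
    d_minus = (cdf - (i - 1) / n).max(axis=1)
    return np.maximum(d_plus, d_minus)


def lilliefors(
    sample,
    mc_replicates: int = DEFAULT_MC_REPLICATES,
    seed: int = 0,
) -> tuple[float, float]:
    """Lilliefors normality test: KS distance to a normal with estimated
    mean/sd, Monte-Carlo p-value.

    Returns ``(statistic, p)``.  Requires n >= 4 and a non-degenerate sample.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValueError(f"Lilliefors test needs n >= 4, got n = {x.size}")
    if x.std(ddof=1) == 0:
        raise ValueError("constant sample: normality is undefined (sd = 0)")
    d = _lilliefors_stat(x)
    rng = np.random.default_rng(seed)
    null = _lilliefors_null_table(x.size, mc_replicates, rng)
    p = (1 + int((null >= d).sum())) / (mc_replicates + 1)
    return d, float(p)


def compare_groups(
    ed_by_label: dict[str, "np.ndarray | list[float]"],
    alpha: float = CORRECTED_CRITICAL,
    mc_replicates: int = DEFAULT_MC_REPLICATES,
    seed: int = 0,
) -> GroupComparison:
    """One-way ANOVA plus Welch pairwise tests at the corrected critical value.

    Degenerate groups (n < 3 or zero variance) are flagged and excluded from
    the pairwise tests and the ANOVA.  At least two valid groups are required.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in ed_by_label.items()}
    excluded = [k for k, v in groups.items() if v.size < 3 or np.ptp(v) == 0]
    valid = {k: v for k, v in groups.items() if k not in excluded}
    if len(valid) < 2:
        raise ValueError(
            f"need >= 2 non-degenerate groups with n >= 3; excluded: {excluded}"
        )
    f, p_anova = sps.f_oneway(*valid.values())
    if f < 0:  # identical groups: numerical noise below zero, p comes out nan
        f, p_anova = 0.0, 1.0
    pairwise: dict[tuple[str, str], PairResult] = {}
    for a, b in combinations(sorted(valid), 2):
        t, p = welch_ttest(valid[a], valid[b])
        pairwise[(a, b)] = PairResult(t=t, p=p, significant=bool(p < alpha))
    normality = {}
    for i, (k, v) in enumerate(sorted(valid.items())):
        normality[k] = lilliefors(v, mc_replicates=mc_replicates, seed=seed + i)
    return GroupComparison(
        groups=groups,
        anova_f=float(f),
        anova_p=float(p_anova),
        pairwise=pairwise,
        corrected_critical=alpha,
        normality=normality,
        excluded=excluded,
    )
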