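"""Effect sizes, two-sample t-test power and sample inclusion criteria.

The inclusion rule for the liquid-solid correlation analysis derives from a
power calculation on pilot effect sizes: the number of cells per group needed
for 0.8 power at the observed Cohen's d set the minimum of 20 HD-CTCs on the
first two scanned slides; touch preps must offer at least 4 reliably
segmentable monolayer clusters of intact tumor cells. Power is computed
exactly from the noncentral t distribution (ncp = d * sqrt(n/2), df = 2n - 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np
from scipy import stats

__all__ = [
    "PowerSpec",
    "InclusionDecision",
    "cohens_d",
    "power_two_sample_t",
    "n_for_power",
    "check_inclusion",
    "compare_concentrations",
]


@dataclass(frozen=True)
class PowerSpec:
    """Significance level, target power and sidedness of the t-test."""

    alpha: float = 0.05
    power: float = 0.8
    alternative: str = "two-sided"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        if self.alternative not in ("two-sided", "one-sided"):
            raise ValueError("alternative must be 'two-sided' or 'one-sided'")


def cohens_d(group_a, group_b) -> float:
    """Cohen's d with the pooled (n_a - 1, n_b - 1)-weighted sd.

    Returns NaN when the pooled sd is zero (flagged missing, not an error).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    pooled_var = (
        (len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)
    ) / (len(a) + len(b) - 2)
    if pooled_var == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


def power_two_sample_t(d: float, n_per_group: int, spec: PowerSpec = PowerSpec()) -> float:
    """Exact power of the two-sample t-test at effect size ``d`` and equal
    group size ``n_per_group`` (noncentral t)."""
    if n_per_group < 2:
        return 0.0
    df = 2 * n_per_group - 2
    ncp = abs(d) * math.sqrt(n_per_group / 2.0)
    if spec.alternative == "two-sided":
        crit = stats.t.ppf(1 - spec.alpha / 2, df)
        return float(
            stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp)
        )
    crit = stats.t.ppf(1 - spec.alpha, df)
    return float(stats.nct.sf(crit, df, ncp))


def n_for_power(d: float, spec: PowerSpec = PowerSpec()) -> int:
    """Smallest per-group n reaching the target power at effect size ``d``."""
    if abs(d) < 1e-6:
        raise ValueError("effect size too small: required n is unbounded")
    lo, hi = 2, 4
    while power_two_sample_t(d, hi, spec) < spec.power:
        hi *= 2
        if hi > 10**8:  # pragma: no cover - guarded by the d check above
            raise RuntimeError("power search failed to bracket")
    while lo < hi:
        mid = (lo + hi) // 2
        if power_two_sample_t(d, mid, spec) >= spec.power:
            hi = mid
        else:
            lo = mid + 1
    return lo


@dataclass
class InclusionDecision:
    """Eligibility of a matched liquid/solid sample pair."""

    liquid_count_first_2_slides: int
    solid_monolayer_clusters: int
    eligible: bool
    reasons: list[str] = field(default_factory=list)


def check_inclusion(
    liquid_count: int,
    monolayer_clusters: int,
    min_liquid: int = 20,
    min_clusters: int = 4,
    strict_clusters: bool = False,
) -> InclusionDecision:
    """Inclusion rule: >= 20 HD-CTCs on the first 2 liquid slides and at
    least ``min_clusters`` solid monolayer clusters of intact tumor cells
    (``strict_clusters`` switches the solid criterion to a strict >)."""
    reasons = []
    if liquid_count < min_liquid:
        reasons.append(
            f"liquid: {liquid_count} HD-CTCs on first 2 slides < minimum {min_liquid}"
        )
    ok_solid = (
        monolayer_clusters > min_clusters
        if strict_clusters
        else monolayer_clusters >= min_clusters
    )
    if not ok_solid:
        cmp = ">" if strict_clusters else ">="
        reasons.append(
            f"solid: {monolayer_clusters} monolayer clusters fails {cmp} {min_clusters}"
        )
    return InclusionDecision(
        liquid_count_first_2_slides=liquid_count,
        solid_monolayer_clusters=monolayer_clusters,
        eligible=not reasons,
        reasons=reasons,
    )


def compare_concentrations(
    values_a, values_b, paired: bool = False
) -> dict[str, float]:
    """Two-sided comparison of two concentration samples.

    Paired (pre- vs post-surgery of the same patients) uses the paired t-test;
    unpaired groups use Welch. Identical paired vectors have zero difference
    variance; by convention p = 1 (no evidence of change).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal lengths")
        if len(a) < 2:
            raise ValueError("need at least 2 pairs")
        diff = a - b
        if diff.std(ddof=1) == 0:
            t_stat, p = (0.0, 1.0) if diff.mean() == 0 else (float("inf"), 0.0)
        else:
            t_stat, p = stats.ttest_rel(a, b)
        return {
            "test": "paired-t",
            "t": float(t_stat),
            "p": float(p),
            "mean_difference": float(diff.mean()),
            "n": int(len(a)),
        }
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        t_stat, p = (0.0, 1.0) if a.mean() == b.mean() else (float("inf"), 0.0)
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "test": "welch-t",
        "t": float(t_stat),
        "p": float(p),
        "mean_difference": float(a.mean() - b.mean()),
        "n": int(len(a) + len(b)),
    }
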