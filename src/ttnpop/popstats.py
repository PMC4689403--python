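"""Carrier prevalence, confidence intervals and group comparison tests.

Carrier counting is allele-count based: for one variant, AC - hom_count
individuals carry it (heterozygotes once, homozygotes once).  Summing over
variants assumes no individual carries two distinct qualifying variants; at
the allele frequencies involved the resulting overcount is below k^2/(2n) and
is documented rather than corrected.

Confidence intervals use the Wilson score interval by default, with
Clopper-Pearson exact as the alternative; both come from statsmodels.  No
multiple-testing correction is applied anywhere; all p-values are nominal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from ttnpop.consequence import ConsequenceCall

WILSON = "wilson"
CLOPPER_PEARSON = "clopper_pearson"
_SM_METHOD = {WILSON: "wilson", CLOPPER_PEARSON: "beta"}


@dataclass(frozen=True)
class PrevalenceEstimate:
    carriers: int
    cohort: int
    prevalence: float  # percent
    ci_low: float  # percent
    ci_high: float  # percent
    ci_method: str
    level: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.prevalence + 1e-9):
            raise ValueError("ci_low above the point estimate")
        if not (self.prevalence - 1e-9 <= self.ci_high <= 100.0):
            raise ValueError("ci_high below the point estimate")


def carriers_from_calls(calls: list[ConsequenceCall]) -> int:
    """Total carriers: sum over calls of AC - hom_count."""
    total = 0
    for call in calls:
        rec = call.record
        if 2 * rec.hom_count > rec.AC:
            raise ValueError(
                f"{call.key}: hom_count {rec.hom_count} inconsistent with AC {rec.AC}"
            )
        total += rec.AC - rec.hom_count
    return total


def prevalence(k: int, n: int) -> float:
    """Point prevalence in percent: 100 k / n."""
    if n <= 0:
        raise ValueError("cohort size must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"carrier count {k} outside [0, {n}]")
    return 100.0 * k / n


def binomial_ci(
    k: int, n: int, method: str = WILSON, level: float = 0.95
) -> tuple[float, float]:
    """Binomial proportion CI in percent (Wilson score or Clopper-Pearson)."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"invalid confidence level {level}")
    if method not in _SM_METHOD:
        raise ValueError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method=_SM_METHOD[method])
    return 100.0 * float(lo), 100.0 * float(hi)


def prevalence_estimate(
    k: int, n: int, method: str = WILSON, level: float = 0.95
) -> PrevalenceEstimate:
    lo, hi = binomial_ci(k, n, method, level)
    return PrevalenceEstimate(
        carriers=k,
        cohort=n,
        prevalence=prevalence(k, n),
        ci_low=lo,
        ci_high=hi,
        ci_method=method,
        level=level,
    )


def one_in_n(prevalence_percent: float) -> int:
    """'One in N' carrier figure: round(100 / prevalence%); exact, not display-rounded."""
    if prevalence_percent <= 0:
        raise ValueError("prevalence must be positive")
    return round(100.0 / prevalence_percent)


def format_one_in(prevalence_percent: float, nearest: int = 50) -> str:
    """Display form rounded to the nearest ``nearest`` (e.g. '≈1 in 500')."""
    n = one_in_n(prevalence_percent)
    display = max(nearest, int(round(n / nearest)) * nearest)
    return f"≈1 in {display}"


def group_chi_square(groups: dict[str, tuple[int, int]]) -> tuple[float, int, float]:
    """Chi-square homogeneity test of carrier proportions across groups.

    ``groups`` maps a label to (carriers, group size).  Returns (statistic,
    degrees of freedom, p).  A warning note is attached to the result when an
    expected cell falls below 1 via ``group_chi_square_details``.
    """
    stat, df, p, _ = group_chi_square_details(groups)
    return stat, df, p


def group_chi_square_details(groups):
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    table = []
    for label, (k, n) in groups.items():
        if n <= 0:
            raise ValueError(f"group {label} has non-positive size")
        if k > n:
            raise ValueError(f"group {label}: carriers exceed size")
        table.append([k, n - k])
    result = stats.chi2_contingency(table, correction=False)
    warning = None
    if (result.expected_freq < 1).any():
        warning = "expected cell below 1; chi-square approximation is unreliable"
    return float(result.statistic), int(result.dof), float(result.pvalue), warning


def pairwise_prop_test(
    k1: int, n1: int, k2: int, n2: int, method: str = "fisher"
) -> float:
    """Two-sided p for a difference in carrier proportions between two groups.

    Default is Fisher's exact on the 2x2 carriers/non-carriers table;
    ``method='chi2'`` uses the chi-square test without continuity correction.
    """
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    if method == "fisher":
        _, p = stats.fisher_exact(table, alternative="two-sided")
    elif method == "chi2":
        p = float(stats.chi2_contingency(table, correction=False).pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(p)


def hwe_het_hom_ratio(q: float) -> float:
    """Expected heterozygous carriers per homozygote under Hardy-Weinberg.

    With allele frequency q, 2 p q of individuals are heterozygous and q^2
    homozygous, so the ratio is 2 (1 - q) / q.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"allele frequency must be in (0, 1), got {q}")
    return 2.0 * (1.0 - q) / q


def allele_freq_from_hom(hom_count: int, cohort: int) -> float:
    """Allele frequency implied by an observed homozygote count: q = sqrt(h/n)."""
    if hom_count <= 0 or cohort <= 0 or hom_count > cohort:
        raise ValueError("invalid homozygote or cohort count")
    return math.sqrt(hom_count / cohort)


def coverage_fraction(coverage, keys, depth_threshold: float) -> float:
    """Fraction of queried variant positions with mean depth >= threshold.

    ``keys`` is an iterable of variant keys (chrom, pos, ref, alt) or
    (chrom, pos) pairs.  Raises listing any positions absent from the
    coverage table.
    """
    positions = []
    for key in keys:
        chrom, pos = key[0], key[1]
        positions.append((chrom, pos))
    if not positions:
        raise ValueError("no positions queried")
    missing = [p for p in positions if coverage.get(*p) is None]
    if missing:
        raise ValueError(f"positions missing from coverage: {missing[:10]}")
    covered = sum(
        1 for p in positions if coverage.get(*p).mean_depth >= depth_threshold
    )
    return covered / len(positions)
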