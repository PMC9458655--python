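"""Germline-somatic interaction statistics.

Exact binomial machinery for the allelic-shift, nominal-count, ordering and
enrichment tests, odds ratios from proportions, and the mutation-mCA
co-occurrence test.  The two-sided binomial uses tail doubling,
p = min(1, 2*min(P[X<=k], P[X>=k])), which is exact and symmetric at
p0 = 0.5 (the null all the shift tests use); the minimum-likelihood
convention is available behind ``method="minlike"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "binom_two_sided",
    "binom_one_sided_ge",
    "ShiftCount",
    "ShiftResult",
    "allelic_shift_test",
    "odds_ratio_from_props",
    "CooccurrenceResult",
    "cooccurrence_test",
    "OrderingResult",
    "clonal_order_test",
    "locus_enrichment",
]


def _check_kn(k: int, n: int, p0: float) -> None:
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"require 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"p0 must be in (0, 1), got {p0}")


def binom_two_sided(k: int, n: int, p0: float = 0.5, method: str = "double") -> float:
    """Exact two-sided binomial p-value.

    ``method='double'`` doubles the smaller tail (capped at 1);
    ``method='minlike'`` sums outcome probabilities <= P[X=k].  The two
    coincide for the symmetric p0 = 0.5 null.
    """
    _check_kn(k, n, p0)
    if method == "double":
        lower = sps.binom.cdf(k, n, p0)
        upper = sps.binom.sf(k - 1, n, p0)
        return float(min(1.0, 2.0 * min(lower, upper)))
    if method == "minlike":
        return float(sps.binomtest(k, n, p0, alternative="two-sided").pvalue)
    raise ValueError(f"unknown method {method!r}")


def binom_one_sided_ge(k: int, n: int, p0: float) -> float:
    """Exact upper-tail binomial p-value P[X >= k]."""
    _check_kn(k, n, p0)
    return float(sps.binom.sf(k - 1, n, p0))


# ---------------------------------------------------------------------------
# allelic shift
# ---------------------------------------------------------------------------


@dataclass
class ShiftCount:
    """Risk-haplotype shift events among informative heterozygous carriers.

    Counting rule per state: gain -> risk haplotype duplicated; loss ->
    risk haplotype retained; CNLOH -> risk haplotype duplicated.
    """

    state: str
    k_risk: int
    n_informative: int

    def __post_init__(self) -> None:
        if not (0 <= self.k_risk <= self.n_informative):
            raise ValueError("require 0 <= k_risk <= n_informative")


@dataclass
class ShiftResult:
    state: str
    k: int
    n: int
    p_value: float | None
    note: str = ""


def allelic_shift_test(shift: ShiftCount) -> ShiftResult:
    """Two-sided exact binomial test of the risk-haplotype shift against a
    50:50 null over informative heterozygous carriers."""
    if shift.n_informative == 0:
        return ShiftResult(shift.state, 0, 0, None, note="no informative carriers")
    p = binom_two_sided(shift.k_risk, shift.n_informative, 0.5)
    return ShiftResult(shift.state, shift.k_risk, shift.n_informative, p)


# ---------------------------------------------------------------------------
# odds ratios and co-occurrence
# ---------------------------------------------------------------------------


def odds_ratio_from_props(p1: float, p2: float) -> float:
    """Odds ratio between two proportions: [p1/(1-p1)] / [p2/(1-p2)]."""
    for name, p in (("p1", p1), ("p2", p2)):
        if not (0.0 < p < 1.0):
            raise ValueError(f"{name} must be strictly inside (0, 1), got {p}")
    return (p1 / (1.0 - p1)) / (p2 / (1.0 - p2))


@dataclass
class CooccurrenceResult:
    odds_ratio: float
    p_value: float
    method: str  # fisher_exact | chi2
    haldane: bool = False


def cooccurrence_test(table2x2, exact_max_n: int = 10_000) -> CooccurrenceResult:
    """Association test on a 2x2 count table.

    Uses Fisher's exact test for tables up to ``exact_max_n`` total counts
    and the chi-square test beyond; the odds ratio applies the Haldane
    +0.5 correction when a cell is zero.
    """
    t = np.asarray(table2x2, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("expected a nonnegative 2x2 table")
    n = t.sum()
    if n == 0:
        raise ValueError("empty table")
    haldane = bool(np.any(t == 0))
    tt = t + 0.5 if haldane else t
    odds_ratio = float((tt[0, 0] * tt[1, 1]) / (tt[0, 1] * tt[1, 0]))
    if n <= exact_max_n:
        _, p = sps.fisher_exact(t.astype(int))
        method = "fisher_exact"
    else:
        _, p, _, _ = sps.chi2_contingency(t, correction=True)
        method = "chi2"
    return CooccurrenceResult(odds_ratio=odds_ratio, p_value=float(p), method=method, haldane=haldane)


# ---------------------------------------------------------------------------
# clonal ordering
# ---------------------------------------------------------------------------


@dataclass
class OrderingResult:
    k_af_gt_cf: int
    n: int
    p_value: float | None
    tie_policy: str
    n_ties: int = 0
    note: str = ""


def clonal_order_test(records, tie_policy: str = "drop") -> OrderingResult:
    """Sign test of V617F allelic fraction exceeding mCA cellular fraction.

    ``records`` is an iterable of (v617f_af, mca_cf) pairs or a DataFrame
    with columns v617f_af and mca_cf.  A predominance of AF > CF indicates
    the point mutation preceded the chromosomal alteration.  Ties are
    dropped under the classical sign test (default) or split evenly under
    ``tie_policy='split'``.
    """
    if hasattr(records, "columns"):
        pairs = list(zip(records["v617f_af"], records["mca_cf"]))
    else:
        pairs = [(float(a), float(c)) for a, c in records]
    for af, cf in pairs:
        if not (0.0 < af <= 1.0) or not (0.0 < cf <= 1.0):
            raise ValueError("v617f_af and mca_cf must be in (0, 1]")
    k = sum(1 for af, cf in pairs if af > cf)
    ties = sum(1 for af, cf in pairs if af == cf)
    n = len(pairs)
    if tie_policy == "drop":
        n_eff, k_eff = n - ties, k
    elif tie_policy == "split":
        n_eff, k_eff = n, k + ties // 2
    else:
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    if n_eff == 0:
        return OrderingResult(0, 0, None, tie_policy, n_ties=ties, note="all pairs tied")
    p = binom_two_sided(k_eff, n_eff, 0.5)
    return OrderingResult(k_eff, n_eff, p, tie_policy, n_ties=ties)


def locus_enrichment(observed_k: int, n: int, reference_rate: float) -> float:
    """One-sided binomial enrichment of mCA counts at a locus against an
    external reference rate (e.g. ~3% in population-based surveys)."""
    if not (0.0 < reference_rate < 1.0):
        raise ValueError(f"reference_rate must be in (0, 1), got {reference_rate}")
    return binom_one_sided_ge(observed_k, n, reference_rate)
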