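"""Exact 2x2 association tests between genotype dichotomies and response.

The 2x2 table is oriented responders x feature:

    a = responders, feature-positive     b = responders, feature-negative
    c = comparators, feature-positive    d = comparators, feature-negative

The two-sided Fisher p-value follows the point-probability convention (the
default of R's ``fisher.test`` and scipy): conditioning on both margins,
sum the hypergeometric probabilities of every table no more likely than the
observed one, with a 1e-7 relative tie tolerance.  The odds ratio is the
cross-product (a*d)/(b*c); its confidence interval inverts the exact
conditional (noncentral hypergeometric) test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from .cohort import Cohort
from .enumeration import CandidateTest, admissible_tests, dichotomize

__all__ = ["ContingencyTable", "ContrastResult", "ContrastSummary",
           "CONTRASTS", "fisher_pvalues_by_count", "fisher_exact_two_sided",
           "odds_ratio_ci", "run_contrast"]

#: response contrasts: name -> (responder categories, comparator categories)
CONTRASTS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "good_vs_none": (("good",), ("none",)),
    "good_vs_modnone": (("good",), ("moderate", "none")),
    "goodmod_vs_none": (("good", "moderate"), ("none",)),
}

_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@lru_cache(maxsize=16384)
def fisher_pvalues_by_count(total_positive: int, n1: int, n2: int
                            ) -> np.ndarray:
    """Two-sided Fisher p for every feasible count ``a`` at fixed margins.

    Returns an array of length ``n1 + 1`` indexed by a = number of
    feature-positives among the n1 responders, given ``total_positive``
    feature-positives overall and group sizes (n1, n2).  Entries outside
    the hypergeometric support are 1.0.  Caching by margins is what makes
    the permutation and power loops cheap: a permutation never changes the
    margins, only ``a``.
    """
    lo = max(0, total_positive - n2)
    hi = min(total_positive, n1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n1 + n2, total_positive, n1)
    out = np.ones(n1 + 1)
    for idx, p_obs in enumerate(pmf):
        out[support[idx]] = pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum()
    np.minimum(out, 1.0, out=out)
    out.setflags(write=False)
    return out


def fisher_exact_two_sided(table: ContingencyTable | Sequence[int]) -> float:
    """Two-sided Fisher exact p-value of a 2x2 table."""
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(*table)
    pv = fisher_pvalues_by_count(table.a + table.c, table.a + table.b,
                                 table.c + table.d)
    return float(pv[table.a])


def odds_ratio_ci(table: ContingencyTable | Sequence[int],
                  level: float = 0.95) -> tuple[float, float, float]:
    """Cross-product odds ratio with an exact conditional CI.

    Returns ``(or, low, high)``.  A zero ``b*c`` yields an infinite odds
    ratio with a one-sided interval; a zero ``a*d`` yields 0.0.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(*table)
    a, b, c, d = table.a, table.b, table.c, table.d
    if b * c == 0:
        est = math.inf if a * d > 0 else math.nan
    else:
        est = (a * d) / (b * c)
    res = _scipy_odds_ratio(table.as_array(), kind="conditional")
    ci = res.confidence_interval(confidence_level=level)
    return est, float(ci.low), float(ci.high)


@dataclass(frozen=True)
class ContrastResult:
    """One candidate test evaluated under one response contrast."""

    amplicon_id: str
    test: CandidateTest
    contrast: str
    table: ContingencyTable
    p_two_sided: float
    odds_ratio: float
    ci95: tuple[float, float]


@dataclass
class ContrastSummary:
    """All admissible tests of one amplicon under one contrast."""

    amplicon_id: str
    contrast: str
    n_responders: int
    n_comparators: int
    results: list[ContrastResult]

    @property
    def n_test(self) -> int:
        return len(self.results)

    @property
    def min_p(self) -> Optional[float]:
        if not self.results:
            return None
        return min(r.p_two_sided for r in self.results)

    @property
    def best(self) -> Optional[ContrastResult]:
        if not self.results:
            return None
        return min(self.results, key=lambda r: r.p_two_sided)


def run_contrast(cohort: Cohort, amplicon_id: str, contrast: str,
                 min_group_fraction: float = 0.10,
                 dedupe: str = "within_kind") -> ContrastSummary:
    """Evaluate every admissible dichotomy of one amplicon under a contrast.

    The analysis set is the patients carrying a label in the contrast AND a
    non-missing genotype at this amplicon (pairwise deletion).  Test
    admissibility (the 10% rule) is judged on this set.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    if amplicon_id not in cohort.genotypes:
        raise KeyError(f"unknown amplicon {amplicon_id!r}")
    resp_cats, comp_cats = CONTRASTS[contrast]
    table = cohort.genotypes[amplicon_id]
    pids = [p for p in sorted(table)
            if cohort.labels.get(p) in resp_cats + comp_cats
            and table[p] is not None]
    calls = [table[p] for p in pids]
    is_resp = np.array([cohort.labels[p] in resp_cats for p in pids])
    n1, n2 = int(is_resp.sum()), int((~is_resp).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError(
            f"contrast {contrast!r} has an empty group at {amplicon_id!r} "
            f"(responders={n1}, comparators={n2})"
        )
    results = []
    # groupings are built from the alleles observed in the analysis set
    for t in admissible_tests(calls, None, min_group_fraction, dedupe):
        a = int((t.feature & is_resp).sum())
        b = n1 - a
        c = t.positive_count - a
        d = n2 - c
        ct = ContingencyTable(a, b, c, d)
        est, lo, hi = odds_ratio_ci(ct)
        results.append(
            ContrastResult(amplicon_id, t, contrast, ct,
                           fisher_exact_two_sided(ct), est, (lo, hi))
        )
    return ContrastSummary(amplicon_id, contrast, n1, n2, results)
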