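"""Genotyping QC: Hardy-Weinberg screening and allele-length/response checks.

The HWE screen collapses a multi-allelic amplicon to a bi-allelic system
for every binary subdivision of its allele set, compares the observed
homozygote/heterozygote distribution to the Hardy-Weinberg expectation
from the collapsed allele frequency with a 1-df chi-square, and reports
the minimum p over subdivisions (an intentionally aggressive screen: the
minimum is deflated relative to uniform).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .response import DeltaDas

__all__ = ["HweResult", "CorrelationResult", "hwe_min_chisq",
           "max_allele_response_correlation", "allele_distribution_by_response"]

# above this allele count, scanning all bipartitions is replaced by the
# threshold + singleton grid used by the association stage
_EXHAUSTIVE_MAX_ALLELES = 8


@dataclass(frozen=True)
class HweResult:
    amplicon_id: str
    min_p: float
    chisq: float
    best_subdivision: tuple[int, ...]
    note: str = ""


def _collapsed_hwe_p(calls: Sequence[tuple[int, int]],
                     group: frozenset[int]) -> tuple[float, float]:
    """1-df chi-square HWE p for genotypes collapsed onto one allele group."""
    n = len(calls)
    n2 = sum(1 for a, b in calls if a in group and b in group)
    n1 = sum(1 for a, b in calls if (a in group) != (b in group))
    n0 = n - n2 - n1
    p = (2 * n2 + n1) / (2 * n)
    if p == 0.0 or p == 1.0:
        return 0.0, 1.0
    expected = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p ** 2])
    observed = np.array([n0, n1, n2])
    chisq = float(((observed - expected) ** 2 / expected).sum())
    return chisq, float(stats.chi2.sf(chisq, df=1))


def _bipartitions(alleles: Sequence[int]):
    """Nontrivial binary subdivisions; each emitted once (side without the
    smallest allele)."""
    rest = list(alleles[1:])
    for r in range(1, len(rest) + 1):
        for combo in combinations(rest, r):
            yield frozenset(combo)


def _grid_subdivisions(alleles: Sequence[int]):
    seen = set()
    for cut in alleles[:-1]:
        g = frozenset(a for a in alleles if a <= cut)
        if g not in seen:
            seen.add(g)
            yield g
    for a in alleles:
        g = frozenset([a])
        if g not in seen:
            seen.add(g)
            yield g


def hwe_min_chisq(calls: Sequence[tuple[int, int]],
                  alleles: Optional[Sequence[int]] = None,
                  amplicon_id: str = "") -> HweResult:
    """Minimum collapsed-HWE chi-square p over binary allele subdivisions.

    With at most 8 alleles all 2^(k-1) - 1 bipartitions are scanned;
    beyond that, thresholds and singletons only.  Fewer than two alleles
    leaves HWE undefined (min_p = 1 with a note).
    """
    calls = [g for g in calls if g is not None]
    if not calls:
        raise ValueError("hwe_min_chisq requires at least one call")
    if alleles is None:
        alleles = sorted({a for g in calls for a in g})
    else:
        alleles = sorted(set(alleles))
    if len(alleles) < 2:
        return HweResult(amplicon_id, 1.0, 0.0, tuple(alleles),
                         note="monomorphic: HWE undefined")
    if len(alleles) <= _EXHAUSTIVE_MAX_ALLELES:
        subdivisions = _bipartitions(alleles)
    else:
        subdivisions = _grid_subdivisions(alleles)
    best_p, best_chi, best_grp = 1.0, 0.0, frozenset(alleles[:1])
    for grp in subdivisions:
        chisq, p = _collapsed_hwe_p(calls, grp)
        if p < best_p:
            best_p, best_chi, best_grp = p, chisq, grp
    return HweResult(amplicon_id, best_p, best_chi, tuple(sorted(best_grp)))


@dataclass(frozen=True)
class CorrelationResult:
    spearman_rho: float
    spearman_p: float
    pearson_r: float
    pearson_p: float
    n: int
    undefined: bool = False


def max_allele_response_correlation(cohort: Cohort, amplicon_id: str
                                    ) -> CorrelationResult:
    """Correlate each patient's maximal allele length with delta DAS28.

    Uses patients with a non-missing genotype and both visits.  Delta is
    baseline minus week 26 (positive = improvement), so a negative
    coefficient means longer alleles go with poorer response.
    """
    from .response import _visit_das28  # local: avoids a public dependency

    if amplicon_id not in cohort.genotypes:
        raise KeyError(f"unknown amplicon {amplicon_id!r}")
    max_len, delta = [], []
    for pid, g in sorted(cohort.genotypes[amplicon_id].items()):
        if g is None:
            continue
        visits = cohort.clinical.get(pid, {})
        if "baseline" not in visits or "week26" not in visits:
            continue
        dd = DeltaDas(_visit_das28(visits["baseline"]),
                      _visit_das28(visits["week26"]))
        max_len.append(max(g))
        delta.append(dd.delta)
    max_len = np.asarray(max_len, dtype=float)
    delta = np.asarray(delta, dtype=float)
    n = len(max_len)
    if n < 3 or np.ptp(max_len) == 0 or np.ptp(delta) == 0:
        return CorrelationResult(np.nan, np.nan, np.nan, np.nan, n,
                                 undefined=True)
    rho, p_rho = stats.spearmanr(max_len, delta)
    r, p_r = stats.pearsonr(max_len, delta)
    return CorrelationResult(float(rho), float(p_rho), float(r), float(p_r), n)


def allele_distribution_by_response(cohort: Cohort, amplicon_id: str
                                    ) -> pd.DataFrame:
    """Within-category percentage of patients per maximal allele length.

    Rows are the EULAR categories (good, moderate, none); columns the
    maximal allele lengths observed; each row sums to 100 (zero rows, with
    a warning, for empty categories).
    """
    from .response import CATEGORIES

    if amplicon_id not in cohort.genotypes:
        raise KeyError(f"unknown amplicon {amplicon_id!r}")
    rows: dict[str, list[int]] = {c: [] for c in CATEGORIES}
    for pid, g in sorted(cohort.genotypes[amplicon_id].items()):
        if g is None:
            continue
        label = cohort.labels.get(pid)
        if label in rows:
            rows[label].append(max(g))
    lengths = sorted({m for v in rows.values() for m in v})
    out = pd.DataFrame(0.0, index=list(CATEGORIES), columns=lengths)
    for cat, vals in rows.items():
        if not vals:
            warnings.warn(f"no genotyped patients labelled {cat!r} at "
                          f"{amplicon_id}", stacklevel=2)
            continue
        counts = pd.Series(vals).value_counts()
        out.loc[cat, counts.index] = 100.0 * counts.values / len(vals)
    return out
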