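"""Enumeration of admissible genotype dichotomies for one amplicon.

Each candidate test is an allele grouping combined with a genetic model.
Two grouping kinds exist: *threshold* (all alleles with length <= some
observed cut) and *singleton* (one allele vs. all others).  The *dominant*
model marks a patient positive when at least one allele lies in the group,
the *recessive* model when both do.  Bi-allelic loci therefore admit a
single grouping and at most two tests; multi-allelic loci admit more.

Tests whose smaller genotype group holds fewer than 10% of the genotyped
patients in the analysis set are discarded; the number of survivors is the
per-amplicon test count N_test entering the Bonferroni correction.

Deduplication (the ``dedupe`` argument):

* ``"within_kind"`` (default): groupings that induce the same allele
  bipartition are emitted once, and when a threshold coincides with a
  singleton the singleton phrasing wins; at the test level, threshold tests
  inducing identical patient partitions are merged (smallest cut kept)
  while identical partitions arising across kinds are retained as distinct
  tests — each kind contributes its own test to N_test.
* ``"none"``: no test-level merging.
* ``"full"``: identical patient partitions are merged across kinds as well
  (singleton phrasing kept).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

__all__ = ["AlleleGrouping", "CandidateTest", "enumerate_groupings",
           "dichotomize", "admissible_tests"]

Model = Literal["dominant", "recessive"]
MODELS: tuple[Model, Model] = ("dominant", "recessive")


@dataclass(frozen=True)
class AlleleGrouping:
    """An allele group: lengths <= ``parameter`` (threshold) or == it (singleton)."""

    kind: Literal["threshold", "singleton"]
    parameter: int

    def members(self, alleles: Iterable[int]) -> frozenset[int]:
        if self.kind == "threshold":
            return frozenset(a for a in alleles if a <= self.parameter)
        return frozenset([self.parameter])

    def contains(self, length: int) -> bool:
        if self.kind == "threshold":
            return length <= self.parameter
        return length == self.parameter

    def label(self, model: Model) -> str:
        word = "One allele" if model == "dominant" else "Both alleles"
        op = "≤" if self.kind == "threshold" else "="
        return f"{word} {op} {self.parameter}"


@dataclass(frozen=True)
class CandidateTest:
    """A dichotomy: grouping x model, with its counts on the analysis set."""

    grouping: AlleleGrouping
    model: Model
    positive_count: int
    negative_count: int
    feature: np.ndarray = field(compare=False, repr=False, default=None)

    @property
    def label(self) -> str:
        return self.grouping.label(self.model)

    @property
    def n(self) -> int:
        return self.positive_count + self.negative_count


def enumerate_groupings(alleles: Sequence[int]) -> list[AlleleGrouping]:
    """All distinct allele groupings for a sorted allele set.

    Thresholds run over every observed length that leaves at least one
    longer allele outside the group; singletons over every allele.
    Groupings inducing the same allele bipartition are emitted once; when a
    threshold coincides with a singleton the singleton wins.  For the
    bi-allelic case, where the two singletons coincide as a bipartition,
    the longer allele (the insertion) is kept as the focal one.  A
    monomorphic locus admits no grouping.
    """
    alleles = sorted(set(alleles))
    if len(alleles) < 2:
        return []
    universe = frozenset(alleles)
    out: dict[frozenset, AlleleGrouping] = {}
    # singletons first (longest first, so the insertion allele is focal)
    for a in sorted(alleles, reverse=True):
        grp = frozenset([a])
        key = frozenset([grp, universe - grp])
        out.setdefault(key, AlleleGrouping("singleton", a))
    for cut in alleles[:-1]:
        grp = frozenset(a for a in alleles if a <= cut)
        key = frozenset([grp, universe - grp])
        out.setdefault(key, AlleleGrouping("threshold", cut))
    return sorted(out.values(), key=lambda g: (g.kind, g.parameter))


def dichotomize(calls: Sequence[tuple[int, int]], grouping: AlleleGrouping,
                model: Model) -> np.ndarray:
    """Boolean feature vector over non-missing calls.

    Dominant: positive iff at least one allele lies in the group;
    recessive: positive iff both do.  Missing calls are a contract
    violation — the caller restricts to genotyped patients first.
    """
    if any(g is None for g in calls):
        raise ValueError("dichotomize requires non-missing calls; pre-filter")
    feat = np.empty(len(calls), dtype=bool)
    for i, (a, b) in enumerate(calls):
        ina, inb = grouping.contains(a), grouping.contains(b)
        feat[i] = (ina or inb) if model == "dominant" else (ina and inb)
    return feat


def admissible_tests(calls: Sequence[tuple[int, int]],
                     alleles: Optional[Sequence[int]] = None,
                     min_group_fraction: float = 0.10,
                     dedupe: str = "within_kind") -> list[CandidateTest]:
    """Candidate tests surviving deduplication and the 10% group-size rule.

    ``len(result)`` is the amplicon's N_test on this analysis set.  The
    minimum-size comparison is real-valued: a group of 17 passes at
    n = 156 (17 >= 15.6) while 10 fails.
    """
    if len(calls) == 0:
        raise ValueError("admissible_tests requires at least one call")
    if dedupe not in ("within_kind", "none", "full"):
        raise ValueError(f"unknown dedupe mode {dedupe!r}")
    if alleles is None:
        alleles = sorted({a for g in calls for a in g})
    n = len(calls)

    candidates: list[CandidateTest] = []
    for grouping in enumerate_groupings(alleles):
        for model in MODELS:
            feat = dichotomize(calls, grouping, model)
            pos = int(feat.sum())
            candidates.append(
                CandidateTest(grouping, model, pos, n - pos, feature=feat)
            )

    if dedupe != "none":
        kept: list[CandidateTest] = []
        seen: dict[tuple, CandidateTest] = {}
        # sort so the smallest threshold cut (and singleton before threshold
        # under "full") is the representative kept for each partition
        order = sorted(
            candidates,
            key=lambda t: (t.grouping.kind != "singleton", t.grouping.parameter),
        )
        for t in order:
            sig = frozenset(
                [t.feature.tobytes(), (~t.feature).tobytes()]
            )  # unordered patient partition
            key = (sig,) if dedupe == "full" else (t.grouping.kind, sig)
            if t.grouping.kind == "singleton" and dedupe == "within_kind":
                # singletons never collide after grouping-level dedup, but
                # guard anyway
                if key in seen:
                    continue
            elif key in seen:
                continue
            seen[key] = t
            kept.append(t)
        candidates = sorted(
            kept, key=lambda t: (t.grouping.kind, t.grouping.parameter,
                                 t.model)
        )

    min_count = min_group_fraction * n
    return [
        t for t in candidates
        if min(t.positive_count, t.negative_count) >= min_count
        and min(t.positive_count, t.negative_count) > 0
    ]
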