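"""Per-amplicon Bonferroni thresholds and permutation-calibrated test counts.

With N_marker testable amplicons and N_test admissible dichotomies at an
amplicon, the family-wise threshold for any single test is
``alpha / (N_marker * N_test)``.  When the N_test dichotomies are strongly
dependent (nested thresholds, duplicated partitions) this over-corrects;
the *effective* number of tests is calibrated by permutation: shuffle the
response labels, record the minimum Fisher p over the test columns each
round, and set

    effective_N_test = [#(min p <= p_ref) / rounds] / p_ref

so that ``alpha / (N_marker * effective_N_test)`` controls the per-amplicon
error at the reference tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .association import fisher_pvalues_by_count

__all__ = ["MultiplicityPlan", "EffectiveTestCount", "bonferroni_threshold",
           "effective_test_count"]


def bonferroni_threshold(n_marker: int, n_test: float,
                         alpha_family: float = 0.05) -> float:
    """Per-test type-I threshold alpha / (n_marker * n_test).

    ``n_test`` may be a permutation-calibrated (non-integer) effective
    count.
    """
    if n_marker < 1 or n_test <= 0:
        raise ValueError("n_marker and n_test must be positive")
    if not 0 < alpha_family < 1:
        raise ValueError("alpha_family must lie in (0, 1)")
    return alpha_family / (n_marker * n_test)


@dataclass(frozen=True)
class EffectiveTestCount:
    """Permutation estimate of the effective number of tests."""

    effective_n: float
    tail_count: int
    n_rounds: int
    p_ref: float

    @property
    def tail_fraction(self) -> float:
        return self.tail_count / self.n_rounds

    @property
    def se_tail_count(self) -> float:
        """Binomial standard error of the tail count."""
        q = self.tail_fraction
        return float(np.sqrt(self.n_rounds * q * (1.0 - q)))

    @property
    def se_effective_n(self) -> float:
        return self.se_tail_count / (self.n_rounds * self.p_ref)


def effective_test_count(features: np.ndarray,
                         group_sizes: tuple[int, int],
                         p_ref: float,
                         n_rounds: int = 600_000,
                         seed: Optional[int] = None,
                         batch_size: int = 20_000) -> EffectiveTestCount:
    """Permutation calibration of the effective test count.

    ``features`` is a boolean patients x tests matrix on the analysis set;
    ``group_sizes`` = (n1, n2) with n1 + n2 = number of patients.  Each
    round assigns n1 "responder" labels uniformly at random, evaluates the
    two-sided Fisher p of every column and records the minimum; the
    estimate is the tail fraction at ``p_ref`` divided by ``p_ref``.

    Because a permutation leaves both margins of every column fixed, the
    p-value of a column is a function of the count of feature-positives
    among the n1 relabelled responders alone; p-values are therefore
    precomputed per column and looked up by count.
    """
    if p_ref <= 0:
        raise ValueError("p_ref must be positive")
    features = np.asarray(features, dtype=bool)
    if features.ndim != 2:
        raise ValueError("features must be 2-D (patients x tests)")
    n_patients, n_tests = features.shape
    if n_tests == 0:
        raise ValueError("at least one test column is required")
    n1, n2 = group_sizes
    if n1 + n2 != n_patients or min(n1, n2) <= 0:
        raise ValueError("group sizes must be positive and sum to #patients")

    totals = features.sum(axis=0)
    lut = np.stack([
        fisher_pvalues_by_count(int(k), n1, n2) for k in totals
    ])  # tests x (n1 + 1)
    col = np.arange(n_tests)
    X = features.astype(np.int16)

    rng = np.random.default_rng(seed)
    tail = 0
    done = 0
    while done < n_rounds:
        b = min(batch_size, n_rounds - done)
        keys = rng.random((b, n_patients))
        idx = np.argpartition(keys, n1 - 1, axis=1)[:, :n1]
        counts = X[idx].sum(axis=1)        # b x tests
        pmin = lut[col, counts].min(axis=1)
        tail += int((pmin <= p_ref).sum())
        done += b

    if tail < 20:
        warnings.warn(
            f"only {tail} permutation minima fell below p_ref={p_ref:g} in "
            f"{n_rounds} rounds; the effective-test-count estimate is noisy",
            stacklevel=2,
        )
    eff = (tail / n_rounds) / p_ref
    return EffectiveTestCount(eff, tail, n_rounds, p_ref)


@dataclass(frozen=True)
class MultiplicityPlan:
    """The multipliers and thresholds governing one amplicon's tests."""

    n_marker: int
    n_test: int
    alpha_family: float = 0.05
    effective_n_test: Optional[float] = None

    @property
    def threshold(self) -> float:
        return bonferroni_threshold(self.n_marker, self.n_test,
                                    self.alpha_family)

    @property
    def adjusted_threshold(self) -> Optional[float]:
        if self.effective_n_test is None:
            return None
        return bonferroni_threshold(self.n_marker, self.effective_n_test,
                                    self.alpha_family)

    def report_block(self) -> str:
        lines = [
            f"n_marker\t{self.n_marker}",
            f"n_test\t{self.n_test}",
            f"alpha_family\t{self.alpha_family:g}",
            f"threshold\t{self.threshold:.4g}",
        ]
        if self.effective_n_test is not None:
            lines += [
                f"effective_n_test\t{self.effective_n_test:.4g}",
                f"adjusted_threshold\t{self.adjusted_threshold:.4g}",
            ]
        return "\n".join(lines)
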