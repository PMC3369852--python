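"""Simulation-based power of the two-sided Fisher exact test.

The sampling model: two fixed-size groups (responders n1, comparators n2)
whose feature-positive counts are independent binomials at the per-group
probabilities (p1, p2); power is the fraction of simulated tables whose
two-sided Fisher p falls at or below the significance threshold.  The
per-group probabilities are typically the observed proportions of the
table whose detectability is being assessed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .association import fisher_pvalues_by_count

__all__ = ["PowerSpec", "PowerResult", "power_fisher"]


@dataclass(frozen=True)
class PowerSpec:
    n1: int
    n2: int
    p1: float
    p2: float
    alpha: float
    n_sims: int = 10_000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.n1, self.n2) < 1:
            raise ValueError("group sizes must be positive")
        if not (0 <= self.p1 <= 1 and 0 <= self.p2 <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_sims < 1000:
            raise ValueError("n_sims must be at least 1000")


@dataclass(frozen=True)
class PowerResult:
    power: float
    n_sims: int
    n_rejections: int

    @property
    def se(self) -> float:
        """Monte-Carlo standard error of the power estimate."""
        return float(np.sqrt(self.power * (1.0 - self.power) / self.n_sims))


def power_fisher(spec: PowerSpec) -> PowerResult:
    """Estimate the power of the two-sided Fisher test under ``spec``.

    Fisher p-values are cached by the positive-count pair: with group
    sizes fixed, the p-value depends only on (k1, k2), so each distinct
    margin configuration is priced once.
    """
    rng = np.random.default_rng(spec.seed)
    k1 = rng.binomial(spec.n1, spec.p1, size=spec.n_sims)
    k2 = rng.binomial(spec.n2, spec.p2, size=spec.n_sims)
    reject_cache: dict[tuple[int, int], bool] = {}
    hits = 0
    for a, c in zip(k1, k2):
        key = (int(a), int(c))
        dec = reject_cache.get(key)
        if dec is None:
            pv = fisher_pvalues_by_count(key[0] + key[1], spec.n1, spec.n2)
            dec = bool(pv[key[0]] <= spec.alpha)
            reject_cache[key] = dec
        hits += dec
    return PowerResult(hits / spec.n_sims, spec.n_sims, hits)
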