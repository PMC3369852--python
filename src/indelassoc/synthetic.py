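"""Synthetic cohort generator with the structure the analysis assumes.

Genotypes are drawn under Hardy-Weinberg proportions from per-amplicon
allele spectra, masked at a configurable missing-call rate; EULAR labels
follow cohort-level category probabilities, optionally tilted at one or
more amplicons so that the good-vs-none odds of feature-positive over
feature-negative patients equals a planted odds ratio.  DAS28 score pairs
are then sampled inside the label's region of the (baseline, week 26)
plane, so classification round-trips the drawn label exactly.

Defaults mirror the study cohort: 237 patients, category probabilities
68/237, 81/237, 88/237, missing rates between 0 and 0.28, drugs in the
160/56/21 proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cohort import Amplicon, ClinicalRecord, Cohort
from .enumeration import AlleleGrouping
from .response import eular_classify

__all__ = ["AmpliconSpectrum", "PlantedEffect", "GeneratorSpec",
           "generate_genotypes", "generate_responses", "generate_cohort"]

#: study label probabilities (good, moderate, none)
STUDY_LABEL_PROBS = (68 / 237, 81 / 237, 88 / 237)
#: study drug mix (infliximab, adalimumab, etanercept)
STUDY_DRUG_PROBS = (160 / 237, 56 / 237, 21 / 237)
#: baseline DAS28 range used for sampling (good-responder range of the cohort)
_BASELINE_RANGE = (3.1, 7.4)
_DAS_MAX = 9.4


@dataclass(frozen=True)
class AmpliconSpectrum:
    """Allele spectrum and missingness of one simulated amplicon."""

    amplicon: Amplicon
    frequencies: tuple[float, ...]
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if len(self.frequencies) != len(self.amplicon.alleles):
            raise ValueError(
                f"{self.amplicon.amplicon_id}: {len(self.frequencies)} "
                f"frequencies for {len(self.amplicon.alleles)} alleles"
            )
        if any(f < 0 for f in self.frequencies):
            raise ValueError("allele frequencies must be non-negative")
        if abs(sum(self.frequencies) - 1.0) > 1e-9:
            raise ValueError("allele frequencies must sum to 1")
        if not 0.0 <= self.missing_rate <= 0.28:
            raise ValueError("missing_rate must lie in [0, 0.28]")


@dataclass(frozen=True)
class PlantedEffect:
    """Link one dichotomy to the good-vs-none odds at a target odds ratio."""

    amplicon_id: str
    grouping: AlleleGrouping
    model: str
    odds_ratio: float

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ValueError("planted odds ratio must be positive")
        if self.model not in ("dominant", "recessive"):
            raise ValueError(f"unknown model {self.model!r}")

    def is_positive(self, pair: tuple[int, int]) -> bool:
        ina, inb = (self.grouping.contains(pair[0]),
                    self.grouping.contains(pair[1]))
        return (ina or inb) if self.model == "dominant" else (ina and inb)


@dataclass
class GeneratorSpec:
    spectra: list[AmpliconSpectrum]
    n_patients: int = 237
    label_probabilities: tuple[float, float, float] = STUDY_LABEL_PROBS
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    drug_probabilities: tuple[float, float, float] = STUDY_DRUG_PROBS
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if abs(sum(self.label_probabilities) - 1.0) > 1e-9:
            raise ValueError("label probabilities must sum to 1")
        ids = {s.amplicon.amplicon_id for s in self.spectra}
        for eff in self.planted_effects:
            if eff.amplicon_id not in ids:
                raise ValueError(
                    f"planted effect on unknown amplicon {eff.amplicon_id!r}"
                )


def _patient_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"P{i + 1:0{width}d}" for i in range(n)]


def generate_genotypes(spec: GeneratorSpec,
                       rng: Optional[np.random.Generator] = None) -> Cohort:
    """Draw genotypes for every amplicon under Hardy-Weinberg proportions."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    pids = _patient_ids(spec.n_patients)
    cohort = Cohort(amplicons={s.amplicon.amplicon_id: s.amplicon
                               for s in spec.spectra})
    for s in spec.spectra:
        alleles = s.amplicon.alleles
        draws = rng.choice(len(alleles), size=(spec.n_patients, 2),
                           p=np.asarray(s.frequencies))
        missing = rng.random(spec.n_patients) < s.missing_rate
        table = {}
        for pid, (i, j), miss in zip(pids, draws, missing):
            if miss:
                table[pid] = None
            else:
                a, b = alleles[i], alleles[j]
                table[pid] = (min(a, b), max(a, b))
        cohort.genotypes[s.amplicon.amplicon_id] = table
    return cohort


def _tilted_probs(base: tuple[float, float, float],
                  odds_ratio: float) -> tuple[float, float, float]:
    """Shift good/none mass so the good-vs-none odds is scaled by
    ``odds_ratio`` while the moderate share is preserved."""
    pg, pm, pn = base
    r = odds_ratio * pg / pn
    tot = pg + pn
    return (tot * r / (1 + r), pm, tot / (1 + r))


def _sample_scores(label: str, rng: np.random.Generator
                   ) -> tuple[float, float]:
    """A (baseline, week26) DAS28 pair whose classification is ``label``."""
    for _ in range(1000):
        baseline = rng.uniform(*_BASELINE_RANGE)
        if label == "good":
            week26 = rng.uniform(0.0, min(3.2, baseline - 1.2))
        elif label == "none":
            week26 = rng.uniform(max(0.0, baseline - 0.6), _DAS_MAX)
        else:
            week26 = rng.uniform(0.0, _DAS_MAX)
        if eular_classify(baseline, week26) == label:
            return baseline, week26
    raise RuntimeError(f"could not sample scores for label {label!r}")


def generate_responses(spec: GeneratorSpec, cohort: Cohort,
                       rng: Optional[np.random.Generator] = None) -> Cohort:
    """Draw labels (tilted by planted effects) and consistent DAS28 pairs.

    Patients whose genotype is missing at a planted amplicon fall back to
    the baseline label probabilities for that effect.
    """
    if rng is None:
        rng = np.random.default_rng(None if spec.seed is None
                                    else spec.seed + 1)
    pids = sorted({p for t in cohort.genotypes.values() for p in t})
    categories = ("good", "moderate", "none")
    drugs = ("infliximab", "adalimumab", "etanercept")
    for pid in pids:
        probs = spec.label_probabilities
        for eff in spec.planted_effects:
            g = cohort.genotypes.get(eff.amplicon_id, {}).get(pid)
            if g is not None and eff.is_positive(g):
                probs = _tilted_probs(probs, eff.odds_ratio)
        label = categories[rng.choice(3, p=np.asarray(probs))]
        cohort.labels[pid] = label
        baseline, week26 = _sample_scores(label, rng)
        drug = drugs[rng.choice(3, p=np.asarray(spec.drug_probabilities))]
        cohort.clinical[pid] = {
            "baseline": ClinicalRecord(pid, "baseline", das28=baseline,
                                       drug=drug),
            "week26": ClinicalRecord(pid, "week26", das28=week26, drug=drug),
        }
    return cohort


def generate_cohort(spec: GeneratorSpec,
                    seed: Optional[int] = None) -> Cohort:
    """Genotypes + responses in one deterministic call."""
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    cohort = generate_genotypes(spec, rng)
    return generate_responses(spec, cohort, rng)
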