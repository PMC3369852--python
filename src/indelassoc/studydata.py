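"""Published summary tables of the Copenhagen TNF-inhibitor cohort.

The per-patient registry data are not public; what is public are the
cohort-level summaries: the two amplicon definitions (the CD6 19-bp
insertion, alleles 493/512 bp, and the STXBP6 TG-repeat microsatellite,
seven alleles 252-294 bp), the genotype distribution of the microsatellite
over the 156 good/no-response patients, the candidate-test catalogue that
survives the 10% rule, and the headline 2x2 tables.  These drive the
worked examples and the acceptance checks.

``study_fixture_cohort`` additionally builds a *synthetic* per-patient
reconstruction exactly consistent with those summaries, for end-to-end
pipeline runs.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .association import ContingencyTable
from .cohort import Amplicon, ClinicalRecord, Cohort
from .synthetic import _sample_scores

__all__ = [
    "CGEN_40002", "CGEN_40003", "N_MARKER", "RESPONSE_COUNTS",
    "TABLE3_GENOTYPE_COUNTS", "table3_calls",
    "TABLE2_CD6", "TABLE2_STXBP6", "TABLE5_CD6",
    "TABLE4_EXPECTED", "study_fixture_cohort",
]

#: CD6 19-bp insertion (chromosome 11); alleles 493 (reference) / 512 (insertion)
CGEN_40002 = Amplicon("CGEN-40002", gene="CD6", chromosome="11",
                      protocol="sequencing", alleles=(493, 512))

#: STXBP6 TG-repeat microsatellite (chromosome 14), seven length alleles
CGEN_40003 = Amplicon("CGEN-40003", gene="STXBP6", chromosome="14",
                      protocol="fragment_analysis",
                      alleles=(252, 271, 275, 280, 284, 288, 294))

#: amplicons with at least one admissible test in the study
N_MARKER = 202

#: EULAR category sizes at week 26
RESPONSE_COUNTS = {"good": 68, "moderate": 81, "none": 88}

#: genotype distribution of the microsatellite in the 156 good/no-response
#: patients (non-zero cells only; sums to 156)
TABLE3_GENOTYPE_COUNTS: dict[tuple[int, int], int] = {
    (252, 271): 1,
    (271, 271): 79,
    (271, 280): 4,
    (271, 284): 19,
    (271, 288): 33,
    (271, 294): 3,
    (275, 280): 1,
    (275, 284): 1,
    (275, 288): 2,
    (275, 294): 1,
    (280, 280): 1,
    (280, 288): 4,
    (284, 284): 1,
    (284, 288): 3,
    (288, 288): 3,
}

#: headline 2x2 tables, oriented (responders+, responders-, comparators+,
#: comparators-)
TABLE2_CD6 = ContingencyTable(31, 37, 14, 74)      # 512 carriers, good vs none
TABLE2_STXBP6 = ContingencyTable(50, 18, 36, 52)   # both alleles <= 280
TABLE5_CD6 = ContingencyTable(31, 37, 26, 141)     # 512 carriers, good vs mod/none

#: the eight admissible microsatellite tests with their (positive, negative)
#: counts on the 156-patient analysis set
TABLE4_EXPECTED: dict[str, tuple[int, int]] = {
    "Both alleles ≤ 271": (80, 76),
    "Both alleles ≤ 280": (86, 70),
    "Both alleles ≤ 284": (107, 49),
    "One allele ≤ 271": (139, 17),
    "Both alleles = 271": (79, 77),
    "One allele = 271": (139, 17),
    "One allele = 284": (24, 132),
    "One allele = 288": (45, 111),
}


def table3_calls() -> list[tuple[int, int]]:
    """The 156 microsatellite genotype calls, expanded from the counts."""
    calls: list[tuple[int, int]] = []
    for pair, count in sorted(TABLE3_GENOTYPE_COUNTS.items()):
        calls.extend([pair] * count)
    return calls


def _largest_remainder(quotas: list[float], total: int) -> list[int]:
    """Integer allocation matching ``total`` with largest-remainder rounding."""
    floors = [int(q) for q in quotas]
    rem = total - sum(floors)
    order = sorted(range(len(quotas)), key=lambda i: quotas[i] - floors[i],
                   reverse=True)
    for i in order[:rem]:
        floors[i] += 1
    return floors


def study_fixture_cohort(seed: int = 0) -> Cohort:
    """A synthetic 237-patient cohort consistent with the published tables.

    The true per-patient data are registry-held; this reconstruction fixes
    everything the published summaries constrain — the label sizes
    (68/81/88), the CD6 carrier cross-tabs of both contrasts (including
    the two moderate responders without a CD6 genotype), and the
    microsatellite genotype marginal with its good/none split on the
    "both alleles <= 280" dichotomy.  Good responders are spread across
    genotype cells proportionally (largest-remainder), which also makes
    that dichotomy the minimum-p test, as observed.  Everything else
    (DAS28 score pairs, drugs, moderate-responder microsatellite
    genotypes) is sampled with the given seed.
    """
    rng = np.random.default_rng(seed)
    cohort = Cohort(amplicons={a.amplicon_id: a
                               for a in (CGEN_40002, CGEN_40003)})

    labels = (["good"] * 68) + (["moderate"] * 81) + (["none"] * 88)
    pids = [f"P{i + 1:03d}" for i in range(237)]
    good = pids[:68]
    moderate = pids[68:149]
    none = pids[149:]
    cohort.labels = dict(zip(pids, labels))

    # --- CD6: carriers per label; a few carriers homozygous (must stay
    # below the 10% rule so only the carrier test is admissible)
    cd6: dict[str, Optional[tuple[int, int]]] = {}

    def fill_cd6(patients, n_pos, n_hom, n_missing=0):
        for k, pid in enumerate(patients):
            if k < n_missing:
                cd6[pid] = None
            elif k < n_missing + n_hom:
                cd6[pid] = (512, 512)
            elif k < n_missing + n_pos:
                cd6[pid] = (493, 512)
            else:
                cd6[pid] = (493, 493)

    fill_cd6(good, 31, 3)
    fill_cd6(moderate, 12, 1, n_missing=2)
    fill_cd6(none, 14, 1)
    cohort.genotypes["CGEN-40002"] = cd6

    # --- STXBP6: good/none patients get the published marginal; the good
    # labels inside each dichotomy side follow the published 50/86 and
    # 18/70 splits, spread across genotype cells by largest remainder.
    cells = sorted(TABLE3_GENOTYPE_COUNTS.items())
    low = [(pair, cnt) for pair, cnt in cells if max(pair) <= 280]
    high = [(pair, cnt) for pair, cnt in cells if max(pair) > 280]
    goods_low = _largest_remainder([50 * c / 86 for _, c in low], 50)
    goods_high = _largest_remainder([18 * c / 70 for _, c in high], 18)

    stx: dict[str, Optional[tuple[int, int]]] = {}
    good_iter = iter(good)
    none_iter = iter(none)
    for (pair, cnt), n_good in zip(low + high, goods_low + goods_high):
        for _ in range(n_good):
            stx[next(good_iter)] = pair
        for _ in range(cnt - n_good):
            stx[next(none_iter)] = pair
    # moderate responders: sampled from the published marginal
    probs = np.array([c for _, c in cells], dtype=float)
    probs /= probs.sum()
    for pid in moderate:
        pair, _ = cells[rng.choice(len(cells), p=probs)]
        stx[pid] = pair
    cohort.genotypes["CGEN-40003"] = dict(sorted(stx.items()))

    # --- clinical: DAS28 pairs consistent with each label, study drug mix
    drugs = (["infliximab"] * 160) + (["adalimumab"] * 56) + (["etanercept"] * 21)
    rng.shuffle(drugs)
    for pid, drug in zip(pids, drugs):
        baseline, week26 = _sample_scores(cohort.labels[pid], rng)
        cohort.clinical[pid] = {
            "baseline": ClinicalRecord(pid, "baseline", das28=baseline,
                                       drug=drug),
            "week26": ClinicalRecord(pid, "week26", das28=week26, drug=drug),
        }
    return cohort
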