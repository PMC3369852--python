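"""Hardy-Weinberg screening and allele-length/response checks."""

import itertools

import numpy as np
import pytest
from scipy import stats

from indelassoc import (allele_distribution_by_response, hwe_min_chisq,
                        max_allele_response_correlation)


def hwe_oracle_min_p(calls):
    """Independent brute force: minimum collapsed-HWE chi-square p over
    every binary subdivision of the observed alleles."""
    alleles = sorted({a for g in calls for a in g})
    best = 1.0
    n = len(calls)
    for r in range(1, len(alleles)):
        for combo in itertools.combinations(alleles, r):
            grp = set(combo)
            n2 = sum(a in grp and b in grp for a, b in calls)
            n1 = sum((a in grp) != (b in grp) for a, b in calls)
            n0 = n - n1 - n2
            p = (2 * n2 + n1) / (2 * n)
            if p in (0.0, 1.0):
                continue
            exp = [n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p * p]
            chi = sum((o - e) ** 2 / e for o, e in zip((n0, n1, n2), exp))
            best = min(best, stats.chi2.sf(chi, 1))
    return best


class TestHwe:
    def test_exact_proportions_give_p_one(self):
        calls = [(1, 1)] * 25 + [(1, 2)] * 50 + [(2, 2)] * 25
        res = hwe_min_chisq(calls)
        assert res.chisq == pytest.approx(0.0, abs=1e-12)
        assert res.min_p == pytest.approx(1.0)

    def test_all_heterozygote_extreme(self):
        calls = [(1, 2)] * 100
        res = hwe_min_chisq(calls)
        assert res.min_p < 1e-15

    def test_matches_brute_force_small_allele_sets(self):
        rng = np.random.default_rng(6)
        for n_alleles in (3, 4, 5):
            alleles = sorted(rng.choice(np.arange(100, 400, 4), n_alleles,
                                        replace=False).tolist())
            freqs = rng.dirichlet(np.ones(n_alleles))
            for rep in range(5):
                draws = rng.choice(alleles, size=(80, 2), p=freqs)
                calls = [tuple(sorted(row)) for row in draws]
                if len({a for g in calls for a in g}) < 2:
                    continue
                res = hwe_min_chisq(calls)
                assert res.min_p == pytest.approx(hwe_oracle_min_p(calls),
                                                  rel=1e-9)

    def test_monomorphic_undefined(self):
        res = hwe_min_chisq([(271, 271)] * 30)
        assert res.min_p == 1.0 and "undefined" in res.note

    def test_null_not_deflated_beyond_min_over_subdivisions(self):
        """On HWE-simulated genotypes the screen's minimum p behaves like
        the same statistic on null data: the 5th percentile over replicates
        stays well above machine-zero and the median is moderate."""
        rng = np.random.default_rng(13)
        alleles = [252, 271, 284, 288]
        freqs = [0.1, 0.55, 0.2, 0.15]
        mins = []
        for _ in range(40):
            draws = rng.choice(alleles, size=(156, 2), p=freqs)
            calls = [tuple(sorted(row)) for row in draws]
            mins.append(hwe_min_chisq(calls).min_p)
        mins = np.sort(mins)
        assert mins[1] > 1e-4      # no wild anti-conservatism
        assert np.median(mins) > 0.05


class TestCorrelation:
    def test_perfect_monotone_decrease(self, study_cohort):
        from indelassoc import Amplicon, Cohort, ClinicalRecord

        cohort = Cohort(amplicons={"A1": Amplicon("A1", alleles=tuple(
            range(100, 120, 2)))})
        cohort.genotypes["A1"] = {}
        for i in range(10):
            pid = f"P{i}"
            length = 100 + 2 * i
            cohort.genotypes["A1"][pid] = (length, length)
            # delta strictly decreasing in max allele length
            cohort.clinical[pid] = {
                "baseline": ClinicalRecord(pid, "baseline", das28=6.0),
                "week26": ClinicalRecord(pid, "week26", das28=2.0 + 0.3 * i),
            }
        res = max_allele_response_correlation(cohort, "A1")
        assert res.spearman_rho == pytest.approx(-1.0)
        assert res.pearson_r == pytest.approx(-1.0)

    def test_planted_linear_effect_recovered(self):
        from indelassoc import Amplicon, Cohort, ClinicalRecord

        rng = np.random.default_rng(21)
        alleles = tuple(range(200, 240, 4))
        cohort = Cohort(amplicons={"A1": Amplicon("A1", alleles=alleles)})
        cohort.genotypes["A1"] = {}
        slope = -0.05
        for i in range(200):
            pid = f"P{i:03d}"
            pair = tuple(sorted(rng.choice(alleles, 2)))
            cohort.genotypes["A1"][pid] = pair
            delta = 2.0 + slope * (max(pair) - 220) + rng.normal(0, 0.8)
            baseline = 6.0
            week26 = float(np.clip(baseline - delta, 0, 9.4))
            cohort.clinical[pid] = {
                "baseline": ClinicalRecord(pid, "baseline", das28=baseline),
                "week26": ClinicalRecord(pid, "week26", das28=week26),
            }
        res = max_allele_response_correlation(cohort, "A1")
        assert res.pearson_r < -0.2 and res.pearson_p < 1e-3
        assert res.spearman_rho < -0.2

    def test_constant_lengths_flagged(self):
        from indelassoc import Amplicon, Cohort, ClinicalRecord

        cohort = Cohort(amplicons={"A1": Amplicon("A1", alleles=(100, 102))})
        cohort.genotypes["A1"] = {}
        for i in range(5):
            pid = f"P{i}"
            cohort.genotypes["A1"][pid] = (100, 100)
            cohort.clinical[pid] = {
                "baseline": ClinicalRecord(pid, "baseline", das28=5.0),
                "week26": ClinicalRecord(pid, "week26", das28=3.0 + 0.1 * i),
            }
        res = max_allele_response_correlation(cohort, "A1")
        assert res.undefined


class TestAlleleDistribution:
    def test_rows_sum_to_100(self, study_cohort):
        table = allele_distribution_by_response(study_cohort, "CGEN-40003")
        for cat in ("good", "moderate", "none"):
            assert table.loc[cat].sum() == pytest.approx(100.0)

    def test_degenerate_category(self, study_cohort):
        import copy

        cohort = copy.deepcopy(study_cohort)
        for pid, lab in cohort.labels.items():
            if lab == "good":
                cohort.genotypes["CGEN-40003"][pid] = (271, 271)
        table = allele_distribution_by_response(cohort, "CGEN-40003")
        assert table.loc["good", 271] == pytest.approx(100.0)

    def test_reconstructs_from_max_length_vector(self, study_cohort):
        table = allele_distribution_by_response(study_cohort, "CGEN-40003")
        # independent recomputation from the per-patient maxima
        from collections import Counter, defaultdict

        by_cat = defaultdict(list)
        for pid, g in study_cohort.genotypes["CGEN-40003"].items():
            if g is not None:
                by_cat[study_cohort.labels[pid]].append(max(g))
        for cat, vals in by_cat.items():
            counts = Counter(vals)
            for length, k in counts.items():
                assert table.loc[cat, length] == pytest.approx(
                    100.0 * k / len(vals))

    def test_longer_alleles_enriched_in_nonresponders(self):
        """A cohort tilted so long-allele carriers respond poorly shows a
        monotone trend of long-allele share across categories."""
        from indelassoc import (AlleleGrouping, Amplicon, AmpliconSpectrum,
                                GeneratorSpec, PlantedEffect, derive_labels,
                                generate_cohort)

        amp = Amplicon("A1", alleles=(252, 271, 288, 294))
        spec = GeneratorSpec(
            spectra=[AmpliconSpectrum(amp, (0.1, 0.5, 0.25, 0.15))],
            n_patients=800,
            planted_effects=[PlantedEffect(
                "A1", AlleleGrouping("threshold", 271), "recessive", 4.0)],
            seed=17,
        )
        cohort = generate_cohort(spec)
        derive_labels(cohort)
        table = allele_distribution_by_response(cohort, "A1")
        long_share = table.loc[:, [288, 294]].sum(axis=1)
        assert long_share["good"] < long_share["none"]
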