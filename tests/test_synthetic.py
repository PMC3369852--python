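"""Synthetic cohort generator: determinism, HWE sampling, planted effects."""

from collections import Counter

import numpy as np
import pytest

from indelassoc import (AlleleGrouping, Amplicon, AmpliconSpectrum, Cohort,
                        GeneratorSpec, PlantedEffect, derive_labels,
                        eular_classify, generate_cohort, generate_genotypes,
                        genotyping_rate)
from indelassoc.studydata import CGEN_40003, TABLE3_GENOTYPE_COUNTS


def table3_spectrum(missing_rate=0.0):
    allele_counts = Counter()
    for (a, b), k in TABLE3_GENOTYPE_COUNTS.items():
        allele_counts[a] += k
        allele_counts[b] += k
    total = sum(allele_counts.values())
    freqs = tuple(allele_counts[a] / total for a in CGEN_40003.alleles)
    return AmpliconSpectrum(CGEN_40003, freqs, missing_rate)


class TestGenerateGenotypes:
    def test_deterministic_under_seed(self):
        spec = GeneratorSpec(spectra=[table3_spectrum(0.1)], n_patients=100,
                             seed=5)
        a = generate_genotypes(spec)
        b = generate_genotypes(spec)
        assert a.genotypes == b.genotypes

    def test_no_missing_when_rate_zero(self):
        spec = GeneratorSpec(spectra=[table3_spectrum(0.0)], n_patients=60,
                             seed=2)
        cohort = generate_genotypes(spec)
        assert genotyping_rate(cohort, "CGEN-40003").rate == 1.0

    def test_missing_rate_bounds_enforced(self):
        with pytest.raises(ValueError):
            table3_spectrum(missing_rate=0.5)

    def test_allele_frequency_recovery(self):
        """Empirical allele frequencies converge on the spectrum at about
        1/sqrt(n)."""
        spectrum = table3_spectrum()
        spec = GeneratorSpec(spectra=[spectrum], n_patients=4000, seed=9)
        cohort = generate_genotypes(spec)
        counts = Counter()
        for g in cohort.genotypes["CGEN-40003"].values():
            counts[g[0]] += 1
            counts[g[1]] += 1
        n_alleles = 2 * 4000
        for allele, f in zip(CGEN_40003.alleles, spectrum.frequencies):
            se = np.sqrt(f * (1 - f) / n_alleles)
            assert counts[allele] / n_alleles == pytest.approx(
                f, abs=max(4 * se, 1e-3))

    def test_genotype_counts_near_hwe_expectation(self):
        """At the published allele frequencies and n = 156, generated
        genotype counts sit within multinomial error of the published
        distribution for the frequent cells."""
        spectrum = table3_spectrum()
        reps, n = 30, 156
        freq_map = dict(zip(CGEN_40003.alleles, spectrum.frequencies))
        homo_271_exp = n * freq_map[271] ** 2
        totals = []
        for rep in range(reps):
            spec = GeneratorSpec(spectra=[spectrum], n_patients=n,
                                 seed=100 + rep)
            cohort = generate_genotypes(spec)
            counts = Counter(cohort.genotypes["CGEN-40003"].values())
            totals.append(counts[(271, 271)])
        mean = np.mean(totals)
        se = np.std(totals, ddof=1) / np.sqrt(reps)
        assert mean == pytest.approx(homo_271_exp, abs=4 * se + 1.0)
        # published count (79) is itself within sampling error of HWE
        assert abs(79 - homo_271_exp) < 3 * np.sqrt(
            homo_271_exp * (1 - freq_map[271] ** 2))


class TestGenerateResponses:
    def test_scores_roundtrip_to_drawn_label(self):
        spec = GeneratorSpec(spectra=[table3_spectrum()], n_patients=300,
                             seed=4)
        cohort = generate_cohort(spec)
        for pid, label in cohort.labels.items():
            b = cohort.clinical[pid]["baseline"].das28
            w = cohort.clinical[pid]["week26"].das28
            assert eular_classify(b, w) == label
        # derive_labels reproduces the drawn labels exactly
        drawn = dict(cohort.labels)
        assert derive_labels(cohort) == drawn

    def test_neutral_effect_matches_no_effect(self):
        amp = Amplicon("A1", alleles=(100, 119))
        spectra = [AmpliconSpectrum(amp, (0.8, 0.2))]
        base = GeneratorSpec(spectra=spectra, n_patients=200, seed=11)
        neutral = GeneratorSpec(
            spectra=spectra, n_patients=200,
            planted_effects=[PlantedEffect(
                "A1", AlleleGrouping("singleton", 119), "dominant", 1.0)],
            seed=11)
        assert (generate_cohort(base).labels
                == generate_cohort(neutral).labels)

    def test_invalid_planted_or_rejected(self):
        with pytest.raises(ValueError):
            PlantedEffect("A1", AlleleGrouping("singleton", 119), "dominant",
                          0.0)

    def test_planted_or_recovered_over_replicates(self):
        """Mean cross-product OR over replicates recovers the planted
        good-vs-none odds ratio within 10%."""
        amp = Amplicon("A1", alleles=(493, 512))
        # carrier frequency about 29%, as for the insertion allele
        q = 1 - np.sqrt(1 - 0.2885)
        spectra = [AmpliconSpectrum(amp, (1 - q, q))]
        target = 4.43
        logors = []
        for rep in range(500):
            spec = GeneratorSpec(
                spectra=spectra, n_patients=237,
                planted_effects=[PlantedEffect(
                    "A1", AlleleGrouping("singleton", 512), "dominant",
                    target)],
                seed=20_000 + rep)
            cohort = generate_cohort(spec)
            pos = {p for p, g in cohort.genotypes["A1"].items()
                   if 512 in g}
            counts = Counter((cohort.labels[p], p in pos)
                             for p in cohort.labels)
            a, b = counts[("good", True)], counts[("good", False)]
            c, d = counts[("none", True)], counts[("none", False)]
            if min(a, b, c, d) == 0:
                continue
            logors.append(np.log(a * d / (b * c)))
        recovered = float(np.exp(np.mean(logors)))
        assert recovered == pytest.approx(target, rel=0.10)

    def test_null_pvalues_not_anticonservative(self):
        """Without planted effects the association p-values are (super-)
        uniform: a one-sided KS test finds no enrichment of small p."""
        from scipy.stats import kstest

        from indelassoc import run_contrast

        amp = Amplicon("A1", alleles=(252, 271, 284, 288))
        pvals = []
        for rep in range(60):
            spec = GeneratorSpec(
                spectra=[AmpliconSpectrum(amp, (0.1, 0.55, 0.2, 0.15))],
                n_patients=156, seed=40_000 + rep)
            cohort = generate_cohort(spec)
            derive_labels(cohort)
            s = run_contrast(cohort, "A1", "good_vs_none")
            if s.min_p is not None:
                # Sidak-flatten the minimum over n_test dependent tests;
                # positive dependence keeps this conservative
                pvals.append(1.0 - (1.0 - s.min_p) ** s.n_test)
        res = kstest(pvals, "uniform", alternative="greater")
        assert res.pvalue > 0.01
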