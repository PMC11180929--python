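"""Generative model of the synthetic three-cohort datasets."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import chisquare

from centscan import (APOE_CENTENARIAN_CHANGES, CohortSpec, ValidationError,
                      null_spec, sample_genotypes_hwe, shifted_allele_freq,
                      simulate_cohorts)
from centscan.io import AD, AGE_MATCHED_CONTROL, CENTENARIAN


class TestShiftedAlleleFreq:
    def test_identity_at_or_one(self):
        assert shifted_allele_freq(0.2, 1.0) == pytest.approx(0.2)

    def test_closed_form(self):
        assert shifted_allele_freq(0.2, 2.0) == pytest.approx(1 / 3)

    @given(st.floats(min_value=0.01, max_value=0.99),
           st.floats(min_value=0.1, max_value=10.0))
    def test_inverse_symmetry(self, p0, or_value):
        p1 = shifted_allele_freq(p0, or_value)
        assert shifted_allele_freq(p1, 1 / or_value) == pytest.approx(p0,
                                                                      abs=1e-12)

    @given(st.floats(min_value=0.01, max_value=0.99),
           st.floats(min_value=0.1, max_value=10.0))
    def test_realizes_requested_odds_ratio(self, p0, or_value):
        p1 = shifted_allele_freq(p0, or_value)
        realized = (p1 / (1 - p1)) / (p0 / (1 - p0))
        assert realized == pytest.approx(or_value, rel=1e-9)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValidationError):
            shifted_allele_freq(0.0, 2.0)
        with pytest.raises(ValidationError):
            shifted_allele_freq(0.2, -1.0)


class TestHWESampling:
    def test_mean_dosage_matches_expectation(self):
        rng = np.random.default_rng(1)
        freq, n = 0.3, 10_000
        d = sample_genotypes_hwe(freq, n, rng)
        se = np.sqrt(2 * freq * (1 - freq) / n)
        assert abs(d.mean() - 2 * freq) < 4 * se

    def test_genotype_classes_fit_hwe(self):
        rng = np.random.default_rng(2)
        freq, n = 0.25, 50_000
        d = sample_genotypes_hwe(freq, n, rng)
        observed = np.bincount(d.astype(int), minlength=3)
        expected = n * np.array([(1 - freq) ** 2, 2 * freq * (1 - freq),
                                 freq ** 2])
        assert chisquare(observed, expected).pvalue > 1e-3

    def test_seeded_draws_are_reproducible(self):
        a = sample_genotypes_hwe(0.3, 100, np.random.default_rng(7))
        b = sample_genotypes_hwe(0.3, 100, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)


class TestSimulateCohorts:
    def test_seeded_runs_bit_reproducible(self, small_panel):
        spec = CohortSpec(n_cases=100, n_controls=100, n_centenarians=50,
                          seed=5)
        a = simulate_cohorts(small_panel, spec)
        b = simulate_cohorts(small_panel, spec)
        assert a.dataset.dosage.equals(b.dataset.dosage)
        assert a.dataset.samples.equals(b.dataset.samples)
        c = simulate_cohorts(small_panel, CohortSpec(
            n_cases=100, n_controls=100, n_centenarians=50, seed=6))
        assert not a.dataset.dosage.equals(c.dataset.dosage)

    def test_null_model_equalizes_group_frequencies(self, small_panel):
        spec = null_spec(small_panel, n_cases=4000, n_controls=4000,
                         n_centenarians=4000, seed=3)
        sim = simulate_cohorts(small_panel, spec)
        ds = sim.dataset
        assert np.allclose(sim.truth["freq_case"], sim.truth["freq_control"])
        assert np.allclose(sim.truth["freq_case"],
                           sim.truth["freq_centenarian"])
        for snp_id in small_panel.snp_ids:
            p = sim.truth.loc[snp_id, "freq_control"]
            se = np.sqrt(p * (1 - p) / (2 * 4000))
            for cohort in (AD, AGE_MATCHED_CONTROL, CENTENARIAN):
                obs = ds.dosage.loc[ds.cohort_mask(cohort), snp_id].mean() / 2
                assert abs(obs - p) < 5 * se

    def test_realized_logor_converges_to_generative(self, small_panel):
        """Empirical case-vs-control allelic log-OR matches truth at n=50k."""
        spec = CohortSpec(n_cases=50_000, n_controls=50_000,
                          n_centenarians=100, seed=9)
        sim = simulate_cohorts(small_panel, spec)
        ds = sim.dataset
        for snp_id in small_panel.snp_ids:
            a = ds.dosage.loc[ds.cohort_mask(AD), snp_id].sum()
            b = 2 * 50_000 - a
            c = ds.dosage.loc[ds.cohort_mask(AGE_MATCHED_CONTROL), snp_id].sum()
            d = 2 * 50_000 - c
            logor = np.log(a * d / (b * c))
            se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            assert abs(logor - sim.truth.loc[snp_id, "logor_case_control"]) \
                < 3 * se

    def test_apoe_carrier_fractions_match_study_margins(self, small_panel):
        """e4 carrier fractions ~ 43/17/7 % under the calibrated change factors."""
        changes = {snp: APOE_CENTENARIAN_CHANGES.get(snp, 2.0)
                   for snp in small_panel.snp_ids}
        spec = CohortSpec(centenarian_change=changes, seed=13)
        sim = simulate_cohorts(small_panel, spec)
        ds = sim.dataset
        expected = {AD: 0.43, AGE_MATCHED_CONTROL: 0.17, CENTENARIAN: 0.07}
        for cohort, frac in expected.items():
            mask = ds.cohort_mask(cohort)
            carriers = (ds.dosage.loc[mask, "rs429358"] > 0).mean()
            se = np.sqrt(frac * (1 - frac) / mask.sum())
            assert abs(carriers - frac) < 4 * se, (cohort, carriers)
        # e2 carriers 3/9/13 %
        expected_e2 = {AD: 0.03, AGE_MATCHED_CONTROL: 0.09, CENTENARIAN: 0.13}
        for cohort, frac in expected_e2.items():
            mask = ds.cohort_mask(cohort)
            carriers = (ds.dosage.loc[mask, "rs7412"] > 0).mean()
            se = np.sqrt(frac * (1 - frac) / mask.sum())
            assert abs(carriers - frac) < 4 * se, (cohort, carriers)

    def test_cohort_margins_and_onset_split(self, small_panel):
        sim = simulate_cohorts(small_panel, CohortSpec(seed=1))
        ds = sim.dataset
        assert ds.counts() == {AD: 2281, AGE_MATCHED_CONTROL: 3165,
                               CENTENARIAN: 346}
        onset = ds.samples.loc[ds.cohort_mask(AD), "onset_age"]
        assert onset.notna().all()
        early = (onset <= 65).mean()
        assert abs(early - 971 / 2281) < 4 * np.sqrt(0.43 * 0.57 / 2281)
        assert ds.samples.loc[~ds.cohort_mask(AD), "onset_age"].isna().all()
        for cohort, frac in {AD: 0.55, AGE_MATCHED_CONTROL: 0.48,
                             CENTENARIAN: 0.71}.items():
            f = (ds.samples.loc[ds.cohort_mask(cohort), "sex"] == "F").mean()
            assert abs(f - frac) < 4 * np.sqrt(frac * (1 - frac) /
                                               ds.counts()[cohort])

    def test_impossible_frequency_names_snp(self, small_panel):
        spec = CohortSpec(centenarian_change=2000.0, seed=0)
        with pytest.raises(ValidationError, match="rs"):
            simulate_cohorts(small_panel, spec)

    def test_pc_confounding_shifts_pc1_only(self, small_panel):
        spec = CohortSpec(n_cases=2000, n_controls=2000, n_centenarians=2000,
                          pc_confounding=1.0, seed=8)
        ds = simulate_cohorts(small_panel, spec).dataset
        pc1_case = ds.samples.loc[ds.cohort_mask(AD), "pc1"].mean()
        pc1_cent = ds.samples.loc[ds.cohort_mask(CENTENARIAN), "pc1"].mean()
        assert pc1_case - pc1_cent == pytest.approx(2.0, abs=0.2)
        pc2_case = ds.samples.loc[ds.cohort_mask(AD), "pc2"].mean()
        assert abs(pc2_case) < 0.1
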