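"""Analytic power, Monte-Carlo validation, escalation, and equivalence."""

import numpy as np
import pandas as pd
import pytest

from centscan import (ValidationError, analytic_power, controls_needed,
                      direction_filter, equivalence_summary, escalate_panel,
                      mc_power)
from centscan.io import AGE_MATCHED_CONTROL, CENTENARIAN
from centscan.power import _fit_counts_logit, _null_loglik


class TestAnalyticPower:
    def test_null_effect_gives_test_size(self):
        assert analytic_power(0.3, 0.0, 8000, 8000) == pytest.approx(0.05,
                                                                     abs=1e-6)
        assert analytic_power(0.1, 0.0, 500, 200, alpha=0.01) == \
            pytest.approx(0.01, abs=1e-6)

    def test_exact_symmetry_under_allele_relabel(self):
        """Swapping which allele is counted (p -> 1-p, beta -> -beta) is a
        pure relabeling and leaves the power invariant exactly."""
        for maf in (0.05, 0.2, 0.4):
            up = analytic_power(maf, 0.25, 4000, 4000)
            relabeled = analytic_power(1 - maf, -0.25, 4000, 4000)
            assert up == pytest.approx(relabeled, abs=1e-9)

    def test_approximate_symmetry_in_effect_sign(self):
        """Risk and protective effects of equal magnitude have near-equal
        power; the small gap reflects the shifted case allele frequency."""
        for maf in (0.2, 0.4):
            up = analytic_power(maf, 0.25, 4000, 4000)
            down = analytic_power(maf, -0.25, 4000, 4000)
            assert up == pytest.approx(down, abs=5e-3)

    def test_monotone_in_controls_and_effect(self):
        grid_n = np.arange(500, 16001, 500)
        p = analytic_power(0.2, 0.15, 4000, grid_n)
        assert np.all(np.diff(p) > 0)
        betas = np.linspace(0.02, 0.25, 25)  # below the power=1 plateau
        p = analytic_power(0.2, betas, 4000, 4000)
        assert np.all(np.diff(p) > 0)

    def test_matches_monte_carlo_at_moderate_effect(self):
        a = analytic_power(0.3, 0.3, 8000, 8000)
        m = mc_power(0.3, 0.3, 8000, 8000, n_reps=20_000, rng=5)
        assert abs(a - m) <= 0.02

    def test_invalid_query_rejected(self):
        with pytest.raises(ValidationError):
            controls_needed(0.7, 0.2)
        with pytest.raises(ValidationError):
            controls_needed(0.2, 0.2, alpha=1.5)


class TestCountsLogitSolver:
    def test_matches_statsmodels_on_random_tables(self):
        """Independent cross-check of the vectorized Newton fitter."""
        import statsmodels.api as sm
        rng = np.random.default_rng(11)
        for _ in range(5):
            w1 = rng.integers(5, 500, 3).astype(float)
            w0 = rng.integers(5, 500, 3).astype(float)
            b0, b1, loglik = _fit_counts_logit(w1, w0)
            g = np.array([0.0, 1.0, 2.0] * 2)
            y = np.repeat([1.0, 0.0], 3)
            X = np.column_stack([np.ones(6), g])
            res = sm.GLM(y, X, family=sm.families.Binomial(),
                         freq_weights=np.concatenate([w1, w0])).fit()
            assert b1 == pytest.approx(res.params[1], abs=1e-6)
            assert loglik == pytest.approx(res.llf, abs=1e-6)

    def test_degenerate_table_collapses_to_null(self):
        # no genotype variation: LRT must be zero, not NaN
        w1 = np.array([50.0, 0.0, 0.0])
        w0 = np.array([70.0, 0.0, 0.0])
        _, b1, loglik = _fit_counts_logit(w1, w0)
        assert b1 == 0.0
        assert loglik == pytest.approx(_null_loglik(50.0, 70.0), abs=1e-9)


class TestControlsNeeded:
    def test_large_effect_common_allele_needs_minimum(self):
        # APOE-scale effects converge at the very first escalation step
        for beta in (1.0, 1.2, -1.1):
            res = controls_needed(0.15, beta, n_cases=8000)
            assert res.converged and res.n_required == 200

    def test_null_effect_hits_cap(self):
        res = controls_needed(0.3, 0.0, n_cases=8000)
        assert not res.converged
        assert res.n_required == res.cap == 16_000

    def test_returned_n_is_minimal_on_grid(self):
        res = controls_needed(0.25, 0.12, n_cases=8000)
        assert res.converged
        n = res.n_required
        assert n % 200 == 0
        assert analytic_power(0.25, 0.12, 8000, n) >= 0.8
        if n > 200:
            assert analytic_power(0.25, 0.12, 8000, n - 200) < 0.8

    def test_agrees_with_step1_grid_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            maf = float(rng.uniform(0.02, 0.5))
            beta = float(rng.choice([-1, 1]) * rng.uniform(0.05, 1.0))
            res = controls_needed(maf, beta, n_cases=8000)
            dense = np.arange(1, 16_001)
            power = analytic_power(maf, beta, 8000, dense)
            hit = power >= 0.8
            if hit.any():
                oracle = 200 * int(np.ceil(dense[np.argmax(hit)] / 200))
                assert res.converged and res.n_required == oracle
            else:
                assert not res.converged and res.n_required == 16_000

    def test_non_increasing_in_effect_and_cases(self):
        betas = [0.08, 0.12, 0.2, 0.4, 0.8]
        ns = [controls_needed(0.2, b, n_cases=8000).n_required for b in betas]
        assert ns == sorted(ns, reverse=True)
        cases = [2500, 5000, 8000, 10_000]
        ns = [controls_needed(0.2, 0.1, n_cases=n).n_required for n in cases]
        assert ns == sorted(ns, reverse=True)


def _scan_frame(rows):
    return pd.DataFrame(rows, columns=["snp_id", "beta_obs", "converged"])


class TestDirectionFilter:
    @pytest.fixture()
    def panel3(self):
        from conftest import make_snp
        from centscan import ReferencePanel
        return ReferencePanel([
            make_snp("common_match", maf=0.3, beta_clin=0.2),
            make_snp("common_flip", maf=0.3, beta_clin=0.2),
            make_snp("rare", maf=0.005, beta_clin=0.5),
        ])

    def test_both_match_retained_flip_excluded(self, panel3):
        cc = _scan_frame([("common_match", 0.15, True),
                          ("common_flip", 0.15, True),
                          ("rare", 0.4, True)])
        cent = _scan_frame([("common_match", 0.3, True),
                            ("common_flip", -0.1, True),
                            ("rare", 0.6, True)])
        keep = direction_filter(cc, cent, panel3)
        assert keep == ["common_match"]

    def test_either_mode_keeps_single_match(self, panel3):
        cc = _scan_frame([("common_match", 0.15, True),
                          ("common_flip", 0.15, True),
                          ("rare", 0.4, True)])
        cent = _scan_frame([("common_match", 0.3, True),
                            ("common_flip", -0.1, True),
                            ("rare", 0.6, True)])
        keep = direction_filter(cc, cent, panel3, require_match_in="either")
        assert keep == ["common_match", "common_flip"]

    def test_rare_snp_always_excluded(self, panel3):
        cc = _scan_frame([("rare", 0.4, True)])
        cent = _scan_frame([("rare", 0.6, True)])
        assert direction_filter(cc, cent, panel3) == []

    def test_nonconverged_never_matches(self, panel3):
        cc = _scan_frame([("common_match", np.nan, False)])
        cent = _scan_frame([("common_match", 0.3, True)])
        assert direction_filter(cc, cent, panel3) == []


def _escalation_frame(entries):
    rows = []
    for snp_id, n_am, c_am, n_ct, c_ct in entries:
        rows.append({"snp_id": snp_id, "control_type": AGE_MATCHED_CONTROL,
                     "n_required": n_am, "converged": c_am})
        rows.append({"snp_id": snp_id, "control_type": CENTENARIAN,
                     "n_required": n_ct, "converged": c_ct})
    return pd.DataFrame(rows)


class TestEquivalenceSummary:
    def test_equal_arms_give_unit_ratios(self):
        df = _escalation_frame([("a", 600, True, 600, True),
                                ("b", 1200, True, 1200, True)])
        s = equivalence_summary(df)
        assert s.mean == 1.0 and s.median == 1.0
        assert s.shortlist == []

    def test_cap_sentinel_arithmetic(self):
        df = _escalation_frame([("a", 16_000, False, 400, True)])
        s = equivalence_summary(df)
        assert s.ratios["a"] == pytest.approx(40.0)
        assert s.shortlist == ["a"]

    def test_double_nonconvergence_excluded(self):
        df = _escalation_frame([("a", 16_000, False, 16_000, False),
                                ("b", 800, True, 400, True)])
        s = equivalence_summary(df)
        assert s.n_excluded_nonconverged == 1
        assert list(s.ratios.index) == ["b"]

    def test_all_nonconverged_is_error(self):
        df = _escalation_frame([("a", 16_000, False, 16_000, False)])
        with pytest.raises(ValidationError):
            equivalence_summary(df)

    def test_stronger_centenarian_betas_raise_ratio(self, small_panel):
        """Doubling the assumed centenarian-arm effect inflates the ratio."""
        snps = [s for s in small_panel if not s.is_apoe]
        cc = _scan_frame([(s.snp_id, s.beta_clin, True) for s in snps])
        cent = _scan_frame([(s.snp_id, 2 * s.beta_clin, True) for s in snps])
        esc = escalate_panel(small_panel, cc, cent,
                             [s.snp_id for s in snps])
        s = equivalence_summary(esc)
        assert s.median > 1.0
        assert (s.ratios >= 1.0).all()
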