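import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from vteppx import (
    CalibrationError,
    Cohort,
    SynthConfig,
    config_digest,
    derive_lognormal_params,
    generate_cohort,
    quantile_prescribing_report,
    summarize_cohort,
)


class TestLognormalMomentMatch:
    def test_vte_targets_closed_form(self):
        mu, sigma = derive_lognormal_params(0.0126, 0.0074)
        assert mu == pytest.approx(math.log(0.0074))
        assert mu == pytest.approx(-4.906, abs=5e-4)
        assert sigma == pytest.approx(1.032, abs=5e-4)

    def test_bleed_targets_closed_form(self):
        _, sigma = derive_lognormal_params(0.0052, 0.0021)
        assert sigma == pytest.approx(1.347, abs=5e-4)

    def test_unit_scale_identity(self):
        med = 0.01
        _, sigma = derive_lognormal_params(med * math.exp(0.5), med)
        assert sigma == pytest.approx(1.0)

    def test_mean_not_above_median_rejected(self):
        with pytest.raises(CalibrationError):
            derive_lognormal_params(0.005, 0.006)

    def test_simulated_draws_recover_targets(self):
        """Simulation oracle: 10^6 draws from the derived law reproduce the
        requested mean and median within 1%."""
        rng = np.random.default_rng(123)
        for mean, median in [(0.0126, 0.0074), (0.0052, 0.0021)]:
            mu, sigma = derive_lognormal_params(mean, median)
            draws = np.exp(rng.normal(mu, sigma, size=1_000_000))
            assert np.median(draws) == pytest.approx(median, rel=0.01)
            assert np.mean(draws) == pytest.approx(mean, rel=0.01)


class TestGenerator:
    def test_fixed_seed_reproducible(self):
        cfg = SynthConfig(n=10, seed=4)
        assert generate_cohort(cfg) == generate_cohort(cfg)

    def test_metadata_records_provenance(self):
        cfg = SynthConfig(n=50, seed=4)
        c = generate_cohort(cfg)
        assert c.metadata["source"] == "synthetic"
        assert c.metadata["seed"] == "4"
        assert c.metadata["config_digest"] == config_digest(cfg)

    def test_risks_respect_clip_intervals(self, default_cohort):
        cfg = SynthConfig()
        assert default_cohort.p_vte.min() >= cfg.vte_clip[0]
        assert default_cohort.p_vte.max() <= cfg.vte_clip[1]
        assert default_cohort.p_bleed.min() >= cfg.bleed_clip[0]
        assert default_cohort.p_bleed.max() <= cfg.bleed_clip[1]

    def test_default_marginals_near_targets(self, default_cohort):
        s = summarize_cohort(default_cohort)
        assert 0.006 <= s.p_vte_median <= 0.009
        assert 0.010 <= s.p_vte_mean <= 0.016

    def test_overall_prescribing_near_target(self, default_cohort):
        rate = default_cohort.physician_prophylaxis.mean()
        assert abs(rate - 0.617) <= 0.03

    def test_prescribing_gradient_strong_on_vte_axis(self, default_cohort):
        rep = quantile_prescribing_report(default_cohort, 10)
        rates = rep[rep.axis == "p_vte"].prescribed_frac.to_numpy()
        assert rates[-1] - rates[0] >= 0.20

    def test_prescribing_flat_on_bleeding_tail(self, default_cohort):
        """High-bleeding-risk patients (>= 10%) are prescribed at close to
        the overall rate: physicians respond to VTE risk, and only a small
        correlation leak reaches the bleeding axis. Asserted on the
        generator's expected prescribing probability because the subgroup
        holds only ~0.2% of patients."""
        a = float(default_cohort.metadata["prescribing_intercept"])
        b = float(default_cohort.metadata["prescribing_slope"])
        log_v = np.log(default_cohort.p_vte)
        z = (log_v - log_v.mean()) / log_v.std()
        expected = expit(a + b * z)
        tail = default_cohort.p_bleed >= 0.10
        assert tail.sum() > 0
        overall = default_cohort.physician_prophylaxis.mean()
        assert abs(expected[tail].mean() - overall) <= 0.10

    def test_marginal_fidelity_across_seeds(self):
        """Mean of sample medians over 20 seeds stays within 5% relative
        error of both risk targets."""
        v_medians, b_medians = [], []
        for seed in range(100, 120):
            c = generate_cohort(SynthConfig(seed=seed))
            v_medians.append(np.median(c.p_vte))
            b_medians.append(np.median(c.p_bleed))
        assert np.mean(v_medians) == pytest.approx(0.0074, rel=0.05)
        assert np.mean(b_medians) == pytest.approx(0.0021, rel=0.05)

    def test_infeasible_prescribing_targets_rejected(self):
        with pytest.raises(CalibrationError):
            generate_cohort(
                SynthConfig(n=100, physician_low_rate=0.7,
                            physician_overall_rate=0.6)
            )
        with pytest.raises(CalibrationError):
            generate_cohort(
                SynthConfig(n=100, physician_low_rate=0.9,
                            physician_high_rate=0.5)
            )


class TestScores:
    def test_zero_noise_pins_threshold_crossings(self):
        c = generate_cohort(SynthConfig(n=5000, seed=21, score_noise=0.0))
        frac_padua = np.mean(c.padua_score >= 4)
        frac_vte = np.mean(c.p_vte >= 0.01)
        assert frac_padua == pytest.approx(frac_vte, abs=1e-9)
        frac_improve = np.mean(c.improve_score >= 7)
        frac_bleed = np.mean(c.p_bleed >= 0.0078)
        assert frac_improve == pytest.approx(frac_bleed, abs=1e-9)

    def test_noise_keeps_crossings_correlated_not_identical(self):
        c = generate_cohort(SynthConfig(n=5000, seed=21, score_noise=0.1))
        padua_high = c.padua_score >= 4
        vte_high = c.p_vte >= 0.01
        agreement = np.mean(padua_high == vte_high)
        assert 0.8 < agreement < 1.0
        assert not np.array_equal(padua_high, vte_high)

    def test_scores_bounded_integers(self, default_cohort):
        assert default_cohort.padua_score.min() >= 0
        assert default_cohort.padua_score.max() <= 10
        assert default_cohort.improve_score.min() >= 0
        assert default_cohort.improve_score.max() <= 12


class TestQuantileReport:
    @staticmethod
    def _manual_cohort(n, rng, ppx):
        return Cohort(
            pd.DataFrame(
                {
                    "patient_id": [f"m{i}" for i in range(n)],
                    "p_vte": rng.uniform(0.004, 0.2, n),
                    "p_bleed": rng.uniform(0.001, 0.1, n),
                    "physician_prophylaxis": ppx,
                }
            )
        )

    def test_risk_independent_prescribing_is_flat(self):
        rng = np.random.default_rng(8)
        n = 5000
        c = self._manual_cohort(n, rng, rng.random(n) < 0.5)
        rep = quantile_prescribing_report(c, 10)
        for axis in ("p_vte", "p_bleed"):
            rates = rep[rep.axis == axis].prescribed_frac
            assert np.all(np.abs(rates - 0.5) < 0.1)

    def test_perfectly_sorted_prescribing_splits_0_100(self):
        rng = np.random.default_rng(9)
        n = 1000
        pv = rng.uniform(0.004, 0.2, n)
        c = Cohort(
            pd.DataFrame(
                {
                    "patient_id": [f"m{i}" for i in range(n)],
                    "p_vte": pv,
                    "p_bleed": rng.uniform(0.001, 0.1, n),
                    "physician_prophylaxis": pv > np.median(pv),
                }
            )
        )
        rep = quantile_prescribing_report(c, 2)
        vte_rates = rep[rep.axis == "p_vte"].prescribed_frac.tolist()
        assert vte_rates == [0.0, 1.0]

    def test_quantiles_are_equal_count(self, default_cohort):
        rep = quantile_prescribing_report(default_cohort, 10)
        counts = rep[rep.axis == "p_vte"].n
        assert counts.max() - counts.min() <= 1

    def test_bad_quantile_counts_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            quantile_prescribing_report(small_cohort, 1)
        with pytest.raises(ValueError):
            quantile_prescribing_report(small_cohort, small_cohort.n + 1)
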