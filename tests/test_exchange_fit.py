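"""Tests of preprocessing, global biexponential fitting and jackknife errors."""

import math

import numpy as np
import pytest

from mimsfit import (
    EnrichmentSpec,
    ExchangeParams,
    FitConfig,
    FlashProtocol,
    MimsSimConfig,
    MimsTrace,
    fast_fraction_a,
    global_fit,
    jackknife_errors,
    mz36_model,
    preprocess,
    simulate_mims,
)


def early_grid(injection=1.0, t_min=1e-4, t_max=20.0, n_post=60, n_pre=8):
    """Grid whose first post-injection sample is early enough for auto
    residual-step estimation (k_f * t_min << 1)."""
    pre = np.linspace(0.0, injection * 0.95, n_pre)
    return np.concatenate([pre, injection + np.geomspace(t_min, t_max, n_post)])


class TestPreprocess:
    def test_zero_artifacts_identity_after_rezeroing(self, wt_sim_config):
        raw = simulate_mims(wt_sim_config)
        clean = preprocess(raw, residual_estimate=None)
        np.testing.assert_allclose(
            clean.t, raw.t - raw.injection_time, atol=1e-15
        )
        np.testing.assert_allclose(clean.y34, raw.y34, atol=1e-12)
        np.testing.assert_allclose(clean.y36, raw.y36, atol=1e-12)
        assert clean.injection_time == 0.0

    def test_auto_step_removal_matches_artifact_free_twin(
        self, wt_truth, enrichment, s2_protocol
    ):
        """Same-seed traces with and without a residual-O2 step agree after
        auto correction (early first sample keeps the estimator unbiased)."""
        base = dict(
            truth=wt_truth, enrichment=enrichment, protocol=s2_protocol,
            time_grid=early_grid(), noise_sigma=0.005, seed=11,
        )
        with_step = simulate_mims(MimsSimConfig(**base, residual_o2_step=0.05))
        without = simulate_mims(MimsSimConfig(**base))
        corrected = preprocess(with_step, residual_estimate="auto")
        twin = preprocess(without, residual_estimate=None)
        # two noisy samples enter the step estimate -> tolerance ~3 sigma sqrt(2)
        tol = 3 * 0.005 * math.sqrt(2) + 0.01
        assert np.max(np.abs(corrected.y34 - twin.y34)) < tol
        assert np.max(np.abs(corrected.y36 - twin.y36)) < tol

    def test_explicit_step_subtraction_is_exact(self, wt_truth, enrichment, s3_protocol):
        cfg = MimsSimConfig(
            truth=wt_truth, enrichment=enrichment, protocol=s3_protocol,
            residual_o2_step=0.07,
        )
        clean = preprocess(simulate_mims(cfg), residual_estimate=(0.07, 0.07))
        twin = preprocess(
            simulate_mims(MimsSimConfig(
                truth=wt_truth, enrichment=enrichment, protocol=s3_protocol
            )),
            residual_estimate=None,
        )
        np.testing.assert_allclose(clean.y34, twin.y34, atol=1e-12)
        np.testing.assert_allclose(clean.y36, twin.y36, atol=1e-12)

    def test_baseline_mean_removed(self, wt_truth, enrichment, s2_protocol):
        cfg = MimsSimConfig(
            truth=wt_truth, enrichment=enrichment, protocol=s2_protocol,
            time_grid=early_grid(), noise_sigma=0.01, seed=3,
        )
        raw = simulate_mims(cfg)
        shifted = MimsTrace(
            t=raw.t, y34=raw.y34 + 0.3, y36=raw.y36 - 0.2,
            injection_time=raw.injection_time, meta=raw.meta,
        )
        clean = preprocess(shifted, residual_estimate="auto")
        pre = clean.t < 0
        assert abs(clean.y34[pre].mean()) < 1e-12
        assert abs(clean.y36[pre].mean()) < 1e-12

    def test_auto_requires_baseline_points(self, wt_truth, enrichment, s2_protocol):
        grid = np.concatenate([[0.9], 1.0 + np.geomspace(1e-3, 10, 30)])
        cfg = MimsSimConfig(
            truth=wt_truth, enrichment=enrichment, protocol=s2_protocol,
            time_grid=grid,
        )
        with pytest.raises(ValueError, match="pre-injection"):
            preprocess(simulate_mims(cfg), residual_estimate="auto")


class TestGlobalFit:
    @pytest.mark.parametrize("k_f,k_s", [(111.0, 0.93), (10.0, 1.0), (500.0, 0.5)])
    def test_exact_recovery_on_noiseless_data(self, enrichment, s2_protocol, k_f, k_s):
        """Noiseless synthetic traces are recovered to <=1e-6 relative error
        for rate contrasts >= 10x, including the channel gains."""
        cfg = MimsSimConfig(
            truth=ExchangeParams(k_f=k_f, k_s=k_s), enrichment=enrichment,
            protocol=s2_protocol, scale_34=1.7, scale_36=0.6,
        )
        clean = preprocess(simulate_mims(cfg), residual_estimate=None)
        res = global_fit(clean, FitConfig(enrichment=enrichment, protocol=s2_protocol))
        assert res.converged
        assert res.estimates.k_f == pytest.approx(k_f, rel=1e-6)
        assert res.estimates.k_s == pytest.approx(k_s, rel=1e-6)
        assert res.scale_34 == pytest.approx(1.7, rel=1e-6)
        assert res.scale_36 == pytest.approx(0.6, rel=1e-6)

    def test_scale_invariance(self, wt_sim_config, fit_config):
        raw = simulate_mims(wt_sim_config)
        clean = preprocess(raw, residual_estimate=None)
        scaled = MimsTrace(
            t=clean.t, y34=clean.y34 * 37.0, y36=clean.y36 * 37.0,
            injection_time=0.0, meta=clean.meta,
        )
        r1 = global_fit(clean, fit_config)
        r2 = global_fit(scaled, fit_config)
        assert r2.estimates.k_f == pytest.approx(r1.estimates.k_f, rel=1e-9)
        assert r2.estimates.k_s == pytest.approx(r1.estimates.k_s, rel=1e-9)

    def test_shared_slow_rate_across_channels(self, wt_sim_config, fit_config):
        """The k_s reported is the one used in both channels' residuals."""
        clean = preprocess(simulate_mims(wt_sim_config), residual_estimate=None)
        res = global_fit(clean, fit_config)
        post = clean.t >= 0
        m36 = res.scale_36 * mz36_model(clean.t[post], res.estimates)
        np.testing.assert_allclose(res.residuals_36, clean.y36[post] - m36, atol=1e-12)

    def test_fixed_a_equals_enrichment_formula(self, wt_sim_config, fit_config):
        clean = preprocess(simulate_mims(wt_sim_config), residual_estimate=None)
        res = global_fit(clean, fit_config)
        assert res.a_fixed
        assert res.a == fast_fraction_a(fit_config.enrichment)

    def test_free_a_recovers_enrichment_value(self, wt_sim_config, enrichment, s2_protocol):
        clean = preprocess(simulate_mims(wt_sim_config), residual_estimate=None)
        config = FitConfig(
            enrichment=enrichment, protocol=s2_protocol, fix_a_from_enrichment=False
        )
        res = global_fit(clean, config)
        assert not res.a_fixed
        assert res.a == pytest.approx(fast_fraction_a(enrichment), rel=1e-4)

    def test_ignoring_interflash_exchange_biases_fast_rate(
        self, wt_truth, enrichment, s2_protocol
    ):
        """Fitting b = 1 on data simulated with inter-flash exchange leaves a
        systematic error in the fast phase that the b-correction removes."""
        config_b = FitConfig(enrichment=enrichment, protocol=s2_protocol)
        config_nob = FitConfig(
            enrichment=enrichment, protocol=s2_protocol, fix_b_from_protocol=False
        )
        bias_b, bias_nob = [], []
        for seed in range(5):
            cfg = MimsSimConfig(
                truth=wt_truth, enrichment=enrichment, protocol=s2_protocol,
                noise_sigma=0.01, seed=seed,
            )
            clean = preprocess(simulate_mims(cfg), residual_estimate=None)
            bias_b.append(global_fit(clean, config_b).estimates.k_f / wt_truth.k_f - 1)
            bias_nob.append(global_fit(clean, config_nob).estimates.k_f / wt_truth.k_f - 1)
        assert abs(np.median(bias_nob)) > abs(np.median(bias_b))
        assert abs(np.median(bias_b)) < 0.05

    def test_low_contrast_flags_degeneracy_with_monophasic_alternative(
        self, enrichment, s3_protocol
    ):
        cfg = MimsSimConfig(
            truth=ExchangeParams(k_f=1.5, k_s=1.0), enrichment=enrichment,
            protocol=s3_protocol, noise_sigma=0.005, seed=0,
        )
        clean = preprocess(simulate_mims(cfg), residual_estimate=None)
        res = global_fit(clean, FitConfig(enrichment=enrichment, protocol=s3_protocol))
        assert res.degenerate
        assert any("monophasic" in w for w in res.warnings)
        assert res.monophasic_alternative is not None
        assert res.monophasic_alternative["k"] == pytest.approx(1.0, rel=0.3)

    def test_too_few_points_rejected(self, enrichment, s3_protocol, wt_truth):
        grid = np.concatenate([np.linspace(0, 0.9, 4), 1.0 + np.geomspace(0.01, 10, 5)])
        cfg = MimsSimConfig(
            truth=wt_truth, enrichment=enrichment, protocol=s3_protocol,
            time_grid=grid,
        )
        clean = preprocess(simulate_mims(cfg), residual_estimate=None)
        with pytest.raises(ValueError, match="post-injection"):
            global_fit(clean, FitConfig(enrichment=enrichment, protocol=s3_protocol))


class TestJackknife:
    def test_noiseless_replicates_give_zero_error(self, wt_sim_config, fit_config):
        """Every leave-one-out refit of an exact-model trace lands on the same
        estimates, so the jackknife SE collapses to ~0."""
        clean = preprocess(simulate_mims(wt_sim_config), residual_estimate=None)
        base = global_fit(clean, fit_config)
        res = jackknife_errors(clean, fit_config, base)
        assert res.se_reliable
        assert res.std_errors["k_f"] < 1e-4 * base.estimates.k_f
        assert res.std_errors["k_s"] < 1e-4 * base.estimates.k_s

    def test_matches_brute_force_leave_one_out(self, wt_truth, enrichment, s2_protocol):
        """Independent oracle: refit each deletion from scratch with global_fit
        and apply the textbook jackknife variance formula."""
        grid = np.concatenate(
            [np.linspace(0, 0.95, 4), 1.0 + np.geomspace(2e-3, 20.0, 12)]
        )
        cfg = MimsSimConfig(
            truth=wt_truth, enrichment=enrichment, protocol=s2_protocol,
            time_grid=grid, noise_sigma=0.01, seed=21,
        )
        fit_config = FitConfig(enrichment=enrichment, protocol=s2_protocol)
        clean = preprocess(simulate_mims(cfg), residual_estimate=None)
        base = global_fit(clean, fit_config)
        res = jackknife_errors(clean, fit_config, base)

        post = np.flatnonzero(clean.t >= 0)
        reps = {"k_f": [], "k_s": []}
        for idx in post:
            keep = np.ones(clean.t.size, dtype=bool)
            keep[idx] = False
            sub = MimsTrace(
                t=clean.t[keep], y34=clean.y34[keep], y36=clean.y36[keep],
                injection_time=0.0, meta=clean.meta,
            )
            r = global_fit(sub, fit_config)
            assert r.converged
            reps["k_f"].append(r.estimates.k_f)
            reps["k_s"].append(r.estimates.k_s)
        n = len(post)
        for name in ("k_f", "k_s"):
            vals = np.array(reps[name])
            expected = math.sqrt((n - 1) / n * np.sum((vals - vals.mean()) ** 2))
            assert res.std_errors[name] == pytest.approx(expected, rel=1e-3)

    def test_replicate_table_returned_for_diagnostics(self, wt_truth, enrichment, s2_protocol):
        cfg = MimsSimConfig(
            truth=wt_truth, enrichment=enrichment, protocol=s2_protocol,
            noise_sigma=0.01, seed=2,
        )
        fit_config = FitConfig(enrichment=enrichment, protocol=s2_protocol)
        clean = preprocess(simulate_mims(cfg), residual_estimate=None)
        res = jackknife_errors(clean, fit_config, global_fit(clean, fit_config))
        n_post = int(np.sum(clean.t >= 0))
        assert set(res.jackknife_replicates) >= {"k_f", "k_s"}
        assert res.jackknife_replicates["k_f"].size == n_post

    def test_requires_converged_base(self, wt_sim_config, fit_config):
        clean = preprocess(simulate_mims(wt_sim_config), residual_estimate=None)
        base = global_fit(clean, fit_config)
        base.converged = False
        with pytest.raises(ValueError, match="converged"):
            jackknife_errors(clean, fit_config, base)
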