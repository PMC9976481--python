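import numpy as np
import pandas as pd
import pytest

from spiralspread.distribution_fits import (
    component_diffusion,
    fit_centred_mixture,
    fit_centred_student,
    gaussianity_diagnostics,
    select_model,
    track_components,
)
from spiralspread.simulate import SimConfig, simulate_replicate


def gmix_sample(n, weights, scales, seed):
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(weights), size=n, p=weights)
    return rng.normal(0.0, np.asarray(scales)[comp])


class TestCentredMixture:
    def test_k1_closed_form(self):
        x = np.array([2.0, -4.0, 10.0, 0.0, 1.0, -1.0, 3.0, -3.0, 5.0, -5.0])
        fit = fit_centred_mixture(x, K=1)
        assert fit.scales[0] == pytest.approx(np.sqrt(np.mean(x**2)))
        assert fit.weights[0] == 1.0
        assert fit.aic == pytest.approx(2.0 - 2.0 * fit.loglik)

    def test_k2_recovery(self):
        x = gmix_sample(4000, [0.5, 0.5], [5.0, 50.0], seed=1)
        fit = fit_centred_mixture(x, K=2, seed=0)
        assert fit.weights[1] == pytest.approx(0.5, abs=0.05)
        assert fit.scales[0] == pytest.approx(5.0, rel=0.1)
        assert fit.scales[1] == pytest.approx(50.0, rel=0.1)
        assert fit.converged and not fit.degenerate

    def test_scales_sorted_and_weights_normalised(self):
        x = gmix_sample(2000, [0.3, 0.7], [2.0, 20.0], seed=2)
        fit = fit_centred_mixture(x, K=3, seed=0)
        assert np.all(np.diff(fit.scales) >= 0)
        assert fit.weights.sum() == pytest.approx(1.0)

    def test_em_loglik_monotone(self):
        x = gmix_sample(500, [0.5, 0.5], [1.0, 10.0], seed=3)
        _, trace = fit_centred_mixture(x, K=2, seed=0, return_trace=True)
        assert len(trace) >= 2
        assert np.all(np.diff(trace) >= -1e-6)

    def test_single_scale_data_effectively_unimodal(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0.0, 7.0, 3000)
        fit = fit_centred_mixture(x, K=2, seed=0)
        assert fit.effectively_unimodal

    def test_pdf_integrates_to_one(self):
        x = gmix_sample(1000, [0.5, 0.5], [1.0, 10.0], seed=5)
        fit = fit_centred_mixture(x, K=2, seed=0)
        grid = np.linspace(-100, 100, 20001)
        assert np.trapezoid(fit.pdf(grid), grid) == pytest.approx(1.0, abs=1e-4)

    def test_too_few_observations_raises(self):
        with pytest.raises(ValueError):
            fit_centred_mixture(np.ones(15), K=2)


class TestCentredStudent:
    def test_recovers_df_three(self):
        rng = np.random.default_rng(6)
        x = 4.0 * rng.standard_t(3.0, size=4000)
        fit = fit_centred_student(x)
        assert 2.5 <= fit.df <= 3.6
        assert fit.scale == pytest.approx(4.0, rel=0.12)

    def test_gaussian_data_hits_nu_cap(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0.0, 5.0, 2000)
        fit = fit_centred_student(x)
        assert fit.df >= 100.0
        assert fit.scale == pytest.approx(5.0, rel=0.1)

    def test_heavier_tails_smaller_nu(self):
        rng = np.random.default_rng(8)
        base = rng.normal(0.0, 1.0, 2000)
        light = fit_centred_student(base)
        contaminated = np.concatenate([base, 20.0 * rng.standard_t(2.0, size=400)])
        heavy = fit_centred_student(contaminated)
        assert heavy.df < light.df

    def test_too_few_observations_raises(self):
        with pytest.raises(ValueError):
            fit_centred_student(np.ones(5))


class TestSelectModel:
    def test_two_component_data_picks_gmix2(self):
        x = gmix_sample(4000, [0.5, 0.5], [5.0, 50.0], seed=9)
        assert select_model(x)["best"] == "gmix2"

    def test_gaussian_control_picks_gaussian(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0.0, 10.0, 4000)
        assert select_model(x)["best"] == "gaussian"

    def test_student_data_picks_student(self):
        rng = np.random.default_rng(11)
        x = 5.0 * rng.standard_t(3.0, size=4000)
        assert select_model(x)["best"] == "student"

    def test_ranking_sorted_by_aic(self):
        x = gmix_sample(1000, [0.5, 0.5], [2.0, 20.0], seed=12)
        out = select_model(x)
        aics = [out["aic"][k] for k in out["ranking"]]
        assert aics == sorted(aics)

    def test_too_few_observations_raises(self):
        with pytest.raises(ValueError):
            select_model(np.ones(20))


class TestKurtosis:
    def test_scale_mixture_closed_form(self):
        # 0.5/0.5 mixture of variances 25 and 2500:
        # excess kurtosis = 3 E[v^2]/E[v]^2 - 3 = 3*(25^2+2500^2)/2 / ((25+2500)/2)^2 - 3
        v = np.array([25.0, 2500.0])
        expected = 3.0 * np.mean(v**2) / np.mean(v) ** 2 - 3.0
        assert expected == pytest.approx(2.88, abs=5e-3)
        x = gmix_sample(100_000, [0.5, 0.5], np.sqrt(v), seed=13)
        diag = gaussianity_diagnostics(x)
        assert diag["excess_kurtosis"] == pytest.approx(expected, rel=0.1)

    def test_gaussian_has_zero_excess(self):
        rng = np.random.default_rng(14)
        diag = gaussianity_diagnostics(rng.normal(0.0, 3.0, 100_000))
        assert diag["excess_kurtosis"] == pytest.approx(0.0, abs=0.05)

    def test_per_replicate_normalisation_removes_between_rep_heterogeneity(self):
        # each replicate is Gaussian, but scales differ across replicates:
        # pooled kurtosis is positive, renormalised kurtosis is ~0
        rng = np.random.default_rng(15)
        reps = [rng.normal(0.0, s, 5000) for s in (1.0, 1.0, 10.0, 10.0)]
        pooled = gaussianity_diagnostics(np.concatenate(reps))
        within = gaussianity_diagnostics(per_replicate=reps)
        assert pooled["excess_kurtosis"] > 1.0
        assert within["excess_kurtosis"] == pytest.approx(0.0, abs=0.1)

    def test_true_scale_mixture_survives_normalisation(self):
        rng = np.random.default_rng(16)
        reps = [gmix_sample(5000, [0.5, 0.5], [5.0, 50.0], seed=100 + i) for i in range(4)]
        within = gaussianity_diagnostics(per_replicate=reps)
        assert within["excess_kurtosis"] > 1.0

    def test_qq_deviation_near_zero_for_gaussian(self):
        rng = np.random.default_rng(17)
        diag = gaussianity_diagnostics(rng.normal(0.0, 2.0, 50_000))
        assert np.all(np.abs(diag["qq_deviation"]) < 0.05)


def synthetic_mixture_table(n_reps=4, n_per=300, t_grid=range(15, 481, 15), seed=18):
    """Detections drawn directly from a known time-constant two-mode law."""
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(n_reps):
        for t in t_grid:
            comp = rng.choice(2, size=n_per, p=[0.5, 0.5])
            s = rng.normal(0.0, np.where(comp == 0, 3.0, 30.0))
            rows.append(pd.DataFrame({"replicate": r, "treatment": "x", "t": t, "s": s}))
    return pd.concat(rows, ignore_index=True)


class TestTrackComponents:
    def test_constant_mixture_recovered_flat(self):
        traj = track_components(synthetic_mixture_table(), B=0)
        rel = traj[traj["reliable"]]
        assert len(rel) >= 20
        assert rel["pi_explorer"].mean() == pytest.approx(0.5, abs=0.05)
        assert rel["sigma_resident"].between(2.0, 4.0).all()
        assert rel["sigma_explorer"].between(25.0, 35.0).all()

    def test_bootstrap_ci_brackets_point_estimate(self):
        traj = track_components(synthetic_mixture_table(n_reps=4, n_per=150), B=50, seed=1)
        rel = traj[traj["reliable"]]
        inside = (
            (rel["pi_ci_low"] <= rel["pi_explorer"]) & (rel["pi_explorer"] <= rel["pi_ci_high"])
        ).mean()
        assert inside >= 0.8

    def test_early_windows_flagged_unreliable(self):
        traj = track_components(synthetic_mixture_table(), B=0)
        assert not traj.loc[traj["t"] < 60, "reliable"].any()
        assert traj.loc[traj["t"] >= 60, "reliable"].all()

    def test_sparse_windows_skipped(self):
        tab = pd.DataFrame(
            {"replicate": 0, "treatment": "x", "t": [15] * 10, "s": np.arange(10.0)}
        )
        assert track_components(tab, B=0, min_pooled=50).empty

    def test_all_resident_simulation_degenerates_to_narrow(self):
        cfg = SimConfig(
            n_agents=200, duration=120, seed=19,
            switch_re_base=0.0, switch_re_density_coef=0.0,
            switch_re_host_boost=0.0, switch_er_hazard=0.0,
        )
        det, _ = simulate_replicate(cfg)
        traj = track_components(det, B=0)
        # single-scale data: both fitted scales track the resident scale
        assert (traj["sigma_explorer"] / traj["sigma_resident"] < 2.0).all()


class TestComponentDiffusion:
    def test_linear_growth_returns_linear_fit(self):
        t = np.arange(15, 481, 15, dtype=float)
        traj = pd.DataFrame({"t": t, "msd_explorer": 25.0 * t})
        fit = component_diffusion(traj, bootstrap_B=49, seed=0)
        assert fit.D == pytest.approx(25.0, rel=1e-6)
        assert not hasattr(fit, "breakpoint") or fit.breakpoint is None

    def test_broken_growth_returns_piecewise_fit(self):
        t = np.arange(15, 481, 15, dtype=float)
        y = np.where(t <= 240, 25.0 * t, 25.0 * 240 + 5.0 * (t - 240))
        rng = np.random.default_rng(20)
        traj = pd.DataFrame({"t": t, "msd_explorer": y + rng.normal(0, 30, t.size)})
        fit = component_diffusion(traj, bootstrap_B=99, seed=1)
        assert hasattr(fit, "breakpoint")
        assert fit.breakpoint == pytest.approx(240.0, abs=45.0)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            component_diffusion(pd.DataFrame({"t": [1.0], "msd_explorer": [1.0]}))
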