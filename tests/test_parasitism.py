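import numpy as np
import pandas as pd
import pytest

from spiralspread.distribution_fits import track_components
from spiralspread.parasitism import (
    assign_discoverer,
    correlate_metrics,
    discovery_times,
    dispersal_kernel,
    gain_curve,
    on_host_fraction,
)


def host_table(s, parasitized, total_visit=None, first_discovery=None):
    s = np.asarray(s, dtype=float)
    n = s.size
    return pd.DataFrame(
        {
            "host_id": np.arange(n),
            "s": s,
            "patch_id": np.arange(n),
            "first_discovery": first_discovery if first_discovery is not None else np.full(n, 10.0),
            "total_visit": total_visit if total_visit is not None else np.full(n, 30.0),
            "parasitized": np.asarray(parasitized, dtype=bool),
        }
    )


class TestDispersalKernel:
    def test_two_point_sigma(self):
        hosts = host_table([-80.0, 80.0, 200.0], [True, True, False])
        k = dispersal_kernel(hosts)
        assert k["sigma_dispersal"] == pytest.approx(80.0)
        assert k["n_parasitized"] == 2 and k["n_hosts"] == 3

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(0)
        s = rng.normal(0, 60, 200).round(0)
        par = rng.random(200) < np.exp(-(s**2) / (2 * 50.0**2))
        k1 = dispersal_kernel(host_table(s, par))
        k2 = dispersal_kernel(host_table(-s, par))
        assert k1["sigma_dispersal"] == pytest.approx(k2["sigma_dispersal"])
        # binned Gaussian fit is only approximately invariant (edges anchor at the minimum)
        assert k1["gaussian_sigma"] == pytest.approx(k2["gaussian_sigma"], rel=0.02)

    def test_gaussian_kernel_recovered(self):
        # deterministic fractions: p(s) = 0.8 exp(-s^2 / (2*60^2)) realised exactly
        s = np.repeat(np.arange(-285.0, 286.0, 30.0), 100)
        p = 0.8 * np.exp(-(s**2) / (2 * 60.0**2))
        rng = np.random.default_rng(1)
        par = rng.random(s.size) < p
        k = dispersal_kernel(host_table(s, par))
        assert k["gaussian_sigma"] == pytest.approx(60.0, rel=0.15)
        assert k["gaussian_amplitude"] == pytest.approx(0.8, abs=0.1)
        assert not k["flat_kernel"]

    def test_flat_kernel_flagged(self):
        s = np.repeat(np.arange(-285.0, 286.0, 30.0), 50)
        rng = np.random.default_rng(2)
        par = rng.random(s.size) < 0.5  # distance-independent
        k = dispersal_kernel(host_table(s, par))
        assert k["flat_kernel"]

    def test_no_parasitism_nan_sigma(self):
        k = dispersal_kernel(host_table([-50.0, 50.0], [False, False]))
        assert np.isnan(k["sigma_dispersal"])
        assert k["n_parasitized"] == 0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            dispersal_kernel(host_table([], []))


class TestOnHostFraction:
    def detections(self, s, t=10.0):
        return pd.DataFrame({"replicate": 0, "treatment": "x", "t": t, "s": np.asarray(s, float)})

    def test_all_on_hosts(self):
        tab = self.detections([15.0, 15.2, -15.1])
        out = on_host_fraction(tab, [-15.0, 15.0], [10.0])
        assert (out["fraction"] == 1.0).all()

    def test_none_on_hosts(self):
        tab = self.detections([0.0, 5.0, -5.0])
        out = on_host_fraction(tab, [100.0], [10.0])
        assert (out["fraction"] == 0.0).all()

    def test_empty_host_list_empty_frame(self):
        out = on_host_fraction(self.detections([1.0]), [], [10.0])
        assert out.empty

    def test_counts_per_bin(self):
        tab = self.detections([1.0, 2.0, 3.0, 14.8, 15.0])
        out = on_host_fraction(tab, [15.0], [10.0], bin_width=10.0)
        total = out["n"].sum()
        assert total == 5
        bin_15 = out[out["bin_centre"] == 15.0]
        assert bin_15["fraction"].iloc[0] == pytest.approx(1.0)


class TestDiscoveryTimes:
    def test_sorted_and_filtered(self):
        hosts = host_table(
            [10.0, -200.0, 50.0],
            [False, False, False],
            first_discovery=np.array([12.0, 300.0, np.nan]),
        )
        out = discovery_times(hosts)
        assert list(out["host_id"]) == [0, 1]
        assert out["abs_s"].is_monotonic_increasing

    def test_all_undiscovered_raises(self):
        hosts = host_table([1.0], [False], first_discovery=np.array([np.nan]))
        with pytest.raises(ValueError):
            discovery_times(hosts)


def constant_mixture_traj(pi=0.5, sig_r=3.0, sig_e=30.0, t_grid=np.arange(15.0, 481.0, 15.0)):
    return pd.DataFrame(
        {
            "t": t_grid,
            "pi_explorer": pi,
            "pi_ci_low": np.nan,
            "pi_ci_high": np.nan,
            "sigma_resident": sig_r,
            "sigma_explorer": sig_e,
            "msd_explorer": sig_e**2,
            "n": 1000,
            "reliable": t_grid >= 60.0,
        }
    )


class TestAssignDiscoverer:
    def test_far_hosts_explorer_near_hosts_resident(self):
        traj = constant_mixture_traj()
        hosts = host_table(
            [0.5, 150.0], [True, True], first_discovery=np.array([120.0, 120.0])
        )
        out = assign_discoverer(hosts, traj)
        assert out.loc[out["s"] == 0.5, "label"].iloc[0] == "resident"
        assert out.loc[out["s"] == 150.0, "label"].iloc[0] == "explorer"

    def test_posterior_monotone_in_distance(self):
        traj = constant_mixture_traj()
        s = np.array([0.0, 2.0, 5.0, 10.0, 30.0, 60.0, 120.0])
        hosts = host_table(s, [True] * s.size, first_discovery=np.full(s.size, 120.0))
        out = assign_discoverer(hosts, traj)
        p = out.sort_values("s")["p_explorer"].to_numpy()
        assert np.all(np.diff(p) >= -1e-12)

    def test_early_discoveries_unassigned(self):
        traj = constant_mixture_traj()
        hosts = host_table([10.0], [True], first_discovery=np.array([30.0]))
        out = assign_discoverer(hosts, traj)
        assert out["label"].iloc[0] == "unassigned"
        assert np.isnan(out["p_explorer"].iloc[0])

    def test_degenerate_mixture_unassigned(self):
        traj = constant_mixture_traj(sig_r=10.0, sig_e=10.5)
        hosts = host_table([50.0], [True], first_discovery=np.array([120.0]))
        out = assign_discoverer(hosts, traj)
        assert out["label"].iloc[0] == "unassigned"

    def test_accuracy_on_well_separated_synthetic_data(self):
        # ground truth: hosts discovered by explorers sit far out, residents near in
        rng = np.random.default_rng(3)
        n = 400
        is_exp = rng.random(n) < 0.5
        s = rng.normal(0.0, np.where(is_exp, 30.0, 3.0))
        hosts = host_table(s, [True] * n, first_discovery=rng.uniform(70.0, 450.0, n))
        out = assign_discoverer(hosts, constant_mixture_traj())
        truth = np.where(is_exp, "explorer", "resident")
        agree = (out["label"].to_numpy() == truth).mean()
        assert agree >= 0.8


class TestGainCurve:
    def test_recovers_tau(self):
        rng = np.random.default_rng(4)
        T = rng.uniform(0.0, 300.0, 4000)
        par = rng.random(4000) < 1.0 - np.exp(-T / 60.0)
        out = gain_curve(host_table(np.zeros(4000), par, total_visit=T))
        assert out["tau_hat"] == pytest.approx(60.0, rel=0.15)
        assert out["asymptote"] > 0.95

    def test_smoothed_and_proportion_shapes_match(self):
        rng = np.random.default_rng(5)
        T = rng.uniform(0.0, 200.0, 500)
        par = rng.random(500) < 1.0 - np.exp(-T / 60.0)
        out = gain_curve(host_table(np.zeros(500), par, total_visit=T))
        assert out["bin_centres"].shape == out["proportion"].shape == out["smoothed"].shape
        # gain is globally increasing: late bins beat early bins
        assert out["proportion"][-3:].mean() > out["proportion"][:3].mean()

    def test_unvisited_hosts_empty_result(self):
        out = gain_curve(host_table([1.0, 2.0], [False, False], total_visit=np.zeros(2)))
        assert out["bin_centres"].size == 0
        assert np.isnan(out["tau_hat"])


class TestCorrelateMetrics:
    def per_rep(self, n=10, seed=6):
        rng = np.random.default_rng(seed)
        front = rng.uniform(50, 300, n)
        return pd.DataFrame(
            {
                "replicate": np.arange(n),
                "front_98": front,
                "sigma_dispersal": front * 0.5 + rng.normal(0, 5, n),
                "total_parasitism": rng.uniform(0.1, 0.4, n),
            }
        )

    def test_default_pairs_present(self):
        out = correlate_metrics(self.per_rep())
        assert len(out) == 3
        assert set(out.columns) == {"x", "y", "rho", "rho2", "p", "n"}

    def test_perfect_monotone_rho2_one(self):
        df = pd.DataFrame({"a": np.arange(10.0), "b": np.exp(np.arange(10.0))})
        out = correlate_metrics(df, pairs=[("a", "b")])
        assert out["rho"].iloc[0] == pytest.approx(1.0)
        assert out["rho2"].iloc[0] == pytest.approx(1.0)

    def test_constant_column_nan(self):
        df = pd.DataFrame({"a": np.arange(10.0), "b": np.full(10, 3.0)})
        out = correlate_metrics(df, pairs=[("a", "b")])
        assert np.isnan(out["rho"].iloc[0])

    def test_too_few_replicates_raises(self):
        with pytest.raises(ValueError):
            correlate_metrics(self.per_rep(n=4))


class TestEndToEndDiffuseRun:
    """Pipeline-level sanity on a simulated diffuse-host experiment."""

    def test_kernel_and_assignment_consistency(self, diffuse_run):
        truth, det, hosts = diffuse_run
        k = dispersal_kernel(hosts)
        assert 0 < k["n_parasitized"] <= k["n_hosts"]
        assert 10.0 < k["sigma_dispersal"] < 315.0

        traj = track_components(det, B=0)
        out = assign_discoverer(hosts, traj)
        merged = out.merge(hosts[["host_id", "s", "discoverer_mode"]], on=["host_id", "s"])
        scored = merged[merged["label"].isin(["resident", "explorer"])]
        if len(scored) >= 20:
            agree = (scored["label"] == scored["discoverer_mode"]).mean()
            assert agree >= 0.6  # informative, well above chance
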