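"""MLE probe-set summarization, probe adjustment and (a, b) fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

import ampbias.correction as corr
from ampbias.correction import (
    FitError,
    ProbeSetMeasurement,
    adjust_probes,
    adjust_table,
    estimate_ips,
    fit_degradation_limits,
)
from ampbias.model import DegradationParams, RetainingRateCurve, p2_retaining_rate
from ampbias.simulate import SyntheticSpec, generate_dataset


def make_set(z, pm, mm=None, L=1000.0):
    return ProbeSetMeasurement(
        probeset_id="ps", sample_id="s", L=L,
        probe_ids=[f"p{i}" for i in range(len(z))],
        z=np.asarray(z, float), pm=np.asarray(pm, float),
        mm=None if mm is None else np.asarray(mm, float),
    )


def flat_curve(values, grid, L=1000.0):
    return RetainingRateCurve(
        cycle=2, grid=np.asarray(grid, float), values=np.asarray(values, float),
        params=DegradationParams(L=L, a=300.0, b=200.0), method="closed-form",
    )


class TestEstimateIps:
    def test_unit_rates_reduce_to_mean(self):
        c = flat_curve([1.0, 1.0], [0.0, 1000.0])
        out = estimate_ips(make_set([100, 200, 300], [4, 6, 8]), c)
        assert out.ips == pytest.approx(6.0)

    def test_weighted_two_probe_case(self):
        c = flat_curve([1.0, 0.5], [0.0, 1000.0])
        out = estimate_ips(make_set([0, 1000], [10, 5]), c)
        assert out.ips == pytest.approx(10.0)  # (10*1 + 5*0.5) / (1 + 0.25)

    def test_noise_free_exact_with_zero_residual(self, curve2):
        z = np.array([100.0, 250.0, 400.0, 550.0])
        p = np.asarray(curve2(z))
        out = estimate_ips(make_set(z, 700.0 * p), curve2)
        assert out.ips == pytest.approx(700.0, rel=1e-12)
        assert out.residual_scale == pytest.approx(0.0, abs=1e-9)

    def test_matches_numerical_least_squares(self, curve2, rng):
        # independent oracle: SVD least-squares solve of pm ~ c * p, plus a
        # coarse Brent minimization as a second, derivative-free route
        for k in range(50):
            z = rng.uniform(50, 950, 11)
            pm = rng.gamma(2.0, 200.0, 11)
            p = np.asarray(curve2(z))
            c_svd = np.linalg.lstsq(p[:, None], pm, rcond=None)[0][0]
            out = estimate_ips(make_set(z, pm), curve2)
            assert out.ips == pytest.approx(c_svd, rel=1e-9)
            if k < 5:
                res = minimize_scalar(
                    lambda c: float(np.sum((pm - c * p) ** 2)),
                    bracket=(0.0, 1000.0), method="brent", options={"xtol": 1e-12},
                )
                assert out.ips == pytest.approx(res.x, rel=1e-6)

    def test_all_rates_below_floor_uncorrectable(self):
        c = flat_curve([0.01, 0.01], [0.0, 1000.0])
        out = estimate_ips(make_set([10, 20], [5, 6]), c)
        assert "uncorrectable" in out.flags
        np.testing.assert_array_equal(out.pm_adj, [5, 6])


class TestAdjustProbes:
    def test_invert_divides_by_rate(self):
        c = flat_curve([0.5, 0.5, 0.5, 0.5], [0, 300, 600, 1000.0])
        out = adjust_probes(make_set([100, 200, 300], [50, 50, 50]), c, mode="invert")
        np.testing.assert_allclose(out.pm_adj, 100.0)

    def test_invert_floors_tiny_rates(self):
        grid = [0.0, 400.0, 1000.0]
        c = flat_curve([0.01, 0.7, 0.7], grid)
        ps = make_set([0.0, 400.0, 500.0, 600.0], [50.0, 70.0, 70.0, 70.0])
        out = adjust_probes(ps, c, mode="invert", p_floor=0.05)
        assert out.pm_adj[0] == pytest.approx(50.0 / 0.05)  # 1000, not 5000

    def test_mle_residual_noise_free_returns_constant(self, curve2):
        z = np.array([150.0, 300.0, 450.0, 600.0])
        pm = 500.0 * np.asarray(curve2(z))
        out = adjust_probes(make_set(z, pm), curve2, mode="mle-residual")
        np.testing.assert_allclose(out.pm_adj, 500.0, rtol=1e-10)

    def test_unit_rates_are_identity_in_both_modes(self):
        c = flat_curve([1.0, 1.0], [0.0, 1000.0])
        pm = [12.0, 40.0, 7.5]
        for mode in ("invert", "mle-residual"):
            out = adjust_probes(make_set([100, 500, 900], pm), c, mode=mode)
            np.testing.assert_allclose(out.pm_adj, pm, rtol=1e-12)

    def test_invert_never_negative(self, curve2, rng):
        z = rng.uniform(12, 600, 11)
        pm = rng.gamma(1.0, 100.0, 11)
        out = adjust_probes(make_set(z, pm), curve2, mode="invert")
        assert np.all(out.pm_adj >= 0)

    def test_mm_adjusted_with_same_rates(self):
        c = flat_curve([0.5, 0.5], [0.0, 1000.0])
        ps = make_set([100, 200, 300], [50, 50, 50], mm=[10, 10, 10])
        out = adjust_probes(ps, c, mode="invert")
        np.testing.assert_allclose(out.mm_adj, 20.0)
        out = adjust_probes(ps, c, mode="mle-residual")
        # ips = 100; mm_adj = ips + (mm - ips * p) = 100 + (10 - 50) = 60
        np.testing.assert_allclose(out.mm_adj, 60.0)

    def test_unknown_mode_rejected(self, curve2):
        with pytest.raises(ValueError, match="mode"):
            adjust_probes(make_set([100], [5]), curve2, mode="quantile")

    def test_few_probes_above_floor_passed_through(self):
        c = flat_curve([0.01, 0.01, 0.5], [0.0, 500.0, 1000.0])
        ps = make_set([0, 100, 1000], [5.0, 6.0, 7.0])
        out = adjust_probes(ps, c)
        assert "too_few_probes" in out.flags
        np.testing.assert_array_equal(out.pm_adj, ps.pm)


class TestAdjustTable:
    def test_matches_per_set_api_and_preserves_columns(self, curve2, small_dataset):
        _, probes, _ = small_dataset
        sub = probes[probes["probeset_id"].isin(probes["probeset_id"].unique()[:30])]
        table = adjust_table(sub, curve2)
        cols = ["sample_id", "probeset_id", "probe_id", "z", "pm"]
        assert table[cols].reset_index(drop=True).equals(sub[cols].reset_index(drop=True))
        for pset, g in table.groupby("probeset_id"):
            src = sub[sub["probeset_id"] == pset]
            ps = make_set(src["z"].to_numpy(), src["pm"].to_numpy())
            ref = adjust_probes(ps, curve2)
            np.testing.assert_allclose(g["pm_adj"].to_numpy(), ref.pm_adj)
            assert g["ips"].iloc[0] == pytest.approx(ref.ips)


class TestFitDegradationLimits:
    def test_zero_residual_profile_recovers_grid_point(self):
        a_star, b_star, L = 300.0, 200.0, 1000.0
        z = np.arange(12, 578, dtype=float)
        p = p2_retaining_rate(z, DegradationParams(L=L, a=a_star, b=b_star), step=1.0)
        df = pd.DataFrame({
            "sample_id": "s1", "probeset_id": "ps1", "probe_id": "p",
            "z": z, "pm": 5000.0 * p, "present": 1,
        })
        params, diag = fit_degradation_limits(
            df, L=L, a_grid=np.array([250.0, 300.0, 350.0]),
            b_grid=np.array([150.0, 200.0, 250.0]), quad_step=1.0,
        )
        assert (params.a, params.b) == (a_star, b_star)
        assert diag["sse"] < 1e-6

    def test_tie_break_prefers_smaller_a_then_b(self, monkeypatch):
        # constant retaining rate makes every grid point fit equally well
        monkeypatch.setattr(
            corr, "p2_retaining_rate",
            lambda z, params, *a, **k: np.full(np.shape(z), 0.5),
        )
        z = np.arange(12, 200, dtype=float)
        df = pd.DataFrame({
            "sample_id": "s1", "probeset_id": "ps1", "probe_id": "p",
            "z": z, "pm": 100.0 + z, "present": 1,
        })
        params, _ = fit_degradation_limits(
            df, L=1000.0, a_grid=np.array([100.0, 200.0]), b_grid=np.array([100.0, 200.0])
        )
        assert (params.a, params.b) == (100.0, 100.0)

    def test_flat_profile_raises(self):
        df = pd.DataFrame({
            "sample_id": "s1", "probeset_id": "ps1", "probe_id": "p",
            "z": np.arange(12, 100, dtype=float), "pm": 7.0, "present": 1,
        })
        with pytest.raises(FitError, match="flat"):
            fit_degradation_limits(df, L=1000.0)

    def test_empty_window_raises(self):
        df = pd.DataFrame({
            "sample_id": "s1", "probeset_id": "ps1", "probe_id": "p",
            "z": [700.0, 800.0], "pm": [5.0, 6.0], "present": 1,
        })
        with pytest.raises(FitError, match="window"):
            fit_degradation_limits(df, L=1000.0)

    def test_recovery_on_synthetic_data(self):
        spec = SyntheticSpec(n_probe_sets=4000, seed=21)
        probes, _ = generate_dataset(spec, cycle=2)
        params, _ = fit_degradation_limits(
            probes, L=1000.0,
            a_grid=np.arange(200.0, 401.0, 50.0),
            b_grid=np.arange(100.0, 301.0, 50.0),
            quad_step=4.0,
        )
        assert abs(params.a - 300.0) <= 50.0
        assert abs(params.b - 200.0) <= 50.0


class TestIpsRecovery:
    def test_unbiased_under_reference_noise(self, curve2, small_dataset):
        # sampling theory: IPS_hat - IPS ~ N(0, sigma^2 / sum p^2); with
        # sigma = 0.1 IPS the median relative error should sit near
        # 0.6745 * 0.1 / sqrt(sum p^2); check agreement within 20%
        _, probes, truth = small_dataset
        adj = adjust_table(probes, curve2)
        ips = adj.groupby("probeset_id")["ips"].first()
        tr = truth.groupby("probeset_id")["ips_true"].first()
        rel = (np.abs(ips - tr) / tr).median()
        p = truth["p_true"].to_numpy().reshape(-1, 11)
        predicted = np.median(0.6745 * 0.1 / np.sqrt((p**2).sum(axis=1)))
        assert rel == pytest.approx(predicted, rel=0.2)

    def test_tight_recovery_under_proportional_noise(self, curve2):
        spec = SyntheticSpec(n_probe_sets=2000, seed=31, noise_model="proportional")
        probes, truth = generate_dataset(spec, cycle=2)
        adj = adjust_table(probes, curve2)
        ips = adj.groupby("probeset_id")["ips"].first()
        tr = truth.groupby("probeset_id")["ips_true"].first()
        assert (np.abs(ips - tr) / tr).median() < 0.05
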