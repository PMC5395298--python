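import dataclasses

import numpy as np
import pytest

from rangeadapt.core_io import DecoderSpec, UnitTuning, canonical_targets, direction_from_angles
from rangeadapt.mechanisms import (
    _one_step_objective,
    _optimize_on_sphere,
    classify_mechanism,
    dose_response,
    mirrored_pair_analysis,
    optimal_reaiming_point,
    reaiming_prediction,
)
from rangeadapt.range_analysis import tuning_ranges
from rangeadapt.synthetic import (
    MechanismSpec,
    SimConfig,
    elevated_aim_table,
    make_population,
    push_aim_table,
    simulate_session,
)
from rangeadapt.tuning import LogLinearFit

from conftest import make_session


class TestDoseResponse:
    def test_dra_cosine_transform_identity(self):
        s = make_session(kind="dra", completeness=1.0, n_units=15, seed=1)
        res, _ = dose_response(tuning_ranges(s), transform="cos")
        assert res.statistic == pytest.approx(1.0, abs=1e-6)
        assert res.extra["intercept"] == pytest.approx(0.0, abs=1e-6)

    def test_speed_gain_constant_ratio(self):
        s = make_session(kind="speed_gain", gain=1.2, n_units=15, seed=2)
        res, _ = dose_response(tuning_ranges(s), transform="abs")
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.extra["intercept"] == pytest.approx(1.0 / 1.2, abs=1e-9)

    def test_slope_invariant_to_depth_rescaling(self):
        s = make_session(kind="dra", completeness=1.0, n_units=12, seed=3)
        tab = tuning_ranges(s)
        res1, _ = dose_response(tab, transform="cos")
        tab2 = tab.copy()
        for col in ("rho_2d", "rho_3d", "rho_2d_full", "rho_3d_full", "diff_planar"):
            tab2[col] = tab2[col] * 3.7  # uniform depth rescaling
        res2, _ = dose_response(tab2, transform="cos")
        assert res1.statistic == pytest.approx(res2.statistic, abs=1e-9)


class TestOptimalReaiming:
    def _fits_units(self, P, b0=15.0, m=6.0, mll=0.35):
        units = [UnitTuning(f"u{i}", b0, m, p) for i, p in enumerate(P)]
        fits = [LogLinearFit(np.log(b0), mll, p, 1.0, 100) for p in P]
        return fits, units

    def test_mirror_symmetric_population_aims_in_plane(self):
        rng = np.random.default_rng(0)
        P = []
        for _ in range(10):
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            P.append(v)
            P.append(np.array([v[0], v[1], -v[2]]))
        fits, units = self._fits_units(P)
        d_star = optimal_reaiming_point(fits, units, DecoderSpec(), np.array([1.0, 0, 0]))
        assert abs(np.degrees(np.arcsin(d_star[2]))) < 1.0

    def test_shared_pd_population_aims_at_pd(self):
        d = np.array([1.0, 0.0, 0.0])
        fits, units = self._fits_units([d] * 8)
        d_star = optimal_reaiming_point(fits, units, DecoderSpec(), d)
        assert np.allclose(d_star, d, atol=1e-3)

    def test_dominates_two_degree_grid(self):
        rng = np.random.default_rng(1)
        P = rng.standard_normal((12, 3))
        P /= np.linalg.norm(P, axis=1, keepdims=True)
        fits, units = self._fits_units(list(P))
        B0 = np.array([f.bll0 for f in fits])
        M = np.array([f.mll for f in fits])
        PL = np.array([f.pll for f in fits])

        def rate_fn(grid):
            return np.exp(B0 + (grid @ PL.T) * M)

        target = np.array([0.0, 1.0, 0.0])
        J = _one_step_objective(rate_fn, units, DecoderSpec(), target, 2, True)
        _, val, _ = _optimize_on_sphere(J, target)
        az = np.radians(np.arange(-180.0, 180.0, 2.0))
        el = np.radians(np.arange(-90.0, 90.1, 2.0))
        AZ, EL = np.meshgrid(az, el)
        grid = np.column_stack(
            [
                (np.cos(EL) * np.cos(AZ)).ravel(),
                (np.cos(EL) * np.sin(AZ)).ravel(),
                np.sin(EL).ravel(),
            ]
        )
        assert val <= J(grid).min() + 1e-6


class TestReaimingPrediction:
    def test_identity_aiming_equalizes_ranges(self):
        """When the aim points coincide with the targets, the predicted
        re-aiming range equals the model planar range."""
        s = make_session(noise="none", n_units=10, seed=4)
        pred, _ = reaiming_prediction(s)
        # evaluate the model ranges directly at the common targets
        t3 = canonical_targets(3)
        from rangeadapt.mechanisms import _common_ids, _fit_3d_loglinear

        fits = _fit_3d_loglinear(s)
        common3, _ = _common_ids()
        C = np.array([t3.direction_of(t) for t in common3])
        for uid, f in fits.items():
            r = np.exp(f.bll0 + f.mll * (C @ f.pll))
            assert pred.loc[uid, "rho_ll"] == pytest.approx(float(r.max() - r.min()), rel=1e-9)

    def test_self_consistent_reaiming_signs_agree(self):
        cfg = SimConfig(
            n_units=20, noise="none", seed=77, loop="open",
            pd_distribution="elevation_biased", pd_bias_deg=20.0, pd_concentration=1.0,
            trials_per_target_3d=(3, 3), trials_per_target_2d=(3, 3),
            b0_range=(16.0, 25.0),
        )
        pop = make_population(cfg)
        base = simulate_session(cfg, units=pop)
        _, cont = reaiming_prediction(base)
        aim = {tid: np.asarray(v) for tid, v in cont["aim_points"].items()}
        t3, t2 = canonical_targets(3), canonical_targets(2)
        for tid2, tid3 in t2.common_with(t3):
            if tid3 in aim:
                aim[tid2] = aim[tid3]
        cfg2 = dataclasses.replace(cfg, mechanism=MechanismSpec(kind="reaiming", aim_table=aim))
        s2 = simulate_session(cfg2, units=pop)
        pred, _ = reaiming_prediction(s2)
        agree = (pred.predicted_sign == pred.observed_sign).mean()
        assert agree >= 0.9

    def test_dra_session_discriminating_pattern(self):
        """Under adaptation, about half the units are predicted (by the
        re-aiming analysis) to decrease, but almost none actually do."""
        s = make_session(kind="dra", completeness=1.0, noise="poisson",
                         n_units=26, seed=5, trials3=(9, 13), trials2=(15, 27),
                         loop="closed")
        pred, cont = reaiming_prediction(s)
        n_pred_dec = cont["pred_dec_obs_inc"] + cont["pred_dec_obs_dec"]
        n_obs_dec = cont["pred_dec_obs_dec"] + cont["pred_inc_obs_dec"]
        assert n_pred_dec >= 0.2 * len(pred)
        assert n_obs_dec <= 0.2 * len(pred)


class TestMirroredPairs:
    def test_dra_pair_both_increase_planar_rate(self, small_units):
        s = make_session(kind="dra", completeness=1.0, units=small_units, seed=6)
        res = mirrored_pair_analysis(s)
        assert len(res) == 1
        for uid, d in res[0]["per_unit"].items():
            assert d["mean_2d_planar"] > d["mean_3d_planar"]

    def test_reaiming_pair_moves_oppositely(self, small_units):
        s = make_session(
            kind="reaiming",
            aim_table=push_aim_table(30.0, bias_azimuth_deg=-135.0),
            units=small_units, seed=7,
        )
        res = mirrored_pair_analysis(s)
        d = res[0]["per_unit"]
        assert d["up"]["mean_2d_planar"] > d["up"]["mean_3d_planar"]
        assert d["dn"]["mean_2d_planar"] < d["dn"]["mean_3d_planar"]

    def test_null_session_no_significant_differences(self, small_units):
        s = make_session(units=small_units, seed=8, trials3=(4, 4), trials2=(4, 4))
        res = mirrored_pair_analysis(s)
        for e in res:
            for d in e["per_unit"].values():
                assert d["tests"]["planar_2d_vs_3d"].p > 0.05

    def test_no_qualifying_pairs_returns_empty(self):
        units = [
            UnitTuning("a", 18.0, 6.0, direction_from_angles(0.0, 40.0)),
            UnitTuning("b", 18.0, 6.0, direction_from_angles(90.0, -40.0)),
        ]
        s = make_session(units=units, seed=9)
        assert mirrored_pair_analysis(s) == []


class TestClassifier:
    @pytest.mark.parametrize(
        "kind, kwargs",
        [
            ("null", {}),
            ("dra", {"completeness": 1.0}),
            ("speed_gain", {"gain": 1.2}),
        ],
    )
    def test_labels_each_mechanism(self, kind, kwargs):
        mech = MechanismSpec(kind=kind, **kwargs)
        cfg = SimConfig(n_units=26, noise="poisson", seed=11, mechanism=mech)
        call = classify_mechanism(simulate_session(cfg))
        assert call.label == kind

    def test_labels_reaiming(self):
        cfg = SimConfig(
            n_units=26, noise="poisson", seed=11,
            mechanism=MechanismSpec(kind="reaiming", aim_table=elevated_aim_table(30.0)),
            pd_distribution="elevation_biased", pd_bias_deg=15.0, pd_concentration=0.5,
        )
        call = classify_mechanism(simulate_session(cfg))
        assert call.label == "reaiming"
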