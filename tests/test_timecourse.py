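import numpy as np
import pandas as pd
import pytest

from rangeadapt.core_io import canonical_targets
from rangeadapt.range_analysis import CoverageError
from rangeadapt.synthetic import MechanismSpec, SimConfig, simulate_session
from rangeadapt.timecourse import (
    average_curves,
    crossval_context_models,
    fit_exponential,
    trial_error_curve,
)

from conftest import make_session


def _session(seed=0, noise="poisson", tau=None, trials3=(4, 4), trials2=(8, 8),
             model_kwargs=None):
    mech = MechanismSpec(kind="dra", completeness=1.0, adaptation_tau=tau)
    cfg = SimConfig(
        n_units=10, noise=noise, seed=seed, mechanism=mech,
        trials_per_target_3d=trials3, trials_per_target_2d=trials2,
        b0_range=(16.0, 25.0),
    )
    return simulate_session(cfg)


class TestCrossvalModels:
    def test_parity_split_balanced_per_target(self):
        s = make_session(noise="poisson", n_units=6, seed=1, trials3=(4, 4), trials2=(4, 4))
        models = crossval_context_models(s, min_trials=2)
        from collections import Counter

        for ctx, per in ((2, 4), (3, 4)):
            counts = Counter(
                (t.target_id, models.parity[(ctx, t.trial_index)])
                for t in s.trials_in_context(ctx)
            )
            assert set(counts.values()) == {per // 2}

    def test_noiseless_even_and_odd_models_identical(self):
        s = make_session(n_units=6, seed=2, trials3=(4, 4), trials2=(4, 4))
        models = crossval_context_models(s, min_trials=1, model="linear")
        for ctx in (2, 3):
            for uid in models.unit_ids:
                fe = models.fits[(ctx, "even")][uid]
                fo = models.fits[(ctx, "odd")][uid]
                assert fe.b0 == pytest.approx(fo.b0, abs=1e-9)
                assert np.allclose(fe.m * fe.p, fo.m * fo.p, atol=1e-9)

    def test_insufficient_trials_raises(self):
        s = make_session(noise="poisson", n_units=4, seed=3, trials3=(2, 2), trials2=(2, 2))
        with pytest.raises(CoverageError):
            crossval_context_models(s, min_trials=5)

    def test_heldout_error_exceeds_training_error(self):
        """Cross-validation property: each parity model predicts its own
        training trials better than the held-out parity's trials."""
        gaps = []
        for seed in range(20):
            cfg = SimConfig(
                n_units=10, noise="poisson", seed=100 + seed, loop="open",
                mechanism=MechanismSpec(kind="dra", completeness=1.0),
                trials_per_target_3d=(4, 4), trials_per_target_2d=(8, 8),
                b0_range=(16.0, 25.0),
            )
            s = simulate_session(cfg)
            models = crossval_context_models(s, min_trials=1, model="linear")
            t2 = canonical_targets(2)
            ids2 = [t.target_id for t in s.trials_in_context(2)]
            train = held = 0.0
            n_train = n_held = 0
            for t in s.trials_in_context(2):
                if not t.success or t.target_id not in t2.ids:
                    continue
                d = t2.direction_of(t.target_id)[:2]
                parity = "even" if t.trial_index % 2 == 0 else "odd"
                other = "odd" if parity == "even" else "even"
                for uid in models.unit_ids:
                    e_tr = abs(t.rates[uid] - models.fits[(2, parity)][uid].predict(d))
                    e_ho = abs(t.rates[uid] - models.fits[(2, other)][uid].predict(d))
                    train += e_tr
                    held += e_ho
            gaps.append(held - train)
        assert np.mean(gaps) > 0


class TestTrialErrorCurve:
    def test_zero_when_observation_matches_prediction(self):
        s = make_session(n_units=6, seed=4, trials3=(4, 4), trials2=(4, 4))
        models = crossval_context_models(s, min_trials=1, model="linear")
        # unit normalization: the dispersion estimates are degenerate for
        # noiseless data and would amplify 1e-13 least-squares round-off
        for key in models.dispersion:
            models.dispersion[key] = 1.0
        curve = trial_error_curve(s, models)
        post = curve.loc[curve.index > 0, "err_2d_model"].dropna()
        # noiseless null session: the 2D model interpolates its own data
        assert np.allclose(post.to_numpy(), 0.0, atol=1e-9)

    def test_instant_adaptation_favors_2d_model_after_switch(self):
        """After the switch, the 2D-context model predicts the adapted
        rates better than the 3D-context model (session-averaged)."""
        curves = []
        for seed in range(10):
            s = make_session(kind="dra", completeness=1.0, noise="poisson",
                             n_units=20, seed=200 + seed, trials3=(6, 6),
                             trials2=(8, 8), loop="closed")
            models = crossval_context_models(s, min_trials=1, model="linear")
            curves.append(trial_error_curve(s, models))
        post = average_curves(curves).loc[lambda df: df.index > 0].dropna()
        assert post["err_2d_model"].mean() < post["err_3d_model"].mean()
        assert (post["err_2d_model"] < post["err_3d_model"]).mean() > 0.7
        # in the noiseless limit the ordering holds at every single offset
        s = make_session(kind="dra", completeness=1.0, n_units=12, seed=5,
                         trials3=(4, 4), trials2=(4, 4))
        models = crossval_context_models(s, min_trials=1, model="linear")
        for key in models.dispersion:
            models.dispersion[key] = 1.0
        curve = trial_error_curve(s, models).loc[lambda df: df.index > 0].dropna()
        assert (curve["err_2d_model"] < curve["err_3d_model"]).all()

    def test_null_session_models_equivalent(self):
        s = make_session(noise="poisson", n_units=12, seed=6,
                         trials3=(6, 6), trials2=(8, 8), loop="closed")
        models = crossval_context_models(s, min_trials=1, model="linear")
        curve = trial_error_curve(s, models)
        post = curve.dropna()
        diff = (post["err_2d_model"] - post["err_3d_model"]).mean()
        scale = post["err_2d_model"].mean()
        assert abs(diff) < 0.2 * scale

    def test_dispersion_scaling_law(self):
        """The normalizer is sqrt(d_2D * d_3D) per unit, so scaling one
        context's dispersions by k scales the metric by k**-0.5 and scaling
        both contexts scales it by 1/k — exactly."""
        s = _session(seed=7)
        models = crossval_context_models(s, min_trials=1)
        base = trial_error_curve(s, models)
        k = 4.0
        for (ctx, uid) in list(models.dispersion):
            if ctx == 2:
                models.dispersion[(ctx, uid)] *= k
        one = trial_error_curve(s, models)
        for (ctx, uid) in list(models.dispersion):
            if ctx == 3:
                models.dispersion[(ctx, uid)] *= k
        both = trial_error_curve(s, models)
        assert np.allclose((one["err_2d_model"] / base["err_2d_model"]).dropna(), k ** -0.5, atol=1e-12)
        assert np.allclose((both["err_2d_model"] / base["err_2d_model"]).dropna(), 1.0 / k, atol=1e-12)


class TestAverageCurves:
    def _curve(self, vals, offsets=(1, 2, 3)):
        return pd.DataFrame(
            {"err_2d_model": vals, "err_3d_model": vals, "n_sessions_averaged": 1},
            index=pd.Index(offsets, name="trial_offset"),
        )

    def test_single_curve_identity(self):
        c = self._curve([1.0, 2.0, 3.0])
        out = average_curves([c])
        assert np.allclose(out["err_2d_model"], [1, 2, 3])

    def test_identical_curves_average_to_themselves(self):
        c = self._curve([1.0, 2.0, 3.0])
        out = average_curves([c, c])
        assert np.allclose(out["err_2d_model"], [1, 2, 3])
        assert (out["n_sessions_averaged"] == 2).all()

    def test_disjoint_offsets_use_available_sessions(self):
        a = self._curve([1.0], offsets=(1,))
        b = self._curve([3.0], offsets=(2,))
        out = average_curves([a, b])
        assert out.loc[1, "err_2d_model"] == 1.0
        assert out.loc[2, "err_2d_model"] == 3.0
        assert (out["n_sessions_averaged"] == 1).all()


class TestFitExponential:
    def _make_curve(self, y, offsets=None):
        offsets = offsets if offsets is not None else np.arange(1, len(y) + 1)
        return pd.DataFrame(
            {"err_2d_model": y, "err_3d_model": y, "n_sessions_averaged": 1},
            index=pd.Index(offsets, name="trial_offset"),
        )

    def test_generate_and_refit_within_cis(self):
        """Marginal 95% CI coverage per parameter across seeded refits.

        The Wald intervals are asymptotic, so coverage is checked per
        parameter (joint coverage of three correlated intervals is
        necessarily below the marginal level)."""
        x = np.arange(1, 121, dtype=float)
        hits = {"a": 0, "b": 0, "c": 0}
        truth = {"a": 0.8, "b": 0.2, "c": -0.2}
        for rep in range(100):
            rng = np.random.default_rng(rep)
            y = 0.8 + 0.2 * np.exp(-0.2 * x) + rng.normal(0, 0.01, len(x))
            fit = fit_exponential(self._make_curve(y))
            for k, v in truth.items():
                hits[k] += fit.ci[k][0] <= v <= fit.ci[k][1]
        for k in hits:
            assert hits[k] >= 90, (k, hits)

    def test_constant_curve_flagged_degenerate(self):
        fit = fit_exponential(self._make_curve(np.full(30, 0.5)))
        assert fit.degenerate_c
        assert abs(fit.b) < 1e-3

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential(self._make_curve(np.linspace(1, 0, 5)))
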