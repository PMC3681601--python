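"""Unit tests for FRAP correction, normalization, model fit and selection."""

import numpy as np
import pytest

from spindlequant.frap import (
    FrapTrace,
    NormalizedTrace,
    RecoveryParams,
    correct_photobleach,
    fit_recovery,
    model_recovery,
    normalize_trace,
    pool_traces,
    select_model,
)
from spindlequant.pipeline import normalize_ensemble
from spindlequant.synthetic import TraceSimConfig, gen_trace_ensemble

from conftest import make_trace

TIMES = np.array([-15.0, -10.0, -5.0, 0.0, 5.0, 10.0, 20.0, 40.0, 80.0, 160.0])


class TestCorrectPhotobleach:
    def test_constant_control_is_identity(self):
        sample = make_trace(TIMES, np.linspace(100, 60, TIMES.size))
        control = make_trace(TIMES, np.full(TIMES.size, 90.0))
        out = correct_photobleach(sample, control)
        np.testing.assert_allclose(out.intensities, sample.intensities)

    def test_direct_arithmetic(self):
        # F = 50, C_pre = 100, F_control = 80 -> 50 * 100 / 80 = 62.5
        sample = make_trace(TIMES, np.full(TIMES.size, 50.0))
        ctrl_vals = np.full(TIMES.size, 80.0)
        ctrl_vals[:3] = 100.0
        control = make_trace(TIMES, ctrl_vals)
        out = correct_photobleach(sample, control)
        np.testing.assert_allclose(out.intensities[3:], 62.5)

    def test_inverts_simulated_acquisition_bleaching(self, oocyte_params):
        cfg = TraceSimConfig(params=oocyte_params, noise_sd=0.0, seed=0)
        from spindlequant.synthetic import gen_frap_trace

        sample, control = gen_frap_trace(cfg)
        bleach_free, _ = gen_frap_trace(
            TraceSimConfig(params=oocyte_params, noise_sd=0.0,
                           acq_bleach_rate=0.0, seed=0)
        )
        out = correct_photobleach(sample, control)
        np.testing.assert_allclose(out.intensities, bleach_free.intensities,
                                   rtol=1e-12)

    def test_nonpositive_control_rejected(self):
        sample = make_trace(TIMES, np.full(TIMES.size, 50.0))
        control = make_trace(TIMES, np.zeros(TIMES.size))
        with pytest.raises(ValueError, match="positive"):
            correct_photobleach(sample, control)


class TestNormalizeTrace:
    def _trace(self, post_value):
        vals = np.concatenate([[100.0] * 3, np.full(TIMES.size - 3, post_value)])
        vals[3] = 20.0  # bleach floor at t = 0
        return make_trace(TIMES, vals)

    def test_midpoint(self):
        out = normalize_trace(self._trace(60.0))
        np.testing.assert_allclose(out.values[1:], 0.5)
        assert out.values[0] == 0.0

    def test_no_recovery_all_zero(self):
        out = normalize_trace(self._trace(20.0))
        np.testing.assert_allclose(out.values, 0.0)

    def test_complete_recovery_is_one(self):
        out = normalize_trace(self._trace(100.0))
        np.testing.assert_allclose(out.values[1:], 1.0)

    def test_zero_bleach_depth_rejected(self):
        vals = np.full(TIMES.size, 100.0)
        with pytest.raises(ValueError, match="no bleach"):
            normalize_trace(make_trace(TIMES, vals))


class TestModelRecovery:
    def test_zero_at_bleach_instant(self, oocyte_params):
        assert model_recovery(0.0, oocyte_params) == 0.0

    def test_half_recovery_definition(self):
        p = RecoveryParams("full_single", f=1.0, tf_half=23.0)
        assert model_recovery(23.0, p) == pytest.approx(0.5)

    def test_oocyte_value_at_fast_half_time(self, oocyte_params):
        # independent brute-force evaluation of the two-term sum
        expected = 0.15 * (1 - 2 ** (-8 / 8)) + 0.85 * (1 - 2 ** (-8 / 300))
        assert model_recovery(8.0, oocyte_params) == pytest.approx(expected)
        assert round(model_recovery(8.0, oocyte_params), 4) == 0.0906

    def test_negative_time_rejected(self, oocyte_params):
        with pytest.raises(ValueError):
            model_recovery(-1.0, oocyte_params)

    def test_limit_is_total_mobile_fraction(self):
        p = RecoveryParams("two_population", f=0.3, s=0.5,
                           tf_half=5.0, ts_half=50.0)
        assert model_recovery(1e9, p) == pytest.approx(0.8)


class TestRecoveryParamsValidation:
    def test_fraction_sum_capped(self):
        with pytest.raises(ValueError):
            RecoveryParams("two_population", f=0.7, s=0.7,
                           tf_half=5.0, ts_half=50.0)

    def test_two_population_rate_ordering_enforced(self):
        with pytest.raises(ValueError, match="tf_half < ts_half"):
            RecoveryParams("two_population", f=0.5, s=0.5,
                           tf_half=50.0, ts_half=5.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="model_kind"):
            RecoveryParams("triple", f=1.0)


class TestFitRecovery:
    def test_noise_free_recovery_free_total(self):
        truth = RecoveryParams("two_population", f=0.3, s=0.5,
                               tf_half=10.0, ts_half=200.0)
        t = np.arange(0.0, 170.0, 5.0)
        trace = NormalizedTrace(times=t, values=model_recovery(t, truth))
        res = fit_recovery(trace, "two_population", free_total=True)
        assert res.converged
        assert res.params.f == pytest.approx(truth.f, rel=1e-4)
        assert res.params.s == pytest.approx(truth.s, rel=1e-4)
        assert res.params.tf_half == pytest.approx(truth.tf_half, rel=1e-4)
        assert res.params.ts_half == pytest.approx(truth.ts_half, rel=1e-4)

    def test_all_zero_trace_degenerate_plateau(self):
        t = np.arange(0.0, 50.0, 5.0)
        trace = NormalizedTrace(times=t, values=np.zeros_like(t))
        with pytest.warns(UserWarning, match="flat zero"):
            res = fit_recovery(trace, "two_population")
        assert res.params.f == 0.0 and res.params.s == 0.0
        assert res.rss == 0.0

    def test_too_few_points_rejected(self):
        trace = NormalizedTrace(times=np.array([0.0, 5.0, 10.0]),
                                values=np.array([0.0, 0.1, 0.2]))
        with pytest.raises(ValueError, match="post-bleach"):
            fit_recovery(trace, "full_single")

    def test_two_population_reported_fast_first(self):
        truth = RecoveryParams("two_population", f=0.4, s=0.6,
                               tf_half=6.0, ts_half=90.0)
        t = np.arange(0.0, 170.0, 5.0)
        trace = NormalizedTrace(times=t, values=model_recovery(t, truth))
        res = fit_recovery(trace, "two_population")
        assert res.params.tf_half < res.params.ts_half

    def test_bootstrap_se_reproducible(self):
        truth = RecoveryParams("single_plus_immobile", f=0.8, tf_half=15.0)
        t = np.arange(0.0, 170.0, 5.0)
        rng = np.random.default_rng(0)
        vals = model_recovery(t, truth) + rng.normal(0, 0.01, t.size)
        vals[0] = 0.0
        trace = NormalizedTrace(times=t, values=vals)
        r1 = fit_recovery(trace, "single_plus_immobile", n_boot=10, seed=5)
        r2 = fit_recovery(trace, "single_plus_immobile", n_boot=10, seed=5)
        assert r1.se == r2.se
        assert r1.se["f"] > 0


class TestPoolTraces:
    def _norm(self, values):
        t = np.arange(0.0, 25.0, 5.0)
        v = np.asarray(values, float)
        v[0] = 0.0
        return NormalizedTrace(times=t, values=v)

    def test_identical_traces(self):
        tr = self._norm([0, 0.2, 0.4, 0.5, 0.6])
        mean, sem = pool_traces([tr, tr, tr])
        np.testing.assert_allclose(mean.values, tr.values)
        np.testing.assert_allclose(sem, 0.0, atol=1e-12)

    def test_mean_of_opposites(self):
        a = self._norm([0, 0, 0, 0, 0])
        b = self._norm([0, 1, 1, 1, 1])
        mean, _ = pool_traces([a, b])
        np.testing.assert_allclose(mean.values[1:], 0.5)

    def test_mismatched_grids_rejected(self):
        a = self._norm([0, 0.1, 0.2, 0.3, 0.4])
        b = NormalizedTrace(times=np.array([0.0, 4.0, 8.0, 12.0, 16.0]),
                            values=np.array([0.0, 0.1, 0.2, 0.3, 0.4]))
        with pytest.raises(ValueError, match="grid"):
            pool_traces([a, b])

    def test_sem_scales_with_replicates(self):
        rng = np.random.default_rng(1)
        t = np.arange(0.0, 25.0, 5.0)
        traces = []
        for _ in range(100):
            v = 0.5 + rng.normal(0, 0.03, t.size)
            v[0] = 0.0
            traces.append(NormalizedTrace(times=t, values=v))
        _, sem = pool_traces(traces)
        # SEM of 100 replicates with sd 0.03 is about 0.003
        assert np.all(sem[1:] < 0.0045)
        assert np.all(sem[1:] > 0.0015)


class TestSelectModel:
    def _pooled(self, params, noise_sd=0.01, n=15, seed=0):
        cfg = TraceSimConfig(params=params, noise_sd=noise_sd, seed=seed)
        pooled, _ = normalize_ensemble(gen_trace_ensemble(cfg, n))
        return pooled

    def test_two_population_selected_for_separated_rates(self, oocyte_params):
        best, table, _ = select_model(self._pooled(oocyte_params))
        assert best == "two_population"
        assert set(table) == {"full_single", "single_plus_immobile",
                              "two_population"}

    def test_full_single_selected_for_full_recovery(self):
        p = RecoveryParams("full_single", f=1.0, tf_half=20.0)
        best, _, _ = select_model(self._pooled(p))
        assert best == "full_single"

    def test_immobile_model_selected_for_embryo_like_data(self):
        p = RecoveryParams("single_plus_immobile", f=0.85, tf_half=15.0)
        best, _, _ = select_model(self._pooled(p, n=11))
        assert best == "single_plus_immobile"

    def test_needs_two_candidates(self):
        with pytest.raises(ValueError):
            select_model(self._pooled(
                RecoveryParams("full_single", f=1.0, tf_half=20.0)),
                candidates=("full_single",))
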