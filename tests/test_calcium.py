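"""Fluo-4 trace processing: calibration, conversion, responses, store metrics, QC."""

import numpy as np
import pytest

from rodflux.calcium import (
    Calibration,
    DyeForm,
    FluoTrace,
    baseline_drift,
    calcium_to_f,
    mrs_block,
    normalize,
    qc_filter,
    response_amplitude,
    solve_kd,
    store_metrics,
    to_calcium,
)
from rodflux.protocols import PerfusionProtocol, Segment, Solution, kcl_series
from rodflux.stats import regression_slope_test


class TestNormalize:
    def test_trivials(self):
        f = np.full(10, 80.0)
        np.testing.assert_allclose(normalize(f, 80.0), 1.0)
        np.testing.assert_allclose(normalize(np.zeros(10), 80.0), 0.0)

    def test_round_trip(self, rng):
        f = rng.uniform(10, 90, 50)
        np.testing.assert_allclose(normalize(f, 75.0) * 75.0, f)

    def test_invalid_fmax(self):
        with pytest.raises(ValueError):
            normalize(np.ones(3), 0.0)


class TestKdCalibration:
    def test_midway_linear_value(self):
        cal = Calibration(f0=100.0, f_max=300.0, f_cal=200.0, ca_cal=494.0)
        assert solve_kd(cal) == pytest.approx(988.0)

    @pytest.mark.parametrize("form", [DyeForm.LINEAR, DyeForm.HYPERBOLIC])
    def test_round_trip_both_forms(self, form):
        kd_true = 990.0
        truth = Calibration(f0=10.0, f_max=100.0, kd=kd_true, dye_form=form)
        f_cal = float(calcium_to_f(np.array([494.0]), truth)[0])
        cal = Calibration(f0=10.0, f_max=100.0, f_cal=f_cal, ca_cal=494.0, dye_form=form)
        assert solve_kd(cal) == pytest.approx(kd_true, rel=1e-3)

    def test_degenerate_calibration_point(self):
        cal = Calibration(f0=100.0, f_max=300.0, f_cal=100.0)
        with pytest.raises(ValueError):
            solve_kd(cal)

    def test_hyperbolic_saturated_point(self):
        cal = Calibration(f0=100.0, f_max=300.0, f_cal=300.0, dye_form=DyeForm.HYPERBOLIC)
        with pytest.raises(ValueError):
            solve_kd(cal)


class TestToCalcium:
    def test_f0_maps_to_zero(self):
        cal = Calibration(f0=10.0, f_max=100.0, kd=990.0)
        assert to_calcium(np.array([10.0]), cal)[0] == pytest.approx(0.0)

    def test_linear_fmax_maps_to_kd(self):
        cal = Calibration(f0=10.0, f_max=100.0, kd=990.0)
        assert to_calcium(np.array([100.0]), cal)[0] == pytest.approx(990.0)

    @pytest.mark.parametrize("form", [DyeForm.LINEAR, DyeForm.HYPERBOLIC])
    def test_calibration_point_self_consistency(self, form):
        truth = Calibration(f0=10.0, f_max=100.0, kd=990.0, dye_form=form)
        f_cal = float(calcium_to_f(np.array([494.0]), truth)[0])
        cal = Calibration(f0=10.0, f_max=100.0, f_cal=f_cal, ca_cal=494.0, dye_form=form)
        cal.kd = solve_kd(cal)
        assert to_calcium(np.array([f_cal]), cal)[0] == pytest.approx(494.0, rel=1e-9)

    def test_hyperbolic_saturation_flagged_not_raised(self):
        cal = Calibration(f0=10.0, f_max=100.0, kd=990.0, dye_form=DyeForm.HYPERBOLIC)
        out = to_calcium(np.array([50.0, 100.0, 120.0]), cal)
        assert np.isfinite(out[0])
        assert np.isnan(out[1]) and np.isnan(out[2])

    @pytest.mark.parametrize("form", [DyeForm.LINEAR, DyeForm.HYPERBOLIC])
    def test_monotone_in_f(self, form):
        cal = Calibration(f0=10.0, f_max=100.0, kd=990.0, dye_form=form)
        f = np.linspace(10.0, 99.9, 200)
        ca = to_calcium(f, cal)
        assert np.all(np.diff(ca) > 0)

    @pytest.mark.parametrize("form", [DyeForm.LINEAR, DyeForm.HYPERBOLIC])
    def test_dye_round_trip_exact(self, form):
        cal = Calibration(f0=10.0, f_max=100.0, kd=990.0, dye_form=form)
        ca = np.array([0.0, 50.0, 494.0, 990.0, 3000.0])
        np.testing.assert_allclose(to_calcium(calcium_to_f(ca, cal), cal), ca, rtol=1e-12)


def make_trace(norm_values, protocol, f_max=100.0, dt=2.0):
    t = np.arange(len(norm_values)) * dt
    return FluoTrace(time=t, f=np.asarray(norm_values) * f_max, protocol=protocol)


class TestResponseAmplitude:
    def test_step_on_flat_baseline(self):
        proto = PerfusionProtocol(segments=[Segment(solution=Solution.K25, onset=40.0, duration=30.0)])
        n = 60
        norm = np.full(n, 0.3)
        norm[20:35] = 0.5  # during the segment
        trace = make_trace(norm, proto)
        meas = response_amplitude(trace, norm, 25)
        assert meas.baseline == pytest.approx(0.3)
        assert meas.amplitude == pytest.approx(0.2)

    def test_flat_trace_zero(self):
        proto = PerfusionProtocol(segments=[Segment(solution=Solution.K40, onset=40.0, duration=30.0)])
        norm = np.full(60, 0.3)
        trace = make_trace(norm, proto)
        assert response_amplitude(trace, norm, 40).amplitude == pytest.approx(0.0)

    def test_missing_segment_error_names_level(self):
        proto = PerfusionProtocol(segments=[Segment(solution=Solution.K25, onset=40.0, duration=30.0)])
        norm = np.full(60, 0.3)
        trace = make_trace(norm, proto)
        with pytest.raises(ValueError, match="40"):
            response_amplitude(trace, norm, 40)


class TestBaselineDrift:
    def test_exact_line(self):
        t = np.arange(0, 120, 2.0)
        norm = 0.2 + 6.3e-5 * t
        assert baseline_drift(t, norm, (0.0, 120.0)) == pytest.approx(6.3e-5, rel=1e-9)

    def test_flat_series(self):
        t = np.arange(0, 120, 2.0)
        assert baseline_drift(t, np.full(t.size, 0.4), (0.0, 120.0)) == pytest.approx(0.0, abs=1e-15)

    def test_noisy_line_within_two_se(self, rng):
        t = np.arange(0, 60, 2.0)
        slope_true = 1.3e-4
        norm = 0.2 + slope_true * t + rng.normal(0, 0.005, t.size)
        est = baseline_drift(t, norm, (0.0, 60.0))
        se = regression_slope_test(t, norm).se
        assert abs(est - slope_true) < 2 * se

    def test_short_window_rejected(self):
        t = np.arange(0, 120, 2.0)
        with pytest.raises(ValueError):
            baseline_drift(t, np.zeros(t.size), (0.0, 5.0))


def store_protocol():
    return PerfusionProtocol(
        segments=[
            Segment(solution=Solution.K25, onset=40.0, duration=20.0),
            Segment(solution=Solution.ZERO_CA_EGTA, onset=120.0, duration=20.0),
            Segment(solution=Solution.IONO_0CA, onset=140.0, duration=60.0),
        ]
    )


class TestStoreMetrics:
    def build(self, ca_baseline=100.0, ca_rec=300.0, ca_floor=30.0, ca_peak=300.0):
        proto = store_protocol()
        t = np.arange(0, 220, 2.0)
        ca = np.full(t.size, ca_baseline)
        ca[(t >= 40) & (t < 120)] = ca_rec  # response + recovery plateau
        ca[(t >= 100) & (t < 120)] = ca_rec  # end-of-recovery window
        ca[(t >= 120) & (t < 140)] = ca_floor
        ca[(t >= 140) & (t < 200)] = ca_peak
        trace = FluoTrace(time=t, f=np.ones(t.size), protocol=proto)
        return trace, ca

    def test_ratio_arithmetic(self):
        trace, ca = self.build()
        m = store_metrics(trace, ca)
        assert m.rel_increase == pytest.approx(2.0)
        assert m.rel_drop == pytest.approx(-0.9)
        assert m.recovery_ratio == pytest.approx(1.0)

    def test_misordered_protocol_rejected(self):
        proto = PerfusionProtocol(
            segments=[
                Segment(solution=Solution.ZERO_CA_EGTA, onset=40.0, duration=20.0),
                Segment(solution=Solution.K25, onset=80.0, duration=20.0),
                Segment(solution=Solution.IONO_0CA, onset=120.0, duration=60.0),
            ]
        )
        t = np.arange(0, 200, 2.0)
        trace = FluoTrace(time=t, f=np.ones(t.size), protocol=proto)
        with pytest.raises(ValueError):
            store_metrics(trace, np.full(t.size, 100.0))

    def test_invariant_to_calibration_rescale(self):
        # under the linear dye form the metrics are ratios of the same
        # affine-transformed quantity: changing Kd rescales all of them away
        trace, _ = self.build()
        f = np.linspace(20.0, 80.0, trace.time.size)
        trace = FluoTrace(time=trace.time, f=f, protocol=trace.protocol)
        cal_a = Calibration(f0=10.0, f_max=100.0, kd=990.0)
        cal_b = Calibration(f0=10.0, f_max=100.0, kd=550.0)
        m_a = store_metrics(trace, to_calcium(f, cal_a))
        m_b = store_metrics(trace, to_calcium(f, cal_b))
        assert m_a.rel_increase == pytest.approx(m_b.rel_increase)
        assert m_a.rel_drop == pytest.approx(m_b.rel_drop)
        assert m_a.recovery_ratio == pytest.approx(m_b.recovery_ratio)


class TestMrsBlock:
    def make_mrs_trace(self, block, store=0.2, drift_gain=2.0, seed=0):
        from rodflux.protocols import drug_protocol
        from rodflux.synthetic import FluoSimParams, simulate_fluorescence_trace

        proto = drug_protocol(Solution.MRS1845, onset=300.0, duration=60.0)
        params = FluoSimParams(store_content=store, drift_gain=drift_gain, noise_sd=0.0,
                               mrs_block_fraction=block)
        trace = simulate_fluorescence_trace(params, proto, seed)
        norm = normalize(trace.f, params.fmax_true)
        return trace, norm

    def test_no_block_no_drop(self):
        # full store: no CSC influx to block, so the blocker changes nothing
        trace, norm = self.make_mrs_trace(block=0.0, store=1.0)
        drop, _ = mrs_block(trace, norm)
        assert abs(drop) < 0.01

    def test_no_block_leaves_drift_running(self):
        # with a depleted store and no block the baseline keeps creeping up
        trace, norm = self.make_mrs_trace(block=0.0, store=0.2)
        drop, _ = mrs_block(trace, norm)
        assert drop > 0.01

    def test_block_produces_negative_drop(self):
        trace, norm = self.make_mrs_trace(block=0.8)
        drop, baseline = mrs_block(trace, norm)
        assert drop < -0.01
        assert baseline > 0

    def test_drop_grows_with_baseline_across_cohort(self):
        # cells with more accumulated CSC influx (longer drift) lose more
        drops, baselines = [], []
        from rodflux.protocols import drug_protocol
        from rodflux.synthetic import FluoSimParams, simulate_fluorescence_trace

        for onset in (120.0, 240.0, 360.0, 480.0):
            proto = drug_protocol(Solution.MRS1845, onset=onset, duration=60.0)
            params = FluoSimParams(store_content=0.2, drift_gain=2.0, noise_sd=0.0, mrs_block_fraction=0.8)
            trace = simulate_fluorescence_trace(params, proto, 0)
            norm = normalize(trace.f, params.fmax_true)
            drop, baseline = mrs_block(trace, norm)
            drops.append(drop)
            baselines.append(baseline)
        res = regression_slope_test(baselines, drops)
        assert res.slope < 0  # bigger baseline -> more negative drop


class TestQcFilter:
    def test_threshold_boundary(self):
        kept, audit = qc_filter({"a": 0.09, "b": 0.10, "c": 0.5})
        assert kept == ["b", "c"]
        assert len(audit) == 1
        assert audit[0]["cell"] == "a"
        assert audit[0]["value"] == 0.09

    def test_all_above_identity(self):
        kept, audit = qc_filter({"a": 0.2, "b": 0.3})
        assert kept == ["a", "b"] and audit == []
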