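"""Sweep-curve differentiation, segmentation, and diastolic parameters."""

import numpy as np
import pytest

from masweep import (
    PhantomSpec,
    SweepCurve,
    SweepRate,
    analytic_truth,
    compute_parameters,
    segment_intervals,
    sweep_rate,
)


def make_curve(normalized, rr_ms=1000.0, essv=1000.0):
    normalized = np.asarray(normalized, dtype=float)
    p = len(normalized)
    cumulative = normalized * essv
    return SweepCurve(
        increments_mm3=np.diff(cumulative),
        cumulative_mm3=cumulative,
        essv_mm3=essv,
        normalized=normalized,
        times_ms=np.arange(p) * (rr_ms / p),
        rr_interval_ms=rr_ms,
    )


class TestSweepRate:
    def test_linear_ramp_gives_constant_rate(self):
        # normalized falls 1 -> 0 linearly over the whole grid: r = 1/T
        p, rr = 40, 800.0
        y = 1.0 - np.arange(p) / p
        rate = sweep_rate(make_curve(y, rr))
        # away from the periodic wrap samples the rate is exactly 1/T
        t_total_s = rr / 1000.0
        assert np.allclose(rate.rate[1:-1], 1.0 / t_total_s, rtol=1e-12)
        assert np.allclose(rate.derivative[1:-1], -1.0 / t_total_s, rtol=1e-12)

    def test_constant_curve_zero_rate(self):
        rate = sweep_rate(make_curve(np.ones(12)))
        assert np.allclose(rate.rate, 0.0)

    def test_sinusoid_matches_analytic_derivative_second_order(self):
        errs = []
        for p in (50, 100):
            t = np.arange(p) / p                     # one period
            y = np.sin(2 * np.pi * t)
            rate = sweep_rate(make_curve(y, rr_ms=1000.0))
            exact = -2 * np.pi * np.cos(2 * np.pi * t)   # per second
            errs.append(np.max(np.abs(rate.rate - exact)))
        # halving the step divides the central-difference error by ~4
        assert errs[1] < errs[0] / 3.0

    def test_too_few_phases_rejected(self):
        with pytest.raises(ValueError, match="five"):
            sweep_rate(make_curve(np.ones(4)))


def synthetic_two_peak(p=40, rr=1000.0, es=10, e_peak=16, a_peak=30,
                       v_shape=True):
    """Curve with a systolic rise and a hand-built diastolic rate profile."""
    y = np.zeros(p)
    y[:es + 1] = np.linspace(0, 1, es + 1)
    r = np.zeros(p)
    width = 3
    for center, height in ((e_peak, 2.0), (a_peak, 1.0)):
        for k in range(-width, width + 1):
            if 0 <= center + k < p:
                r[center + k] = max(r[center + k],
                                    height * (1 - abs(k) / (width + 0.0)))
    if not v_shape:     # flat zero diastasis between the pulses
        pass
    dt_s = rr / p / 1000.0
    y[es:] = 1.0 - np.concatenate([[0.0], np.cumsum(r[es:-1] + r[es + 1:])
                                   * dt_s / 2])
    curve = make_curve(y, rr)
    rate = SweepRate(rate=r, derivative=-r, times_ms=curve.times_ms)
    return curve, rate


class TestSegmentation:
    def test_phantom_boundaries_at_plateau_edges(self):
        spec = PhantomSpec()
        truth = analytic_truth(spec, n_dense=500)
        curve, rate = truth.truth_curve, sweep_rate(truth.truth_curve)
        seg = segment_intervals(curve, rate)
        m = truth.motion
        spacing = spec.rr_ms / 500
        assert seg.ed_onset_ms == pytest.approx(m.t_sys_ms, abs=2 * spacing)
        e_end = m.e_pulse_start_ms + m.e_pulse_width_ms
        assert seg.ed_end_ms == pytest.approx(e_end, abs=0.05 * spec.rr_ms)
        assert seg.as_onset_ms == pytest.approx(m.a_pulse_start_ms,
                                                abs=0.05 * spec.rr_ms)
        assert seg.ed_end_ms <= seg.md_end_ms <= seg.as_onset_ms

    def test_single_interior_minimum_gives_empty_mid_diastole(self):
        # E and A triangles meet at one V-shaped minimum sample
        curve, rate = synthetic_two_peak(e_peak=16, a_peak=22)
        seg = segment_intervals(curve, rate)
        assert seg.ed_end_ms == seg.as_onset_ms

    def test_single_peak_raises_fusion_error(self):
        curve, rate = synthetic_two_peak()
        r = rate.rate.copy()
        r[25:] = 0.0                       # remove the A wave
        with pytest.raises(ValueError, match="fusion"):
            segment_intervals(curve, SweepRate(r, -r, rate.times_ms))

    def test_manual_override_replaces_boundaries(self):
        curve, rate = synthetic_two_peak()
        seg = segment_intervals(curve, rate,
                                override={"ed_end_ms": 530.0,
                                          "as_onset_ms": 660.0})
        assert seg.source == "manual"
        assert seg.ed_end_ms == 530.0
        assert seg.as_onset_ms == 660.0

    def test_unknown_override_rejected(self):
        curve, rate = synthetic_two_peak()
        with pytest.raises(ValueError, match="unknown"):
            segment_intervals(curve, rate, override={"nonsense_ms": 1.0})


class TestParameters:
    def test_constructed_peak_ratio(self):
        curve, rate = synthetic_two_peak(p=40, es=10, e_peak=16, a_peak=30)
        seg = segment_intervals(curve, rate)
        params = compute_parameters(curve, rate, seg)
        assert params.psr_e == pytest.approx(2.0)
        assert params.psr_a == pytest.approx(1.0)
        assert params.psr_ratio == pytest.approx(2.0)

    def test_linear_recovery_dsvrt50(self):
        # ES at 40% of RR, linear fall 1 -> 0 until cycle end:
        # the 0.5 crossing sits at 70% RR, i.e. 30% RR after ED onset
        p, rr = 100, 1000.0
        t = np.arange(p) / p
        y = np.where(t <= 0.4, t / 0.4, (1 - t) / 0.6)
        curve = make_curve(y, rr)
        rate = sweep_rate(curve)
        # a strictly linear recovery has no E/A structure: segment manually
        from masweep.diastology import IntervalSegmentation
        seg = IntervalSegmentation(
            es_index=40, ed_onset_ms=400.0, ed_end_ms=700.0,
            md_end_ms=700.0, as_onset_ms=700.0, cycle_end_ms=rr,
            source="manual")
        params = compute_parameters(curve, rate, seg)
        assert params.dsvrt50_pct_rr == pytest.approx(30.0, abs=0.5)

    def test_triangular_wave_deceleration_time_exact(self):
        # rate rises to a peak at t_p then falls linearly to zero at t_z:
        # DT is the extrapolated (here actual) zero crossing, t_z - t_p
        p, rr = 50, 1000.0
        r = np.zeros(p)
        peak, zero = 20, 32
        r[15:peak + 1] = np.linspace(0, 2.0, peak - 15 + 1)
        r[peak:zero + 1] = np.linspace(2.0, 0.0, zero - peak + 1)
        r[38:44] = 0.8                                   # A plateau
        dt_s = rr / p / 1000.0
        y = np.concatenate([[1.0], 1.0 - np.cumsum((r[:-1] + r[1:]) / 2) * dt_s])
        y[:13] = np.linspace(0, 1, 13)
        curve = make_curve(y, rr)
        rate = SweepRate(r, -r, curve.times_ms)
        from masweep.diastology import IntervalSegmentation
        seg = IntervalSegmentation(
            es_index=13, ed_onset_ms=curve.times_ms[13],
            ed_end_ms=curve.times_ms[zero], md_end_ms=curve.times_ms[36],
            as_onset_ms=curve.times_ms[36], cycle_end_ms=rr, source="manual")
        params = compute_parameters(curve, rate, seg)
        expected = curve.times_ms[zero] - curve.times_ms[peak]
        assert params.dt_sv_ms == pytest.approx(expected, rel=1e-9)
        assert params.at_sv_ms == pytest.approx(
            curve.times_ms[peak] - curve.times_ms[13], rel=1e-9)

    def test_phantom_truth_parameters_match_closed_forms(self):
        spec = PhantomSpec()
        truth = analytic_truth(spec)
        m, tp = truth.motion, truth.truth_params
        d = spec.systolic_descent_mm
        assert tp.psr_e == pytest.approx(m.peak_e_velocity_mm_s / d, rel=0.01)
        assert tp.psr_a == pytest.approx(m.peak_a_velocity_mm_s / d, rel=0.01)
        assert tp.psr_ratio == pytest.approx(spec.ea_peak_ratio, rel=0.01)
        assert tp.pct_recovery_ed == pytest.approx(100 * spec.e_fraction, abs=1.0)
        assert tp.pct_recovery_as == pytest.approx(
            100 * (1 - spec.e_fraction), abs=1.0)

    def test_time_rescaling_invariance(self):
        fast = analytic_truth(PhantomSpec(rr_ms=857.0))
        slow = analytic_truth(PhantomSpec(rr_ms=1714.0))
        f, s = fast.truth_params, slow.truth_params
        assert s.psr_e == pytest.approx(f.psr_e / 2, rel=1e-6)
        assert s.psr_a == pytest.approx(f.psr_a / 2, rel=1e-6)
        assert s.psr_ratio == pytest.approx(f.psr_ratio, rel=1e-6)
        assert s.pct_recovery_ed == pytest.approx(f.pct_recovery_ed, rel=1e-6)
        assert s.dsvrt50_pct_rr == pytest.approx(f.dsvrt50_pct_rr, rel=1e-6)
        assert s.dt_sv_ms == pytest.approx(2 * f.dt_sv_ms, rel=1e-6)

    def test_recovery_fractions_conserve_essv(self):
        truth = analytic_truth(PhantomSpec())
        tp = truth.truth_params
        md_pct = 100.0 * tp.avg_rate_md  # ~0: diastasis plateau
        total = tp.pct_recovery_ed + tp.pct_recovery_as
        assert total + md_pct == pytest.approx(100.0, abs=2.0)

    def test_volume_scaling_only_affects_absolute_quantities(self):
        truth = analytic_truth(PhantomSpec())
        base = truth.truth_curve
        scaled = make_curve(base.normalized, base.rr_interval_ms,
                            essv=base.essv_mm3 * 3.0)
        rate_b, rate_s = sweep_rate(base), sweep_rate(scaled)
        seg_b = segment_intervals(base, rate_b)
        seg_s = segment_intervals(scaled, rate_s)
        pb = compute_parameters(base, rate_b, seg_b)
        ps = compute_parameters(scaled, rate_s, seg_s)
        assert ps.psr_e == pytest.approx(pb.psr_e, rel=1e-9)
        assert ps.pct_recovery_ed == pytest.approx(pb.pct_recovery_ed, rel=1e-9)
        assert ps.dsvrt50_pct_rr == pytest.approx(pb.dsvrt50_pct_rr, rel=1e-9)
        assert ps.psr_e_abs_cm3s == pytest.approx(3 * pb.psr_e_abs_cm3s, rel=1e-9)
        assert ps.essv_cm3 == pytest.approx(3 * pb.essv_cm3, rel=1e-9)

    def test_stroke_volume_ratios_optional(self):
        truth = analytic_truth(PhantomSpec())
        curve = truth.truth_curve
        rate = sweep_rate(curve)
        seg = segment_intervals(curve, rate)
        without = compute_parameters(curve, rate, seg)
        with_sv = compute_parameters(curve, rate, seg, stroke_volume_ml=90.0)
        assert without.sweep_over_sv_ed_pct is None
        assert with_sv.sweep_over_sv_ed_pct == pytest.approx(
            100 * with_sv.abs_sweep_ed_cm3 / 90.0)

    def test_incomplete_recovery_flags_dsvrt(self):
        # curve never recovers below 0.5 after end-systole
        p = 40
        y = np.concatenate([np.linspace(0, 1, 10), np.full(30, 1.0)])
        y[10:] = np.linspace(1.0, 0.7, 30)
        curve = make_curve(y)
        rate = sweep_rate(curve)
        from masweep.diastology import IntervalSegmentation
        seg = IntervalSegmentation(
            es_index=9, ed_onset_ms=curve.times_ms[9],
            ed_end_ms=curve.times_ms[20], md_end_ms=curve.times_ms[25],
            as_onset_ms=curve.times_ms[25], cycle_end_ms=1000.0,
            source="manual")
        params = compute_parameters(curve, rate, seg)
        assert np.isnan(params.dsvrt50_pct_rr)
        assert "incomplete_recovery_dsvrt_undefined" in params.qc_flags
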