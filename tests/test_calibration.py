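import math
import random

import numpy as np
import pytest

from potsense import (
    CalibrationPoint,
    DilutionProtocol,
    NoiseModel,
    SensorParams,
    compute_lod,
    extract_plateaus,
    fit_calibration,
    nikolsky_emf,
    select_linear_range,
    simulate_dilution_trace,
)
from potsense.calibration import (
    InsufficientDataError,
    NoIntersectionError,
    NoLinearRangeError,
)


def two_segment_points(slope=59.16, break_log10=-5.0, plateau_emf=0.0, levels=None):
    """Exact piecewise-linear calibration: flat below the breakpoint."""
    levels = levels if levels is not None else np.arange(-8.0, 0.0)
    return [
        CalibrationPoint(x, plateau_emf + max(0.0, x - break_log10) * slope)
        for x in levels
    ]


class TestExtractPlateaus:
    def test_zero_noise_plateaus_equal_forward_model(self, ideal_sensor, fim_protocol):
        (trace,) = simulate_dilution_trace(fim_protocol, ideal_sensor, NoiseModel(), 1)
        points = extract_plateaus(trace, fim_protocol)
        bg = {ion: c for ion, c in fim_protocol.background.entries.items()}
        for p, level in zip(points, fim_protocol.levels):
            assert p.log10_activity == pytest.approx(math.log10(level))
            assert p.emf_mV == pytest.approx(nikolsky_emf(ideal_sensor, level, bg))

    def test_window_averaging_suppresses_noise(self, ideal_sensor):
        proto = DilutionProtocol((1e-2, 1e-3), dwell_s=100.0)
        (trace,) = simulate_dilution_trace(
            proto, ideal_sensor, NoiseModel(sd_mV=1.0, seed=3), 1
        )
        points = extract_plateaus(trace, proto, settle_fraction=0.5)
        truth = nikolsky_emf(ideal_sensor, 1e-2)
        # 50-sample mean: sd 1/sqrt(50) ~ 0.14 mV; 4 sigma bound
        assert abs(points[0].emf_mV - truth) < 0.6

    def test_trace_shorter_than_schedule_is_an_error(self, ideal_sensor):
        short = DilutionProtocol((1e-2, 1e-3), dwell_s=10.0)
        (trace,) = simulate_dilution_trace(short, ideal_sensor, NoiseModel(), 1)
        long = DilutionProtocol((1e-2, 1e-3, 1e-4), dwell_s=10.0)
        with pytest.raises(InsufficientDataError, match="0.0001"):
            extract_plateaus(trace, long)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.5])
    def test_settle_fraction_bounds(self, bad, ideal_sensor):
        proto = DilutionProtocol((1e-2, 1e-3), dwell_s=10.0)
        (trace,) = simulate_dilution_trace(proto, ideal_sensor, NoiseModel(), 1)
        with pytest.raises(ValueError):
            extract_plateaus(trace, proto, settle_fraction=bad)


class TestFitCalibration:
    def test_exact_recovery_with_zero_noise(self):
        pts = [CalibrationPoint(x, 100.0 + 59.16 * x) for x in (-5.0, -4.0, -3.0)]
        curve = fit_calibration(pts)
        assert curve.slope == pytest.approx(59.16)
        assert curve.intercept == pytest.approx(100.0)
        assert curve.slope_sd == 0.0
        assert curve.r_squared == pytest.approx(1.0)

    def test_two_collinear_points_fit_exactly(self):
        pts = [CalibrationPoint(-3.0, 0.0), CalibrationPoint(-2.0, 59.16)]
        curve = fit_calibration(pts)
        assert curve.slope == pytest.approx(59.16)
        assert curve.r_squared == pytest.approx(1.0)

    def test_replicate_spread_reported_as_sd(self, tma):
        rng = np.random.default_rng(11)
        pts = []
        true_slopes = rng.normal(55.14, 4.44, size=5)
        for i, s in enumerate(true_slopes):
            for x in np.arange(-5.0, 0.0):
                pts.append(CalibrationPoint(x, s * x, f"E{i + 1}"))
        curve = fit_calibration(pts)
        assert curve.slope == pytest.approx(true_slopes.mean())
        assert curve.slope_sd == pytest.approx(true_slopes.std(ddof=1))

    def test_invariant_to_point_order_and_emf_offset(self):
        pts = [
            CalibrationPoint(x, 55.0 * x + 0.3 * ((-1) ** i), f"E{1 + i % 2}")
            for i, x in enumerate(np.arange(-6.0, 0.0))
        ]
        base = fit_calibration(pts)
        shuffled = pts[:]
        random.Random(0).shuffle(shuffled)
        shifted = [
            CalibrationPoint(p.log10_activity, p.emf_mV + 123.4, p.electrode_id)
            for p in pts
        ]
        assert fit_calibration(shuffled).slope == pytest.approx(base.slope)
        assert fit_calibration(shifted).slope == pytest.approx(base.slope)

    def test_single_level_is_insufficient(self):
        pts = [CalibrationPoint(-3.0, 1.0), CalibrationPoint(-3.0, 1.1)]
        with pytest.raises(InsufficientDataError):
            fit_calibration(pts)

    def test_range_filter_applies_before_fitting(self):
        pts = two_segment_points()
        curve = fit_calibration(pts, fit_range=(-5.0, 0.0))
        assert curve.slope == pytest.approx(59.16)


class TestSelectLinearRange:
    def test_ideal_nernstian_curve_returns_full_span(self):
        pts = [CalibrationPoint(x, 59.16 * x) for x in np.arange(-5.0, 0.0)]
        assert select_linear_range(pts) == (-5.0, -1.0)

    def test_interference_floor_is_excluded(self):
        pts = two_segment_points(break_log10=-5.0)
        low, high = select_linear_range(pts)
        assert low == -5.0 and high == -1.0

    def test_dead_electrode_has_no_linear_range(self):
        pts = [CalibrationPoint(x, 0.0) for x in np.arange(-6.0, 0.0)]
        with pytest.raises(NoLinearRangeError):
            select_linear_range(pts)

    def test_range_is_contained_in_input_span(self):
        pts = two_segment_points()
        low, high = select_linear_range(pts)
        xs = [p.log10_activity for p in pts]
        assert min(xs) <= low < high <= max(xs)

    def test_needs_at_least_three_levels(self):
        with pytest.raises(InsufficientDataError):
            select_linear_range([CalibrationPoint(-2, 0), CalibrationPoint(-1, 59)])


class TestComputeLod:
    def test_exact_breakpoint_recovered(self):
        res = compute_lod(two_segment_points(break_log10=-5.0))
        assert res.intersection_log10 == pytest.approx(-5.0, abs=1e-9)
        assert res.lod == pytest.approx(1e-5, rel=1e-6)

    def test_interference_plateau_is_the_analytic_intersection(
        self, ideal_sensor, fim_protocol
    ):
        # Plateau of the emf equation sits at k * a_j = 10^(-1.12) * 1e-4
        (trace,) = simulate_dilution_trace(fim_protocol, ideal_sensor, NoiseModel(), 1)
        res = compute_lod(extract_plateaus(trace, fim_protocol))
        assert res.intersection_log10 == pytest.approx(-5.12, abs=0.05)

    def test_explicit_split_matches_construction(self):
        pts = two_segment_points(break_log10=-4.0)
        res = compute_lod(pts, split=4)  # plateau: -8..-5, Nernstian: -4..-1
        assert res.intersection_log10 == pytest.approx(-4.0, abs=1e-9)

    def test_split_leaving_one_level_rejected(self):
        with pytest.raises(InsufficientDataError):
            compute_lod(two_segment_points(), split=1)

    def test_straight_line_has_no_intersection(self):
        pts = [CalibrationPoint(x, 59.16 * x) for x in np.arange(-8.0, 0.0)]
        with pytest.raises(NoIntersectionError):
            compute_lod(pts)

    def test_parallel_segments_rejected(self):
        pts = [CalibrationPoint(x, 10.0 * x) for x in np.arange(-8.0, -4.0)]
        pts += [CalibrationPoint(x, 10.0 * x + 5.0) for x in np.arange(-4.0, 0.0)]
        with pytest.raises(NoIntersectionError):
            compute_lod(pts, split=4)

    def test_noise_does_not_bias_the_lod(self, ideal_sensor, fim_protocol):
        noise_free = compute_lod(
            extract_plateaus(
                simulate_dilution_trace(fim_protocol, ideal_sensor, NoiseModel(), 1)[0],
                fim_protocol,
            )
        ).intersection_log10
        estimates = []
        for seed in range(40):
            noise = NoiseModel(sd_mV=1.0, seed=seed)
            (trace,) = simulate_dilution_trace(fim_protocol, ideal_sensor, noise, 1)
            estimates.append(
                compute_lod(extract_plateaus(trace, fim_protocol)).intersection_log10
            )
        assert abs(np.mean(estimates) - noise_free) < 0.1


class TestRoundTrip:
    def test_simulate_extract_fit_recovers_slope_exactly(self, tma):
        params = SensorParams(tma, E0_mV=250.0, slope_mV_per_decade=55.14)
        proto = DilutionProtocol(tuple(10.0 ** -np.arange(1.0, 6.0)), dwell_s=20.0)
        traces = simulate_dilution_trace(proto, params, NoiseModel(), 3)
        pts = [p for tr in traces for p in extract_plateaus(tr, proto)]
        curve = fit_calibration(pts)
        assert curve.slope == pytest.approx(55.14, abs=1e-9)
        assert curve.slope_sd == pytest.approx(0.0, abs=1e-9)

    def test_bias_vanishes_as_noise_shrinks(self, tma):
        proto = DilutionProtocol(tuple(10.0 ** -np.arange(1.0, 6.0)), dwell_s=20.0)
        params = SensorParams(tma, slope_mV_per_decade=55.14)
        errors = []
        for sd in (2.0, 0.2):
            est = []
            for seed in range(20):
                (trace,) = simulate_dilution_trace(
                    proto, params, NoiseModel(sd_mV=sd, seed=seed), 1
                )
                est.append(fit_calibration(extract_plateaus(trace, proto)).slope)
            errors.append(abs(np.mean(est) - 55.14))
        assert errors[1] < errors[0] + 0.05  # consistent: shrinking noise, shrinking bias
        assert errors[1] < 0.1
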