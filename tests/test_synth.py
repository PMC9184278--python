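"""Synthetic rotation-movie generator: schedules, counting and metadata."""

import math

import numpy as np
import pytest

from microedtk import (
    AcquisitionPlan,
    DetectorSpec,
    ReflectionEvent,
    generate_reflection_schedule,
    simulate_flat_field,
    simulate_movie,
)


class TestReflectionSchedule:
    def test_zero_spots_gives_empty_schedule(self, small_spec):
        assert generate_reflection_schedule(0, 63.0, spec=small_spec,
                                            beamstop_radius=4.0) == []

    def test_fixed_seed_is_deterministic(self, small_spec):
        kwargs = dict(spec=small_spec, seed=11, beamstop_radius=4.0, edge_margin=2.0)
        a = generate_reflection_schedule(20, 63.0, **kwargs)
        b = generate_reflection_schedule(20, 63.0, **kwargs)
        assert a == b

    def test_angles_within_range_and_spots_outside_beamstop(self):
        spec = DetectorSpec(width=256, height=256)
        events = generate_reflection_schedule(
            100, 63.0, seed=5, start_angle=-31.5, spec=spec, beamstop_radius=20.0
        )
        cx = cy = 128.0
        for ev in events:
            assert -31.5 <= ev.center_angle <= 31.5
            x, y = ev.detector_center
            assert math.hypot(x - cx, y - cy) > 20.0
            assert ev.expected_electrons >= 0

    def test_beamstop_covering_face_raises(self, small_spec):
        with pytest.raises(ValueError, match="beam-stop"):
            generate_reflection_schedule(1, 10.0, spec=small_spec,
                                         beamstop_radius=1000.0)


class TestSimulateMovie:
    def test_no_background_no_spots_is_all_zero(self, small_spec, short_plan):
        stack = simulate_movie(short_plan, small_spec, [], seed=0)
        assert stack.total_counts == 0
        assert stack.n_images == 4

    def test_oscillation_metadata_tiles_the_wedge(self, small_spec, short_plan):
        stack = simulate_movie(short_plan, small_spec, [], seed=0)
        assert np.allclose(
            stack.osc_range, short_plan.rotation_rate * short_plan.summation_window
        )
        # contiguous: each image starts where the previous ended
        assert np.allclose(stack.osc_start[1:], stack.osc_start[:-1] + stack.osc_range[:-1])
        assert np.isclose(stack.osc_range.sum(), short_plan.total_rotation)
        assert np.isclose(stack.osc_start[0], short_plan.wedge_start)

    def test_counts_conserved_from_raw_frames(self, small_spec, short_plan):
        schedule = generate_reflection_schedule(
            5, short_plan.total_rotation, intensity_scale=30.0, seed=2,
            start_angle=short_plan.wedge_start, spec=small_spec, beamstop_radius=4.0,
        )
        stack, frames = simulate_movie(
            short_plan, small_spec, schedule, background_rate=1.0, seed=3,
            return_frames=True,
        )
        assert stack.total_counts == frames.sum()  # resets carry no counts
        assert np.all(frames <= 1)
        assert np.all(stack.images.max(axis=(1, 2)) <= stack.frames_per_image)

    def test_single_spot_recovers_electron_budget_at_low_flux(self):
        # a spot of E electrons loses 1/reset_period to reset frames and a
        # small (<3% at this occupancy) coincidence-loss fraction
        spec = DetectorSpec(width=64, height=64)
        plan = AcquisitionPlan(exposure_time=2.0, summation_window=0.5,
                               rotation_rate=0.2)
        e_budget = 300.0
        spot = ReflectionEvent(
            spot_id="s", center_angle=0.0, rocking_width=0.2,
            detector_center=(32.0, 32.0), footprint_sigma=2.0,
            expected_electrons=e_budget,
        )
        stack = simulate_movie(plan, spec, [spot], seed=7)
        expected = e_budget * (1 - 1 / spec.reset_period)
        tol = 3 * math.sqrt(e_budget) + 0.03 * e_budget
        assert abs(stack.total_counts - expected) <= tol

    def test_background_counts_scale_linearly(self, small_spec, short_plan):
        low = simulate_movie(short_plan, small_spec, [], background_rate=0.5, seed=4)
        high = simulate_movie(short_plan, small_spec, [], background_rate=1.0, seed=5)
        ratio = high.total_counts / low.total_counts
        # 3 sigma on the ratio at these totals is about 0.08
        assert ratio == pytest.approx(2.0, abs=0.15)

    def test_off_detector_spot_is_skipped_with_warning(self, small_spec, short_plan):
        spot = ReflectionEvent(
            spot_id="ghost", center_angle=0.0, rocking_width=0.2,
            detector_center=(1000.0, 1000.0), footprint_sigma=2.0,
            expected_electrons=100.0,
        )
        with pytest.warns(UserWarning, match="off-detector"):
            stack = simulate_movie(short_plan, small_spec, [spot], seed=6)
        assert stack.total_counts == 0


class TestFlatField:
    def test_zero_flux_is_all_zero(self, small_spec, short_plan):
        stack = simulate_flat_field(short_plan, small_spec, 0.0, 1e4, seed=0)
        assert stack.total_counts == 0

    def test_total_counts_near_expected_at_low_occupancy(self, small_spec):
        plan = AcquisitionPlan(exposure_time=4.0, summation_window=1.0)
        flux, area = 0.3, 1e4
        stack = simulate_flat_field(plan, small_spec, flux, area, seed=8)
        # expectation excludes the 1/32 of frames spent resetting
        n_expected = flux * area * plan.exposure_time * (1 - 1 / small_spec.reset_period)
        assert abs(stack.total_counts - n_expected) <= 3 * math.sqrt(n_expected)

    def test_fixed_seed_reproducible(self, small_spec, short_plan):
        a = simulate_flat_field(short_plan, small_spec, 0.4, 1e4, seed=12)
        b = simulate_flat_field(short_plan, small_spec, 0.4, 1e4, seed=12)
        assert np.array_equal(a.images, b.images)

    def test_relative_error_shrinks_as_flux_drops(self, small_spec):
        # coincidence loss scales with occupancy: the low-flux run must sit
        # closer to its expectation (relative to it) than a high-flux run
        plan = AcquisitionPlan(exposure_time=4.0, summation_window=1.0)
        area = 1e4
        rel = {}
        for flux in (20.0, 0.2):
            totals = []
            for seed in range(5):
                st = simulate_flat_field(plan, small_spec, flux, area, seed=100 + seed)
                totals.append(st.total_counts)
            n_expected = flux * area * plan.exposure_time * (1 - 1 / 32)
            rel[flux] = abs(np.mean(totals) - n_expected) / n_expected
        assert rel[0.2] < rel[20.0]


def test_movie_stack_validates_metadata_lengths(small_spec, short_plan):
    from microedtk import MovieStack

    with pytest.raises(ValueError):
        MovieStack(
            images=np.zeros((3, 4, 4), dtype=int),
            osc_start=np.zeros(2),
            osc_range=np.zeros(3),
            exposure=np.ones(3),
        )
    with pytest.raises(ValueError):
        MovieStack(
            images=np.full((1, 2, 2), -1),
            osc_start=np.zeros(1),
            osc_range=np.zeros(1),
            exposure=np.ones(1),
        )
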