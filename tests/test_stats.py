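"""Merging statistics, occupancy-DQE histograms and spot line profiles."""

import math

import numpy as np
import pytest

from microedtk import (
    AcquisitionPlan,
    DetectorSpec,
    InsufficientDataError,
    ObservationSet,
    expected_dqe,
    line_profile,
    merge_statistics,
    pixel_histogram_dqe,
    simulate_flat_field,
)
from microedtk.stats import cc_star


def brute_force_r_stats(groups):
    """Loop-based evaluation of the three R formulas, kept deliberately naive."""
    num_merge = num_meas = num_pim = denom = 0.0
    for values in groups.values():
        values = list(values)
        n = len(values)
        if n < 2:
            continue
        mean = sum(values) / n
        dev = sum(abs(v - mean) for v in values)
        num_merge += dev
        num_meas += math.sqrt(n / (n - 1)) * dev
        num_pim += math.sqrt(1 / (n - 1)) * dev
        denom += sum(values)
    return num_merge / denom, num_meas / denom, num_pim / denom


def random_observation_set(rng, n_groups=None):
    n_groups = n_groups or rng.integers(3, 12)
    groups = {}
    for g in range(n_groups):
        n_obs = int(rng.integers(2, 7))
        mean = float(rng.uniform(5, 100))
        groups[f"h{g}"] = mean + rng.normal(0, math.sqrt(mean), size=n_obs)
    return ObservationSet(groups=groups)


class TestMergeStatistics:
    def test_identical_duplicates_give_perfect_statistics(self):
        obs = ObservationSet({f"h{i}": [v, v] for i, v in enumerate([10.0, 20.0, 5.0, 8.0])})
        stats = merge_statistics(obs, seed=0)
        assert stats.r_merge == 0.0
        assert stats.r_meas == 0.0
        assert stats.cc_half == pytest.approx(1.0, abs=1e-12)
        assert stats.cc_star == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_pair_group(self):
        # single group {10, 12}: dev = 2, denominator 22
        obs = ObservationSet({"h0": [10.0, 12.0]})
        stats = merge_statistics(obs, seed=0, on_insufficient_cc="nan")
        assert stats.r_merge == pytest.approx(2 / 22)
        assert stats.r_meas == pytest.approx(math.sqrt(2) * 2 / 22)
        assert stats.r_pim == pytest.approx(2 / 22)
        assert math.isnan(stats.cc_half)

    def test_cc_half_requires_three_usable_groups(self):
        obs = ObservationSet({"a": [10.0, 12.0], "b": [5.0, 6.0], "c": [7.0]})
        with pytest.raises(InsufficientDataError):
            merge_statistics(obs, seed=0)

    def test_all_singletons_rejected(self):
        obs = ObservationSet({"a": [1.0], "b": [2.0], "c": [3.0]})
        with pytest.raises(InsufficientDataError):
            merge_statistics(obs, seed=0, on_insufficient_cc="nan")

    def test_matches_brute_force_oracle_on_random_sets(self, rng):
        for _ in range(50):
            obs = random_observation_set(rng)
            stats = merge_statistics(obs, seed=1)
            r_merge, r_meas, r_pim = brute_force_r_stats(obs.groups)
            assert stats.r_merge == pytest.approx(r_merge, rel=1e-12)
            assert stats.r_meas == pytest.approx(r_meas, rel=1e-12)
            assert stats.r_pim == pytest.approx(r_pim, rel=1e-12)
            assert stats.r_pim <= stats.r_merge <= stats.r_meas

    def test_multiplicity_and_completeness(self):
        obs = ObservationSet(
            {"a": [1.0, 2.0], "b": [3.0, 4.0], "c": [5.0, 6.0], "d": [7.0, 8.0]},
            expected_unique=8,
        )
        stats = merge_statistics(obs, seed=0)
        assert stats.multiplicity == pytest.approx(2.0)
        assert stats.completeness == pytest.approx(0.5)

    def test_mean_i_over_sigma(self):
        obs = ObservationSet(
            {"a": [10.0, 10.0], "b": [20.0, 20.0], "c": [5.0, 5.0]},
            sigmas={"a": [2.0, 2.0], "b": [4.0, 4.0], "c": [1.0, 1.0]},
        )
        stats = merge_statistics(obs, seed=0)
        assert stats.mean_i_over_sigma == pytest.approx(5.0)

    def test_cc_half_split_is_seeded(self, rng):
        obs = random_observation_set(rng, n_groups=20)
        a = merge_statistics(obs, seed=3).cc_half
        b = merge_statistics(obs, seed=3).cc_half
        assert a == b

    def test_cc_half_increases_with_signal_to_noise(self):
        rng = np.random.default_rng(99)
        means = rng.uniform(10, 200, size=40)

        def build(noise_sd):
            local = np.random.default_rng(7)
            return ObservationSet(
                {f"h{i}": m + local.normal(0, noise_sd, size=4) for i, m in enumerate(means)}
            )

        quiet = merge_statistics(build(2.0), seed=0).cc_half
        noisy = merge_statistics(build(60.0), seed=0).cc_half
        assert quiet > noisy


class TestCCStar:
    def test_closed_form_at_099(self):
        assert cc_star(0.99) == pytest.approx(0.99749, abs=1e-5)

    def test_endpoints_and_monotonicity(self):
        assert cc_star(1.0) == 1.0
        assert cc_star(0.0) == 0.0
        grid = np.linspace(0, 1, 50)
        values = [cc_star(c) for c in grid]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_negative_cc_half_is_nan_with_warning(self):
        with pytest.warns(UserWarning):
            assert math.isnan(cc_star(-0.2))


class TestOccupancyHistogram:
    def test_all_zero_stack_has_single_zero_bin(self, small_spec, short_plan):
        from microedtk import simulate_movie

        stack = simulate_movie(short_plan, small_spec, [], seed=0)
        hist = pixel_histogram_dqe(stack)
        assert hist.occupancy.tolist() == [0]
        assert hist.min_dqe == 1.0

    def test_binary_occupancy_has_unit_min_dqe(self, small_spec):
        frames = np.zeros((250, 4, 4), dtype=np.int64)
        frames[10, 1, 1] = 1
        hist = pixel_histogram_dqe(frames, small_spec)
        assert hist.min_dqe == 1.0
        assert hist.frequency[1] == 1

    def test_flat_field_modal_bin_matches_oracle_annotation(self, small_spec):
        plan = AcquisitionPlan(exposure_time=2.0, summation_window=1.0)
        flux, area = 5.0, 1e4
        stack = simulate_flat_field(plan, small_spec, flux, area, seed=21)
        hist = pixel_histogram_dqe(stack)
        # per-pixel mean per 1 s interval, less the reset-frame share
        occupancy = flux * area / (32 * 32 * 250) * 250 * (31 / 32)
        modal = hist.occupancy[1:][np.argmax(hist.frequency[1:])]
        assert abs(modal - occupancy) <= 3 * math.sqrt(occupancy)
        idx = int(modal)
        assert hist.dqe[idx] == pytest.approx(expected_dqe(idx, 250))
        assert hist.min_dqe <= hist.dqe[idx]


class TestLineProfile:
    def test_constant_image_is_flat_with_unit_ratio(self):
        image = np.full((20, 20), 7.0)
        prof = line_profile(image, (2, 8, 18, 12), axis="x")
        assert np.allclose(prof.values, 7.0)
        assert prof.peak_over_background == pytest.approx(1.0)

    def test_gaussian_spot_peaks_at_its_center(self):
        yy, xx = np.mgrid[0:64, 0:64]
        image = 100 * np.exp(-((xx - 30) ** 2 + (yy - 40) ** 2) / (2 * 2.0**2))
        prof = line_profile(image, (15, 37, 46, 44), axis="x")
        assert abs(prof.peak_position - 30) <= 1
        assert prof.peak_over_background > 10

    def test_scaling_image_scales_profile_but_not_ratio(self):
        rng = np.random.default_rng(5)
        image = rng.poisson(3.0, size=(32, 32)).astype(float)
        image[16, 16] = 200
        box = (8, 14, 24, 19)
        a = line_profile(image, box)
        b = line_profile(image * 4, box)
        assert np.allclose(b.values, 4 * a.values)
        assert b.peak_over_background == pytest.approx(a.peak_over_background)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            line_profile(np.zeros((10, 10)), (5, 2, 5, 8))
        with pytest.raises(ValueError):
            line_profile(np.zeros((10, 10)), (2, 2, 20, 8))


def test_observation_set_from_dataframe_groups_rows():
    import pandas as pd

    df = pd.DataFrame(
        {
            "reflection_id": ["a", "a", "b", "b", "b"],
            "intensity": [1.0, 2.0, 3.0, 4.0, 5.0],
            "sigma": [0.1, 0.2, 0.3, 0.4, 0.5],
        }
    )
    obs = ObservationSet.from_dataframe(df)
    assert obs.n_unique == 2
    assert obs.n_total == 5
    assert np.array_equal(obs.groups["b"], [3.0, 4.0, 5.0])
    assert np.array_equal(obs.sigmas["a"], [0.1, 0.2])
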