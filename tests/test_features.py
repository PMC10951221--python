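"""The 60-feature bank: analytic cases, combination rules, table structure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from soleposture import (
    DYNAMIC_FEATURES,
    FEATURE_NAMES,
    FREQUENCY_FEATURES,
    FeatureTable,
    POSITIONAL_FEATURES,
    combine_asymmetry,
    combine_average,
    compute_foot_features,
    dynamic_features,
    frequency_features,
    minmax_normalize,
    positional_features,
)
from soleposture.features import CHI2_95_2

from conftest import make_trajectory


class TestInventory:
    def test_partition_sizes(self):
        assert len(POSITIONAL_FEATURES) == 19
        assert len(DYNAMIC_FEATURES) == 21
        assert len(FREQUENCY_FEATURES) == 20
        assert len(set(FEATURE_NAMES)) == 60

    def test_full_vector_names_and_determinism(self, sine_trajectory):
        v1 = compute_foot_features(sine_trajectory)
        v2 = compute_foot_features(sine_trajectory)
        assert tuple(v1) == FEATURE_NAMES
        assert v1 == v2


class TestPositional:
    def test_constant_trajectory_zero_dispersion(self):
        traj = make_trajectory(np.full(50, 3.0), np.full(50, -2.0))
        v = positional_features(traj)
        assert v["mean_value_ml"] == 3.0
        assert v["mean_value_ap"] == -2.0
        assert v["rms_radius"] == 0.0
        assert v["ellipse_area"] == 0.0
        assert all(np.isfinite(v[name]) for name in POSITIONAL_FEATURES)

    def test_alternating_pair_symmetry(self):
        ml = np.tile([-1.0, 1.0], 25)
        traj = make_trajectory(ml, np.zeros(50))
        v = positional_features(traj)
        assert v["mean_value_ml"] == pytest.approx(0.0)
        assert v["rms_ml"] == pytest.approx(1.0)
        assert v["rms_radius"] == pytest.approx(1.0)
        assert v["range_ml"] == pytest.approx(2.0)
        assert v["range_resultant"] == pytest.approx(2.0)

    def test_confidence_ellipse_gaussian_closed_form(self):
        rng = np.random.default_rng(42)
        sigma = 2.0
        n = 10_000
        traj = make_trajectory(
            rng.normal(0, sigma, n), rng.normal(0, sigma, n)
        )
        v = positional_features(traj)
        expected = np.pi * CHI2_95_2 * sigma**2
        assert v["ellipse_area"] == pytest.approx(expected, rel=0.03)

    def test_translation_covariance(self, sine_trajectory):
        v0 = positional_features(sine_trajectory)
        shifted = make_trajectory(
            sine_trajectory.ml + 5.0, sine_trajectory.ap - 3.0
        )
        v1 = positional_features(shifted)
        assert v1["mean_value_ml"] - v0["mean_value_ml"] == pytest.approx(5.0)
        assert v1["mean_value_ap"] - v0["mean_value_ap"] == pytest.approx(-3.0)
        for name in POSITIONAL_FEATURES:
            if name.startswith("mean_value"):
                continue
            assert v1[name] == pytest.approx(v0[name], rel=1e-9, abs=1e-9)

    def test_insufficient_frames_all_missing(self):
        traj = make_trajectory([1.0], [2.0])
        assert all(np.isnan(x) for x in positional_features(traj).values())


class TestDynamic:
    def test_zero_crossings_of_unit_sine(self):
        t = np.arange(360) / 12.0
        traj = make_trajectory(np.sin(2 * np.pi * t), np.zeros_like(t))
        v = dynamic_features(traj)
        assert 58 <= v["zero_crossing_velocity_ml"] <= 60

    def test_constant_trajectory_limits(self):
        traj = make_trajectory(np.full(100, 1.0), np.full(100, 2.0))
        v = dynamic_features(traj)
        assert v["mean_velocity"] == 0.0
        assert v["zero_crossing_velocity_ml"] == 0.0
        assert v["zero_crossing_velocity_ap"] == 0.0
        assert v["total_excursion"] == 0.0

    def test_circular_sway_area_rate(self):
        # radius r at angular rate w sweeps pi r^2 per 2pi/w seconds
        r, freq, fs, dur = 5.0, 0.5, 50.0, 20.0
        t = np.arange(int(dur * fs)) / fs
        traj = make_trajectory(
            r * np.cos(2 * np.pi * freq * t),
            r * np.sin(2 * np.pi * freq * t),
            fs=fs,
        )
        v = dynamic_features(traj)
        assert v["sway_area_per_second"] == pytest.approx(
            np.pi * r**2 * freq, rel=0.02
        )

    def test_gap_breaks_difference_chain(self):
        # a large jump across an invalid gap must not create velocity
        ml = np.r_[np.zeros(50), np.full(50, 100.0)]
        valid = np.ones(100, dtype=bool)
        valid[49:51] = False
        traj = make_trajectory(ml, np.zeros(100), valid=valid)
        v = dynamic_features(traj)
        assert v["peak_velocity_ml"] == 0.0
        assert v["total_excursion"] == 0.0


class TestFrequency:
    def test_pure_tone_mode_and_band_energy(self):
        t = np.arange(360) / 12.0
        traj = make_trajectory(np.sin(2 * np.pi * 2.0 * t), np.zeros_like(t))
        v = frequency_features(traj)
        bin_width = 12.0 / 128
        assert abs(v["frequency_mode_ml"] - 2.0) <= bin_width
        # nearly all energy lives at/below the tone (band edge inclusive)
        assert v["energy_below_05_ml"] < 0.05
        assert v["energy_05_2_ml"] + v["energy_above_2_ml"] >= 0.9

    def test_white_noise_parseval(self):
        rng = np.random.default_rng(7)
        ratios = []
        for _ in range(50):
            x = rng.normal(0, 1.5, 1024)
            traj = make_trajectory(x, np.zeros_like(x))
            v = frequency_features(traj)
            ratios.append(v["total_power_ml"] / x.var())
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)

    def test_constant_signal_zero_spectrum(self):
        traj = make_trajectory(np.full(360, 4.0), np.full(360, 4.0))
        v = frequency_features(traj)
        assert v["total_power_ml"] == 0.0
        assert np.isnan(v["frequency_mode_ml"])
        assert np.isnan(v["power_frequency_50_ap"])

    def test_too_short_all_missing(self):
        traj = make_trajectory(np.ones(10), np.ones(10))
        assert all(np.isnan(x) for x in frequency_features(traj).values())


class TestCombination:
    def test_average_arithmetic(self):
        left = {"a": 2.0, "b": 1.0}
        right = {"a": 4.0, "b": 1.0}
        assert combine_average(left, right) == {"a": 3.0, "b": 1.0}

    def test_average_idempotent_on_equal_feet(self):
        v = {"a": 1.3, "b": -4.0}
        assert combine_average(v, v) == v

    def test_asymmetry_cases(self):
        left = {"eq": 5.0, "max": 3.0, "half": 3.0, "zero": 0.0}
        right = {"eq": 5.0, "max": 0.0, "half": 1.0, "zero": 0.0}
        out = combine_asymmetry(left, right)
        assert out["eq"] == 0.0
        assert out["max"] == 1.0
        assert out["half"] == 0.5
        assert out["zero"] == 0.0

    def test_zero_denominator_unequal_is_missing(self):
        out = combine_asymmetry({"a": 2.0}, {"a": -2.0})
        assert np.isnan(out["a"])

    def test_negative_denominator_warns(self):
        with pytest.warns(UserWarning, match="negative denominator"):
            out = combine_asymmetry({"a": -3.0}, {"a": -1.0})
        assert out["a"] == pytest.approx(-0.5)

    @given(
        left=st.floats(0.0, 1e6),
        right=st.floats(0.0, 1e6),
    )
    def test_asymmetry_bounded_for_nonnegative(self, left, right):
        out = combine_asymmetry({"x": left}, {"x": right})
        if not np.isnan(out["x"]):
            assert 0.0 <= out["x"] <= 1.0


class TestNormalization:
    def test_minmax_example(self):
        df = pd.DataFrame({("average", "EO", "f"): [2.0, 4.0, 6.0]})
        df.columns = pd.MultiIndex.from_tuples(df.columns)
        out = minmax_normalize(FeatureTable(data=df))
        np.testing.assert_allclose(out.data.iloc[:, 0], [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero(self):
        df = pd.DataFrame({("average", "EO", "f"): [3.0, 3.0, 3.0]})
        df.columns = pd.MultiIndex.from_tuples(df.columns)
        out = minmax_normalize(FeatureTable(data=df))
        np.testing.assert_allclose(out.data.iloc[:, 0], 0.0)

    def test_held_out_row_not_clipped(self):
        df = pd.DataFrame(
            {("average", "EO", "f"): [2.0, 4.0, 6.0, 8.0]},
            index=["a", "b", "c", "d"],
        )
        df.columns = pd.MultiIndex.from_tuples(df.columns)
        out = minmax_normalize(FeatureTable(data=df), fit_rows=["a", "b", "c"])
        assert out.data.loc["d"].iloc[0] == pytest.approx(1.5)

    @given(vals=st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=8))
    def test_fit_rows_bounded(self, vals):
        df = pd.DataFrame({("average", "EO", "f"): vals})
        df.columns = pd.MultiIndex.from_tuples(df.columns)
        out = minmax_normalize(FeatureTable(data=df))
        col = out.data.iloc[:, 0]
        assert col.min() >= -1e-12 and col.max() <= 1.0 + 1e-12
        if len(set(vals)) > 1:
            assert col.min() == pytest.approx(0.0, abs=1e-12)
            assert col.max() == pytest.approx(1.0, abs=1e-12)
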