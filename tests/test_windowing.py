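"""Window schemes, per-window statistics, bell windowing, feature assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enoseslice import preprocessing as pp
from enoseslice import windowing as wn
from enoseslice.windowing import (
    FeatureMatrix,
    bell_window,
    extract_features,
    feature_count,
    make_window_scheme,
    stat_feature,
    weighted_area_feature,
    window_slices,
)


class TestWindowScheme:
    def test_five_windows_equal_spans(self):
        scheme = make_window_scheme(5)
        assert np.allclose(scheme.boundaries, [20, 56, 92, 128, 164, 200])

    def test_one_window(self):
        scheme = make_window_scheme(1)
        assert np.allclose(scheme.boundaries, [20, 200])

    def test_no_window_covers_full_record(self):
        scheme = make_window_scheme(0)
        assert scheme.region == (0.0, 260.0)
        assert scheme.boundaries is None

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            make_window_scheme(-1)

    def test_soft_cap_configurable(self):
        with pytest.raises(ValueError):
            make_window_scheme(11)
        assert make_window_scheme(11, max_windows=12).n_windows == 11

    def test_default_bell_parameters(self):
        scheme = make_window_scheme(5)
        for i, (a, b, c) in enumerate(scheme.bell_params):
            lo, hi = scheme.boundaries[i], scheme.boundaries[i + 1]
            assert c == pytest.approx((lo + hi) / 2)
            assert a == pytest.approx((hi - lo) / 2)
            assert b == 5.0


class TestStatFeature:
    @pytest.mark.parametrize(
        "values,statistic,expected",
        [
            ([1, 3, 2], "mean", 2.0),
            ([4, 1, 3, 2], "median", 2.5),
            ([1, 3, 2], "median", 2.0),
            ([1, 3, 2], "max", 3.0),
            ([1, 3, 2], "min", 1.0),
            ([7], "max", 7.0),
            ([7], "median", 7.0),
        ],
    )
    def test_examples(self, values, statistic, expected):
        assert stat_feature(values, statistic) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            stat_feature([], "mean")

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ValueError):
            stat_feature([1.0], "mode")

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    @settings(deadline=None, derandomize=True)
    def test_ordering_invariant(self, values):
        assert (
            stat_feature(values, "max")
            >= stat_feature(values, "mean")
            >= stat_feature(values, "min")
        )


class TestBellWindow:
    def test_unity_at_centre(self):
        assert bell_window(50.0, a_i=18.0, b_i=5.0, c_i=50.0) == 1.0

    @pytest.mark.parametrize("sign", [-1, 1])
    def test_half_at_half_width(self, sign):
        assert bell_window(50.0 + sign * 18.0, 18.0, 5.0, 50.0) == pytest.approx(0.5, abs=1e-12)

    def test_two_half_widths_b1(self):
        # (t - c)/a = 2, b = 1 -> 1/(1 + 2^2) = 0.2
        assert bell_window(4.0, 1.0, 1.0, 2.0) == pytest.approx(0.2, abs=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            bell_window(0.0, a_i=0.0, b_i=1.0, c_i=0.0)
        with pytest.raises(ValueError):
            bell_window(0.0, a_i=1.0, b_i=0.0, c_i=0.0)

    @given(
        st.floats(-50, 50),
        st.floats(0.5, 20),
        st.floats(0.5, 8),
    )
    @settings(deadline=None, derandomize=True)
    def test_symmetric_and_decreasing(self, dt, a, b):
        c = 10.0
        k_plus = bell_window(c + dt, a, b, c)
        k_minus = bell_window(c - dt, a, b, c)
        assert k_plus == pytest.approx(k_minus, rel=1e-9)
        assert 0.0 < k_plus <= 1.0
        further = bell_window(c + dt * 1.5 + 1.0, a, b, c) if dt >= 0 else None
        if further is not None:
            assert further <= k_plus + 1e-12


class TestWeightedArea:
    def test_zero_response_zero_area(self):
        scheme = make_window_scheme(5)
        t = np.arange(20.0, 200.05, 0.1)
        assert weighted_area_feature(np.zeros_like(t), t, 0, scheme) == 0.0

    def test_unit_response_unit_weight_gives_total_time(self):
        # enormous half-width drives the bell weight to exactly 1 everywhere
        scheme = wn.WindowScheme(
            n_windows=1, region=(0.0, 1.0), boundaries=np.array([0.0, 1.0]),
            bell_params=((1e12, 1.0, 0.5),),
        )
        t = np.linspace(0.0, 1.0, 11)
        area = weighted_area_feature(np.ones_like(t), t, 0, scheme)
        assert area == pytest.approx(11 * 0.1, abs=1e-12)

    def test_ramp_matches_brute_force(self):
        scheme = wn.WindowScheme(
            n_windows=1, region=(0.0, 4.0), boundaries=np.array([0.0, 4.0]),
            bell_params=((1.5, 2.0, 2.0),),
        )
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        r = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        expected = sum(
            rv / (1.0 + abs((tv - 2.0) / 1.5) ** 4.0) * 1.0 for tv, rv in zip(t, r)
        )
        assert weighted_area_feature(r, t, 0, scheme) == pytest.approx(expected, rel=1e-12)

    def test_non_uniform_grid_rejected(self):
        scheme = make_window_scheme(1)
        t = np.array([0.0, 0.1, 0.3])
        with pytest.raises(ValueError, match="uniform"):
            weighted_area_feature(np.zeros(3), t, 0, scheme)

    def test_linear_in_response(self):
        scheme = make_window_scheme(3)
        t = np.arange(20.0, 200.05, 0.1)
        rng = np.random.default_rng(0)
        r1, r2 = rng.normal(size=t.size), rng.normal(size=t.size)
        w1 = weighted_area_feature(r1, t, 1, scheme)
        w2 = weighted_area_feature(r2, t, 1, scheme)
        w12 = weighted_area_feature(2.0 * r1 + 3.0 * r2, t, 1, scheme)
        assert w12 == pytest.approx(2.0 * w1 + 3.0 * w2, rel=1e-9)

    def test_steep_bell_approaches_rectangular_window(self, small_corrected):
        # at b = 50 the bell is near-rectangular; compare with the hard
        # slice area on a smooth (noise-averaged plateau) signal
        rec = small_corrected[0]
        scheme5 = make_window_scheme(5)
        t, vals = pp.select_sensing_region(rec, scheme5)
        smooth = np.convolve(vals[0], np.ones(51) / 51, mode="same")
        steep = wn.WindowScheme(
            n_windows=5, region=scheme5.region, boundaries=scheme5.boundaries,
            bell_params=tuple((a, 50.0, c) for a, _, c in scheme5.bell_params),
        )
        masks = window_slices(t, scheme5)
        for i in (1, 2, 3):  # interior windows, away from region edges
            rect = smooth[masks[i]].sum() * 0.1
            bell = weighted_area_feature(smooth, t, i, steep)
            assert bell == pytest.approx(rect, rel=0.01)


class TestWindowPartition:
    @pytest.mark.parametrize("n", [1, 2, 5, 7, 10])
    def test_slices_partition_region(self, n, small_dataset):
        scheme = make_window_scheme(n)
        t, _ = pp.select_sensing_region(small_dataset[0], scheme)
        masks = window_slices(t, scheme)
        counts = np.sum(masks, axis=0)
        assert np.all(counts == 1)


class TestExtractFeatures:
    @pytest.mark.parametrize("n", range(0, 11))
    def test_feature_count_formula(self, n, small_corrected):
        scheme = make_window_scheme(n)
        fm = extract_features(small_corrected, scheme, "max")
        expected = 8 if n == 0 else 8 * n + 2
        assert fm.p == expected == feature_count(n)

    def test_slice_stats_match_naive_loop(self, small_corrected):
        scheme = make_window_scheme(5)
        for stat in wn.STATISTICS:
            fm = extract_features(small_corrected, scheme, stat)
            rec = small_corrected[2]
            row = fm.values[2]
            t, vals = pp.select_sensing_region(rec, scheme)
            for w in range(5):
                lo, hi = scheme.boundaries[w], scheme.boundaries[w + 1]
                seg_idx = [
                    j for j, tv in enumerate(t)
                    if (tv >= lo - 0.05) and (tv < hi - 0.05 or (w == 4 and tv <= hi + 0.05))
                ]
                for c in range(8):
                    seg = sorted(float(vals[c, j]) for j in seg_idx)
                    if stat == "max":
                        expected = seg[-1]
                    elif stat == "min":
                        expected = seg[0]
                    elif stat == "mean":
                        expected = sum(seg) / len(seg)
                    else:
                        m = len(seg)
                        expected = (
                            (seg[m // 2 - 1] + seg[m // 2]) / 2 if m % 2 == 0 else seg[m // 2]
                        )
                    if stat == "mean":
                        # summation order may differ by a few ulp
                        assert row[w * 8 + c] == pytest.approx(expected, abs=1e-12)
                    else:
                        assert row[w * 8 + c] == expected

    def test_row_order_and_labels_preserved(self, small_corrected):
        fm = extract_features(small_corrected, make_window_scheme(2), "mean")
        assert np.array_equal(fm.labels, small_corrected.labels)
        assert np.array_equal(fm.sample_ids, small_corrected.sample_ids)

    def test_bell_area_mode_counts(self, small_corrected):
        fm = extract_features(small_corrected, make_window_scheme(3), mode="bell_area")
        assert fm.p == 26
        assert fm.feature_names[0] == "S1_W1_area"

    def test_mixed_length_records_rejected(self, small_dataset):
        from dataclasses import replace

        short = replace(
            small_dataset[0],
            timestamps=small_dataset[0].timestamps[:-1],
            gas=small_dataset[0].gas[:, :-1],
            env=small_dataset[0].env[:, :-1],
        )
        from enoseslice.synthetic import Dataset

        with pytest.raises(ValueError, match="mixed-length"):
            extract_features(Dataset([small_dataset[1], short]), make_window_scheme(1), "max")

    def test_csv_round_trip(self, small_corrected, tmp_path):
        fm = extract_features(small_corrected, make_window_scheme(2), "median")
        path = tmp_path / "features.csv"
        fm.to_csv(path)
        back = FeatureMatrix.from_csv(path)
        assert back.feature_names == fm.feature_names
        assert np.array_equal(back.labels, fm.labels)
        assert np.array_equal(back.values, fm.values)
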