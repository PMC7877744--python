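"""The six movement features and the normalized feature matrix."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinclust.features import (
    angular_velocity,
    build_feature_matrix,
    max_normalize,
    mean_angle,
    path_distance,
    peak_angle,
    peak_angular_velocity,
    range_of_motion,
    zero_crossings,
)


class TestScalarFeatures:
    @pytest.mark.parametrize(
        "trace,expected",
        [([1, 5, 3], 5.0), ([2, 2, 2], 2.0), ([-3, -1, -2], -1.0)],
    )
    def test_peak_angle_is_signed_maximum(self, trace, expected):
        assert peak_angle(trace) == expected

    @pytest.mark.parametrize(
        "trace,expected",
        [([1, 5, 3], 4.0), ([7, 7], 0.0), (np.linspace(0, 10, 50), 10.0)],
    )
    def test_range_of_motion(self, trace, expected):
        assert range_of_motion(trace) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "trace,expected",
        [([0, 1, 3, 2], 4.0), ([5, 5, 5], 0.0), (np.linspace(0, 7, 23), 7.0)],
    )
    def test_path_distance_sums_absolute_steps(self, trace, expected):
        assert path_distance(trace) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "trace,expected", [([0, 10], 5.0), ([4, 4, 4], 4.0), ([-2, -1, 0, 1, 2], 0.0)]
    )
    def test_mean_angle(self, trace, expected):
        assert mean_angle(trace) == pytest.approx(expected)

    def test_empty_trace_rejected_everywhere(self):
        for fn in (peak_angle, range_of_motion, mean_angle):
            with pytest.raises(ValueError):
                fn([])
        with pytest.raises(ValueError):
            path_distance([1.0])


class TestVelocity:
    def test_linear_ramp_has_constant_velocity(self):
        trace = 2.0 * np.arange(50)  # 2 deg/frame
        np.testing.assert_allclose(angular_velocity(trace, 100.0), 200.0)

    def test_constant_trace_has_zero_velocity(self):
        np.testing.assert_allclose(angular_velocity(np.full(30, 5.0), 100.0), 0.0)

    def test_sine_velocity_matches_analytic_derivative(self):
        # unit-time sine sampled densely: d/dt sin(2 pi t) peaks at 2 pi
        n = 2000
        t = np.linspace(0.0, 1.0, n)
        vel = angular_velocity(np.sin(2 * np.pi * t), frame_rate=n - 1)
        assert np.max(vel) == pytest.approx(2 * np.pi, rel=1e-4)
        np.testing.assert_allclose(
            vel[1:-1], 2 * np.pi * np.cos(2 * np.pi * t)[1:-1], atol=1e-2
        )

    def test_peak_velocity_signed_convention(self):
        up = 2.0 * np.arange(20)
        down = -1.0 * np.arange(20)
        assert peak_angular_velocity(up, 100.0) == pytest.approx(200.0)
        assert peak_angular_velocity(down, 100.0) == pytest.approx(-100.0)
        assert peak_angular_velocity(down, 100.0, absolute=True) == pytest.approx(100.0)
        assert peak_angular_velocity(np.full(10, 3.0), 100.0) == 0.0


class TestZeroCrossings:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ([1, -1, 1, -1], 3),
            ([1, 2, 3, 0.5], 0),
            ([1, 0, -1], 1),  # +,0,- counts once
            ([0, 0, 2, 0], 0),
        ],
    )
    def test_counts_strict_sign_changes(self, seq, expected):
        assert zero_crossings(seq) == expected

    def test_sine_over_two_periods(self):
        # velocity of sin over exactly 2 periods at 100 samples/period -> cos,
        # which crosses zero 4 times; brute-force sign-change count agrees
        t = np.arange(200) / 100.0
        vel = angular_velocity(np.sin(2 * np.pi * t), 100.0)
        signs = np.sign(vel[vel != 0])
        brute = int(np.sum(signs[1:] != signs[:-1]))
        assert zero_crossings(vel) == brute == 4


class TestMaxNormalization:
    def test_column_divided_by_max_abs(self):
        X, scales = max_normalize(np.array([[2.0, -4.0], [4.0, 2.0]]))
        np.testing.assert_allclose(X, [[0.5, -1.0], [1.0, 0.5]])
        np.testing.assert_allclose(scales, [4.0, 4.0])

    def test_zero_column_passes_through_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            X, _ = max_normalize(np.array([[0.0, 1.0], [0.0, 2.0]]))
        np.testing.assert_allclose(X[:, 0], 0.0)

    def test_normalized_columns_have_unit_max_abs(self):
        rng = np.random.default_rng(2)
        X, _ = max_normalize(rng.standard_normal((20, 6)))
        np.testing.assert_allclose(np.max(np.abs(X), axis=0), 1.0)


@st.composite
def _traces(draw):
    values = draw(
        st.lists(
            st.floats(-50, 50, allow_nan=False), min_size=2, max_size=40
        )
    )
    return np.asarray(values)


class TestFeatureIdentities:
    @settings(derandomize=True, max_examples=200)
    @given(_traces())
    def test_rom_never_exceeds_path_distance(self, trace):
        assert range_of_motion(trace) <= path_distance(trace) + 1e-9

    @settings(derandomize=True, max_examples=100)
    @given(_traces())
    def test_equality_holds_iff_monotone(self, trace):
        rom = range_of_motion(trace)
        pdist = path_distance(trace)
        diffs = np.diff(trace)
        monotone = np.all(diffs >= 0) or np.all(diffs <= 0)
        if monotone:
            assert pdist == pytest.approx(rom)
        else:
            assert pdist > rom - 1e-12

    def test_amplitude_features_scale_equivariant_after_normalization(self):
        """Multiplying all trajectories by c > 0 leaves the normalized matrix
        unchanged for the four amplitude-like features."""
        rng = np.random.default_rng(3)
        raw = rng.standard_normal((10, 4)) * [30, 20, 50, 15]
        for c in (2.0, 0.1):
            a, _ = max_normalize(raw)
            b, _ = max_normalize(c * raw)
            np.testing.assert_allclose(a, b, atol=1e-12)


class TestBuildFeatureMatrix:
    @staticmethod
    def _table():
        rows = []
        for pid, cond, label in [("N1", "Norm", 0), ("N2", "Norm", 0),
                                 ("B1", "BP", 1), ("B2", "BP", 1)]:
            for trial in (1, 2):
                rows.append(
                    {
                        "participant_id": pid,
                        "condition": cond,
                        "task": "JHFT1",
                        "trial_index": trial,
                        "dof": "torso_rot",
                        "peak_angle": 2.0 if label else 1.0,
                        "range_of_motion": 4.0,
                        "path_distance": 5.0,
                        "mean_angle": -4.0 if label else 2.0,
                        "peak_angular_velocity": 10.0,
                        "zero_crossings": 3,
                    }
                )
        return pd.DataFrame(rows)

    def test_rows_labels_and_normalization(self):
        participants = {"N1": 0, "N2": 0, "B1": 1, "B2": 1}
        X, labels, meta = build_feature_matrix(
            self._table(), "JHFT1", "torso_rot", participants
        )
        assert X.shape == (8, 6)
        assert sorted(labels) == [0] * 4 + [1] * 4
        assert np.max(np.abs(X), axis=0) == pytest.approx(1.0)
        # max-absolute convention: mean_angle column contains -1 and 0.5
        col = X[:, 3]
        assert set(np.round(col, 6)) == {-1.0, 0.5}

    def test_normalize_false_passes_raw_values(self):
        participants = {"N1": 0, "N2": 0, "B1": 1, "B2": 1}
        X, _, _ = build_feature_matrix(
            self._table(), "JHFT1", "torso_rot", participants, normalize=False
        )
        assert set(X[:, 0]) == {1.0, 2.0}

    def test_average_trials_collapses_to_one_row_per_participant(self):
        participants = {"N1": 0, "N2": 0, "B1": 1, "B2": 1}
        X, labels, _ = build_feature_matrix(
            self._table(), "JHFT1", "torso_rot", participants, average_trials=True
        )
        assert X.shape == (4, 6)

    def test_missing_participant_raises_with_key(self):
        participants = {"N1": 0, "N2": 0, "B1": 1, "GHOST": 1}
        with pytest.raises(ValueError, match="GHOST"):
            build_feature_matrix(self._table(), "JHFT1", "torso_rot", participants)
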