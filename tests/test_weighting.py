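"""Inter-marker distances and Gaussian weight construction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import constant_dataset
from mocapfill.dataset import MarkerDataset
from mocapfill.exceptions import NoCommonSupportError, ParameterError
from mocapfill.weighting import (
    ReconstructionParams,
    WeightVector,
    build_weight_vector,
    gaussian_weight,
    mean_marker_distance,
)


class TestMeanDistance:
    def test_three_four_five(self):
        ds = constant_dataset([(0, 0, 0), (3, 4, 0)])
        assert mean_marker_distance(ds, 0, 1) == pytest.approx(5.0)

    def test_common_support_only(self):
        # B present frames 0-4, missing 5-9 while A moves away
        data = np.zeros((10, 6))
        data[:, 0] = np.arange(10) * 100.0  # A moves along x
        data[:, 3] = 5.0  # B fixed at x=5
        data[5:, 3:] = np.nan
        ds = MarkerDataset(data=data, labels=["A", "B"])
        expected = np.mean(np.abs(np.arange(5) * 100.0 - 5.0))
        assert mean_marker_distance(ds, 0, 1) == pytest.approx(expected)

    def test_self_distance_rejected(self):
        ds = constant_dataset([(0, 0, 0), (1, 0, 0)])
        with pytest.raises(ParameterError):
            mean_marker_distance(ds, 0, 0)

    def test_no_common_frames(self):
        data = np.ones((4, 6))
        data[:2, :3] = np.nan
        data[2:, 3:] = np.nan
        ds = MarkerDataset(data=data, labels=["A", "B"])
        with pytest.raises(NoCommonSupportError):
            mean_marker_distance(ds, 0, 1)


class TestGaussianWeight:
    def test_closed_form(self):
        assert gaussian_weight(0.0, 200.0) == 1.0
        assert gaussian_weight(200.0, 200.0) == pytest.approx(math.exp(-0.5))

    @settings(deadline=None, derandomize=True)
    @given(
        d=st.floats(0.0, 5000.0),
        step=st.floats(1e-3, 1000.0),
        sigma=st.floats(10.0, 2000.0),
    )
    def test_strictly_decreasing(self, d, step, sigma):
        assert gaussian_weight(d + step, sigma) < gaussian_weight(d, sigma) or (
            gaussian_weight(d, sigma) == 0.0
        )

    def test_bad_sigma(self):
        with pytest.raises(ParameterError):
            gaussian_weight(1.0, 0.0)


class TestBuildWeightVector:
    def test_coincident_markers_get_unit_weight(self):
        ds = constant_dataset([(0, 0, 0), (0, 0, 0), (0, 0, 0)])
        w = build_weight_vector(ds, [0], ReconstructionParams())
        np.testing.assert_allclose(w.per_marker, [0.02, 1.0, 1.0])

    def test_max_rule_over_targets(self):
        # marker at 100 mm from target A, 1000 mm from target B, sigma=200
        ds = constant_dataset([(0, 0, 0), (1000 - 100, 0, 0), (1000, 0, 0)])
        w = build_weight_vector(ds, [0, 2], ReconstructionParams(sigma=200.0))
        assert w.per_marker[1] == pytest.approx(math.exp(-(100.0**2) / 80000.0))

    def test_five_marker_chain_matches_hand_computation(self):
        # chain spaced 150 mm apart along x; expected table computed with
        # plain python from the distance average and the exp formula
        positions = [(150.0 * i, 0.0, 0.0) for i in range(5)]
        ds = constant_dataset(positions)
        params = ReconstructionParams(sigma=200.0, w_mm=0.02)
        w = build_weight_vector(ds, [2], params)
        expected = []
        for j in range(5):
            if j == 2:
                expected.append(0.02)
            else:
                d = abs(positions[j][0] - positions[2][0])
                expected.append(math.exp(-(d**2) / (2 * 200.0**2)))
        np.testing.assert_allclose(w.per_marker, expected, rtol=1e-12)

    def test_triples_share_weight(self):
        ds = constant_dataset([(0, 0, 0), (50, 0, 0), (0, 400, 0)])
        w = build_weight_vector(ds, [1], ReconstructionParams())
        assert (w.weights.reshape(-1, 3) == w.weights[::3][:, None]).all()

    def test_permutation_equivariance(self, small_noisy_dataset):
        ds = small_noisy_dataset
        params = ReconstructionParams()
        perm = [3, 0, 5, 1, 7, 2, 6, 4]
        permuted = ds.select_markers(perm)
        w = build_weight_vector(ds, [0], params).per_marker
        w_p = build_weight_vector(permuted, [perm.index(0)], params).per_marker
        np.testing.assert_allclose(w_p, w[perm], rtol=1e-12)

    def test_translation_invariance(self, small_noisy_dataset):
        params = ReconstructionParams()
        w = build_weight_vector(small_noisy_dataset, [2], params).weights
        shifted = small_noisy_dataset.translate((500.0, -300.0, 250.0))
        w_s = build_weight_vector(shifted, [2], params).weights
        np.testing.assert_allclose(w_s, w, rtol=1e-9)

    def test_orphan_marker_gets_floor_weight(self):
        data = np.ones((6, 9))
        data[:, 0:3] += [[1], [2], [3], [4], [5], [6]]
        data[:3, 3:6] = np.nan  # B only present when target is absent
        data[3:, 0:3] = np.nan  # target A absent frames 3-5
        ds = MarkerDataset(data=data, labels=["A", "B", "C"])
        w = build_weight_vector(ds, [0], ReconstructionParams())
        assert w.per_marker[1] == pytest.approx(1e-6)


class TestParams:
    def test_defaults(self):
        p = ReconstructionParams()
        assert (p.w_mm, p.sigma, p.theta_lambda, p.theta_d) == (0.02, 200.0, 0.99, 0.5)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"w_mm": 0.0},  # identical bases; explicitly rejected
            {"w_mm": 1.5},
            {"sigma": -1.0},
            {"theta_lambda": 0.0},
            {"theta_d": -0.1},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            ReconstructionParams(**kwargs)

    def test_weight_vector_validation(self):
        with pytest.raises(ParameterError):
            WeightVector(np.array([0.5, 0.5, 0.4]))  # triple not constant
        with pytest.raises(ParameterError):
            WeightVector(np.zeros(3))  # zero weights
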