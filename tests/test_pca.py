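"""The dual-basis engine: truncation rule, transition matrix, reconstruction."""

import numpy as np
import pytest

from conftest import exact_rank_dataset, subspace_completion_oracle
from mocapfill.dataset import MarkerDataset
from mocapfill.exceptions import (
    DegenerateBasisError,
    InsufficientSupportError,
    ParameterError,
)
from mocapfill.pca import (
    _k_retained,
    extract_complete_frames,
    fit_basis,
    reconstruct_eq1,
    transition_matrix,
)
from mocapfill.synthetic import make_single_marker_gap
from mocapfill.weighting import ReconstructionParams, WeightVector, build_weight_vector


def unit_weights(p):
    return WeightVector(np.ones(p))


class TestExtractCompleteFrames:
    def test_gap_block_removed(self, rank3_dataset):
        ds = make_single_marker_gap(rank3_dataset.select_frames(range(20)), 0, 4, 7)
        n, idx = extract_complete_frames(ds)
        assert n.shape == (16, ds.data.shape[1])
        np.testing.assert_array_equal(idx, [0, 1, 2, 3] + list(range(8, 20)))

    def test_gap_free_returns_all(self, rank3_dataset):
        n, idx = extract_complete_frames(rank3_dataset)
        assert n.shape[0] == rank3_dataset.n_frames
        assert (n == rank3_dataset.data).all()

    def test_insufficient_support(self, rank3_dataset):
        ds = make_single_marker_gap(
            rank3_dataset, 0, 0, rank3_dataset.n_frames - 1
        )
        with pytest.raises(InsufficientSupportError) as err:
            extract_complete_frames(ds)
        assert err.value.n_complete == 0


class TestTruncationRule:
    def test_stated_example(self):
        # singular values (3,1,0,0): cumulative fractions 0.75, 1.0 -> k=2
        assert _k_retained(np.array([3.0, 1.0, 0.0, 0.0]), 0.99) == 2

    def test_theta_one_keeps_all_nonzero(self):
        assert _k_retained(np.array([3.0, 1.0, 0.5, 0.0]), 1.0) == 3

    def test_small_theta_keeps_one(self):
        assert _k_retained(np.array([3.0, 1.0]), 0.1) == 1

    def test_fit_basis_stores_rule(self, rank3_dataset):
        p = rank3_dataset.data.shape[1]
        b = fit_basis(rank3_dataset.data, unit_weights(p), 1.0)
        # noise-free: rank of the centered matrix equals the latent rank
        assert b.k_retained == 3
        assert (np.diff(b.singular_values) <= 1e-9).all()
        # orthonormality
        v = b.vectors
        np.testing.assert_allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-8)

    def test_training_matrix_reproduced(self, small_noisy_dataset):
        x = small_noisy_dataset.data
        b = fit_basis(x, unit_weights(x.shape[1]), 1.0)
        centered = x - b.column_means
        recon = (centered @ b.vectors) @ b.vectors.T
        np.testing.assert_allclose(recon, centered, atol=1e-8 * np.abs(centered).max())

    def test_degenerate_input(self):
        x = np.ones((5, 6))
        with pytest.raises(DegenerateBasisError):
            fit_basis(x, unit_weights(6), 0.99)


class TestTransitionMatrix:
    def test_identity_when_nothing_zeroed(self, small_noisy_dataset):
        x = small_noisy_dataset.data
        w = unit_weights(x.shape[1])
        b = fit_basis(x, w, 0.99)
        t = transition_matrix(x, x, b, b, w)
        np.testing.assert_allclose(t, np.eye(b.k_retained), atol=1e-8)

    def test_exact_low_rank_mapping(self):
        # rank-3 data, 3m = 12 columns, one marker zeroed
        ds = exact_rank_dataset(n_markers=4, n_frames=200, rank=3, seed=5)
        x = ds.data
        w = unit_weights(12)
        z = x.copy()
        z[:, 0:3] = 0.0
        bf = fit_basis(x, w, 1.0)
        bz = fit_basis(z, w, 1.0)
        t = transition_matrix(x, z, bf, bz, w)
        s_full = (x - bf.column_means) @ bf.truncated
        s_zeros = (z - bz.column_means) @ bz.truncated
        resid = np.linalg.norm(s_zeros @ t - s_full) / np.linalg.norm(s_full)
        assert resid < 1e-6

    def test_row_permutation_invariance(self, small_noisy_dataset):
        x = small_noisy_dataset.data
        w = unit_weights(x.shape[1])
        z = x.copy()
        z[:, 3:6] = 0.0
        bf, bz = fit_basis(x, w, 0.99), fit_basis(z, w, 0.99)
        t = transition_matrix(x, z, bf, bz, w)
        rng = np.random.default_rng(0)
        perm = rng.permutation(x.shape[0])
        t_p = transition_matrix(x[perm], z[perm], bf, bz, w)
        np.testing.assert_allclose(t_p, t, atol=1e-8)


class TestReconstructEq1:
    def test_gap_free_is_noop(self, rank3_dataset):
        w = build_weight_vector(rank3_dataset, [0], ReconstructionParams())
        res = reconstruct_eq1(rank3_dataset, [0], w, 0.99)
        np.testing.assert_array_equal(res.filled.data, rank3_dataset.data)

    def test_exact_subspace_recovery_vs_oracle(self):
        truth = exact_rank_dataset(n_markers=40, n_frames=500, rank=3, seed=9)
        corrupted = make_single_marker_gap(truth, 12, 200, 299)
        w = build_weight_vector(corrupted, [12], ReconstructionParams())
        res = reconstruct_eq1(corrupted, [12], w, 1.0)
        gap = np.isnan(corrupted.data)
        err = np.linalg.norm(
            (res.filled.data - truth.data)[gap].reshape(-1, 3), axis=1
        )
        assert err.mean() < 0.1
        oracle = subspace_completion_oracle(corrupted.data)
        np.testing.assert_allclose(res.filled.data[gap], oracle[gap], atol=1e-3)

    def test_observed_samples_bit_identical(self, rank3_dataset):
        corrupted = make_single_marker_gap(rank3_dataset, 2, 50, 120)
        w = build_weight_vector(corrupted, [2], ReconstructionParams())
        res = reconstruct_eq1(corrupted, [2], w, 0.99)
        obs = ~np.isnan(corrupted.data)
        assert (res.filled.data[obs] == corrupted.data[obs]).all()

    def test_translation_equivariance(self, rank3_dataset):
        corrupted = make_single_marker_gap(rank3_dataset, 2, 50, 120)
        params = ReconstructionParams()
        w = build_weight_vector(corrupted, [2], params)
        res = reconstruct_eq1(corrupted, [2], w, 0.99)
        shift = np.array([500.0, -300.0, 250.0])
        shifted = corrupted.translate(shift)
        w_s = build_weight_vector(shifted, [2], params)
        res_s = reconstruct_eq1(shifted, [2], w_s, 0.99)
        np.testing.assert_allclose(
            res_s.filled.data,
            res.filled.data + np.tile(shift, corrupted.n_markers),
            atol=1e-6,
        )

    def test_errors_propagate(self, rank3_dataset):
        all_gone = make_single_marker_gap(
            rank3_dataset, 0, 0, rank3_dataset.n_frames - 1
        )
        for j in range(1, rank3_dataset.n_markers):
            all_gone = make_single_marker_gap(
                all_gone, j, 0, rank3_dataset.n_frames - 1
            )
        w = WeightVector(np.ones(rank3_dataset.data.shape[1]))
        with pytest.raises(InsufficientSupportError):
            reconstruct_eq1(all_gone, [0], w, 0.99)

    def test_no_targets_with_gaps_rejected(self, rank3_dataset):
        corrupted = make_single_marker_gap(rank3_dataset, 2, 50, 120)
        w = WeightVector(np.ones(rank3_dataset.data.shape[1]))
        with pytest.raises(ParameterError):
            reconstruct_eq1(corrupted, [], w, 0.99)
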