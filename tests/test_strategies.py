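"""R1 and R2 multi-gap drivers and the theta_d neighbour selection."""

import numpy as np
import pytest

from conftest import constant_dataset, exact_rank_dataset, subspace_completion_oracle
from mocapfill.dataset import MarkerDataset
from mocapfill.exceptions import ParameterError
from mocapfill.pca import reconstruct_eq1
from mocapfill.strategies import (
    fill_gaps,
    reconstruct_r1,
    reconstruct_r2,
    select_neighbors_r2,
)
from mocapfill.synthetic import make_single_marker_gap
from mocapfill.weighting import ReconstructionParams, build_weight_vector


def _gap(ds, marker, start, end):
    return make_single_marker_gap(ds, marker, start, end)


@pytest.fixture(scope="module")
def rank4_disjoint_gaps():
    """Exact rank-4 data with 3 markers gapped at disjoint times (~30%)."""
    truth = exact_rank_dataset(n_markers=12, n_frames=300, rank=4, seed=11)
    corrupted = _gap(_gap(_gap(truth, 1, 0, 29), 5, 100, 129), 9, 200, 229)
    return truth, corrupted


class TestR1:
    def test_single_marker_equals_eq1(self, rank3_dataset):
        corrupted = _gap(rank3_dataset, 3, 100, 180)
        params = ReconstructionParams()
        filled, report = reconstruct_r1(corrupted, params)
        w = build_weight_vector(corrupted, [3], params)
        direct = reconstruct_eq1(corrupted, [3], w, params.theta_lambda)
        assert (filled.data == direct.filled.data).all()
        assert report.gap_counts == {rank3_dataset.labels[3]: 81}

    def test_disjoint_gaps_recovered(self, rank4_disjoint_gaps):
        truth, corrupted = rank4_disjoint_gaps
        filled, _ = reconstruct_r1(corrupted, ReconstructionParams(theta_lambda=1.0))
        gap = np.isnan(corrupted.data)
        err = np.linalg.norm((filled.data - truth.data)[gap].reshape(-1, 3), axis=1)
        assert err.mean() < 0.5

    def test_gap_free_unchanged(self, rank3_dataset):
        filled, report = reconstruct_r1(rank3_dataset)
        np.testing.assert_array_equal(filled.data, rank3_dataset.data)
        assert report.n_gap_frames == 0


class TestNeighborSelection:
    def test_distance_cutoff_arithmetic(self):
        # B at 100 mm, C at 900 mm from target A: D_A = 500, cutoff 250
        ds = constant_dataset([(0, 0, 0), (100, 0, 0), (900, 0, 0)], n_frames=40)
        ds = _gap(_gap(_gap(ds, 0, 0, 9), 1, 20, 24), 2, 30, 34)
        dec = select_neighbors_r2(ds, 0, ReconstructionParams(theta_d=0.5))
        assert dec.mean_distance == pytest.approx(500.0)
        assert 1 in dec.included_markers
        assert dec.omitted_markers == {2: "beyond-theta-d"}
        assert dec.dropped_frames == frozenset(range(20, 25))

    def test_overlap_omitted_regardless_of_distance(self):
        ds = constant_dataset([(0, 0, 0), (0, 0, 0), (10, 0, 0)], n_frames=80)
        ds = _gap(_gap(ds, 0, 55, 70), 1, 50, 60)  # B overlaps target frames 55-60
        dec = select_neighbors_r2(ds, 0, ReconstructionParams(theta_d=0.5))
        assert dec.omitted_markers == {1: "temporal-overlap"}

    def test_permissive_theta_includes_all(self):
        ds = constant_dataset(
            [(0, 0, 0), (100, 0, 0), (250, 0, 0), (400, 0, 0)], n_frames=60
        )
        ds = _gap(_gap(_gap(ds, 0, 0, 9), 1, 20, 24), 2, 30, 39)
        dec = select_neighbors_r2(ds, 0, ReconstructionParams(theta_d=2.0))
        assert dec.included_markers == frozenset({1, 2, 3})
        assert dec.dropped_frames == frozenset(range(20, 25)) | frozenset(range(30, 40))

    def test_target_without_gaps_rejected(self, rank3_dataset):
        with pytest.raises(ParameterError):
            select_neighbors_r2(rank3_dataset, 0, ReconstructionParams())


class TestR2:
    def test_single_marker_bitwise_equals_r1(self, rank3_dataset):
        corrupted = _gap(rank3_dataset, 3, 100, 180)
        f1, _ = reconstruct_r1(corrupted)
        f2, _ = reconstruct_r2(corrupted)
        assert (f1.data == f2.data).all()

    def test_disjoint_gaps_each_marker_recovered(self, rank4_disjoint_gaps):
        truth, corrupted = rank4_disjoint_gaps
        params = ReconstructionParams(theta_lambda=1.0)
        f2, report = reconstruct_r2(corrupted, params)
        f1, _ = reconstruct_r1(corrupted, params)
        gap = np.isnan(corrupted.data)
        e2 = np.linalg.norm((f2.data - truth.data)[gap].reshape(-1, 3), axis=1).mean()
        e1 = np.linalg.norm((f1.data - truth.data)[gap].reshape(-1, 3), axis=1).mean()
        assert e2 < 0.5
        assert e2 <= e1 + 1e-9  # consecutive pass sees strictly more frames
        assert not report.unfilled

    def test_matches_subspace_oracle(self, rank4_disjoint_gaps):
        truth, corrupted = rank4_disjoint_gaps
        oracle = subspace_completion_oracle(corrupted.data)
        f2, _ = reconstruct_r2(corrupted, ReconstructionParams(theta_lambda=1.0))
        gap = np.isnan(corrupted.data)
        np.testing.assert_allclose(f2.data[gap], oracle[gap], atol=1e-3)

    def test_observed_samples_never_modified(self, rank4_disjoint_gaps):
        _, corrupted = rank4_disjoint_gaps
        for strategy in ("r1", "r2", "spline", "linear"):
            filled, _ = fill_gaps(corrupted, strategy)
            obs = ~np.isnan(corrupted.data)
            assert (filled.data[obs] == corrupted.data[obs]).all()

    def test_marker_permutation_equivariance(self, rank4_disjoint_gaps):
        # no feedback between markers: relabeling the dataset permutes the
        # result identically (processing order is irrelevant)
        _, corrupted = rank4_disjoint_gaps
        perm = [7, 1, 9, 0, 5, 3, 11, 2, 10, 4, 8, 6]
        f, _ = reconstruct_r2(corrupted)
        f_p, _ = reconstruct_r2(corrupted.select_markers(perm))
        cols = np.concatenate([np.arange(3 * j, 3 * j + 3) for j in perm])
        np.testing.assert_allclose(f_p.data, f.data[:, cols], atol=1e-6)

    def test_isolated_marker_reported_unfilled(self):
        # every neighbour of the target is corrupted and overlaps its gap
        ds = constant_dataset(
            [(0, 0, 0), (10, 0, 0), (20, 0, 0)], n_frames=60
        )
        noisy = ds.with_data(
            ds.data + np.random.default_rng(0).normal(0, 1.0, ds.data.shape)
        )
        corrupted = _gap(_gap(_gap(noisy, 0, 20, 30), 1, 25, 35), 2, 18, 28)
        filled, report = reconstruct_r2(corrupted)
        assert "P0" in report.unfilled
        assert np.isnan(filled.marker("P0")[25]).all()

    def test_unknown_strategy(self, rank3_dataset):
        with pytest.raises(ParameterError):
            fill_gaps(rank3_dataset, "r3")
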