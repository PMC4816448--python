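import numpy as np
import pytest

from mocapfill.dataset import MarkerDataset
from mocapfill.synthetic import GaitModelParams, generate_gait


def exact_rank_dataset(
    n_markers: int = 10, n_frames: int = 300, rank: int = 3, seed: int = 1
) -> MarkerDataset:
    """Noise-free gait-like dataset whose matrix has rank exactly rank+1."""
    return generate_gait(
        GaitModelParams(
            n_markers=n_markers,
            n_frames=n_frames,
            latent_rank=rank,
            noise_sd=0.0,
            seed=seed,
        )
    )


def subspace_completion_oracle(data: np.ndarray) -> np.ndarray:
    """Brute-force least-squares completion on the complete-frame subspace.

    Independent reference for the dual-basis reconstruction: fit the exact
    row subspace of the complete frames, then solve each incomplete row's
    coefficients from its observed coordinates and predict the missing ones.
    """
    complete = data[~np.isnan(data).any(axis=1)]
    mu = complete.mean(axis=0)
    _, s, vt = np.linalg.svd(complete - mu, full_matrices=False)
    r = int((s > s[0] * 1e-9).sum())
    basis = vt[:r].T  # (p, r)
    out = data.copy()
    for i in np.flatnonzero(np.isnan(data).any(axis=1)):
        obs = ~np.isnan(data[i])
        coef, *_ = np.linalg.lstsq(basis[obs], data[i, obs] - mu[obs], rcond=None)
        pred = basis @ coef + mu
        out[i, ~obs] = pred[~obs]
    return out


@pytest.fixture(scope="session")
def rank3_dataset() -> MarkerDataset:
    return exact_rank_dataset(n_markers=10, n_frames=300, rank=3, seed=1)


@pytest.fixture(scope="session")
def small_noisy_dataset() -> MarkerDataset:
    """A small, fast, near-low-rank gait dataset for pipeline tests."""
    return generate_gait(
        GaitModelParams(
            n_markers=8, n_frames=400, frame_rate=120.0, latent_rank=5, seed=7
        )
    )


def constant_dataset(offsets, n_frames: int = 50, frame_rate: float = 100.0):
    """Markers frozen at fixed positions (zero motion); offsets is (m, 3)."""
    offsets = np.asarray(offsets, dtype=float)
    data = np.tile(offsets.reshape(1, -1), (n_frames, 1))
    labels = [f"P{i}" for i in range(offsets.shape[0])]
    return MarkerDataset(data=data, labels=labels, frame_rate=frame_rate)
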