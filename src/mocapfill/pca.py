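"""The dual-PCA reconstruction engine.

Gap filling rests on one linear-algebra step.  Let ``M`` be the ``n x 3m``
measurement matrix with gaps, and ``N`` the ``k x 3m`` sub-matrix of frames
with complete marker information.  Two weighted PCAs are fitted: one on
``N`` (basis ``PC``) and one on ``N_zeros``, a copy of ``N`` in which the
corrupted markers' columns are zeroed (basis ``PC_zeros``).  Because human
gait is highly intercorrelated, both representations are sparse: a small
number of components, selected by a threshold ``theta_lambda`` on the
cumulative sum of normalized singular values, carries the posture
information.  A transition matrix ``T`` maps truncated ``PC_zeros`` scores
to truncated ``PC`` scores (least squares over the shared training frames).
An estimate of the missing coordinates is then

    R = M_zeros @ PC_zeros_trunc @ T @ PC_trunc.T

where ``M_zeros`` is the centered, weighted measurement matrix with gaps
zero-filled, and the truncated-basis transpose plays the role of the basis
inverse.  Only the gap entries of the result are kept; observed samples are
never modified.

Conventions (they matter for exactness):

* centering uses the column means of the complete frames ``N`` and is
  applied to every matrix before weighting and zero-filling; the same means
  are added back at the end;
* weights are applied as column scaling after centering, identically to
  ``N``, ``N_zeros`` and ``M_zeros``, and divided out of ``R`` before
  un-centering, so they cancel exactly on gap-free data;
* the two bases are truncated independently with the same ``theta_lambda``;
* normalized singular values means division by their plain sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .dataset import MarkerDataset
from .exceptions import (
    DegenerateBasisError,
    InsufficientSupportError,
    ParameterError,
)
from .weighting import WeightVector

logger = logging.getLogger(__name__)

__all__ = [
    "PrincipalBasis",
    "BasisPair",
    "extract_complete_frames",
    "fit_basis",
    "transition_matrix",
    "reconstruct_eq1",
    "Eq1Result",
]


@dataclass(frozen=True)
class PrincipalBasis:
    """An orthonormal PC basis of a centered, weighted training matrix.

    ``vectors`` holds all right singular vectors (columns); ``k_retained``
    is the truncation index chosen by the singular-value threshold.
    ``column_means`` are the means of the raw (pre-weighted) training data,
    needed to un-center reconstructions.
    """

    vectors: np.ndarray  # (3m, k_total), orthonormal columns
    singular_values: np.ndarray  # (k_total,), non-increasing
    column_means: np.ndarray  # (3m,)
    k_retained: int

    @property
    def truncated(self) -> np.ndarray:
        return self.vectors[:, : self.k_retained]

    def explained_fraction(self) -> np.ndarray:
        """Cumulative sum of normalized singular values."""
        s = self.singular_values
        return np.cumsum(s) / s.sum()


class BasisPair(NamedTuple):
    """The full and zeroed bases plus the transition matrix between them."""

    full: PrincipalBasis
    zeroed: PrincipalBasis
    transition: np.ndarray  # (k_zeroed, k_full)


class Eq1Result(NamedTuple):
    filled: MarkerDataset
    reconstruction: np.ndarray  # (n, 3m) reconstruction matrix R, in mm
    bases: BasisPair


def extract_complete_frames(
    dataset: MarkerDataset, min_complete: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Rows of ``M`` with no missing marker, in original order.

    Returns ``(N, frame_indices)``.  Raises
    :class:`InsufficientSupportError` when fewer than ``min_complete``
    complete frames exist.
    """
    complete = ~np.isnan(dataset.data).any(axis=1)
    idx = np.flatnonzero(complete)
    if idx.size < min_complete:
        raise InsufficientSupportError(
            f"only {idx.size} complete frames (need >= {min_complete})",
            n_complete=int(idx.size),
        )
    return dataset.data[idx], idx


def _k_retained(s: np.ndarray, theta_lambda: float) -> int:
    """Smallest k whose cumulative normalized singular-value sum reaches
    ``theta_lambda``, never counting numerically-zero singular values."""
    total = s.sum()
    if total <= 0:
        raise DegenerateBasisError("all singular values are zero")
    tol = s[0] * max(s.size, 1) * np.finfo(float).eps
    nnz = int((s > tol).sum())
    frac = np.cumsum(s) / total
    k = int(np.searchsorted(frac, theta_lambda, side="left")) + 1
    return max(1, min(k, nnz))


def fit_basis(
    matrix: np.ndarray, weight_vector: WeightVector, theta_lambda: float
) -> PrincipalBasis:
    """Weighted PCA of a training matrix (complete frames).

    Columns are centered by their means, scaled by the weights, and
    decomposed by SVD.  ``k_retained`` follows the ``theta_lambda`` rule on
    the cumulative sum of normalized singular values.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ParameterError("training matrix needs at least 2 rows")
    w = weight_vector.weights
    if w.size != matrix.shape[1]:
        raise ParameterError("weight vector length does not match column count")
    mu = matrix.mean(axis=0)
    x = (matrix - mu) * w
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        raise DegenerateBasisError("training matrix has no variance")
    k = _k_retained(s, theta_lambda)
    return PrincipalBasis(
        vectors=vt.T, singular_values=s, column_means=mu, k_retained=k
    )


def _scores(matrix: np.ndarray, basis: PrincipalBasis, w: np.ndarray) -> np.ndarray:
    return ((matrix - basis.column_means) * w) @ basis.truncated


def transition_matrix(
    n_full: np.ndarray,
    n_zeros: np.ndarray,
    basis_full: PrincipalBasis,
    basis_zeroed: PrincipalBasis,
    weight_vector: WeightVector,
) -> np.ndarray:
    """Least-squares map from zeroed-basis scores to full-basis scores.

    Both matrices must contain the same frames in the same order.  The map
    minimizes ``|| S_zeros @ T - S_full ||_F`` over the training frames; a
    rank-deficient score matrix falls back to the pseudoinverse solution
    (with a logged warning).
    """
    if n_full.shape != n_zeros.shape:
        raise ParameterError("N and N_zeros must have identical shape")
    w = weight_vector.weights
    s_full = _scores(n_full, basis_full, w)
    s_zeros = _scores(n_zeros, basis_zeroed, w)
    t, _, rank, sv = np.linalg.lstsq(s_zeros, s_full, rcond=None)
    if rank < s_zeros.shape[1]:
        cond = sv[0] / sv[rank - 1] if rank > 0 else np.inf
        logger.warning(
            "zeroed score matrix is rank deficient (rank %d of %d, cond %.3g); "
            "using pseudoinverse solution",
            rank,
            s_zeros.shape[1],
            cond,
        )
    return t


def reconstruct_eq1(
    dataset: MarkerDataset,
    targets,
    weight_vector: WeightVector,
    theta_lambda: float,
    min_complete: int = 10,
) -> Eq1Result:
    """One pass of the dual-basis reconstruction.

    ``targets`` are the marker indices (or labels) whose columns are zeroed
    in the training copy and whose gaps are filled from the reconstruction
    matrix.  Observed samples pass through untouched; a gap-free dataset is
    returned unchanged.
    """
    targets = sorted({dataset.marker_index(t) for t in targets})
    if not dataset.has_gaps:
        return Eq1Result(dataset.copy(), dataset.data.copy(), None)
    if not targets:
        raise ParameterError("no target markers given")

    n_mat, _ = extract_complete_frames(dataset, min_complete=min_complete)
    target_cols = np.concatenate([np.arange(3 * j, 3 * j + 3) for j in targets])

    n_zeros = n_mat.copy()
    n_zeros[:, target_cols] = 0.0

    basis_full = fit_basis(n_mat, weight_vector, theta_lambda)
    basis_zeroed = fit_basis(n_zeros, weight_vector, theta_lambda)
    t = transition_matrix(n_mat, n_zeros, basis_full, basis_zeroed, weight_vector)

    w = weight_vector.weights
    mu = basis_full.column_means
    m_centered = dataset.data - mu
    m_zeros = np.nan_to_num(m_centered * w, nan=0.0)
    # the zeroed basis centers its (all-zero) target columns to zero, so
    # projecting the centered, weighted, zero-filled rows is consistent with
    # the training scores used to fit T
    s = m_zeros @ basis_zeroed.truncated
    r_weighted = s @ t @ basis_full.truncated.T
    r = r_weighted / w + mu

    filled = dataset.data.copy()
    gap = np.isnan(dataset.data)
    in_targets = np.zeros(dataset.data.shape[1], dtype=bool)
    in_targets[target_cols] = True
    gap &= in_targets  # only the targets' gaps are filled in this pass
    filled[gap] = r[gap]
    return Eq1Result(
        dataset.with_data(filled), r, BasisPair(basis_full, basis_zeroed, t)
    )
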