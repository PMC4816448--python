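"""Gaussian distance weighting of marker coordinates.

Markers close to the marker being reconstructed carry most of the usable
correlation information, so their coordinate columns are up-weighted before
the principal-component decomposition.  The weight of marker ``j`` relative
to a reconstruction target ``i`` is a Gaussian in their time-averaged
Euclidean distance,

    w_j = exp(-d_ij^2 / (2 sigma^2)),

where ``d_ij`` averages over exactly the frames in which both markers are
observed.  The target marker's own columns get the small constant ``w_mm``:
its observed samples must participate (otherwise the zeroed and full bases
coincide and the reconstruction collapses) but must not dominate the basis.
With several targets, a non-target marker takes the largest weight over all
targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataset import MarkerDataset
from .exceptions import NoCommonSupportError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "ReconstructionParams",
    "WeightVector",
    "mean_marker_distance",
    "gaussian_weight",
    "build_weight_vector",
]

#: weight given to markers whose distance to every target is unknown
#: (no shared frames); strictly positive so the weighted matrix keeps
#: well-defined columns, small enough to exclude them in practice
ORPHAN_WEIGHT = 1e-6


@dataclass(frozen=True)
class ReconstructionParams:
    """The four tunable parameters of the reconstruction algorithm.

    Attributes
    ----------
    w_mm : float in (0, 1]
        Weight on the missing marker's own coordinate columns.  Must be
        non-zero: with ``w_mm = 0`` the zeroed and full PC bases are
        identical and the gap columns can never be recovered.
    sigma : float, mm
        Length scale of the Gaussian neighbour weighting.
    theta_lambda : float in (0, 1]
        Threshold on the cumulative sum of normalized singular values that
        selects how many PC vectors to retain.
    theta_d : float >= 0
        Relative distance cutoff of the consecutive (R2) strategy: a
        corrupted neighbour farther than ``theta_d`` times the target's mean
        distance to all markers is dropped from the analysis.
    min_complete_frames : int
        Minimum number of complete frames required to fit the PC bases.
    """

    w_mm: float = 0.02
    sigma: float = 200.0
    theta_lambda: float = 0.99
    theta_d: float = 0.5
    min_complete_frames: int = 10

    def __post_init__(self):
        if not 0.0 < self.w_mm <= 1.0:
            raise ParameterError(
                "w_mm must be in (0, 1]; zero would make the zeroed and full "
                "PC bases identical"
            )
        if not self.sigma > 0:
            raise ParameterError("sigma must be a positive length in mm")
        if not 0.0 < self.theta_lambda <= 1.0:
            raise ParameterError("theta_lambda must be in (0, 1]")
        if self.theta_d < 0:
            raise ParameterError("theta_d must be >= 0")
        if self.min_complete_frames < 2:
            raise ParameterError("min_complete_frames must be at least 2")


@dataclass(frozen=True)
class WeightVector:
    """Per-coordinate weights, constant within each marker's X,Y,Z triple."""

    weights: np.ndarray  # (3m,)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1 or w.size % 3:
            raise ParameterError("weight vector length must be a multiple of 3")
        if not ((w > 0) & (w <= 1)).all():
            raise ParameterError("weights must lie in (0, 1]")
        tri = w.reshape(-1, 3)
        if not (tri == tri[:, :1]).all():
            raise ParameterError("the three columns of a marker must share one weight")

    @property
    def per_marker(self) -> np.ndarray:
        return self.weights[::3]


def mean_marker_distance(dataset: MarkerDataset, i: int | str, j: int | str) -> float:
    """Time-averaged Euclidean distance between two markers, in mm.

    Averages over exactly the frames in which both markers are observed.
    """
    i = dataset.marker_index(i)
    j = dataset.marker_index(j)
    if i == j:
        raise ParameterError("distance of a marker to itself is not defined")
    a = dataset.marker(i)
    b = dataset.marker(j)
    both = ~(np.isnan(a[:, 0]) | np.isnan(b[:, 0]))
    if not both.any():
        raise NoCommonSupportError(
            f"markers {dataset.labels[i]!r} and {dataset.labels[j]!r} share no frames"
        )
    return float(np.linalg.norm(a[both] - b[both], axis=1).mean())


def gaussian_weight(d: float, sigma: float):
    """The Gaussian weight exp(-d^2 / (2 sigma^2)) for a distance d >= 0."""
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ParameterError("distances are non-negative")
    out = np.exp(-(d**2) / (2.0 * sigma**2))
    return float(out) if out.ndim == 0 else out


def build_weight_vector(
    dataset: MarkerDataset, targets, params: ReconstructionParams
) -> WeightVector:
    """Coordinate weights for reconstructing the given target markers.

    Each non-target marker receives the largest Gaussian weight over all
    targets; target markers receive ``w_mm``.  Distances are computed from
    the dataset as given (the original, corrupted data), never from
    reconstructed values.  A marker with no shared frames with any target is
    effectively excluded via a tiny positive weight.
    """
    targets = {dataset.marker_index(t) for t in targets}
    if not targets:
        raise ParameterError("at least one target marker is required")
    m = dataset.n_markers
    w = np.empty(m)
    for j in range(m):
        if j in targets:
            w[j] = params.w_mm
            continue
        best = None
        for i in targets:
            try:
                d = mean_marker_distance(dataset, i, j)
            except NoCommonSupportError:
                continue
            g = gaussian_weight(d, params.sigma)
            best = g if best is None else max(best, g)
        if best is None:
            logger.warning(
                "marker %r shares no frames with any target; assigned weight %g",
                dataset.labels[j],
                ORPHAN_WEIGHT,
            )
            best = ORPHAN_WEIGHT
        # far markers can underflow exp() to exactly 0; keep them positive
        w[j] = max(best, ORPHAN_WEIGHT)
    return WeightVector(weights=np.repeat(w, 3))
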