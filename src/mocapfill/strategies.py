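"""Multi-gap reconstruction strategies.

Two drivers handle datasets with gaps in several markers:

* **R1 (simultaneous)** — one pass of the dual-basis reconstruction with
  every corrupted marker zeroed in the training copy.  The training matrix
  is restricted to frames without any gap, and each complete marker's weight
  is the largest Gaussian weight over all corrupted markers.  Simple, but
  frames that are only partly complete are discarded, and the weights are a
  compromise across all targets.

* **R2 (consecutive)** — each corrupted marker is reconstructed on its own
  from the original corrupted data.  For target marker ``i``, any other
  corrupted marker ``h`` is either omitted entirely or its gap frames are
  dropped: ``h`` is omitted when its mean distance to ``i`` exceeds
  ``theta_d`` times ``D_i`` (the mean distance from ``i`` to all other
  markers), when its gaps overlap in time with the target's (its zeroed gap
  frames would corrupt the training rows), or when the two markers share no
  observed frames.  Otherwise ``h`` stays and its gap frames are removed,
  so the training matrix keeps rows R1 would discard.

Reconstructed values of one marker are never fed into the reconstruction of
another; every marker works from the original data, which makes the R2
result independent of the processing order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dataset import MarkerDataset
from .exceptions import InsufficientSupportError, NoCommonSupportError, ParameterError
from .pca import reconstruct_eq1
from .weighting import ReconstructionParams, build_weight_vector, mean_marker_distance

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborDecision",
    "FillReport",
    "reconstruct_r1",
    "reconstruct_r2",
    "select_neighbors_r2",
    "fill_gaps",
]


@dataclass(frozen=True)
class NeighborDecision:
    """Which markers and frames take part in one R2 reconstruction."""

    target: int
    included_markers: frozenset[int]
    dropped_frames: frozenset[int]
    omitted_markers: dict[int, str]  # index -> reason
    mean_distance: float  # D_i, mm

    def __post_init__(self):
        if self.included_markers & set(self.omitted_markers):
            raise ParameterError("included and omitted marker sets overlap")


@dataclass
class FillReport:
    """Summary of one gap-filling run."""

    strategy: str
    params: ReconstructionParams | None
    gap_counts: dict[str, int] = field(default_factory=dict)
    unfilled: dict[str, str] = field(default_factory=dict)
    decisions: dict[str, NeighborDecision] = field(default_factory=dict)

    @property
    def n_gap_frames(self) -> int:
        return sum(self.gap_counts.values())

    @property
    def complete_success(self) -> bool:
        return not self.unfilled


def _gap_counts(dataset: MarkerDataset) -> dict[str, int]:
    mask = dataset.gap_mask.missing
    return {
        dataset.labels[j]: int(mask[:, j].sum())
        for j in range(dataset.n_markers)
        if mask[:, j].any()
    }


def reconstruct_r1(
    dataset: MarkerDataset, params: ReconstructionParams | None = None
) -> tuple[MarkerDataset, FillReport]:
    """Simultaneous reconstruction of all corrupted markers in one pass."""
    params = params or ReconstructionParams()
    report = FillReport(strategy="r1", params=params, gap_counts=_gap_counts(dataset))
    gapped = dataset.gap_mask.gapped_markers()
    if not gapped:
        logger.info("no gaps found; returning dataset unchanged")
        return dataset.copy(), report
    weights = build_weight_vector(dataset, gapped, params)
    result = reconstruct_eq1(
        dataset,
        gapped,
        weights,
        params.theta_lambda,
        min_complete=params.min_complete_frames,
    )
    return result.filled, report


def select_neighbors_r2(
    dataset: MarkerDataset, target_marker: int | str, params: ReconstructionParams
) -> NeighborDecision:
    """Apply the theta_d / temporal-overlap rules for one target marker."""
    i = dataset.marker_index(target_marker)
    mask = dataset.gap_mask
    if not mask.missing[:, i].any():
        raise ParameterError(
            f"marker {dataset.labels[i]!r} has no gaps; nothing to decide"
        )
    target_gaps = set(mask.frames_of(i).tolist())

    distances: dict[int, float] = {}
    for j in range(dataset.n_markers):
        if j == i:
            continue
        try:
            distances[j] = mean_marker_distance(dataset, i, j)
        except NoCommonSupportError:
            pass
    if not distances:
        raise InsufficientSupportError(
            f"marker {dataset.labels[i]!r} shares no frames with any other marker"
        )
    d_i = float(np.mean(list(distances.values())))
    cutoff = params.theta_d * d_i

    included: set[int] = set()
    omitted: dict[int, str] = {}
    dropped: set[int] = set()
    for j in range(dataset.n_markers):
        if j == i:
            continue
        j_gaps = mask.frames_of(j)
        if j_gaps.size == 0:
            included.add(j)  # complete markers always participate
            continue
        if j not in distances:
            omitted[j] = "no-common-support"
        elif target_gaps & set(j_gaps.tolist()):
            omitted[j] = "temporal-overlap"
        elif distances[j] > cutoff:
            omitted[j] = "beyond-theta-d"
        else:
            included.add(j)
            dropped.update(j_gaps.tolist())
    if not included:
        raise InsufficientSupportError(
            f"every neighbour of marker {dataset.labels[i]!r} was omitted"
        )
    return NeighborDecision(
        target=i,
        included_markers=frozenset(included),
        dropped_frames=frozenset(dropped),
        omitted_markers=omitted,
        mean_distance=d_i,
    )


def reconstruct_r2(
    dataset: MarkerDataset, params: ReconstructionParams | None = None
) -> tuple[MarkerDataset, FillReport]:
    """Consecutive per-marker reconstruction with neighbour selection.

    Markers that cannot be reconstructed (all neighbours omitted, or too few
    complete frames in their reduced dataset) are reported in
    ``report.unfilled`` and left as gaps; the run is a partial success, not
    a failure.
    """
    params = params or ReconstructionParams()
    report = FillReport(strategy="r2", params=params, gap_counts=_gap_counts(dataset))
    gapped = dataset.gap_mask.gapped_markers()
    if not gapped:
        logger.info("no gaps found; returning dataset unchanged")
        return dataset.copy(), report

    out = dataset.data.copy()
    for i in gapped:
        label = dataset.labels[i]
        try:
            decision = select_neighbors_r2(dataset, i, params)
            keep_markers = sorted(decision.included_markers | {i})
            keep_frames = np.setdiff1d(
                np.arange(dataset.n_frames), sorted(decision.dropped_frames)
            )
            reduced = dataset.select_markers(keep_markers).select_frames(keep_frames)
            pos = keep_markers.index(i)
            weights = build_weight_vector(reduced, [pos], params)
            result = reconstruct_eq1(
                reduced,
                [pos],
                weights,
                params.theta_lambda,
                min_complete=params.min_complete_frames,
            )
        except InsufficientSupportError as exc:
            logger.warning("marker %r left unfilled: %s", label, exc)
            report.unfilled[label] = str(exc)
            continue
        else:
            report.decisions[label] = decision
            # overlap omission guarantees the target's gap frames survive the
            # frame drop, so every gap maps into the reduced dataset
            gap_frames = dataset.gap_mask.frames_of(i)
            red_rows = np.searchsorted(keep_frames, gap_frames)
            out[np.ix_(gap_frames, range(3 * i, 3 * i + 3))] = result.filled.data[
                np.ix_(red_rows, range(3 * pos, 3 * pos + 3))
            ]
    return dataset.with_data(out), report


_STRATEGIES = {"r1": reconstruct_r1, "r2": reconstruct_r2}


def fill_gaps(
    dataset: MarkerDataset,
    strategy: str = "r2",
    params: ReconstructionParams | None = None,
) -> tuple[MarkerDataset, FillReport]:
    """Fill gaps with one of the available methods.

    ``strategy`` is one of ``r1``, ``r2`` (dual-basis reconstruction),
    ``spline`` or ``linear`` (conventional per-coordinate interpolation).
    """
    from . import baselines

    strategy = strategy.lower()
    if strategy in _STRATEGIES:
        return _STRATEGIES[strategy](dataset, params)
    if strategy == "spline":
        filled = baselines.fill_spline(dataset)
    elif strategy == "linear":
        filled = baselines.fill_linear(dataset)
    else:
        raise ParameterError(
            f"unknown strategy {strategy!r}; choose r1, r2, spline or linear"
        )
    report = FillReport(
        strategy=strategy, params=None, gap_counts=_gap_counts(dataset)
    )
    return filled, report
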