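"""In-memory representation of marker trajectory data.

A motion-capture trial with ``m`` markers sampled over ``n`` frames is stored
as an ``n x 3m`` measurement matrix: the three Cartesian coordinates of each
marker are adjacent columns, in X, Y, Z order, in millimetres.  A marker is
either fully observed or fully missing at a frame; missing marker-frames are
encoded as NaN in all three coordinate columns.  Zeros are legal coordinates,
never gaps (file readers that use zero-filling or flags to mark invalid
points translate those to NaN on input).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ParameterError

logger = logging.getLogger(__name__)

__all__ = ["MarkerDataset", "GapMask"]


@dataclass
class MarkerDataset:
    """An ``n x 3m`` marker measurement matrix with metadata.

    Parameters
    ----------
    data : ndarray of shape (n_frames, 3 * n_markers)
        Coordinates in mm; NaN encodes a missing marker-frame.  If only one
        or two of a marker's coordinates are NaN at a frame, the whole
        marker-frame is demoted to missing (with a logged warning): gaps are
        per-marker events, never per-axis.
    labels : sequence of str
        One unique name per marker.
    frame_rate : float
        Sampling rate in Hz.
    units : str
        Unit tag; "mm" is canonical and assumed by the default weighting
        scale.
    """

    data: np.ndarray
    labels: list[str]
    frame_rate: float = 100.0
    units: str = "mm"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = list(self.labels)
        if self.data.ndim != 2:
            raise ParameterError("data must be a 2-D (frames x coordinates) array")
        n, p = self.data.shape
        if p % 3 != 0:
            raise ParameterError(
                f"coordinate count {p} is not a multiple of 3; columns must "
                "come in X,Y,Z triples"
            )
        m = p // 3
        if n < 1:
            raise ParameterError("dataset needs at least one frame")
        if m < 2:
            raise ParameterError("dataset needs at least two markers")
        if len(self.labels) != m:
            raise ParameterError(
                f"{len(self.labels)} labels for {m} markers"
            )
        if len(set(self.labels)) != m:
            raise ParameterError("marker labels must be unique")
        if not self.frame_rate > 0:
            raise ParameterError("frame_rate must be positive")
        self._demote_partial_gaps()

    def _demote_partial_gaps(self) -> None:
        """Force per-axis NaNs to whole-marker NaNs."""
        tri = np.isnan(self.data).reshape(self.n_frames, self.n_markers, 3)
        n_missing = tri.sum(axis=2)
        partial = (n_missing > 0) & (n_missing < 3)
        if partial.any():
            logger.warning(
                "%d marker-frames had 1-2 missing coordinates; demoted to "
                "fully missing",
                int(partial.sum()),
            )
            any_missing = n_missing > 0
            mask3 = np.repeat(any_missing, 3, axis=1)
            self.data[mask3] = np.nan

    # ------------------------------------------------------------------
    # basic geometry
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_markers(self) -> int:
        return self.data.shape[1] // 3

    def marker_columns(self, j: int) -> slice:
        """Column slice of marker ``j`` (X, Y, Z)."""
        return slice(3 * j, 3 * j + 3)

    def marker(self, key: int | str) -> np.ndarray:
        """The (n, 3) trajectory of one marker (a view into ``data``)."""
        j = self.marker_index(key)
        return self.data[:, 3 * j : 3 * j + 3]

    def marker_index(self, key: int | str) -> int:
        if isinstance(key, str):
            try:
                return self.labels.index(key)
            except ValueError:
                raise KeyError(f"unknown marker label {key!r}") from None
        j = int(key)
        if not 0 <= j < self.n_markers:
            raise KeyError(f"marker index {j} out of range")
        return j

    # ------------------------------------------------------------------
    # gaps
    @property
    def gap_mask(self) -> "GapMask":
        return GapMask.from_dataset(self)

    @property
    def has_gaps(self) -> bool:
        return bool(np.isnan(self.data).any())

    # ------------------------------------------------------------------
    # derived datasets
    def copy(self) -> "MarkerDataset":
        return replace(self, data=self.data.copy(), labels=list(self.labels))

    def with_data(self, data: np.ndarray) -> "MarkerDataset":
        return replace(self, data=np.asarray(data, dtype=float))

    def select_markers(self, indices) -> "MarkerDataset":
        """Sub-dataset keeping only the given markers, in the given order."""
        indices = [self.marker_index(i) for i in indices]
        cols = np.concatenate([np.arange(3 * j, 3 * j + 3) for j in indices])
        return replace(
            self,
            data=self.data[:, cols].copy(),
            labels=[self.labels[j] for j in indices],
        )

    def select_frames(self, indices) -> "MarkerDataset":
        indices = np.asarray(indices, dtype=int)
        return replace(self, data=self.data[indices].copy(), labels=list(self.labels))

    def translate(self, offset) -> "MarkerDataset":
        """Rigid translation of every marker by an (3,) offset in mm."""
        offset = np.asarray(offset, dtype=float).reshape(3)
        return self.with_data(self.data + np.tile(offset, self.n_markers))

    # ------------------------------------------------------------------
    # pandas interop
    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{lab}_{ax}" for lab in self.labels for ax in "XYZ"]
        return pd.DataFrame(self.data, columns=cols)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, frame_rate: float = 100.0, units: str = "mm"
    ) -> "MarkerDataset":
        """Build a dataset from a frame-by-coordinate DataFrame.

        Columns must follow the ``<label>_X``, ``<label>_Y``, ``<label>_Z``
        naming convention, in complete triples.
        """
        labels = _labels_from_columns(list(df.columns))
        return cls(
            data=df.to_numpy(dtype=float),
            labels=labels,
            frame_rate=frame_rate,
            units=units,
        )


def _labels_from_columns(columns: list[str]) -> list[str]:
    from .exceptions import FormatError

    if len(columns) % 3 != 0:
        raise FormatError(f"{len(columns)} coordinate columns; expected triples")
    labels = []
    for i in range(0, len(columns), 3):
        triple = columns[i : i + 3]
        stems = set()
        for name, ax in zip(triple, "XYZ"):
            if not name.endswith(f"_{ax}"):
                raise FormatError(
                    f"column {name!r} does not follow the <label>_{ax} pattern "
                    f"(offending label group: {triple})"
                )
            stems.add(name[:-2])
        if len(stems) != 1:
            raise FormatError(f"columns {triple} do not share one marker label")
        labels.append(stems.pop())
    return labels


@dataclass
class GapMask:
    """Boolean n x m indicator of missing marker-frames (True = absent)."""

    missing: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.ndim != 2:
            raise ParameterError("gap mask must be 2-D (frames x markers)")

    @classmethod
    def from_dataset(cls, dataset: MarkerDataset) -> "GapMask":
        tri = np.isnan(dataset.data).reshape(
            dataset.n_frames, dataset.n_markers, 3
        )
        return cls(missing=tri.any(axis=2))

    @property
    def n_missing(self) -> int:
        return int(self.missing.sum())

    def coordinate_mask(self) -> np.ndarray:
        """Expand to the n x 3m coordinate grid."""
        return np.repeat(self.missing, 3, axis=1)

    def gapped_markers(self) -> list[int]:
        """Indices of markers with at least one missing frame."""
        return list(np.flatnonzero(self.missing.any(axis=0)))

    def frames_of(self, j: int) -> np.ndarray:
        """Frame indices where marker ``j`` is missing."""
        return np.flatnonzero(self.missing[:, j])
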