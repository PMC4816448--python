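"""Readers and writers for marker trajectory files.

Supported containers:

* **CSV** — one header row of ``<label>_X, <label>_Y, <label>_Z`` columns,
  one row per frame, missing values as empty cells or ``NaN``; the frame
  rate travels in a ``# frame_rate=<Hz>`` comment line.
* **TRC** — tab-separated Motion Analysis / OpenSim convention with the
  DataRate header block; blank fields are gaps.
* **C3D** — via the bundled minimal codec (:mod:`mocapfill._c3d`); invalid
  points (negative residual or zero-filled) become gaps.
* **study container** — MATLAB ``.mat`` files holding the measurement matrix
  in an array named ``Data`` (v5 via scipy, v7.3 via HDF5); the frame rate
  is not stored in the container and must be supplied by the caller.

All readers return mm-unit :class:`~mocapfill.dataset.MarkerDataset` objects;
declared m/cm units are converted.
"""

from __future__ import annotations

import io as _stdio
import logging
import re
from pathlib import Path

import numpy as np

from . import _c3d
from .dataset import MarkerDataset, _labels_from_columns
from .exceptions import FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "read_csv",
    "write_csv",
    "read_trc",
    "write_trc",
    "read_c3d",
    "write_c3d",
    "read_study_dataset",
    "read_any",
]

_UNIT_TO_MM = {"mm": 1.0, "cm": 10.0, "m": 1000.0}


def _to_mm(data: np.ndarray, units: str) -> np.ndarray:
    units = units.strip().lower()
    if units not in _UNIT_TO_MM:
        raise FormatError(f"unsupported distance unit {units!r}")
    return data * _UNIT_TO_MM[units]


# ----------------------------------------------------------------------
# CSV

def read_csv(path, frame_rate: float | None = None, units: str = "mm") -> MarkerDataset:
    """Read the plain-CSV trajectory table.

    ``frame_rate`` overrides the ``# frame_rate=`` comment; if neither is
    given, 100 Hz is assumed.  ``units`` declares the file's unit for
    unlabeled data (converted to mm).
    """
    path = Path(path)
    file_rate = None
    header = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                m = re.search(r"frame_rate\s*=\s*([0-9.eE+-]+)", line)
                if m:
                    file_rate = float(m.group(1))
                continue
            cells = [c.strip() for c in line.split(",")]
            if header is None:
                header = cells
                continue
            if len(cells) != len(header):
                raise FormatError(
                    f"row {lineno}: {len(cells)} cells, header has {len(header)}"
                )
            rows.append(
                [np.nan if c == "" or c.lower() == "nan" else float(c) for c in cells]
            )
    if header is None:
        raise FormatError(f"{path}: no header row")
    labels = _labels_from_columns(header)
    data = np.array(rows, dtype=float).reshape(len(rows), len(header))
    rate = frame_rate if frame_rate is not None else (file_rate or 100.0)
    return MarkerDataset(
        data=_to_mm(data, units), labels=labels, frame_rate=rate, units="mm"
    )


def write_csv(dataset: MarkerDataset, path) -> None:
    """Write the CSV dialect read by :func:`read_csv` (missing = empty cell)."""
    buf = _stdio.StringIO()
    buf.write(f"# frame_rate={dataset.frame_rate:g}\n")
    buf.write(",".join(f"{lab}_{ax}" for lab in dataset.labels for ax in "XYZ"))
    buf.write("\n")
    for row in dataset.data:
        buf.write(",".join("" if np.isnan(v) else f"{v:.10g}" for v in row))
        buf.write("\n")
    Path(path).write_text(buf.getvalue())


# ----------------------------------------------------------------------
# TRC

def read_trc(path) -> MarkerDataset:
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 5:
        raise FormatError(f"{path}: too short for a TRC file")
    keys = lines[1].split("\t")
    vals = lines[2].split("\t")
    hdr = dict(zip(keys, vals))
    try:
        rate = float(hdr["DataRate"])
        n_markers = int(hdr["NumMarkers"])
        units = hdr.get("Units", "mm")
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: malformed TRC header block: {exc}") from exc
    label_cells = lines[3].split("\t")
    labels = [c for c in label_cells[2:] if c.strip()]
    if len(labels) != n_markers:
        raise FormatError(
            f"{path}: header declares {n_markers} markers, found {len(labels)} labels"
        )
    rows = []
    for line in lines[4:]:
        cells = line.split("\t")
        if not cells or not cells[0].strip().isdigit():
            continue  # skips the X1/Y1/Z1 sub-header and blank separator lines
        coords = cells[2 : 2 + 3 * n_markers]
        coords += [""] * (3 * n_markers - len(coords))
        rows.append([np.nan if c.strip() == "" else float(c) for c in coords])
    if not rows:
        raise FormatError(f"{path}: no data rows")
    data = np.array(rows, dtype=float)
    return MarkerDataset(
        data=_to_mm(data, units), labels=labels, frame_rate=rate, units="mm"
    )


def write_trc(dataset: MarkerDataset, path) -> None:
    m = dataset.n_markers
    rate = dataset.frame_rate
    n = dataset.n_frames
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{Path(path).name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
        "OrigDataStartFrame\tOrigNumFrames",
        f"{rate:g}\t{rate:g}\t{n}\t{m}\tmm\t{rate:g}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(dataset.labels) + "\t\t",
        "\t\t"
        + "\t".join(f"X{j + 1}\tY{j + 1}\tZ{j + 1}" for j in range(m)),
        "",
    ]
    for i, row in enumerate(dataset.data):
        cells = [str(i + 1), f"{i / rate:.6f}"]
        cells += ["" if np.isnan(v) else f"{v:.6f}" for v in row]
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# C3D

def read_c3d(path) -> MarkerDataset:
    xyz, labels, rate, units = _c3d.read(path)
    n = xyz.shape[0]
    data = xyz.reshape(n, -1)
    return MarkerDataset(
        data=_to_mm(data, units), labels=labels, frame_rate=rate, units="mm"
    )


def write_c3d(dataset: MarkerDataset, path) -> None:
    pts = dataset.data.reshape(dataset.n_frames, dataset.n_markers, 3)
    _c3d.write(path, pts, dataset.labels, dataset.frame_rate, units="mm")


# ----------------------------------------------------------------------
# study container (.mat with array "Data")

def read_study_dataset(path, frame_rate: float, labels=None) -> MarkerDataset:
    """Read a MATLAB container holding the measurement matrix in ``Data``.

    The container does not store the sampling rate, so ``frame_rate`` is
    required (e.g. 240 for a treadmill-walk trial captured at 240 Hz).
    Labels default to ``M1..Mm``.
    """
    path = Path(path)
    arr = _load_mat_array(path, "Data")
    if arr is None:
        raise FormatError(f"{path}: no array 'Data' in container")
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise FormatError(f"{path}: 'Data' must be 2-D, got shape {arr.shape}")
    if arr.shape[1] % 3 != 0:
        raise FormatError(
            f"{path}: 'Data' has {arr.shape[1]} columns; expected a multiple of 3"
        )
    m = arr.shape[1] // 3
    if labels is None:
        labels = [f"M{i + 1}" for i in range(m)]
    return MarkerDataset(data=arr, labels=labels, frame_rate=frame_rate, units="mm")


def _load_mat_array(path: Path, name: str):
    try:
        from scipy.io import loadmat

        mat = loadmat(path)
        return mat.get(name)
    except (NotImplementedError, ValueError):
        # MATLAB v7.3 containers are HDF5 files that scipy cannot parse
        import h5py

        try:
            with h5py.File(path, "r") as fh:
                if name not in fh:
                    return None
                # MATLAB stores matrices transposed in HDF5
                return np.array(fh[name]).T
        except OSError as exc:
            raise FormatError(f"{path}: not a readable MATLAB container: {exc}")


# ----------------------------------------------------------------------
# dispatch

def read_any(path, fmt: str | None = None, frame_rate: float | None = None) -> MarkerDataset:
    """Read a trajectory file, inferring the format from the suffix.

    ``fmt`` forces one of ``csv``, ``trc``, ``c3d``, ``study``.
    """
    path = Path(path)
    fmt = fmt or {
        ".csv": "csv",
        ".tsv": "csv",
        ".trc": "trc",
        ".c3d": "c3d",
        ".mat": "study",
    }.get(path.suffix.lower())
    if fmt == "csv":
        return read_csv(path, frame_rate=frame_rate)
    if fmt == "trc":
        return read_trc(path)
    if fmt == "c3d":
        return read_c3d(path)
    if fmt == "study":
        if frame_rate is None:
            raise FormatError("study containers require an explicit frame rate")
        return read_study_dataset(path, frame_rate=frame_rate)
    raise FormatError(f"cannot infer format of {path}")
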