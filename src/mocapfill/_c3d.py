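"""Minimal C3D container support.

Implements the subset of the C3D standard needed for marker trajectories:
Intel (little-endian) byte order, floating-point or scaled-integer 3D point
data, and the POINT parameter group (USED, FRAMES, RATE, SCALE, UNITS,
LABELS, DATA_START).  Analog channels are skipped on read and never written.
Points flagged invalid (negative residual) or zero-filled are returned as
missing.

The writer always emits little-endian float data with residual 0 for valid
points and -1 for missing ones.
"""

from __future__ import annotations

import struct

import numpy as np

from .exceptions import FormatError

_INTEL = 84  # processor type byte: 83 + 1


# ----------------------------------------------------------------------
# reading

def _read_params(blob: bytes):
    """Walk the parameter section; return {(GROUP, PARAM): value}."""
    groups: dict[int, str] = {}
    raw_params: list[tuple[int, str, int, list[int], bytes]] = []
    pos = 0
    while pos < len(blob):
        nname = struct.unpack_from("b", blob, pos)[0]
        if nname == 0:
            break
        gid = struct.unpack_from("b", blob, pos + 1)[0]
        nchars = abs(nname)  # negative length marks a locked entry
        name = blob[pos + 2 : pos + 2 + nchars].decode("ascii", "replace").strip()
        ptr_pos = pos + 2 + nchars
        offset = struct.unpack_from("<h", blob, ptr_pos)[0]
        if gid < 0:  # group record
            groups[-gid] = name.upper()
        else:  # parameter record
            p = ptr_pos + 2
            dtype = struct.unpack_from("b", blob, p)[0]
            ndims = struct.unpack_from("B", blob, p + 1)[0]
            dims = [
                struct.unpack_from("B", blob, p + 2 + i)[0] for i in range(ndims)
            ]
            dstart = p + 2 + ndims
            count = int(np.prod(dims)) if dims else 1
            nbytes = count * abs(dtype)
            raw_params.append((gid, name.upper(), dtype, dims, blob[dstart : dstart + nbytes]))
        if offset == 0:
            break
        pos = ptr_pos + offset
    out = {}
    for gid, name, dtype, dims, data in raw_params:
        key = (groups.get(gid, str(gid)), name)
        if dtype == -1:
            if len(dims) <= 1:
                out[key] = data.decode("ascii", "replace")
            else:  # char array: first dim is string length
                slen = dims[0]
                n = int(np.prod(dims[1:]))
                out[key] = [
                    data[i * slen : (i + 1) * slen].decode("ascii", "replace").strip()
                    for i in range(n)
                ]
        elif dtype == 1:
            out[key] = np.frombuffer(data, dtype=np.int8).reshape(dims[::-1] or (1,))
        elif dtype == 2:
            out[key] = np.frombuffer(data, dtype="<i2").reshape(dims[::-1] or (1,))
        elif dtype == 4:
            out[key] = np.frombuffer(data, dtype="<f4").reshape(dims[::-1] or (1,))
        else:
            raise FormatError(f"unknown C3D parameter type {dtype}")
    return out


def read(path):
    """Read a C3D file.

    Returns ``(points, labels, frame_rate, units)`` where ``points`` is an
    (n_frames, n_markers, 3) float array with NaN for invalid points and
    ``units`` is the declared distance unit string.
    """
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 512:
        raise FormatError("file too short to be a C3D container")
    param_block, magic = struct.unpack_from("<BB", buf, 0)
    if magic != 0x50:
        raise FormatError("not a C3D file (bad magic byte)")
    npoints, analog_per_frame, first, last = struct.unpack_from("<4H", buf, 2)
    data_start_block = struct.unpack_from("<H", buf, 16)[0]

    poff = (param_block - 1) * 512
    proc = buf[poff + 3]
    if proc != _INTEL:
        raise FormatError(f"unsupported C3D processor type {proc} (Intel only)")
    scale = struct.unpack_from("<f", buf, 12)[0]
    frame_rate = struct.unpack_from("<f", buf, 20)[0]

    params = _read_params(buf[poff + 4 :])
    if ("POINT", "SCALE") in params:
        scale = float(np.ravel(params[("POINT", "SCALE")])[0])
    if ("POINT", "RATE") in params:
        frame_rate = float(np.ravel(params[("POINT", "RATE")])[0])
    if ("POINT", "DATA_START") in params:
        data_start_block = int(np.ravel(params[("POINT", "DATA_START")])[0])
    units = params.get(("POINT", "UNITS"), "mm")
    if isinstance(units, list):
        units = units[0] if units else "mm"
    units = units.strip() or "mm"
    labels = params.get(("POINT", "LABELS"))

    n_frames = last - first + 1
    is_float = scale < 0
    word = 4 if is_float else 2
    frame_words = 4 * npoints + analog_per_frame
    doff = (data_start_block - 1) * 512
    need = doff + n_frames * frame_words * word
    if need > len(buf):
        raise FormatError("truncated C3D data section")
    raw = np.frombuffer(
        buf, dtype="<f4" if is_float else "<i2", count=n_frames * frame_words, offset=doff
    ).reshape(n_frames, frame_words).astype(float)
    pts = raw[:, : 4 * npoints].reshape(n_frames, npoints, 4)
    xyz = pts[:, :, :3].copy()
    residual = pts[:, :, 3]
    if not is_float:
        xyz *= abs(scale)
    invalid = (residual < 0) | (np.abs(pts[:, :, :3]).sum(axis=2) == 0)
    xyz[invalid] = np.nan
    if not labels or len(labels) < npoints:
        labels = [f"M{i + 1}" for i in range(npoints)]
    else:
        labels = list(labels[:npoints])
    return xyz, labels, float(frame_rate), units


# ----------------------------------------------------------------------
# writing

def _param_record(gid: int, name: str, dtype: int, dims: list[int], data: bytes,
                  last: bool = False) -> bytes:
    name_b = name.encode("ascii")
    body = struct.pack("b", dtype) + struct.pack("B", len(dims))
    body += bytes(dims) + data + b"\x00"  # trailing zero-length description
    offset = 0 if last else 2 + len(body)
    return (
        struct.pack("bb", len(name_b), gid)
        + name_b
        + struct.pack("<h", offset)
        + body
    )


def _group_record(gid: int, name: str) -> bytes:
    name_b = name.encode("ascii")
    body = b"\x00"
    return (
        struct.pack("bb", len(name_b), -gid)
        + name_b
        + struct.pack("<h", 2 + len(body))
        + body
    )


def write(path, points: np.ndarray, labels, frame_rate: float, units: str = "mm"):
    """Write an (n_frames, n_markers, 3) array as a float Intel C3D file."""
    points = np.asarray(points, dtype=float)
    n_frames, npoints, _ = points.shape
    if n_frames > 65535:
        raise FormatError("C3D frame counter is 16-bit; dataset too long")

    slen = max(max(len(l) for l in labels), 4)
    label_blob = b"".join(l.ljust(slen).encode("ascii") for l in labels)

    recs = [_group_record(1, "POINT")]
    recs.append(_param_record(1, "USED", 2, [], struct.pack("<h", npoints)))
    recs.append(_param_record(1, "FRAMES", 2, [], struct.pack("<h", n_frames)))
    recs.append(_param_record(1, "SCALE", 4, [], struct.pack("<f", -1.0)))
    recs.append(_param_record(1, "RATE", 4, [], struct.pack("<f", frame_rate)))
    recs.append(
        _param_record(1, "UNITS", -1, [len(units)], units.encode("ascii"))
    )
    recs.append(
        _param_record(1, "LABELS", -1, [slen, npoints], label_blob)
    )
    # DATA_START is patched below once the parameter section size is known
    data_start_rec_idx = len(recs)
    recs.append(_param_record(1, "DATA_START", 2, [], struct.pack("<h", 0), last=True))

    blob = b"".join(recs)
    n_param_blocks = -(-(len(blob) + 4) // 512)
    data_start_block = 2 + n_param_blocks
    recs[data_start_rec_idx] = _param_record(
        1, "DATA_START", 2, [], struct.pack("<h", data_start_block), last=True
    )
    blob = b"".join(recs)

    header = bytearray(512)
    struct.pack_into("<BB", header, 0, 2, 0x50)
    struct.pack_into("<4H", header, 2, npoints, 0, 1, n_frames)
    struct.pack_into("<f", header, 12, -1.0)  # point scale (float data)
    struct.pack_into("<H", header, 16, data_start_block)
    struct.pack_into("<H", header, 18, 1)  # analog samples per frame
    struct.pack_into("<f", header, 20, frame_rate)

    pblock = bytearray(n_param_blocks * 512)
    struct.pack_into("<BB", pblock, 0, 2, 0x50)
    pblock[2] = n_param_blocks
    pblock[3] = _INTEL
    pblock[4 : 4 + len(blob)] = blob

    frames = np.zeros((n_frames, npoints, 4), dtype="<f4")
    frames[:, :, :3] = np.nan_to_num(points, nan=0.0)
    missing = np.isnan(points).any(axis=2)
    frames[:, :, 3] = np.where(missing, -1.0, 0.0)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(pblock)
        fh.write(frames.tobytes())
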