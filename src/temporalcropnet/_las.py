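"""Minimal LAS 1.2 reader/writer (point format 0) for labelled clouds.

Only what the pipeline needs: x/y/z and the classification byte.  The
reader accepts point formats 0-3 from any LAS 1.x file (coordinates and
classification sit at fixed offsets in all of them); the writer always
emits LAS 1.2 / point format 0 with a millimetre coordinate scale.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

_HEADER_SIZE = 227
_POINT_SIZE = 20  # point data record format 0
_SCALE = 0.001

_POINT_DTYPE = np.dtype(
    [
        ("x", "<i4"),
        ("y", "<i4"),
        ("z", "<i4"),
        ("intensity", "<u2"),
        ("flags", "u1"),
        ("classification", "u1"),
        ("scan_angle", "i1"),
        ("user_data", "u1"),
        ("point_source", "<u2"),
    ]
)


def read_las(path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    """Return ``(xyz, classification)``; classification is None if all zero."""
    raw = Path(path).read_bytes()
    if raw[:4] != b"LASF":
        raise IOError(f"{path}: not a LAS file (bad signature)")
    (point_offset,) = struct.unpack_from("<I", raw, 96)
    point_format = raw[104]
    (record_len,) = struct.unpack_from("<H", raw, 105)
    (n_points,) = struct.unpack_from("<I", raw, 107)
    if point_format & 0x3F > 3:
        raise IOError(f"{path}: unsupported LAS point format {point_format}")
    sx, sy, sz, ox, oy, oz = struct.unpack_from("<6d", raw, 131)
    body = raw[point_offset : point_offset + n_points * record_len]
    if len(body) < n_points * record_len:
        raise IOError(f"{path}: truncated point records")
    records = np.frombuffer(body, dtype=np.uint8).reshape(n_points, record_len)
    base = records[:, :_POINT_SIZE].copy().view(_POINT_DTYPE).reshape(n_points)
    xyz = np.empty((n_points, 3), dtype=np.float64)
    xyz[:, 0] = base["x"] * sx + ox
    xyz[:, 1] = base["y"] * sy + oy
    xyz[:, 2] = base["z"] * sz + oz
    classification = (base["classification"] & 0x1F).astype(np.uint8)
    if not classification.any():
        return xyz, None
    return xyz, classification


def write_las(
    path: str | Path, xyz: np.ndarray, classification: np.ndarray | None = None
) -> None:
    xyz = np.asarray(xyz, dtype=np.float64)
    n = len(xyz)
    offset = xyz.min(axis=0)
    records = np.zeros(n, dtype=_POINT_DTYPE)
    scaled = np.round((xyz - offset) / _SCALE)
    if np.abs(scaled).max() > np.iinfo(np.int32).max:
        raise ValueError("coordinate span too large for millimetre LAS scale")
    records["x"] = scaled[:, 0].astype(np.int32)
    records["y"] = scaled[:, 1].astype(np.int32)
    records["z"] = scaled[:, 2].astype(np.int32)
    if classification is not None:
        records["classification"] = np.asarray(classification, dtype=np.uint8)

    header = bytearray(_HEADER_SIZE)
    header[0:4] = b"LASF"
    struct.pack_into("<BB", header, 24, 1, 2)  # version 1.2
    struct.pack_into("<32s", header, 26, b"temporalcropnet")
    struct.pack_into("<H", header, 94, _HEADER_SIZE)  # header size
    struct.pack_into("<I", header, 96, _HEADER_SIZE)  # offset to point data
    struct.pack_into("<I", header, 100, 0)  # number of VLRs
    header[104] = 0  # point data format
    struct.pack_into("<H", header, 105, _POINT_SIZE)
    struct.pack_into("<I", header, 107, n)
    struct.pack_into("<6d", header, 131, _SCALE, _SCALE, _SCALE, *offset)
    lo = xyz.min(axis=0)
    hi = xyz.max(axis=0)
    # header stores max/min interleaved per axis: x_max x_min y_max ...
    struct.pack_into("<6d", header, 179, hi[0], lo[0], hi[1], lo[1], hi[2], lo[2])
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(records.tobytes())
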