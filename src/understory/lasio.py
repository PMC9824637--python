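"""Minimal LAS point-cloud file I/O.

Reads uncompressed LAS 1.2-1.4 (point record formats 0-3 and 6-8) and writes
LAS 1.2 point format 0.  Only the fields the pipeline consumes are decoded:
coordinates, return number, and classification.  Compressed LAZ is not
supported; callers receive an explicit error and should decompress first.

Coordinates are stored in LAS files as scaled 32-bit integers, so a write/read
round trip quantizes them to the scale step (1 mm by default).
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

_SIGNATURE = b"LASF"
_DEFAULT_SCALE = 0.001

# point record layouts we decode: (return-byte offset, classification offset)
_FMT_LAYOUT = {
    0: (14, 15),
    1: (14, 15),
    2: (14, 15),
    3: (14, 15),
    6: (14, 16),
    7: (14, 16),
    8: (14, 16),
}
_MIN_RECLEN = {0: 20, 1: 28, 2: 26, 3: 34, 6: 30, 7: 36, 8: 38}


class LasFormatError(ValueError):
    """Raised for files that are not readable uncompressed LAS."""


def read_las(path: str | Path) -> dict[str, np.ndarray]:
    """Read a LAS file into arrays.

    Returns a dict with float64 ``x``/``y``/``z`` in file units (metres for
    all files this package writes) and integer ``return_number`` and
    ``classification`` arrays.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) == 0:
        return _empty()
    if len(raw) < 227:
        raise LasFormatError(f"{path}: too short to hold a LAS header")
    if raw[:4] != _SIGNATURE:
        if raw[:4] == b"LASZ" or path.suffix.lower() == ".laz":
            raise LasFormatError(
                f"{path}: compressed LAZ is not supported; convert to LAS first"
            )
        raise LasFormatError(f"{path}: not a LAS file (bad signature)")

    ver_major, ver_minor = raw[24], raw[25]
    offset_to_points = struct.unpack_from("<I", raw, 96)[0]
    fmt = raw[104]
    fmt &= 0x3F  # high bits flag LAZ compression
    reclen = struct.unpack_from("<H", raw, 105)[0]
    n_legacy = struct.unpack_from("<I", raw, 107)[0]
    scales = struct.unpack_from("<3d", raw, 131)
    offsets = struct.unpack_from("<3d", raw, 155)
    n_points = n_legacy
    if ver_major == 1 and ver_minor >= 4:
        n64 = struct.unpack_from("<Q", raw, 247)[0]
        if n64:
            n_points = n64
    if fmt not in _FMT_LAYOUT:
        raise LasFormatError(f"{path}: unsupported point record format {fmt}")
    if reclen < _MIN_RECLEN[fmt]:
        raise LasFormatError(f"{path}: record length {reclen} too small for format {fmt}")
    if n_points == 0:
        return _empty()
    avail = (len(raw) - offset_to_points) // reclen
    if avail < n_points:
        raise LasFormatError(f"{path}: truncated point data ({avail} of {n_points} records)")

    body = np.frombuffer(
        raw, dtype=np.uint8, count=n_points * reclen, offset=offset_to_points
    ).reshape(n_points, reclen)
    xyz_int = (
        body[:, :12].reshape(-1).view("<i4").reshape(n_points, 3).astype(np.float64)
    )
    ret_off, cls_off = _FMT_LAYOUT[fmt]
    ret_mask = 0x0F if fmt >= 6 else 0x07
    return_number = (body[:, ret_off] & ret_mask).astype(np.int64)
    classification = body[:, cls_off].astype(np.int64)
    if fmt < 6:
        classification &= 0x1F
    return {
        "x": xyz_int[:, 0] * scales[0] + offsets[0],
        "y": xyz_int[:, 1] * scales[1] + offsets[1],
        "z": xyz_int[:, 2] * scales[2] + offsets[2],
        "return_number": return_number,
        "classification": classification,
    }


def write_las(
    path: str | Path,
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    return_number: np.ndarray | None = None,
    classification: np.ndarray | None = None,
    scale: float = _DEFAULT_SCALE,
) -> None:
    """Write arrays as LAS 1.2, point data record format 0."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    n = x.size
    if return_number is None:
        return_number = np.ones(n, dtype=np.int64)
    if classification is None:
        classification = np.ones(n, dtype=np.int64)

    if n:
        mins = np.array([x.min(), y.min(), z.min()])
        maxs = np.array([x.max(), y.max(), z.max()])
    else:
        mins = maxs = np.zeros(3)
    offs = np.floor(mins)

    header = bytearray(227)
    header[0:4] = _SIGNATURE
    header[24] = 1  # version major
    header[25] = 2  # version minor
    header[26:26 + 10] = b"understory"[:10]
    header[58:58 + 10] = b"understory"[:10]
    struct.pack_into("<H", header, 94, 227)   # header size
    struct.pack_into("<I", header, 96, 227)   # offset to point data
    struct.pack_into("<I", header, 100, 0)    # number of VLRs
    header[104] = 0                           # point data format
    struct.pack_into("<H", header, 105, 20)   # record length
    struct.pack_into("<I", header, 107, n)
    by_return = np.bincount(np.clip(return_number, 1, 5), minlength=6)[1:6] if n else np.zeros(5, int)
    struct.pack_into("<5I", header, 111, *(int(c) for c in by_return))
    struct.pack_into("<3d", header, 131, scale, scale, scale)
    struct.pack_into("<3d", header, 155, *offs)
    struct.pack_into("<6d", header, 179,
                     maxs[0], mins[0], maxs[1], mins[1], maxs[2], mins[2])

    rec = np.zeros(n, dtype=np.dtype([
        ("X", "<i4"), ("Y", "<i4"), ("Z", "<i4"),
        ("intensity", "<u2"), ("flags", "u1"), ("classification", "u1"),
        ("scan_angle", "i1"), ("user_data", "u1"), ("point_source", "<u2"),
    ]))
    rec["X"] = np.round((x - offs[0]) / scale).astype(np.int64)
    rec["Y"] = np.round((y - offs[1]) / scale).astype(np.int64)
    rec["Z"] = np.round((z - offs[2]) / scale).astype(np.int64)
    # return number in bits 0-2, number of returns (bits 3-5) set to 1
    rec["flags"] = ((np.clip(return_number, 1, 7) & 0x07) | (1 << 3)).astype(np.uint8)
    rec["classification"] = np.clip(classification, 0, 31).astype(np.uint8)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(rec.tobytes())


def _empty() -> dict[str, np.ndarray]:
    zero = np.zeros(0)
    zint = np.zeros(0, dtype=np.int64)
    return {"x": zero, "y": zero.copy(), "z": zero.copy(),
            "return_number": zint, "classification": zint.copy()}
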