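"""Minimal C3D motion-capture file reader and writer.

C3D is the standard binary container for labelled 3D point trajectories
produced by optical capture pipelines.  This module implements the subset the
package needs: Intel-byte-order files with labelled points, floating-point or
integer sample storage, the POINT parameter group (USED, FRAMES, LABELS,
RATE, SCALE, UNITS, DATA_START) and per-sample residuals, where a negative
residual marks an invalid (occluded / gap) sample.  Gaps are surfaced as NaN
coordinates; policy on them belongs to the caller.

The writer exists so tests and the synthetic generator can produce real C3D
fixtures; it always writes floating-point data in millimetres.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["read_c3d_raw", "write_c3d"]

_BLOCK = 512
_INTEL = 84  # processor type flag for little-endian files


def write_c3d(
    path: str | Path,
    marker_names: list[str],
    positions: np.ndarray,
    frame_rate: float = 100.0,
) -> None:
    """Write labelled point trajectories to ``path``.

    ``positions`` has shape (T, M, 3) in millimetres; NaN coordinates are
    stored as zero with residual -1 (the C3D convention for invalid samples).
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 3 or positions.shape[2] != 3:
        raise ValueError(f"positions must be (T, M, 3), got {positions.shape}")
    T, M, _ = positions.shape
    if M != len(marker_names):
        raise ValueError("marker_names length must match positions second axis")

    # section length does not depend on the DATA_START value, so build twice
    n_param_blocks = (len(_build_parameter_section(marker_names, T, frame_rate, 0)) + _BLOCK - 1) // _BLOCK
    data_start = 2 + n_param_blocks  # 1-based block index
    params = _build_parameter_section(marker_names, T, frame_rate, data_start)
    params = params.ljust(n_param_blocks * _BLOCK, b"\x00")

    header = bytearray(_BLOCK)
    struct.pack_into("<BB", header, 0, 2, 0x50)          # param block pointer, magic
    struct.pack_into("<H", header, 2, M)                 # points per frame
    struct.pack_into("<H", header, 4, 0)                 # analog samples
    struct.pack_into("<H", header, 6, 1)                 # first frame
    struct.pack_into("<H", header, 8, T)                 # last frame
    struct.pack_into("<H", header, 10, 0)                # max gap
    struct.pack_into("<f", header, 12, -1.0)             # scale < 0 -> float data
    struct.pack_into("<H", header, 16, data_start)
    struct.pack_into("<H", header, 18, 0)                # analog per frame
    struct.pack_into("<f", header, 20, float(frame_rate))

    frames = np.zeros((T, M, 4), dtype="<f4")
    frames[:, :, :3] = np.nan_to_num(positions, nan=0.0)
    invalid = np.isnan(positions).any(axis=2)
    frames[:, :, 3] = np.where(invalid, -1.0, 0.0)

    raw = bytes(header) + params + frames.tobytes()
    pad = (-len(raw)) % _BLOCK
    Path(path).write_bytes(raw + b"\x00" * pad)


def _param_record(group_id: int, name: str, dtype: int, dims: list[int], payload: bytes) -> bytes:
    name_b = name.encode("ascii")
    body = struct.pack("<bb", dtype, len(dims)) + bytes(dims) + payload + b"\x00"
    rec = struct.pack("<bb", len(name_b), group_id) + name_b
    rec += struct.pack("<h", 2 + len(body)) + body
    return rec


def _group_record(group_id: int, name: str) -> bytes:
    name_b = name.encode("ascii")
    body = b"\x00"  # empty description
    return struct.pack("<bb", len(name_b), -group_id) + name_b + struct.pack("<h", 2 + len(body)) + body


def _build_parameter_section(marker_names: list[str], n_frames: int, frame_rate: float,
                             data_start: int) -> bytes:
    label_len = max(4, max(len(n) for n in marker_names))
    labels = b"".join(n.encode("ascii").ljust(label_len) for n in marker_names)
    gid = 1
    recs = [
        _group_record(gid, "POINT"),
        _param_record(gid, "USED", 2, [], struct.pack("<h", len(marker_names))),
        _param_record(gid, "FRAMES", 2, [], struct.pack("<h", n_frames)),
        _param_record(gid, "SCALE", 4, [], struct.pack("<f", -1.0)),
        _param_record(gid, "RATE", 4, [], struct.pack("<f", float(frame_rate))),
        _param_record(gid, "UNITS", -1, [2], b"mm"),
        _param_record(gid, "DATA_START", 2, [], struct.pack("<h", data_start)),
        _param_record(gid, "LABELS", -1, [label_len, len(marker_names)], labels),
    ]
    header = struct.pack("<BBbb", 1, 0x50, 0, _INTEL)  # block count patched below
    body = header + b"".join(recs) + struct.pack("<bb", 0, 0)
    n_blocks = (len(body) + _BLOCK - 1) // _BLOCK
    return body[:2] + struct.pack("<bb", n_blocks, _INTEL) + body[4:]


def read_c3d_raw(path: str | Path) -> tuple[list[str], np.ndarray, float]:
    """Read a C3D file; return (labels, positions (T, M, 3) in mm, frame rate).

    Invalid samples (negative residual) come back as NaN.  Raises
    ``FileNotFoundError`` for a missing file and ``ValueError`` for files the
    reader does not understand or that contain no labelled points or frames.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 2 * _BLOCK:
        raise ValueError(f"{path}: too short to be a C3D file")
    param_block, magic = struct.unpack_from("<BB", raw, 0)
    if magic != 0x50:
        raise ValueError(f"{path}: not a C3D file (bad magic byte {magic:#x})")
    n_points = struct.unpack_from("<H", raw, 2)[0]
    first_frame = struct.unpack_from("<H", raw, 6)[0]
    last_frame = struct.unpack_from("<H", raw, 8)[0]
    header_scale = struct.unpack_from("<f", raw, 12)[0]
    data_start = struct.unpack_from("<H", raw, 16)[0]
    frame_rate = struct.unpack_from("<f", raw, 20)[0]

    params = _parse_parameters(raw, (param_block - 1) * _BLOCK, path)
    point = params.get("POINT", {})
    labels = point.get("LABELS")
    if labels:
        labels = [l.strip() for l in labels]
        labels = [l for l in labels if l]
    if not labels:
        raise ValueError(f"{path}: no labelled points (POINT:LABELS empty or missing)")
    n_points = int(point.get("USED", [n_points])[0]) or n_points
    n_frames = int(point.get("FRAMES", [last_frame - first_frame + 1])[0])
    if n_frames < 1 or n_points < 1:
        raise ValueError(f"{path}: zero frames or zero points")
    if len(labels) < n_points:
        raise ValueError(f"{path}: {n_points} points but only {len(labels)} labels")
    labels = labels[:n_points]
    scale = float(point.get("SCALE", [header_scale])[0])
    data_start = int(point.get("DATA_START", [data_start])[0])
    rate = float(point.get("RATE", [frame_rate])[0]) or frame_rate
    units = point.get("UNITS")
    unit_factor = 1.0
    if units:
        u = "".join(units).strip().lower()
        unit_factor = {"mm": 1.0, "cm": 10.0, "m": 1000.0}.get(u, 1.0)

    offset = (data_start - 1) * _BLOCK
    count = n_frames * n_points * 4
    if scale < 0:
        vals = np.frombuffer(raw, dtype="<f4", count=count, offset=offset).astype(float)
    else:
        vals = np.frombuffer(raw, dtype="<i2", count=count, offset=offset).astype(float)
        vals[0::4] *= scale
        vals[1::4] *= scale
        vals[2::4] *= scale
    frames = vals.reshape(n_frames, n_points, 4)
    xyz = frames[:, :, :3] * unit_factor
    xyz = np.where(frames[:, :, 3:4] < 0, np.nan, xyz)
    return labels, xyz, rate


def _parse_parameters(raw: bytes, offset: int, path) -> dict[str, dict[str, list]]:
    processor = raw[offset + 3]
    if processor != _INTEL:
        raise ValueError(f"{path}: unsupported processor type {processor} (only Intel)")
    groups: dict[int, str] = {}
    values: dict[int, dict[str, list]] = {}
    pos = offset + 4
    while pos < len(raw) - 2:
        n_char, group_id = struct.unpack_from("<bb", raw, pos)
        if n_char == 0:
            break
        name = raw[pos + 2 : pos + 2 + abs(n_char)].decode("ascii", "replace")
        p = pos + 2 + abs(n_char)
        (next_off,) = struct.unpack_from("<h", raw, p)
        if group_id < 0:  # group definition
            groups[-group_id] = name
        else:  # parameter
            dtype, ndims = struct.unpack_from("<bb", raw, p + 2)
            q = p + 4
            dims = list(raw[q : q + ndims])
            q += ndims
            n_items = int(np.prod(dims)) if dims else 1
            if dtype == -1:
                if len(dims) >= 2:
                    L = dims[0]
                    data = [
                        raw[q + i * L : q + (i + 1) * L].decode("ascii", "replace")
                        for i in range(n_items // L)
                    ]
                else:
                    data = [raw[q : q + n_items].decode("ascii", "replace")]
            elif dtype == 1:
                data = list(np.frombuffer(raw, dtype="<i1", count=n_items, offset=q))
            elif dtype == 2:
                data = list(np.frombuffer(raw, dtype="<i2", count=n_items, offset=q))
            elif dtype == 4:
                data = list(np.frombuffer(raw, dtype="<f4", count=n_items, offset=q))
            else:
                data = []
            values.setdefault(group_id, {})[name] = data
        if next_off <= 0:
            break
        pos = p + next_off
    return {groups.get(gid, f"GROUP{gid}"): params for gid, params in values.items()}
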