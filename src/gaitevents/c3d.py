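"""Minimal C3D motion-capture file reader/writer.

Supports the common modern subset of the C3D standard: Intel (little-endian)
processor type, floating-point point data, POINT and EVENT parameter groups.
Analog channels are ignored on read and never written.  This is sufficient to
round-trip marker trajectories with event annotations and to read
standard-layout files from typical clinical pipelines; files using DEC/MIPS
byte order or integer point storage raise a format error.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

__all__ = ["C3DRecord", "read_c3d", "write_c3d", "C3DFormatError"]

_BLOCK = 512
_PROC_INTEL = 84  # 83 + 1


class C3DFormatError(ValueError):
    pass


@dataclass
class C3DRecord:
    """In-memory contents of a C3D file (points in file units)."""

    points: np.ndarray           # T x P x 3
    labels: list[str]
    rate: float
    units: str = "mm"
    first_frame: int = 1
    events: list[tuple[str, str, float]] = field(default_factory=list)  # (label, context, time_s)


# ---------------------------------------------------------------------------
# writing

def _pad_strings(strings: list[str], width: int) -> bytes:
    return b"".join(s.encode("ascii")[:width].ljust(width) for s in strings)


def _param_record(name: str, group_id: int, ptype: int, dims: list[int], data: bytes,
                  last: bool = False) -> bytes:
    name_b = name.encode("ascii")
    body = struct.pack("<bB", ptype, len(dims)) + bytes(dims) + data + b"\x00"
    offset = 0 if last else 2 + len(body)
    return struct.pack("<bb", len(name_b), group_id) + name_b + struct.pack("<h", offset) + body


def _group_record(name: str, group_id: int) -> bytes:
    name_b = name.encode("ascii")
    body = b"\x00"  # empty description
    return struct.pack("<bb", len(name_b), -group_id) + name_b + struct.pack("<h", 2 + len(body)) + body


def write_c3d(path, points: np.ndarray, labels: list[str], rate: float,
              events: list[tuple[str, str, float]] | None = None, units: str = "mm") -> None:
    """Write a float-storage C3D file.

    points: T x P x 3 array in ``units``; events: (label, context, time_s)
    with time measured from frame 0 at ``rate``.
    """
    points = np.asarray(points, dtype=np.float32)
    if points.ndim != 3 or points.shape[2] != 3:
        raise ValueError(f"points must be T x P x 3, got {points.shape}")
    if not np.isfinite(points).all():
        raise ValueError("points contain non-finite values")
    T, P, _ = points.shape
    events = list(events or [])

    label_w = max(4, max((len(l) for l in labels), default=4))
    recs = [_group_record("POINT", 1)]
    recs.append(_param_record("USED", 1, 2, [], struct.pack("<h", P)))
    recs.append(_param_record("FRAMES", 1, 2, [], struct.pack("<h", min(T, 32767))))
    recs.append(_param_record("SCALE", 1, 4, [], struct.pack("<f", -1.0)))
    recs.append(_param_record("RATE", 1, 4, [], struct.pack("<f", float(rate))))
    recs.append(_param_record("UNITS", 1, -1, [len(units)], units.encode("ascii")))
    recs.append(_param_record("LABELS", 1, -1, [label_w, P], _pad_strings(labels, label_w)))

    recs.append(_group_record("EVENT", 2))
    n_ev = len(events)
    ev_label_w = max(4, max((len(e[0]) for e in events), default=4))
    ev_ctx_w = max(4, max((len(e[1]) for e in events), default=4))
    recs.append(_param_record("USED", 2, 2, [], struct.pack("<h", n_ev)))
    times = b"".join(struct.pack("<ff", 0.0, float(t)) for _, _, t in events)
    recs.append(_param_record("TIMES", 2, 4, [2, n_ev], times))
    recs.append(_param_record("CONTEXTS", 2, -1, [ev_ctx_w, n_ev],
                              _pad_strings([e[1] for e in events], ev_ctx_w)))
    recs.append(_param_record("LABELS", 2, -1, [ev_label_w, n_ev],
                              _pad_strings([e[0] for e in events], ev_label_w), last=True))

    param_body = b"".join(recs)
    n_param_blocks = -(-(len(param_body) + 4) // _BLOCK)
    param_section = struct.pack("<BBBB", 1, 80, n_param_blocks, _PROC_INTEL) + param_body
    param_section += b"\x00" * (n_param_blocks * _BLOCK - len(param_section))
    data_start = 2 + n_param_blocks

    header = bytearray(_BLOCK)
    struct.pack_into("<BB", header, 0, 2, 80)            # param section block, magic
    struct.pack_into("<H", header, 2, P)                 # points per frame
    struct.pack_into("<H", header, 4, 0)                 # analog measurements per frame
    struct.pack_into("<H", header, 6, 1)                 # first frame (1-based)
    struct.pack_into("<H", header, 8, min(T, 65535))     # last frame
    struct.pack_into("<H", header, 10, 0)                # max interpolation gap
    struct.pack_into("<f", header, 12, -1.0)             # scale (negative: float data)
    struct.pack_into("<H", header, 16, data_start)       # data section start block
    struct.pack_into("<H", header, 18, 0)                # analog samples per frame
    struct.pack_into("<f", header, 20, float(rate))      # point frame rate

    frame_data = np.zeros((T, P, 4), dtype="<f4")
    frame_data[:, :, :3] = points
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(param_section)
        fh.write(frame_data.tobytes())


# ---------------------------------------------------------------------------
# reading

def _read_params(raw: bytes):
    """Parse the parameter section into {GROUP: {PARAM: (type, dims, bytes)}}."""
    if len(raw) < 4:
        raise C3DFormatError("parameter section truncated")
    proc = raw[3]
    if proc != _PROC_INTEL:
        raise C3DFormatError(f"unsupported processor type {proc} (only Intel supported)")
    pos = 4
    group_names: dict[int, str] = {}
    params: dict[int, dict[str, tuple[int, list[int], bytes]]] = {}
    while pos + 2 <= len(raw):
        name_len, group_id = struct.unpack_from("<bb", raw, pos)
        if name_len == 0 or group_id == 0:
            break
        n = abs(name_len)
        name = raw[pos + 2 : pos + 2 + n].decode("ascii", "replace").upper()
        off_pos = pos + 2 + n
        (offset,) = struct.unpack_from("<h", raw, off_pos)
        if group_id < 0:  # group definition
            group_names[-group_id] = name
        else:  # parameter
            p = off_pos + 2
            ptype, ndims = struct.unpack_from("<bB", raw, p)
            dims = list(raw[p + 2 : p + 2 + ndims])
            size = abs(ptype)
            count = int(np.prod(dims)) if dims else 1
            data = raw[p + 2 + ndims : p + 2 + ndims + size * count]
            params.setdefault(group_id, {})[name] = (ptype, dims, data)
        if offset <= 0:
            break
        pos = off_pos + offset
    out: dict[str, dict[str, tuple[int, list[int], bytes]]] = {}
    for gid, ps in params.items():
        out[group_names.get(gid, f"G{gid}")] = ps
    return out


def _strings(param) -> list[str]:
    _, dims, data = param
    if not dims:
        return [data.decode("ascii", "replace").strip()]
    w = dims[0]
    n = int(np.prod(dims[1:])) if len(dims) > 1 else 1
    return [data[i * w : (i + 1) * w].decode("ascii", "replace").strip() for i in range(n)]


def _scalar(param, fmt: str):
    _, _, data = param
    return struct.unpack_from(fmt, data)[0]


def read_c3d(path) -> C3DRecord:
    """Read a C3D file (Intel, float or int point storage)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _BLOCK or raw[1] != 80:
        raise C3DFormatError("not a C3D file (bad magic)")
    param_block = raw[0]
    n_points = struct.unpack_from("<H", raw, 2)[0]
    analog_per_frame = struct.unpack_from("<H", raw, 4)[0]
    first_frame = struct.unpack_from("<H", raw, 6)[0]
    last_frame = struct.unpack_from("<H", raw, 8)[0]
    scale = struct.unpack_from("<f", raw, 12)[0]
    data_start = struct.unpack_from("<H", raw, 16)[0]
    rate = struct.unpack_from("<f", raw, 20)[0]

    groups = _read_params(raw[(param_block - 1) * _BLOCK :])
    point = groups.get("POINT", {})
    if "RATE" in point:
        rate = float(_scalar(point["RATE"], "<f"))
    if "SCALE" in point:
        scale = float(_scalar(point["SCALE"], "<f"))
    if "USED" in point:
        n_points = int(_scalar(point["USED"], "<h"))
    n_frames = last_frame - first_frame + 1
    if "FRAMES" in point:
        n_frames = max(n_frames, int(_scalar(point["FRAMES"], "<h")))
    labels = _strings(point["LABELS"])[:n_points] if "LABELS" in point else [
        f"PT{i}" for i in range(n_points)
    ]
    units = _strings(point["UNITS"])[0] if "UNITS" in point else "mm"

    if scale >= 0:
        raise C3DFormatError("integer point storage not supported (POINT:SCALE >= 0)")
    start = (data_start - 1) * _BLOCK
    per_frame = n_points * 4 * 4 + analog_per_frame * 4
    avail = (len(raw) - start) // per_frame if per_frame else 0
    n_frames = min(n_frames, avail)
    if n_frames < 1:
        raise C3DFormatError("no point data frames")
    buf = np.frombuffer(raw, dtype="<f4", count=per_frame // 4 * n_frames, offset=start)
    buf = buf.reshape(n_frames, per_frame // 4)
    points = buf[:, : n_points * 4].reshape(n_frames, n_points, 4)[:, :, :3].astype(float)

    events: list[tuple[str, str, float]] = []
    ev = groups.get("EVENT", {})
    if ev and "USED" in ev and int(_scalar(ev["USED"], "<h")) > 0:
        n_ev = int(_scalar(ev["USED"], "<h"))
        _, tdims, tdata = ev["TIMES"]
        times = np.frombuffer(tdata, dtype="<f4").reshape(-1, 2)[:n_ev]
        ev_labels = _strings(ev["LABELS"])[:n_ev] if "LABELS" in ev else [""] * n_ev
        ev_ctx = _strings(ev["CONTEXTS"])[:n_ev] if "CONTEXTS" in ev else [""] * n_ev
        for i in range(n_ev):
            t = float(times[i, 0]) * 60.0 + float(times[i, 1])
            events.append((ev_labels[i], ev_ctx[i], t))

    return C3DRecord(
        points=points,
        labels=labels,
        rate=float(rate),
        units=units,
        first_frame=first_frame,
        events=events,
    )
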