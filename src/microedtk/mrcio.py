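"""Minimal MRC2014 stack I/O for counting movies.

Writes mode-2 (float32) image stacks with a bare 1024-byte header — the
layout unit-gain counting movies are delivered in — plus a plain-text
``key = value`` sidecar carrying the rotation metadata that MRC headers have
no standard slot for. Covers only what this toolkit needs: single-volume
stacks, no extended header.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["write_mrc_stack", "read_mrc_stack", "write_sidecar", "read_sidecar"]

_HEADER_SIZE = 1024
_MAP_ID = b"MAP "
_MACHINE_STAMP_LE = bytes([0x44, 0x44, 0x00, 0x00])


def write_mrc_stack(images: np.ndarray, path) -> None:
    """Write an (n, h, w) stack as a mode-2 little-endian MRC file."""
    images = np.asarray(images)
    if images.ndim != 3:
        raise ValueError("expected an (n_images, height, width) stack")
    n, h, w = images.shape
    data = np.ascontiguousarray(images, dtype="<f4")

    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<3i", header, 0, w, h, n)  # NX NY NZ
    struct.pack_into("<i", header, 12, 2)  # MODE 2 = float32
    struct.pack_into("<3i", header, 28, w, h, n)  # MX MY MZ
    struct.pack_into("<3f", header, 40, float(w), float(h), float(n))  # CELLA
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # CELLB
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # MAPC MAPR MAPS
    dmin, dmax = (float(data.min()), float(data.max())) if data.size else (0.0, 0.0)
    struct.pack_into("<3f", header, 76, dmin, dmax, float(data.mean()) if data.size else 0.0)
    struct.pack_into("<i", header, 88, 1)  # ISPG 1: volume/stack
    header[208:212] = _MAP_ID
    header[212:216] = _MACHINE_STAMP_LE

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


def read_mrc_stack(path) -> np.ndarray:
    """Read a mode-2 MRC stack written by :func:`write_mrc_stack`."""
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER_SIZE:
        raise ValueError(f"{path}: truncated MRC header")
    if raw[208:212] != _MAP_ID:
        raise ValueError(f"{path}: missing 'MAP ' identifier at byte 208")
    w, h, n = struct.unpack_from("<3i", raw, 0)
    (mode,) = struct.unpack_from("<i", raw, 12)
    if mode != 2:
        raise ValueError(f"{path}: unsupported MRC mode {mode} (only mode 2)")
    expected = _HEADER_SIZE + 4 * n * h * w
    if len(raw) < expected:
        raise ValueError(f"{path}: payload shorter than NX*NY*NZ")
    data = np.frombuffer(raw, dtype="<f4", count=n * h * w, offset=_HEADER_SIZE)
    return data.reshape(n, h, w).copy()


def write_sidecar(metadata: dict, path) -> None:
    """Write rotation metadata as ``key = value`` lines."""
    with open(path, "w") as fh:
        for key, value in metadata.items():
            if isinstance(value, (list, tuple, np.ndarray)):
                value = " ".join(repr(float(v)) for v in np.asarray(value).ravel())
            fh.write(f"{key} = {value}\n")


def read_sidecar(path) -> dict:
    """Read a sidecar written by :func:`write_sidecar` (values stay strings)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, val = (s.strip() for s in line.split("=", 1))
            out[key] = val
    return out
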