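"""Bit-exact conversion between counting movie stacks and still formats.

Counting movies carry real pixel values at unit gain (one counted electron =
one count). Crystallographic integration programs consume unsigned 16-bit
stills, so on conversion every count is multiplied by the gain scale (32)
and rounded to the nearest integer; the inverse map divides by 32 and rounds
again. The still dialect written here is SMV (Super Marty View): a 512-byte
ASCII header followed by a little-endian unsigned-short payload, with the
ADSC key set that downstream integration software expects. The final image
of a stack is discarded on conversion (it covers a partial window on the
instrument), so a 420-image stack yields 419 stills.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import AcquisitionPlan, electron_wavelength
from .synth import MovieStack

__all__ = [
    "SMVImage",
    "ConversionError",
    "SMVFormatError",
    "counts_to_smv_value",
    "smv_value_to_electrons",
    "stack_to_smv",
    "write_smv",
    "read_smv",
    "write_smv_stack",
    "write_tiff",
]

logger = logging.getLogger(__name__)

SMV_HEADER_BYTES = 512
SMV_MAX = 65535
_REQUIRED_READ_KEYS = ("HEADER_BYTES", "SIZE1", "SIZE2")


class ConversionError(ValueError):
    """Raised when stack metadata needed for conversion is missing."""


class SMVFormatError(ValueError):
    """Raised on a malformed SMV file, naming the offending key."""


@dataclass
class SMVImage:
    """One SMV still: an unsigned 16-bit pixel grid plus its ASCII header."""

    pixels: np.ndarray
    header: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("SMV pixels must be a 2-D grid")
        if self.pixels.dtype != np.uint16:
            if np.any(self.pixels < 0) or np.any(self.pixels > SMV_MAX):
                raise ValueError("pixel values must fit an unsigned 16-bit range")
            self.pixels = self.pixels.astype(np.uint16)


def _round_half_away(x):
    """Round to nearest integer, halves away from zero (inputs nonnegative)."""
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


def counts_to_smv_value(count, gain_scale: int = 32):
    """Map unit-gain electron counts to stored SMV integers.

    stored = round(gain_scale x count), rounding half away from zero,
    saturated at 65535. One counted electron stores as 32. Saturation is the
    only lossy path; clipped pixels are counted and logged. Accepts scalars
    or arrays (counts may be fractional if upstream summing produced them).
    """
    arr = np.asarray(count)
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    stored = _round_half_away(arr * gain_scale)
    n_clipped = int(np.count_nonzero(stored > SMV_MAX))
    if n_clipped:
        logger.warning("saturated %d pixel(s) at %d during SMV conversion", n_clipped, SMV_MAX)
    stored = np.minimum(stored, SMV_MAX).astype(np.uint16)
    return int(stored) if stored.ndim == 0 else stored


def smv_value_to_electrons(value, gain_scale: int = 32):
    """Invert the stored scaling: electrons = round(value / gain_scale).

    Half-integer quotients round away from zero (47 -> 1, 48 -> 2 at the
    default scale); exact inverse of :func:`counts_to_smv_value` on integer
    counts in [0, 2047].
    """
    arr = np.asarray(value)
    if np.any(arr < 0):
        raise ValueError("stored values must be nonnegative")
    electrons = _round_half_away(arr / gain_scale).astype(np.int64)
    return int(electrons) if electrons.ndim == 0 else electrons


def _build_header(
    stack: MovieStack, plan: AcquisitionPlan, index: int, pedestal: int
) -> dict[str, str]:
    h, w = stack.shape
    px = plan.pixel_size_mm
    beam_x = w / 2.0 * px
    beam_y = h / 2.0 * px
    hdr = {
        "HEADER_BYTES": str(SMV_HEADER_BYTES),
        "DIM": "2",
        "BYTE_ORDER": "little_endian",
        "TYPE": "unsigned_short",
        "SIZE1": str(w),
        "SIZE2": str(h),
        "PIXEL_SIZE": f"{px:.6f}",
        "DISTANCE": f"{plan.effective_distance:.3f}",
        "WAVELENGTH": f"{electron_wavelength(plan.accelerating_voltage):.6f}",
        "OSC_START": f"{stack.osc_start[index]:.6f}",
        "OSC_RANGE": f"{stack.osc_range[index]:.6f}",
        "PHI": f"{stack.osc_start[index]:.6f}",
        "BEAM_CENTER_X": f"{beam_x:.4f}",
        "BEAM_CENTER_Y": f"{beam_y:.4f}",
        "TIME": f"{stack.exposure[index]:.6f}",
    }
    if pedestal:
        hdr["IMAGE_PEDESTAL"] = str(pedestal)
    return hdr


def stack_to_smv(
    stack: MovieStack,
    plan: AcquisitionPlan | None = None,
    *,
    keep_last: bool = False,
    pedestal: int = 0,
) -> list[SMVImage]:
    """Convert a counting movie stack to a sequence of SMV stills.

    The final image is discarded unless ``keep_last`` (it spans a partial
    summation window as acquired); each remaining image is scaled by the
    gain rule and paired with a header carrying per-image oscillation
    metadata, the relativistic wavelength and the effective detector
    distance. A one-image stack therefore yields no stills (with a warning).

    Raises :class:`ConversionError` listing the missing plan fields when the
    metadata needed for headers is absent.
    """
    plan = plan or stack.plan
    if plan is None:
        raise ConversionError("no AcquisitionPlan available: missing [plan]")
    missing = []
    if plan.pixel_size_mm is None:
        missing.append("pixel_size_mm")
    if missing:
        raise ConversionError(f"plan is missing required metadata: {', '.join(missing)}")
    if stack.n_images == 0:
        raise ConversionError("stack is empty")

    n_keep = stack.n_images if keep_last else stack.n_images - 1
    if n_keep == 0:
        warnings.warn("single-image stack: nothing remains after discarding the last image", stacklevel=2)
        return []
    out = []
    for i in range(n_keep):
        pixels = counts_to_smv_value(stack.images[i])
        if pedestal:
            pixels = np.minimum(pixels.astype(np.int64) + pedestal, SMV_MAX).astype(np.uint16)
        out.append(SMVImage(pixels=pixels, header=_build_header(stack, plan, i, pedestal)))
    return out


def write_smv(image: SMVImage, path) -> None:
    """Write one SMV still: 512-byte ASCII header + uint16 little-endian payload."""
    h, w = image.pixels.shape
    hdr = dict(image.header)
    hdr.setdefault("HEADER_BYTES", str(SMV_HEADER_BYTES))
    hdr.setdefault("DIM", "2")
    hdr.setdefault("BYTE_ORDER", "little_endian")
    hdr.setdefault("TYPE", "unsigned_short")
    hdr["SIZE1"] = str(w)
    hdr["SIZE2"] = str(h)
    text = "{\n" + "".join(f"{k}={v};\n" for k, v in hdr.items()) + "}\n"
    blob = text.encode("ascii")
    if len(blob) > SMV_HEADER_BYTES:
        raise SMVFormatError("header exceeds HEADER_BYTES=512")
    blob += b" " * (SMV_HEADER_BYTES - len(blob))
    with open(path, "wb") as fh:
        fh.write(blob)
        fh.write(np.ascontiguousarray(image.pixels, dtype="<u2").tobytes())


def read_smv(path) -> SMVImage:
    """Read one SMV still, validating header keys against the payload."""
    raw = Path(path).read_bytes()
    end = raw.find(b"}")
    if not raw.startswith(b"{") or end < 0:
        raise SMVFormatError(f"{path}: no ASCII header block")
    header: dict[str, str] = {}
    for line in raw[1:end].decode("ascii", errors="replace").splitlines():
        line = line.strip().rstrip(";")
        if "=" in line:
            key, val = line.split("=", 1)
            header[key.strip()] = val.strip()
    for key in _REQUIRED_READ_KEYS:
        if key not in header:
            raise SMVFormatError(f"{path}: missing required header key {key}")
    offset = int(header["HEADER_BYTES"])
    w, h = int(header["SIZE1"]), int(header["SIZE2"])
    expected = offset + 2 * w * h
    if len(raw) < expected:
        raise SMVFormatError(f"{path}: payload does not match SIZE1 x SIZE2")
    order = "<" if header.get("BYTE_ORDER", "little_endian") == "little_endian" else ">"
    pixels = np.frombuffer(raw, dtype=f"{order}u2", count=w * h, offset=offset)
    return SMVImage(pixels=pixels.reshape(h, w).astype(np.uint16), header=header)


def write_smv_stack(images: list[SMVImage], out_dir, prefix: str = "image") -> list[Path]:
    """Write a converted sequence as zero-padded sequential files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    width = max(3, len(str(len(images))))
    paths = []
    for i, image in enumerate(images, start=1):
        p = out_dir / f"{prefix}_{i:0{width}d}.img"
        write_smv(image, p)
        paths.append(p)
    return paths


def write_tiff(stack: MovieStack, path) -> None:
    """Export the full stack (no discard, no rescaling) as a multi-page TIFF.

    Raw unit-gain counts are preserved exactly, so the total electron content
    of the stack survives the export.
    """
    import tifffile

    data = np.asarray(stack.images)
    if data.size and data.max() > np.iinfo(np.uint16).max:
        dtype = np.uint32
    else:
        dtype = np.uint16
    tifffile.imwrite(path, data.astype(dtype))
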