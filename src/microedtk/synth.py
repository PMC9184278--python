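"""Synthetic continuous-rotation counting-mode diffraction movies.

Generates raw counted frames containing Bragg-spot events plus Poisson
background, then sums them into images exactly as the detector pipeline
does. Spots are parametric events — an angular position, a Gaussian rocking
profile, a Gaussian detector footprint and an expected electron budget —
not products of a reciprocal-lattice model: the goal is controllable
fixtures whose ground truth is known, for exercising the counting,
conversion, planning and statistics paths.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .detector import DetectorSpec, count_frame
from .geometry import AcquisitionPlan

__all__ = [
    "ReflectionEvent",
    "MovieStack",
    "generate_reflection_schedule",
    "simulate_movie",
    "simulate_flat_field",
]

# truncation radii for the two Gaussian profiles (stage angle / detector face)
_ROCKING_TRUNC_SD = 3.0
_FOOTPRINT_TRUNC_SD = 4.0
# FWHM = 2 sqrt(2 ln 2) sigma
_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class ReflectionEvent:
    """One Bragg spot's passage through the diffracting condition.

    ``expected_electrons`` is the total expected electron count integrated
    over the full rocking passage; ``rocking_width`` is the full width at
    half maximum of the angular excitation profile.
    """

    spot_id: str
    center_angle: float  # deg at which the reflection is fully excited
    rocking_width: float  # deg, FWHM of the excitation profile
    detector_center: tuple[float, float]  # (x, y) pixels
    footprint_sigma: float  # pixels, isotropic Gaussian spread
    expected_electrons: float

    def __post_init__(self) -> None:
        if self.rocking_width <= 0:
            raise ValueError("rocking_width must be positive")
        if self.footprint_sigma <= 0:
            raise ValueError("footprint_sigma must be positive")
        if self.expected_electrons < 0:
            raise ValueError("expected_electrons must be nonnegative")


@dataclass
class MovieStack:
    """Ordered summed counting images with rotation metadata.

    Invariant: osc_range[i] = rotation_rate x exposure[i] for every image,
    images share dimensions, and counts are nonnegative integers.
    """

    images: np.ndarray  # (n, h, w) integer counts
    osc_start: np.ndarray  # deg, stage angle at each image's first frame
    osc_range: np.ndarray  # deg spanned by each image
    exposure: np.ndarray  # s per image
    plan: AcquisitionPlan | None = None
    spec: DetectorSpec | None = None
    frames_per_image: np.ndarray | None = None  # non-reset frames contributing

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        self.osc_start = np.asarray(self.osc_start, dtype=float)
        self.osc_range = np.asarray(self.osc_range, dtype=float)
        self.exposure = np.asarray(self.exposure, dtype=float)
        n = self.images.shape[0]
        if not (len(self.osc_start) == len(self.osc_range) == len(self.exposure) == n):
            raise ValueError("metadata arrays must match the number of images")
        if self.images.size and np.any(self.images < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_images(self) -> int:
        return int(self.images.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.images.shape[1:])

    @property
    def total_counts(self) -> int:
        return int(self.images.sum())


def generate_reflection_schedule(
    n_spots: int,
    rotation_range: float,
    intensity_scale: float = 200.0,
    seed: int = 0,
    *,
    start_angle: float = 0.0,
    spec: DetectorSpec | None = None,
    rocking_width: float = 0.2,
    footprint_sigma: float = 2.0,
    beamstop_radius: float | None = None,
    edge_margin: float = 8.0,
) -> list[ReflectionEvent]:
    """Draw a random schedule of parametric reflections.

    Spot center angles are uniform over [start_angle, start_angle +
    rotation_range]; detector positions are uniform over the detector face
    excluding a central beam-stop disc of ``beamstop_radius`` pixels
    (default: 2% of the shorter detector side, ~40 px on a 2048-wide camera)
    and an ``edge_margin``-pixel border; expected electron budgets are
    exponential with mean ``intensity_scale`` (the acentric Wilson intensity
    distribution). Deterministic under a fixed seed.
    """
    if n_spots < 0:
        raise ValueError("n_spots must be nonnegative")
    if rotation_range <= 0:
        raise ValueError("rotation_range must be positive")
    spec = spec or DetectorSpec()
    if beamstop_radius is None:
        beamstop_radius = 0.02 * min(spec.width, spec.height)
    if 2 * edge_margin >= min(spec.width, spec.height):
        raise ValueError("edge_margin leaves no usable detector area")
    rng = np.random.default_rng(seed)
    cx, cy = spec.width / 2.0, spec.height / 2.0

    events: list[ReflectionEvent] = []
    for i in range(n_spots):
        angle = start_angle + rng.uniform(0.0, rotation_range)
        for _ in range(10_000):
            x = rng.uniform(edge_margin, spec.width - edge_margin)
            y = rng.uniform(edge_margin, spec.height - edge_margin)
            if math.hypot(x - cx, y - cy) > beamstop_radius:
                break
        else:
            raise ValueError(
                "beam-stop disc covers the usable detector face; "
                "reduce beamstop_radius or enlarge the detector"
            )
        events.append(
            ReflectionEvent(
                spot_id=f"spot_{i:04d}",
                center_angle=angle,
                rocking_width=rocking_width,
                detector_center=(x, y),
                footprint_sigma=footprint_sigma,
                expected_electrons=float(rng.exponential(intensity_scale)),
            )
        )
    return events


def _footprint(event: ReflectionEvent, spec: DetectorSpec):
    """Truncated, normalized 2-D Gaussian footprint and its pixel window.

    Returns (y_slice, x_slice, weights) or None when the footprint lies
    entirely off the detector face.
    """
    x0, y0 = event.detector_center
    r = _FOOTPRINT_TRUNC_SD * event.footprint_sigma
    xlo, xhi = int(math.floor(x0 - r)), int(math.ceil(x0 + r)) + 1
    ylo, yhi = int(math.floor(y0 - r)), int(math.ceil(y0 + r)) + 1
    xlo, xhi = max(xlo, 0), min(xhi, spec.width)
    ylo, yhi = max(ylo, 0), min(yhi, spec.height)
    if xlo >= xhi or ylo >= yhi:
        return None
    xs = np.arange(xlo, xhi) + 0.5
    ys = np.arange(ylo, yhi) + 0.5
    gx = np.exp(-0.5 * ((xs - x0) / event.footprint_sigma) ** 2)
    gy = np.exp(-0.5 * ((ys - y0) / event.footprint_sigma) ** 2)
    w = np.outer(gy, gx)
    total = w.sum()
    if total <= 0:
        return None
    return slice(ylo, yhi), slice(xlo, xhi), w / total


def _rocking_weights(
    event: ReflectionEvent, frame_angles_lo: np.ndarray, frame_angles_hi: np.ndarray
) -> np.ndarray:
    """Fraction of the (truncated) rocking profile falling in each frame."""
    sigma = event.rocking_width / _FWHM_TO_SIGMA
    lo = event.center_angle - _ROCKING_TRUNC_SD * sigma
    hi = event.center_angle + _ROCKING_TRUNC_SD * sigma
    a = np.clip(frame_angles_lo, lo, hi)
    b = np.clip(frame_angles_hi, lo, hi)
    cdf = norm(loc=event.center_angle, scale=sigma).cdf
    span = cdf(hi) - cdf(lo)
    return (cdf(b) - cdf(a)) / span


def simulate_movie(
    plan: AcquisitionPlan,
    spec: DetectorSpec,
    schedule: list[ReflectionEvent],
    background_rate: float = 0.0,
    seed: int = 0,
    return_frames: bool = False,
) -> MovieStack | tuple[MovieStack, np.ndarray]:
    """Simulate a continuous-rotation counting movie.

    For each non-reset raw frame, per-pixel arrival means are
    background_rate / frame_rate plus each active spot's contribution (its
    Gaussian footprint scaled by the fraction of its rocking profile swept
    during the frame). Arrivals are Poisson, independent across pixels and
    frames; each raw frame is binarized (at most one electron per pixel per
    frame) and frames are summed into images of ``plan.summation_window``
    seconds with reset frames excluded.

    ``background_rate`` is in electrons per pixel per second. With
    ``return_frames=True`` the raw counted frames (including reset slots,
    which carry no data) are returned too — intended for small grids only.
    """
    if background_rate < 0:
        raise ValueError("background_rate must be nonnegative")
    rng = np.random.default_rng(seed)
    n_raw = int(round(plan.exposure_time * spec.frame_rate))
    slots = int(round(plan.summation_window * spec.frame_rate))
    if slots < 1:
        raise ValueError("summation window must cover at least one raw frame")
    n_images = -(-n_raw // slots)
    h, w = spec.shape
    start = plan.wedge_start
    dphi = plan.rotation_rate / spec.frame_rate  # deg per raw frame

    frame_lo = start + dphi * np.arange(n_raw)
    frame_hi = frame_lo + dphi

    # precompute footprints and per-frame rocking weights per spot
    active: list[tuple[slice, slice, np.ndarray, np.ndarray]] = []
    for event in schedule:
        fp = _footprint(event, spec)
        if fp is None:
            warnings.warn(
                f"{event.spot_id}: footprint entirely off-detector; skipped",
                stacklevel=2,
            )
            continue
        ysl, xsl, weights = fp
        if plan.rotation_rate > 0:
            rock = _rocking_weights(event, frame_lo, frame_hi)
        else:
            rock = np.full(n_raw, 1.0 / n_raw)
        active.append((ysl, xsl, event.expected_electrons * weights, rock))

    bg_mean = background_rate / spec.frame_rate
    reset = spec.reset_mask(n_raw)
    images = np.zeros((n_images, h, w), dtype=np.int64)
    frames_per_image = np.zeros(n_images, dtype=int)
    raw_frames = np.zeros((n_raw, h, w), dtype=np.uint8) if return_frames else None

    for i in range(n_raw):
        if bg_mean > 0:
            arrivals = rng.poisson(bg_mean, size=(h, w))
        else:
            arrivals = np.zeros((h, w), dtype=np.int64)
        for ysl, xsl, fp_mean, rock in active:
            if rock[i] > 0:
                arrivals[ysl, xsl] += rng.poisson(fp_mean * rock[i])
        counted = count_frame(arrivals)
        if raw_frames is not None and not reset[i]:
            raw_frames[i] = counted
        if not reset[i]:
            j = i // slots
            images[j] += counted
            frames_per_image[j] += 1

    stack = MovieStack(
        images=images,
        osc_start=start + plan.rotation_rate * plan.summation_window * np.arange(n_images),
        osc_range=np.full(n_images, plan.rotation_rate * plan.summation_window),
        exposure=np.full(n_images, plan.summation_window),
        plan=plan,
        spec=spec,
        frames_per_image=frames_per_image,
    )
    if return_frames:
        return stack, raw_frames
    return stack


def simulate_flat_field(
    plan: AcquisitionPlan,
    spec: DetectorSpec,
    flux: float,
    illuminated_area: float,
    seed: int = 0,
) -> MovieStack:
    """Simulate a flat-field counting movie in imaging mode.

    ``flux`` (e-/A^2/s) over an illuminated specimen area of
    ``illuminated_area`` (A^2) is spread uniformly over the detector face,
    giving a per-pixel per-frame arrival mean of
    flux x area / (n_pixels x frame_rate). The counting and summation path
    is identical to :func:`simulate_movie`; used to calibrate flux via
    :func:`microedtk.geometry.estimate_flux`.
    """
    if flux < 0:
        raise ValueError("flux must be nonnegative")
    if illuminated_area <= 0:
        raise ValueError("illuminated_area must be positive")
    rng = np.random.default_rng(seed)
    n_raw = int(round(plan.exposure_time * spec.frame_rate))
    slots = int(round(plan.summation_window * spec.frame_rate))
    if slots < 1:
        raise ValueError("summation window must cover at least one raw frame")
    n_images = -(-n_raw // slots)
    h, w = spec.shape
    mean = flux * illuminated_area / (h * w * spec.frame_rate)
    reset = spec.reset_mask(n_raw)

    images = np.zeros((n_images, h, w), dtype=np.int64)
    frames_per_image = np.zeros(n_images, dtype=int)
    # chunk raw frames so the Poisson draw block stays modest
    block = max(1, int(2e7) // (h * w))
    i = 0
    while i < n_raw:
        m = min(block, n_raw - i)
        if mean > 0:
            counted = count_frame(rng.poisson(mean, size=(m, h, w)))
        else:
            counted = np.zeros((m, h, w), dtype=np.int64)
        for k in range(m):
            if not reset[i + k]:
                j = (i + k) // slots
                images[j] += counted[k]
                frames_per_image[j] += 1
        i += m

    return MovieStack(
        images=images,
        osc_start=np.zeros(n_images),
        osc_range=np.zeros(n_images),
        exposure=np.full(n_images, plan.summation_window),
        plan=plan,
        spec=spec,
        frames_per_image=frames_per_image,
    )
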