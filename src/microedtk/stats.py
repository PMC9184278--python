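"""Data-quality analytics for counting diffraction data.

Three views of quality:

* crystallographic merging statistics (R_merge, R_meas, R_pim, CC1/2, CC*,
  multiplicity, completeness, mean I/sigma) on grouped multi-observation
  reflection intensities;
* per-pixel occupancy histograms annotated with the closed-form
  coincidence-loss DQE, to judge whether an exposure stayed in the linear
  counting regime;
* line profiles through a Bragg spot with a peak-over-background summary.

The merging statistics follow the standard unmerged-intensity definitions:

    R_merge = sum_h sum_i |I_hi - <I_h>| / sum_h sum_i I_hi
    R_meas  = sum_h sqrt(n_h/(n_h-1)) sum_i |I_hi - <I_h>| / sum_h sum_i I_hi
    R_pim   = sum_h sqrt(1/(n_h-1))  sum_i |I_hi - <I_h>| / sum_h sum_i I_hi
    CC1/2   = Pearson correlation of random half-dataset group means
    CC*     = sqrt(2 CC1/2 / (1 + CC1/2))

where h runs over unique reflections with at least two observations and
<I_h> is the group mean. Negative intensities are kept in all sums.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .detector import DetectorSpec, expected_dqe
from .synth import MovieStack

__all__ = [
    "ObservationSet",
    "MergeStats",
    "OccupancyHistogram",
    "LineProfile",
    "InsufficientDataError",
    "merge_statistics",
    "pixel_histogram_dqe",
    "line_profile",
]


class InsufficientDataError(ValueError):
    """Raised when a statistic is undefined on the given observations."""


@dataclass
class ObservationSet:
    """Observed intensities grouped by unique reflection.

    ``groups`` maps a reflection identifier to its observed intensities;
    ``sigmas`` optionally carries matching per-observation uncertainties
    (all positive). ``expected_unique`` is the number of symmetry-unique
    reflections the experiment could have measured, used for completeness.
    """

    groups: dict
    sigmas: dict | None = None
    expected_unique: int | None = None

    def __post_init__(self) -> None:
        clean = {}
        for key, values in self.groups.items():
            arr = np.asarray(values, dtype=float)
            if arr.size == 0:
                raise ValueError(f"group {key!r} is empty")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"group {key!r} contains non-finite intensities")
            clean[key] = arr
        self.groups = clean
        if self.sigmas is not None:
            for key, values in self.sigmas.items():
                arr = np.asarray(values, dtype=float)
                if np.any(arr <= 0):
                    raise ValueError(f"sigmas for {key!r} must be positive")
                self.sigmas[key] = arr

    @classmethod
    def from_dataframe(cls, df, expected_unique: int | None = None) -> "ObservationSet":
        """Build from a table with columns reflection_id, intensity[, sigma]."""
        groups = {}
        sigmas = {} if "sigma" in df.columns else None
        for key, sub in df.groupby("reflection_id", sort=True):
            groups[key] = sub["intensity"].to_numpy(dtype=float)
            if sigmas is not None:
                sigmas[key] = sub["sigma"].to_numpy(dtype=float)
        return cls(groups=groups, sigmas=sigmas, expected_unique=expected_unique)

    @classmethod
    def from_csv(cls, path, expected_unique: int | None = None) -> "ObservationSet":
        import pandas as pd

        return cls.from_dataframe(pd.read_csv(path), expected_unique=expected_unique)

    @property
    def n_total(self) -> int:
        return int(sum(len(v) for v in self.groups.values()))

    @property
    def n_unique(self) -> int:
        return len(self.groups)


@dataclass
class MergeStats:
    """Merging-quality summary of an :class:`ObservationSet`."""

    r_merge: float
    r_meas: float
    r_pim: float
    cc_half: float
    cc_star: float
    mean_i_over_sigma: float
    multiplicity: float
    completeness: float
    n_total: int
    n_unique: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _cc_half(groups: dict, rng: np.random.Generator) -> float:
    """Pearson correlation between random half-dataset group means.

    Each group's observations are randomly split in two halves (odd groups
    drop one observation at random via the shuffle); groups need >= 2
    observations to be usable and >= 3 usable groups are required for a
    meaningful correlation.
    """
    half1, half2 = [], []
    for values in groups.values():
        if len(values) < 2:
            continue
        perm = rng.permutation(len(values))
        usable = len(values) - (len(values) % 2)
        take = perm[:usable]
        half = usable // 2
        half1.append(values[take[:half]].mean())
        half2.append(values[take[half:]].mean())
    if len(half1) < 3:
        raise InsufficientDataError(
            "CC1/2 needs at least 3 reflections with >= 2 observations"
        )
    a, b = np.asarray(half1), np.asarray(half2)
    sa, sb = a.std(), b.std()
    if sa == 0 and sb == 0 and np.allclose(a, b):
        return 1.0  # identical constant halves: perfect agreement
    if sa == 0 or sb == 0:
        raise InsufficientDataError("CC1/2 undefined: a half-dataset is constant")
    return float(np.corrcoef(a, b)[0, 1])


def cc_star(cc_half: float) -> float:
    """Analytic extrapolation of CC1/2 to the merged dataset's correlation."""
    if cc_half < 0:
        warnings.warn("CC1/2 < 0: CC* is undefined, returning NaN", stacklevel=2)
        return float("nan")
    return math.sqrt(2.0 * cc_half / (1.0 + cc_half))


def merge_statistics(
    obs: ObservationSet, seed: int = 0, on_insufficient_cc: str = "raise"
) -> MergeStats:
    """Compute merging statistics on grouped unmerged intensities.

    R-statistics sum over reflections observed at least twice (a single
    observation carries no internal-consistency information); multiplicity
    and completeness count every group. ``seed`` governs the random
    half-dataset split behind CC1/2, so a fixed seed is reproducible.

    CC1/2 needs at least three multiply-observed reflections; with fewer,
    ``on_insufficient_cc='raise'`` (default) raises
    :class:`InsufficientDataError` while ``'nan'`` records NaN and keeps
    the R-statistics.
    """
    rng = np.random.default_rng(seed)
    num_merge = num_meas = num_pim = denom = 0.0
    n_multi = 0
    for values in obs.groups.values():
        n = len(values)
        if n < 2:
            continue
        n_multi += 1
        dev = float(np.abs(values - values.mean()).sum())
        num_merge += dev
        num_meas += math.sqrt(n / (n - 1)) * dev
        num_pim += math.sqrt(1.0 / (n - 1)) * dev
        denom += float(values.sum())
    if n_multi == 0:
        raise InsufficientDataError(
            "R-statistics need at least one reflection with >= 2 observations"
        )
    if denom == 0:
        raise InsufficientDataError("R-statistics undefined: intensity sum is zero")

    try:
        cch = _cc_half(obs.groups, rng)
    except InsufficientDataError:
        if on_insufficient_cc != "nan":
            raise
        warnings.warn("too few multiply-observed reflections for CC1/2; recording NaN",
                      stacklevel=2)
        cch = float("nan")

    if obs.sigmas:
        ratios = [
            obs.groups[k] / obs.sigmas[k] for k in obs.groups if k in obs.sigmas
        ]
        mean_ios = float(np.concatenate(ratios).mean()) if ratios else float("nan")
    else:
        mean_ios = float("nan")

    completeness = (
        obs.n_unique / obs.expected_unique if obs.expected_unique else float("nan")
    )
    return MergeStats(
        r_merge=num_merge / denom,
        r_meas=num_meas / denom,
        r_pim=num_pim / denom,
        cc_half=cch,
        cc_star=cc_star(cch),
        mean_i_over_sigma=mean_ios,
        multiplicity=obs.n_total / obs.n_unique,
        completeness=completeness,
        n_total=obs.n_total,
        n_unique=obs.n_unique,
    )


@dataclass
class OccupancyHistogram:
    """Per-pixel occupancy histogram with expected coincidence-loss DQE."""

    occupancy: np.ndarray  # electrons per pixel per frame interval (bin values)
    frequency: np.ndarray  # number of (pixel, interval) cells at that occupancy
    dqe: np.ndarray  # expected DQE per bin; NaN at occupancy 0
    n_frames: int
    min_dqe: float  # minimum expected DQE over occupied nonzero bins (1.0 if none)


def pixel_histogram_dqe(stack, spec: DetectorSpec | None = None) -> OccupancyHistogram:
    """Histogram per-pixel counts per frame interval, annotated with DQE.

    Accepts a :class:`MovieStack` of summed images (uniform exposure
    required) or a raw (n, h, w) stack of counted frames. Counts are
    aggregated into consecutive intervals of one second of raw frames
    (``spec.frames_per_interval``); each occupancy bin n >= 1 is annotated
    with the closed-form expected DQE at that occupancy, and the minimum
    over occupied bins summarizes the worst coincidence loss in the data.
    """
    if isinstance(stack, MovieStack):
        spec = spec or stack.spec or DetectorSpec()
        if stack.n_images == 0:
            raise ValueError("stack is empty")
        exposures = np.asarray(stack.exposure)
        if not np.allclose(exposures, exposures[0]):
            raise ValueError("per-image exposures must be uniform")
        per_interval = max(1, int(round(1.0 / exposures[0])))
        images = np.asarray(stack.images)
    else:
        spec = spec or DetectorSpec()
        frames = np.asarray(stack)
        if frames.ndim != 3 or frames.shape[0] == 0:
            raise ValueError("expected a nonempty (n, h, w) frame stack")
        per_interval = spec.frames_per_interval
        images = frames

    n = images.shape[0]
    n_int = -(-n // per_interval)
    totals = np.stack(
        [images[j * per_interval : (j + 1) * per_interval].sum(axis=0) for j in range(n_int)]
    )
    freq = np.bincount(totals.astype(np.int64).ravel())
    occupancy = np.arange(len(freq))
    dqe = np.full(len(freq), np.nan)
    if len(freq) > 1:
        dqe[1:] = expected_dqe(occupancy[1:], spec.frames_per_interval)
    occupied = (freq > 0) & (occupancy >= 1)
    min_dqe = float(dqe[occupied].min()) if occupied.any() else 1.0
    return OccupancyHistogram(
        occupancy=occupancy,
        frequency=freq,
        dqe=dqe,
        n_frames=spec.frames_per_interval,
        min_dqe=min_dqe,
    )


@dataclass
class LineProfile:
    """Profile through a box with peak-over-background summaries."""

    positions: np.ndarray  # pixel coordinate along the long axis
    values: np.ndarray  # mean across the short axis at each position
    peak: float
    peak_position: int
    background: float
    peak_over_background: float
    i_over_sigma: float


def line_profile(image, box: tuple[int, int, int, int], axis: str = "x") -> LineProfile:
    """Profile a summed image through a rectangular box.

    ``box`` is (x0, y0, x1, y1), half-open. The profile is the mean across
    the short axis at each position along ``axis``; background is the median
    of the profile excluding a central third (where the spot sits). The
    reported I/sigma treats short-axis sums as Poisson counts:
    (peak - background) * m / sqrt(peak * m) for short-axis width m.
    """
    image = np.asarray(image)
    x0, y0, x1, y1 = box
    if not (0 <= x0 < x1 <= image.shape[1] and 0 <= y0 < y1 <= image.shape[0]):
        raise ValueError("box is degenerate or outside the image bounds")
    sub = image[y0:y1, x0:x1]
    if axis == "x":
        values = sub.mean(axis=0)
        positions = np.arange(x0, x1)
        m = sub.shape[0]
    elif axis == "y":
        values = sub.mean(axis=1)
        positions = np.arange(y0, y1)
        m = sub.shape[1]
    else:
        raise ValueError("axis must be 'x' or 'y'")

    n = len(values)
    third = n // 3
    lo, hi = third, n - third
    flank = np.concatenate([values[:lo], values[hi:]]) if n >= 3 else values
    background = float(np.median(flank))
    peak_idx = int(np.argmax(values))
    peak = float(values[peak_idx])
    pob = peak / background if background > 0 else float("inf") if peak > 0 else 1.0
    signal_sum = (peak - background) * m
    ios = signal_sum / math.sqrt(peak * m) if peak > 0 else 0.0
    return LineProfile(
        positions=positions,
        values=values,
        peak=peak,
        peak_position=int(positions[peak_idx]),
        background=background,
        peak_over_background=pob,
        i_over_sigma=float(ios),
    )
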