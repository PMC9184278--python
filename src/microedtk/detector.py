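"""Counting-detector model: per-frame binarized counting, reset frames,
coincidence-loss DQE, and cumulative damage accounting.

An electron-counting camera registers at most one electron per pixel per raw
frame. When two or more electrons strike the same pixel within one frame,
the extra events are lost ("coincidence loss") and the detective quantum
efficiency (DQE), defined here as counted electrons over incoming electrons
per pixel per frame interval, drops below 1. This module provides a seeded
Monte-Carlo simulation of that loss, its closed-form expectation (a
balls-in-bins occupancy problem), frame summation with periodic reset frames
excluded, and a ledger of lifetime per-pixel exposure against the sensor's
damage threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DetectorSpec",
    "DQECurve",
    "DamageLedger",
    "SummationResult",
    "expected_dqe",
    "simulate_pixel_dqe",
    "simulate_dqe_curve",
    "count_frame",
    "sum_frames",
    "accumulate_damage",
    "plot_dqe_curve",
]


@dataclass(frozen=True)
class DetectorSpec:
    """Physics constants of a counting camera.

    Defaults describe a 250 Hz direct electron detector whose sensor is read
    out twofold-binned to 2048 x 2048 pixels, resets on every 32nd raw frame,
    stores counts scaled by 32 in 16-bit stills, and whose per-pixel DQE
    deteriorates 10% after a lifetime exposure of 1.5e9 electrons.
    """

    frame_rate: float = 250.0  # raw frames per second
    reset_period: int = 32  # every reset_period-th raw frame carries no data
    width: int = 2048
    height: int = 2048
    gain_scale: int = 32  # counts-to-stored-value multiplier
    damage_threshold: float = 1.5e9  # electrons per pixel, DQE -10% point
    max_exposure: float = 420.0  # seconds, longest allowed acquisition

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.reset_period < 2:
            raise ValueError("reset_period must be >= 2")
        if self.gain_scale < 1:
            raise ValueError("gain_scale must be >= 1")
        if self.damage_threshold <= 0:
            raise ValueError("damage_threshold must be positive")
        if self.width < 1 or self.height < 1:
            raise ValueError("detector dimensions must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, columns) = (height, width)."""
        return (self.height, self.width)

    @property
    def frames_per_interval(self) -> int:
        """Raw frames in a one-second interval (the DQE simulation window)."""
        return int(round(self.frame_rate))

    def reset_mask(self, n_frames: int) -> np.ndarray:
        """Boolean mask over 0-based raw-frame indices; True marks resets.

        Frame i is a reset when (i + 1) % reset_period == 0, i.e. frames
        32, 64, ... in 1-based counting for the default period of 32.
        """
        idx = np.arange(n_frames)
        return (idx + 1) % self.reset_period == 0


@dataclass
class DQECurve:
    """Simulated DQE as a function of incoming electrons per pixel per interval."""

    n_in: np.ndarray  # incoming electrons per pixel per n_frames-interval
    dqe_mean: np.ndarray  # mean simulated DQE (dimensionless, <= 1)
    dqe_sd: np.ndarray  # standard deviation across repetitions
    n_frames: int  # frames per interval
    n_reps: int  # repetitions per n_in value

    def __post_init__(self) -> None:
        self.n_in = np.asarray(self.n_in)
        self.dqe_mean = np.asarray(self.dqe_mean, dtype=float)
        self.dqe_sd = np.asarray(self.dqe_sd, dtype=float)
        if not (len(self.n_in) == len(self.dqe_mean) == len(self.dqe_sd)):
            raise ValueError("n_in, dqe_mean, dqe_sd must have equal length")
        if np.any(self.dqe_mean <= 0) or np.any(self.dqe_mean > 1):
            raise ValueError("dqe_mean values must lie in (0, 1]")
        if np.any(self.dqe_sd < 0):
            raise ValueError("dqe_sd must be nonnegative")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"n_in": self.n_in, "dqe_mean": self.dqe_mean, "dqe_sd": self.dqe_sd}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_frames: int = 250, n_reps: int = 0) -> "DQECurve":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            n_in=df["n_in"].to_numpy(),
            dqe_mean=df["dqe_mean"].to_numpy(),
            dqe_sd=df["dqe_sd"].to_numpy(),
            n_frames=n_frames,
            n_reps=n_reps,
        )


@dataclass
class DamageLedger:
    """Lifetime per-pixel electron totals against the damage threshold."""

    cumulative_electrons: np.ndarray
    flagged_fraction: float = 0.0

    @classmethod
    def empty(cls, spec: DetectorSpec) -> "DamageLedger":
        return cls(np.zeros(spec.shape, dtype=np.float64), 0.0)


@dataclass
class SummationResult:
    """Output of sum_frames: summed images plus bookkeeping."""

    images: np.ndarray  # (n_images, h, w)
    frames_per_image: np.ndarray  # non-reset frames contributing per image
    partial_last: bool  # final image covered fewer raw-frame slots


def expected_dqe(n_in, n_frames: int = 250):
    """Expected DQE for ``n_in`` electrons landing uniformly on ``n_frames`` frames.

    With each of n_in electrons assigned to one of n_frames frames uniformly
    at random, the expected number of occupied frames is
    n_frames * (1 - (1 - 1/n_frames)**n_in), so

        E[DQE] = (n_frames / n_in) * (1 - (1 - 1/n_frames)**n_in).

    Strictly decreasing in n_in for fixed n_frames. Accepts scalars or arrays.
    """
    n_in = np.asarray(n_in)
    if np.any(n_in < 1):
        raise ValueError("n_in must be >= 1 (DQE is a ratio over incoming electrons)")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    out = (n_frames / n_in) * (1.0 - (1.0 - 1.0 / n_frames) ** n_in)
    # a single electron is always counted; keep that case exact
    out = np.where(n_in == 1, 1.0, out)
    return float(out) if out.ndim == 0 else out


def simulate_pixel_dqe(
    n_in: int,
    spec: DetectorSpec | None = None,
    n_reps: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    n_frames: int | None = None,
) -> tuple[float, float]:
    """Monte-Carlo DQE of a single pixel over one frame interval.

    Each repetition assigns each of ``n_in`` electrons to a uniformly random
    frame among ``n_frames`` (default: one second of raw frames, 250). The
    counted output N_out is the number of frames that received at least one
    electron, and DQE = N_out / n_in. Returns (mean, sd) over repetitions;
    sd uses the n-1 denominator (0.0 when n_reps == 1).

    Reset frames are deliberately not excluded from the candidate slots; the
    summation path models resets separately.
    """
    if n_in < 1:
        raise ValueError("n_in must be >= 1: DQE = N_out/N_in is undefined at 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if n_frames is None:
        n_frames = (spec or DetectorSpec()).frames_per_interval
    rng = np.random.default_rng(seed)

    dqe = np.empty(n_reps, dtype=np.float64)
    # chunk repetitions so the (reps, n_in) draw matrix stays modest
    chunk = max(1, int(2e7) // max(n_in, 1))
    done = 0
    while done < n_reps:
        m = min(chunk, n_reps - done)
        draws = rng.integers(0, n_frames, size=(m, n_in), dtype=np.int32)
        draws.sort(axis=1)
        n_out = 1 + np.count_nonzero(np.diff(draws, axis=1), axis=1)
        dqe[done : done + m] = n_out / n_in
        done += m
    mean = float(dqe.mean())
    sd = float(dqe.std(ddof=1)) if n_reps > 1 else 0.0
    return mean, sd


def simulate_dqe_curve(
    n_in_values,
    spec: DetectorSpec | None = None,
    n_reps: int = 1000,
    seed: int = 0,
    n_frames: int | None = None,
) -> DQECurve:
    """Simulate the DQE at each occupancy in ``n_in_values`` (seeded, reproducible)."""
    spec = spec or DetectorSpec()
    if n_frames is None:
        n_frames = spec.frames_per_interval
    n_in_values = np.asarray(n_in_values, dtype=int)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(n_in_values))
    means = np.empty(len(n_in_values))
    sds = np.empty(len(n_in_values))
    for i, (n, child) in enumerate(zip(n_in_values, children)):
        means[i], sds[i] = simulate_pixel_dqe(
            int(n), spec, n_reps=n_reps, seed=child, n_frames=n_frames
        )
    return DQECurve(n_in_values, means, sds, n_frames=n_frames, n_reps=n_reps)


def count_frame(arrivals) -> np.ndarray:
    """Binarize one raw frame: each pixel records at most one electron.

    Input is a grid of nonnegative integer arrival counts; output cells are
    min(count, 1), so the output total never exceeds the input total.
    """
    arrivals = np.asarray(arrivals)
    if np.any(arrivals < 0):
        raise ValueError("arrival counts must be nonnegative")
    return np.minimum(arrivals, 1)


def sum_frames(frames, spec: DetectorSpec, window: float) -> SummationResult:
    """Sum counted frames into images, excluding reset frames.

    ``frames`` is an ordered (n, h, w) stack of counted (0/1) frames covering
    consecutive raw-frame slots. Slots at reset positions are dropped; the
    remaining frames are partitioned into consecutive windows of
    ``window * frame_rate`` raw slots and summed elementwise. Total electrons
    are conserved: the images sum to the total of all non-reset frames.

    A final window covering fewer raw slots than the rest is flagged via
    ``partial_last`` (and a warning).
    """
    slots = window * spec.frame_rate
    if slots < 1:
        raise ValueError("window must cover at least one raw frame")
    slots = int(round(slots))

    frames = np.asarray(frames)
    if frames.size == 0:
        return SummationResult(
            images=np.zeros((0,) + frames.shape[1:], dtype=np.int64),
            frames_per_image=np.zeros(0, dtype=int),
            partial_last=False,
        )
    n = frames.shape[0]
    reset = spec.reset_mask(n)

    n_images = -(-n // slots)  # ceil
    h, w = frames.shape[1:]
    images = np.zeros((n_images, h, w), dtype=np.int64)
    contributing = np.zeros(n_images, dtype=int)
    for j in range(n_images):
        lo, hi = j * slots, min((j + 1) * slots, n)
        keep = ~reset[lo:hi]
        images[j] = frames[lo:hi][keep].sum(axis=0)
        contributing[j] = int(keep.sum())
    partial = n % slots != 0
    if partial:
        warnings.warn(
            f"final image covers only {n - (n_images - 1) * slots} of {slots} "
            "raw-frame slots",
            stacklevel=2,
        )
    return SummationResult(images, contributing, partial)


def accumulate_damage(
    ledger: DamageLedger, image, spec: DetectorSpec
) -> DamageLedger:
    """Add a summed image's electrons to the lifetime ledger.

    Returns a new ledger; per-pixel totals only ever increase. Emits a
    warning the first time any pixel crosses the damage threshold (the
    exposure at which that pixel's DQE is expected to have dropped 10%).
    """
    image = np.asarray(image)
    if image.shape != ledger.cumulative_electrons.shape:
        raise ValueError(
            f"image shape {image.shape} does not match ledger "
            f"{ledger.cumulative_electrons.shape}"
        )
    if np.any(image < 0):
        raise ValueError("image counts must be nonnegative")
    new_total = ledger.cumulative_electrons + image
    newly_flagged = np.count_nonzero(
        (new_total >= spec.damage_threshold)
        & (ledger.cumulative_electrons < spec.damage_threshold)
    )
    if newly_flagged:
        warnings.warn(
            f"{newly_flagged} pixel(s) crossed the damage threshold of "
            f"{spec.damage_threshold:g} electrons",
            stacklevel=2,
        )
    flagged = float(np.mean(new_total >= spec.damage_threshold))
    return DamageLedger(new_total, flagged)


def plot_dqe_curve(curve: DQECurve, ax=None, log_x: bool = True):
    """Plot a simulated DQE curve with a +/- 1 sd band."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.n_in, curve.dqe_mean, color="tab:blue", lw=1.5)
    ax.fill_between(
        curve.n_in,
        curve.dqe_mean - curve.dqe_sd,
        np.minimum(curve.dqe_mean + curve.dqe_sd, 1.0),
        alpha=0.3,
        color="tab:blue",
    )
    if log_x:
        ax.set_xscale("log")
    ax.set_xlabel(f"electrons per pixel per {curve.n_frames}-frame interval")
    ax.set_ylabel("DQE (counted / incoming)")
    ax.set_ylim(0, 1.05)
    return ax
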