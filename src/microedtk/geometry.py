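"""Acquisition planning arithmetic for continuous-rotation diffraction.

Electron wavelength, rotation coverage, per-image oscillation, dose scaling
with beam diameter, selected-area geometry, resolution at a detector radius
and flux calibration from flat-field counting movies. All angles are in
degrees, doses in e-/A^2, lengths at the detector in mm and beam diameters
in um unless noted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy import constants

__all__ = [
    "AcquisitionPlan",
    "RotationCoverage",
    "electron_wavelength",
    "rotation_coverage",
    "per_image_oscillation",
    "scale_dose_with_beam",
    "total_dose",
    "estimate_flux",
    "selected_area_diameter",
    "resolution_at_radius",
]


@dataclass(frozen=True)
class AcquisitionPlan:
    """Parameters of one continuous-rotation counting experiment.

    Defaults follow a low-fluence protocol on a 300 kV instrument: a 420 s
    exposure at 0.15 deg/s (a 63 deg wedge), images summed over 1.0 s, a
    20 um parallel beam, 960 mm nominal camera length with a 1.81x
    post-column magnification, and a 100 um selected-area aperture that
    isolates ~2 um at the specimen (demagnification 50).

    ``flux`` (e-/A^2/s) is optional and normally measured from a flat-field
    counting movie; ``pixel_size_mm`` is instrument-specific and has no
    factual default — set it before converting to still formats or computing
    resolution at a radius.
    """

    accelerating_voltage: float = 300.0  # kV
    rotation_rate: float = 0.15  # deg / s
    exposure_time: float = 420.0  # s
    summation_window: float = 1.0  # s per image
    beam_diameter: float = 20.0  # um
    flux: float | None = None  # e- / A^2 / s (measured)
    camera_length_nominal: float = 960.0  # mm
    post_column_magnification: float = 1.81
    selected_area_aperture: float = 100.0  # um
    sa_demagnification: float = 50.0
    start_angle: float | None = None  # deg; None -> symmetric wedge
    pixel_size_mm: float | None = None  # mm at the detector

    def __post_init__(self) -> None:
        for name in (
            "accelerating_voltage",
            "exposure_time",
            "summation_window",
            "beam_diameter",
            "camera_length_nominal",
            "post_column_magnification",
            "selected_area_aperture",
            "sa_demagnification",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rotation_rate < 0:
            raise ValueError("rotation_rate must be nonnegative")
        if self.summation_window > self.exposure_time:
            raise ValueError("summation_window cannot exceed exposure_time")
        if self.flux is not None and self.flux < 0:
            raise ValueError("flux must be nonnegative")
        if self.pixel_size_mm is not None and self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")

    @property
    def wavelength(self) -> float:
        """Relativistic electron wavelength in Angstrom."""
        return electron_wavelength(self.accelerating_voltage)

    @property
    def total_rotation(self) -> float:
        """Total wedge in degrees: rate x exposure time."""
        return self.rotation_rate * self.exposure_time

    @property
    def osc_per_image(self) -> float:
        """Oscillation spanned by one summed image, degrees."""
        return per_image_oscillation(self.rotation_rate, self.summation_window)

    @property
    def effective_distance(self) -> float:
        """Sample-to-detector distance in mm: nominal x post-column magnification."""
        return self.camera_length_nominal * self.post_column_magnification

    @property
    def wedge_start(self) -> float:
        if self.start_angle is not None:
            return self.start_angle
        return -self.total_rotation / 2.0

    @property
    def n_images(self) -> int:
        return int(round(self.exposure_time / self.summation_window))

    def with_flux(self, flux: float) -> "AcquisitionPlan":
        return replace(self, flux=flux)

    @classmethod
    def from_config(cls, path) -> "AcquisitionPlan":
        """Read a plain-text ``key = value`` config (``#`` starts a comment)."""
        values: dict[str, float] = {}
        fields = set(cls.__dataclass_fields__)
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, val = (s.strip() for s in line.split("=", 1))
                if key not in fields:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                values[key] = float(val)
        return cls(**values)


class RotationCoverage(NamedTuple):
    degrees: float
    wedge_start: float
    wedge_stop: float


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic de Broglie wavelength of an electron, in Angstrom.

    lambda = h / sqrt(2 m0 e V (1 + e V / (2 m0 c^2)))

    with CODATA constants. 300 kV gives 0.0197 A to three significant
    figures; the relativistic correction vanishes as V -> 0.
    """
    if voltage_kv <= 0:
        raise ValueError("accelerating voltage must be positive")
    v = voltage_kv * 1e3
    ev = constants.e * v
    lam = constants.h / math.sqrt(
        2 * constants.m_e * ev * (1 + ev / (2 * constants.m_e * constants.c**2))
    )
    return lam * 1e10


def rotation_coverage(
    rate: float, time: float, start_angle: float | None = None
) -> RotationCoverage:
    """Total rotation in degrees plus the wedge it spans.

    With no explicit start angle the wedge is symmetric about zero, e.g.
    0.2 deg/s for 420 s covers 84 deg, spanning -42 to +42 deg.
    """
    if rate < 0 or time < 0:
        raise ValueError("rate and time must be nonnegative")
    coverage = rate * time
    if start_angle is None:
        return RotationCoverage(coverage, -coverage / 2.0, coverage / 2.0)
    return RotationCoverage(coverage, start_angle, start_angle + coverage)


def per_image_oscillation(rate: float, window: float) -> float:
    """Degrees of rotation spanned by one summed image: rate x window."""
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    if window <= 0:
        raise ValueError("window must be positive")
    return rate * window


def scale_dose_with_beam(dose: float, from_diameter: float, to_diameter: float) -> float:
    """Rescale a fluence when the beam is condensed or spread.

    A fixed total current spread uniformly over the beam disc gives a fluence
    proportional to 1/diameter^2: dose x (from/to)^2. Spreading 20 -> 25 um
    reduces 1.0 e-/A^2 to 0.64 e-/A^2.
    """
    if from_diameter <= 0 or to_diameter <= 0:
        raise ValueError("beam diameters must be positive")
    if dose < 0:
        raise ValueError("dose must be nonnegative")
    return dose * (from_diameter / to_diameter) ** 2


def total_dose(plan: AcquisitionPlan) -> float:
    """Total fluence of the experiment: flux x exposure time, in e-/A^2."""
    if plan.flux is None:
        raise ValueError("plan.flux is not set; measure it with estimate_flux")
    return plan.flux * plan.exposure_time


def estimate_flux(flat_field, illuminated_area: float) -> float:
    """Calibrate flux (e-/A^2/s) from one or more flat-field counting movies.

    The estimate is total recorded electrons divided by the illuminated
    specimen area (A^2) and the effective counting time; passing several
    repeat stacks pools counts and time, i.e. averages the repeats.

    Reset frames record nothing while the specimen is still illuminated, so
    the wall-clock exposure overstates the counting time by 1/reset_period.
    When a stack carries ``frames_per_image`` bookkeeping (and a detector
    spec) the exact non-reset frame count is used; otherwise the wall-clock
    exposure is taken as-is.
    """
    if illuminated_area <= 0:
        raise ValueError("illuminated_area must be positive")
    stacks = flat_field if isinstance(flat_field, (list, tuple)) else [flat_field]
    if not stacks:
        raise ValueError("at least one flat-field stack is required")
    total_counts = 0.0
    total_time = 0.0
    for stack in stacks:
        if stack.n_images == 0:
            raise ValueError("flat-field stack is empty")
        total_counts += float(stack.images.sum())
        if stack.frames_per_image is not None and stack.spec is not None:
            total_time += float(np.sum(stack.frames_per_image)) / stack.spec.frame_rate
        else:
            total_time += float(np.sum(stack.exposure))
    if total_time <= 0:
        raise ValueError("total exposure time must be positive")
    return total_counts / (illuminated_area * total_time)


def selected_area_diameter(aperture: float, demagnification: float) -> float:
    """Diameter at the specimen isolated by a selected-area aperture, um.

    A 100 um aperture with the default demagnification of 50 isolates a
    region about 2 um across.
    """
    if aperture <= 0 or demagnification <= 0:
        raise ValueError("aperture and demagnification must be positive")
    return aperture / demagnification


def resolution_at_radius(
    radius: float, pixel_size: float, plan: AcquisitionPlan
) -> float:
    """d-spacing (A) diffracting to a given radius (pixels) on the detector.

    Uses the Bragg relation with the effective distance
    D = camera_length_nominal x post_column_magnification:
    theta = arctan(radius x pixel_size / D) / 2, d = lambda / (2 sin theta).
    """
    if radius <= 0:
        raise ValueError("radius must be positive (d -> infinity at 0)")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    two_theta = math.atan(radius * pixel_size / plan.effective_distance)
    return plan.wavelength / (2.0 * math.sin(two_theta / 2.0))
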