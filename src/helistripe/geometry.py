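"""Scanner geometry, acquisition parameters and the closed-form relations
between them.

All lengths are millimetres; angles are degrees at every public interface
(radians are used only inside trigonometric calls).  The coordinate frame is
the unwrapped cylinder: ``z`` is the slice (table-travel) direction, ``u`` is
the unwrapped circumference.

The central quantities
----------------------
* *FID* / *FSD* — focus-to-isocenter and focus-to-(plate) surface distances.
  A width measured on the entrance surface of the cylindrical plate is
  magnified to the rotation center by the ratio FID/FSD.
* *feed per rotation* — table travel per gantry rotation,
  ``pitch x nominal collimation``.
* *stripe tilt* — on the unwrapped cylinder one gantry rotation draws one
  stripe, tilted by ``arctan(feed / circumference)`` from the circumferential
  axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

__all__ = [
    "ScannerGeometry",
    "AcquisitionParams",
    "BeamModel",
    "feed_per_rotation",
    "stripe_tilt_angle",
    "correct_beam_width",
    "dose_efficiency",
    "stripes_separable",
]


def _from_dict(cls, data: dict):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"{cls.__name__}: unknown keys {sorted(unknown)}; expected a subset of {sorted(known)}"
        )
    return cls(**data)


@dataclass(frozen=True)
class ScannerGeometry:
    """Fixed geometry of the scanner and the cylindrical plate holder.

    Parameters
    ----------
    fid : float
        Focus-to-isocenter distance (mm).
    plate_radius : float
        Radius of the cylindrical plate holder (mm).  250 mm for a plate
        wrapped around a 500-mm diameter phantom.
    focal_spot_z : float
        z-extent of the focal spot (mm); sets the scale of the beam penumbra.
    focus_collimator_distance : float
        Distance from the focus to the z-collimator blades (mm).
    """

    fid: float = 600.0
    plate_radius: float = 250.0
    focal_spot_z: float = 1.0
    focus_collimator_distance: float = 200.0

    def __post_init__(self):
        if not (self.fid > self.plate_radius > 0):
            raise ValueError("require fid > plate_radius > 0")
        if self.focal_spot_z < 0:
            raise ValueError("focal_spot_z must be >= 0")
        if not (0 < self.focus_collimator_distance < self.fid - self.plate_radius):
            raise ValueError("require 0 < focus_collimator_distance < fid - plate_radius")

    @property
    def fsd(self) -> float:
        """Focus-to-surface distance (mm): the beam-entrance surface of the
        cylinder, ``fid - plate_radius``."""
        return self.fid - self.plate_radius

    @property
    def magnification(self) -> float:
        """Plate-to-isocenter width magnification FID/FSD."""
        return self.fid / self.fsd

    @property
    def circumference(self) -> float:
        return 2.0 * math.pi * self.plate_radius

    def to_dict(self) -> dict:
        return {
            "fid": self.fid,
            "plate_radius": self.plate_radius,
            "focal_spot_z": self.focal_spot_z,
            "focus_collimator_distance": self.focus_collimator_distance,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ScannerGeometry":
        return _from_dict(cls, data)


@dataclass(frozen=True)
class AcquisitionParams:
    """Helical acquisition settings.

    ``pitch`` is table feed per rotation divided by the nominal collimation;
    ``scan_range_d`` is the planned scan range ``d`` (the image range set at
    the console); ``ramp_rotations`` is the duration, in gantry rotations, of
    the active-collimator opening/closing ramp at each end of the scan.
    """

    nominal_collimation: float
    pitch: float
    scan_range_d: float
    rotation_time: float = 0.5
    active_collimator: bool = False
    ramp_rotations: float = 0.5

    def __post_init__(self):
        for name in ("nominal_collimation", "pitch", "scan_range_d", "rotation_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.ramp_rotations < 0:
            raise ValueError("ramp_rotations must be >= 0")

    @property
    def feed(self) -> float:
        """Table feed per rotation (mm)."""
        return feed_per_rotation(self.pitch, self.nominal_collimation)

    def to_dict(self) -> dict:
        return {
            "nominal_collimation": self.nominal_collimation,
            "pitch": self.pitch,
            "scan_range_d": self.scan_range_d,
            "rotation_time": self.rotation_time,
            "active_collimator": self.active_collimator,
            "ramp_rotations": self.ramp_rotations,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "AcquisitionParams":
        return _from_dict(cls, data)


@dataclass(frozen=True)
class BeamModel:
    """Trapezoidal z-aperture of the beam at the isocenter.

    ``actual_bw_iso`` is the FWHM of the trapezoid (the actual beam width,
    nominal collimation plus overbeaming); ``penumbra_iso`` is the width of
    each linear flank.  The flat top (umbra) is
    ``actual_bw_iso - penumbra_iso`` and must be non-negative.
    """

    actual_bw_iso: float
    penumbra_iso: float = 3.0

    def __post_init__(self):
        if self.actual_bw_iso <= 0:
            raise ValueError("actual_bw_iso must be > 0")
        if self.penumbra_iso < 0:
            raise ValueError("penumbra_iso must be >= 0")
        if self.umbra < 0:
            raise ValueError("penumbra_iso may not exceed actual_bw_iso (umbra < 0)")

    @property
    def umbra(self) -> float:
        """Width of the flat top of the trapezoid (mm)."""
        return self.actual_bw_iso - self.penumbra_iso

    @property
    def base(self) -> float:
        """Full base of the trapezoid (mm): umbra + 2 penumbras."""
        return self.actual_bw_iso + self.penumbra_iso

    @property
    def fwtm(self) -> float:
        """Full width at tenth maximum of the aperture (mm)."""
        return self.umbra + 1.8 * self.penumbra_iso

    def to_dict(self) -> dict:
        return {"actual_bw_iso": self.actual_bw_iso, "penumbra_iso": self.penumbra_iso}

    @classmethod
    def from_dict(cls, data: dict) -> "BeamModel":
        return _from_dict(cls, data)


def feed_per_rotation(pitch: float, nominal_collimation: float) -> float:
    """Table feed per gantry rotation (mm): ``pitch x nominal_collimation``."""
    if pitch < 0 or nominal_collimation < 0:
        raise ValueError("pitch and nominal_collimation must be non-negative")
    return pitch * nominal_collimation


def stripe_tilt_angle(feed: float, plate_radius: float) -> float:
    """Tilt of the helical stripe on the unwrapped cylinder, in degrees.

    One rotation advances the table by ``feed`` while sweeping one
    circumference ``2 pi plate_radius``, so the stripe rises at
    ``arctan(feed / circumference)``.
    """
    if plate_radius <= 0:
        raise ValueError("plate_radius must be > 0")
    if feed < 0:
        raise ValueError("feed must be >= 0")
    return math.degrees(math.atan2(feed, 2.0 * math.pi * plate_radius))


def correct_beam_width(fwhm_plate: float, geometry: ScannerGeometry) -> float:
    """Magnify a FWHM measured on the plate surface to the rotation center:
    ``BW = FWHM x FID / FSD``."""
    if not math.isfinite(fwhm_plate) or fwhm_plate <= 0:
        raise ValueError("fwhm_plate must be a positive finite length")
    return fwhm_plate * geometry.fid / geometry.fsd


def dose_efficiency(nominal_bw: float, actual_bw: float) -> float:
    """Fraction of the emitted beam used for imaging: nominal / actual width."""
    if nominal_bw <= 0 or actual_bw <= 0:
        raise ValueError("beam widths must be > 0")
    return nominal_bw / actual_bw


def stripes_separable(
    beam: BeamModel, geometry: ScannerGeometry, acquisition: AcquisitionParams
) -> bool:
    """Whether adjacent stripes are disjoint on the plate.

    The stripe footprint along z on the plate is the beam base projected to
    the entrance surface, ``base x FSD / FID``.  Adjacent rotations are
    ``feed`` apart, so the stripes separate iff the footprint is strictly
    smaller than the feed.  A large plate radius shrinks FSD/FID and keeps
    stripes separable even at pitch < 1.
    """
    feed = acquisition.feed
    if feed <= 0:
        return False
    footprint = beam.base * geometry.fsd / geometry.fid
    return footprint < feed
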