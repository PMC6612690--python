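"""Forward model of helical stripe images on a cylindrical imaging plate.

The source moves on a helix: the gantry angle advances uniformly while the
beam center z advances by one table feed per rotation.  Each point of the
cylindrical plate accumulates entrance exposure while it faces the source,
weighted by

* inverse-square distance to the focus,
* incidence obliquity (cosine between the ray and the surface normal,
  floored at zero — grazing rays contribute nothing),
* an in-plane fan fluence profile, Gaussian in the ray's impact parameter
  at the isocenter (half value at ``fan_half_value_mm``), emulating the
  scanner's beam-shaping filter — without it, near-tangent rays fill the
  gaps between stripes, which contradicts the cleanly separated stripes a
  large-radius plate records at pitch < 1,
* the trapezoidal z-aperture evaluated at the ray's z-offset scaled to the
  isocenter, clipped by the z-collimator blade positions.

Exposure is entrance-only: the 500-mm acrylic phantom inside the plate
cylinder attenuates the exit beam to negligible levels, so only the first
intersection of each ray with the cylinder is recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .geometry import AcquisitionParams, BeamModel, ScannerGeometry, _from_dict, stripe_tilt_angle
from .image import PlateSet, StripeImage
from .profiles import PeakNotResolvedError, Profile, measure_fwtm

__all__ = [
    "GridSpec",
    "SimulationTruth",
    "aperture_profile",
    "collimator_schedule",
    "simulate_stripe_image",
    "simulate_flat_profile",
    "encode_pv",
    "split_into_plates",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class GridSpec:
    """Sampling grid of the unwrapped plate.

    ``u_extent`` defaults to the full circumference; ``z_extent`` defaults
    to automatic sizing that covers the whole exposed length plus a margin.
    When given, the z window is centered on the middle of the scan range.
    """

    pixel_spacing: float = 0.2
    u_extent: Optional[float] = None
    z_extent: Optional[float] = None

    def __post_init__(self):
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")
        if self.u_extent is not None and self.u_extent <= 0:
            raise ValueError("u_extent must be > 0")
        if self.z_extent is not None and self.z_extent <= 0:
            raise ValueError("z_extent must be > 0")

    def to_dict(self) -> dict:
        return {"pixel_spacing": self.pixel_spacing, "u_extent": self.u_extent,
                "z_extent": self.z_extent}

    @classmethod
    def from_dict(cls, data: dict) -> "GridSpec":
        return _from_dict(cls, data)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of one simulated acquisition.

    ``exposure_length`` is the FWTM of the noiseless column-mean z-profile;
    ``overranging_true = (exposure_length - d) / 2``.  For a non-helical
    flat-plate simulation ``overranging_true`` is None.
    """

    actual_bw_iso: float
    exposure_length: float
    overranging_true: Optional[float]
    tilt_true: float

    def to_dict(self) -> dict:
        return {
            "actual_bw_iso": self.actual_bw_iso,
            "exposure_length": self.exposure_length,
            "overranging_true": self.overranging_true,
            "tilt_true": self.tilt_true,
        }


def aperture_profile(z_off_iso, beam: BeamModel):
    """Relative beam intensity at z-offset ``z_off_iso`` (mm) from the beam
    center plane, at the isocenter.

    Symmetric trapezoid: 1 over the umbra, linear penumbra ramps, 0 outside
    the base.  Its FWHM equals ``beam.actual_bw_iso`` exactly.
    """
    z = np.abs(np.asarray(z_off_iso, dtype=float))
    if beam.penumbra_iso > 0:
        out = np.clip((beam.base / 2.0 - z) / beam.penumbra_iso, 0.0, 1.0)
    else:
        out = (z <= beam.actual_bw_iso / 2.0).astype(float)
    return out if out.ndim else float(out)


def collimator_schedule(
    z_table: float, acquisition: AcquisitionParams, beam: BeamModel
) -> Tuple[float, float]:
    """z-collimator blade edges (mm at isocenter) for beam center ``z_table``.

    Without the active collimator the aperture is fully open,
    ``z_table ± base/2``.  With it, while the beam center is within
    ``ramp_rotations`` rotations of a range boundary, the blade on the
    outside of the scan range is clamped at that boundary: the lower edge at
    z = 0 during the opening ramp, the upper edge at z = d during the
    closing ramp.  When the beam center sits exactly on a boundary the
    exposed width is half the fully open width.  Mid-scan both edges are
    fully open.
    """
    half = beam.base / 2.0
    lower = z_table - half
    upper = z_table + half
    if acquisition.active_collimator:
        ramp = acquisition.ramp_rotations * acquisition.feed
        if z_table <= ramp:
            lower = max(lower, 0.0)
        if z_table >= acquisition.scan_range_d - ramp:
            upper = min(upper, acquisition.scan_range_d)
    return lower, upper


def _fan_weight(dphi: np.ndarray, fid: float, radius: float,
                dist: np.ndarray, fan_half_value_mm: Optional[float]) -> np.ndarray:
    """In-plane fan fluence at the ray's isocenter impact parameter."""
    if fan_half_value_mm is None:
        return np.ones_like(dist)
    p = fid * radius * np.abs(np.sin(dphi)) / dist
    return np.exp(-_LN2 * (p / fan_half_value_mm) ** 2)


def simulate_stripe_image(
    geometry: ScannerGeometry,
    beam: BeamModel,
    acquisition: AcquisitionParams,
    grid: Optional[GridSpec] = None,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    *,
    theta_step_deg: float = 0.5,
    lead_rotations: float = 0.5,
    start_angle_deg: float = 0.0,
    fan_half_value_mm: Optional[float] = 80.0,
    exposure_peak: float = 1000.0,
) -> Tuple[StripeImage, SimulationTruth]:
    """Accumulate entrance exposure on the unwrapped cylinder.

    The exposure starts with the beam center ``base/2 + lead_rotations x
    feed`` before the scan range and ends symmetrically after it: the fully
    open beam base clears the range boundary, plus the extra rotations
    helical reconstruction needs at each end.  This lead-in/out — not the
    scan range alone — determines the ground-truth exposure length, which is
    why overranging grows with pitch and collimation.

    Returns the image in exposure units (peak normalised to
    ``exposure_peak``) and the ground truth.  ``noise_sd`` adds seeded
    multiplicative Gaussian noise on E (relative SD), which is additive on
    the log-encoded pixel value.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if theta_step_deg <= 0:
        raise ValueError("theta_step_deg must be > 0")
    if lead_rotations < 0:
        raise ValueError("lead_rotations must be >= 0")
    grid = grid or GridSpec()

    fid = geometry.fid
    radius = geometry.plate_radius
    circ = geometry.circumference
    feed = acquisition.feed
    d = acquisition.scan_range_d
    base = beam.base
    pen = beam.penumbra_iso
    s = grid.pixel_spacing

    u_extent = grid.u_extent if grid.u_extent is not None else circ
    if u_extent > circ * (1.0 + 1e-6) + s:
        raise ValueError("u_extent exceeds the plate circumference")
    n_u = max(8, int(round(u_extent / s)))
    u_len = n_u * s
    full_wrap = abs(u_len - circ) <= s

    max_dist = math.sqrt(fid * fid - radius * radius)
    z_half_plate = (base / 2.0) * max_dist / fid  # largest |z - z_c| reached on the plate

    zc0 = -(base / 2.0 + lead_rotations * feed)
    zc1 = d + base / 2.0 + lead_rotations * feed
    if grid.z_extent is None:
        margin = max(5.0 * s, 2.0)
        z_lo = zc0 - z_half_plate - margin
        z_hi = zc1 + z_half_plate + margin
    else:
        z_lo = d / 2.0 - grid.z_extent / 2.0
        z_hi = d / 2.0 + grid.z_extent / 2.0
    n_z = max(8, int(round((z_hi - z_lo) / s)))

    warnings_list = []
    pen_plate = pen * geometry.fsd / fid
    if pen > 0 and s > pen_plate:
        warnings_list.append(
            f"pixel spacing {s} mm exceeds the plate-level penumbra {pen_plate:.3f} mm; "
            "the penumbra is under-resolved"
        )

    E = np.zeros((n_z, n_u), dtype=np.float64)
    z_centers = z_lo + (np.arange(n_z) + 0.5) * s
    u_centers = (np.arange(n_u) + 0.5) * s
    phi = u_centers / radius

    alpha_max = math.acos(radius / fid)
    dth = math.radians(theta_step_deg)
    n_steps = int(math.ceil((zc1 - zc0) / feed * 2.0 * math.pi / dth)) + 1
    start_angle = math.radians(start_angle_deg)
    inv_pen = 1.0 / pen if pen > 0 else None
    band_half_u = alpha_max * radius

    for t in range(n_steps):
        theta = start_angle + t * dth
        zc = zc0 + feed * (t * dth) / (2.0 * math.pi)
        if zc > zc1:
            break
        lower, upper = collimator_schedule(zc, acquisition, beam)
        if upper <= lower:
            continue
        i0 = max(0, int(math.floor((zc - z_half_plate - z_lo) / s)))
        i1 = min(n_z, int(math.ceil((zc + z_half_plate - z_lo) / s)) + 1)
        if i0 >= i1:
            continue
        zr = z_centers[i0:i1, None] - zc

        u_src = (radius * theta) % circ
        clamped = acquisition.active_collimator and (
            lower > zc - base / 2.0 + 1e-12 or upper < zc + base / 2.0 - 1e-12
        )
        for off in (-circ, 0.0, circ):
            a = u_src - band_half_u + off
            b = u_src + band_half_u + off
            j0 = max(0, int(math.ceil(a / s - 0.5)))
            j1 = min(n_u - 1, int(math.floor(b / s - 0.5)))
            if j0 > j1:
                continue
            dphi = phi[j0 : j1 + 1] - (theta - off / radius)
            dphi = (dphi + math.pi) % (2.0 * math.pi) - math.pi
            cosd = np.cos(dphi)
            obl = fid * cosd - radius
            np.clip(obl, 0.0, None, out=obl)
            dist2 = fid * fid + radius * radius - 2.0 * fid * radius * cosd
            dist = np.sqrt(dist2)
            w = obl / (dist2 * dist)
            w *= _fan_weight(dphi, fid, radius, dist, fan_half_value_mm)
            w *= dth
            scale = fid / dist
            dz = zr * scale[None, :]
            if inv_pen is not None:
                ap = np.clip((base / 2.0 - np.abs(dz)) * inv_pen, 0.0, 1.0)
            else:
                ap = (np.abs(dz) <= beam.actual_bw_iso / 2.0).astype(float)
            if clamped:
                z_iso = dz + zc
                ap *= (z_iso >= lower) & (z_iso <= upper)
            E[i0:i1, j0 : j1 + 1] += w[None, :] * ap

    peak = float(E.max())
    if peak <= 0:
        raise RuntimeError("simulation produced no exposure; check grid and parameters")
    E *= exposure_peak / peak

    zprof = Profile(E.mean(axis=1), spacing=s, axis="z", start=z_lo + 0.5 * s)
    exposure_length = measure_fwtm(zprof)
    truth = SimulationTruth(
        actual_bw_iso=beam.actual_bw_iso,
        exposure_length=exposure_length,
        overranging_true=(exposure_length - d) / 2.0,
        tilt_true=stripe_tilt_angle(feed, radius),
    )

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        E *= np.clip(1.0 + noise_sd * rng.standard_normal(E.shape), 0.0, None)

    meta = {
        "geometry": geometry.to_dict(),
        "acquisition": acquisition.to_dict(),
        "beam": beam.to_dict(),
        "grid": grid.to_dict(),
        "truth": truth.to_dict(),
        "seed": seed,
        "noise_sd": noise_sd,
        "theta_step_deg": theta_step_deg,
        "lead_rotations": lead_rotations,
        "start_angle_deg": start_angle_deg,
        "fan_half_value_mm": fan_half_value_mm,
        "exposure_peak": exposure_peak,
        "full_circumference": full_wrap,
        "units": "E",
        "axis_convention": "rows = z increasing with table feed; columns = unwrapped circumference",
        "warnings": warnings_list,
    }
    if acquisition.active_collimator:
        # stripes whose beam-center z fell inside a collimator ramp are tapered
        ramp = acquisition.ramp_rotations * feed
        meta["taper_zones"] = [
            [zc0 - base, ramp + pen],
            [d - ramp - pen, zc1 + base],
        ]
    image = StripeImage(E, pixel_spacing=s, units="E", z_origin=z_lo, u_origin=0.0, meta=meta)
    return image, truth


def simulate_flat_profile(
    beam: BeamModel,
    acquisition: Optional[AcquisitionParams] = None,
    *,
    helical: bool = False,
    spacing: float = 0.2,
    lead_rotations: float = 0.5,
) -> Tuple[Profile, SimulationTruth]:
    """Dose z-profile on a flat plate at the rotation center (conventional mode).

    At the isocenter every ray crosses with its nominal z-offset, so a
    non-helical (stationary-table) rotation records the aperture trapezoid
    itself and the FWHM equals the actual beam width with unit
    magnification.  A helical run sweeps the (collimator-clipped) aperture
    along z at constant speed, giving the conventional overranging profile.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    base = beam.base
    if not helical:
        z = np.arange(-base, base + spacing, spacing)
        vals = aperture_profile(z, beam)
        prof = Profile(np.asarray(vals), spacing=spacing, axis="z", start=float(z[0]))
        return prof, SimulationTruth(
            actual_bw_iso=beam.actual_bw_iso,
            exposure_length=measure_fwtm(prof),
            overranging_true=None,
            tilt_true=0.0,
        )

    if acquisition is None:
        raise ValueError("helical flat-plate simulation requires acquisition parameters")
    feed = acquisition.feed
    d = acquisition.scan_range_d
    zc0 = -(base / 2.0 + lead_rotations * feed)
    zc1 = d + base / 2.0 + lead_rotations * feed
    margin = max(5.0 * spacing, 2.0)
    z = np.arange(zc0 - base / 2.0 - margin, zc1 + base / 2.0 + margin, spacing)
    step = spacing / 4.0
    vals = np.zeros_like(z)
    for zc in np.arange(zc0, zc1 + step / 2.0, step):
        lower, upper = collimator_schedule(zc, acquisition, beam)
        if upper <= lower:
            continue
        ap = aperture_profile(z - zc, beam)
        vals += ap * ((z >= lower) & (z <= upper)) * step
    prof = Profile(vals, spacing=spacing, axis="z", start=float(z[0]))
    fwtm = measure_fwtm(prof)
    return prof, SimulationTruth(
        actual_bw_iso=beam.actual_bw_iso,
        exposure_length=fwtm,
        overranging_true=(fwtm - d) / 2.0,
        tilt_true=0.0,
    )


def encode_pv(image_E: StripeImage, gray_level_G: float = 1024.0, bit_depth: int = 16) -> StripeImage:
    """Log-encode exposure to computed-radiography pixel values:
    ``PV = G log10(E)``, clipped to the container range and quantised.

    Non-positive exposures map to PV 0; their count is recorded in the
    metadata (``n_nonpositive``).
    """
    if image_E.units != "E":
        raise ValueError("encode_pv expects an image in exposure units")
    if gray_level_G <= 0:
        raise ValueError("gray level G must be > 0")
    if not 1 <= bit_depth <= 16:
        raise ValueError("bit_depth must be between 1 and 16")
    E = np.asarray(image_E.values, dtype=float)
    positive = E > 0
    pv = np.zeros_like(E)
    pv[positive] = gray_level_G * np.log10(E[positive])
    pv = np.clip(pv, 0.0, 2.0**bit_depth - 1.0)
    pv = np.rint(pv).astype(np.uint16)
    meta = dict(image_E.meta)
    meta.update(
        units="PV",
        gray_level=gray_level_G,
        bit_depth=bit_depth,
        n_nonpositive=int(np.count_nonzero(~positive)),
    )
    return StripeImage(pv, image_E.pixel_spacing, units="PV",
                       z_origin=image_E.z_origin, u_origin=image_E.u_origin, meta=meta)


def split_into_plates(image: StripeImage, n_plates: int = 5, overlap: float = 0.0) -> PlateSet:
    """Partition the unwrapped image into ``n_plates`` sub-images along the
    circumferential axis (layout order a→e), optionally sharing ``overlap``
    millimetres across each interior boundary.

    With ``overlap = 0`` the plates tile the image exactly and stitching
    reproduces it bit-identically.
    """
    if n_plates < 1:
        raise ValueError("n_plates must be >= 1")
    if overlap < 0:
        raise ValueError("overlap must be >= 0")
    s = image.pixel_spacing
    n_u = image.n_u
    edges = [int(round(k * n_u / n_plates)) for k in range(n_plates + 1)]
    o2 = int(round(overlap / (2.0 * s)))
    min_width = min(e1 - e0 for e0, e1 in zip(edges[:-1], edges[1:]))
    if n_plates > 1 and 2 * o2 >= min_width:
        raise ValueError("overlap is as large as a plate width")
    plates = []
    for k in range(n_plates):
        lo = max(0, edges[k] - (o2 if k > 0 else 0))
        hi = min(n_u, edges[k + 1] + (o2 if k < n_plates - 1 else 0))
        meta = dict(image.meta)
        meta.update(
            plate_index=k,
            n_plates=n_plates,
            overlap_mm=overlap,
            col_offset=lo,
            base_edges=[edges[k], edges[k + 1]],
            full_circumference=False,
        )
        plates.append(
            StripeImage(
                image.values[:, lo:hi].copy(),
                pixel_spacing=s,
                units=image.units,
                z_origin=image.z_origin,
                u_origin=image.u_origin + lo * s,
                meta=meta,
            )
        )
    return PlateSet(plates)
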