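"""1-D dose-profile container and sub-pixel FWHM / FWTM estimators.

Widths are measured relative to a background estimated from the outer 10%
of samples on each tail, with the crossing positions on each flank found by
linear interpolation between the bracketing samples.  This gives sub-sample
resolution without any smoothing; an optional odd-width moving average can
be applied first (its width is the caller's to record).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Profile",
    "PeakNotResolvedError",
    "measure_fwhm",
    "measure_fwtm",
    "width_at_fraction",
]

_TAIL_FRACTION = 0.1


class PeakNotResolvedError(RuntimeError):
    """The profile does not cross the requested level on both flanks."""


@dataclass
class Profile:
    """Sampled 1-D intensity versus position.

    ``start`` is the position (mm) of the first sample; sample ``i`` sits at
    ``start + i * spacing``.  ``axis`` records what the positions mean:
    ``"z"`` (slice direction) or ``"perpendicular_to_stripe"``.
    """

    values: np.ndarray
    spacing: float
    axis: str = "z"
    start: float = 0.0
    units: str = "E"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("Profile requires a 1-D array")
        if len(self.values) < 8:
            raise ValueError("Profile requires at least 8 samples")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Profile values must be finite")
        if self.axis not in ("z", "perpendicular_to_stripe"):
            raise ValueError("axis must be 'z' or 'perpendicular_to_stripe'")

    @property
    def positions(self) -> np.ndarray:
        return self.start + np.arange(len(self.values)) * self.spacing

    def smoothed(self, width: int) -> "Profile":
        """Moving-average smoothing with an odd window of ``width`` samples."""
        if width % 2 != 1 or width < 1:
            raise ValueError("smoothing width must be a positive odd integer")
        if width == 1:
            return self
        kernel = np.full(width, 1.0 / width)
        pad = width // 2
        padded = np.pad(self.values, pad, mode="edge")
        vals = np.convolve(padded, kernel, mode="valid")
        return Profile(vals, self.spacing, self.axis, self.start, self.units,
                       {**self.meta, "smooth_width": width})


def tail_background(values: np.ndarray, tail_fraction: float = _TAIL_FRACTION) -> float:
    """Mean of the outer ``tail_fraction`` of samples on each tail."""
    values = np.asarray(values, dtype=float)
    n = max(1, int(round(tail_fraction * len(values))))
    return float(np.mean(np.concatenate([values[:n], values[-n:]])))


def width_at_fraction(profile: Profile, fraction: float, smooth: int | None = None) -> float:
    """Full width (mm) at ``fraction`` of the background-corrected maximum.

    The level is ``background + fraction * (peak - background)``.  Scanning
    outward from the peak, the first sample below the level brackets the
    crossing on each flank; the crossing is linearly interpolated.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if smooth:
        profile = profile.smoothed(smooth)
    v = profile.values
    x = profile.positions
    bg = tail_background(v)
    ipk = int(np.argmax(v))
    peak = v[ipk]
    if peak <= bg:
        raise PeakNotResolvedError("no peak above the tail background")
    level = bg + fraction * (peak - bg)

    li = ipk
    while li > 0 and v[li] >= level:
        li -= 1
    if v[li] >= level:
        raise PeakNotResolvedError(
            f"profile does not fall below the {fraction:.0%} level on the left flank"
        )
    left = x[li] + (level - v[li]) / (v[li + 1] - v[li]) * profile.spacing

    ri = ipk
    n = len(v)
    while ri < n - 1 and v[ri] >= level:
        ri += 1
    if v[ri] >= level:
        raise PeakNotResolvedError(
            f"profile does not fall below the {fraction:.0%} level on the right flank"
        )
    right = x[ri - 1] + (level - v[ri - 1]) / (v[ri] - v[ri - 1]) * profile.spacing
    return float(right - left)


def measure_fwhm(profile: Profile, smooth: int | None = None) -> float:
    """Full width at half maximum (mm), background-corrected."""
    return width_at_fraction(profile, 0.5, smooth=smooth)


def measure_fwtm(profile: Profile, smooth: int | None = None) -> float:
    """Full width at tenth maximum (mm), background-corrected."""
    return width_at_fraction(profile, 0.1, smooth=smooth)
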