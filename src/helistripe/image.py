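"""In-memory containers for stripe images and plate sets.

A :class:`StripeImage` is the unwrapped cylindrical plate: rows index the
slice direction ``z`` (increasing with table travel), columns index the
unwrapped circumference ``u``.  Pixel *centers* sit at
``origin + (i + 0.5) * pixel_spacing`` (0-based indices).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np

__all__ = ["StripeImage", "PlateSet"]

VALID_UNITS = ("E", "PV")


@dataclass
class StripeImage:
    """2-D scalar image on the unwrapped cylinder.

    ``units`` is ``"E"`` for exposure (linear) or ``"PV"`` for the
    log-encoded computed-radiography pixel value.
    """

    values: np.ndarray
    pixel_spacing: float
    units: str = "E"
    z_origin: float = 0.0
    u_origin: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("StripeImage requires a 2-D array (z rows, u columns)")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")
        if self.units not in VALID_UNITS:
            raise ValueError(f"units must be one of {VALID_UNITS}")

    @property
    def n_z(self) -> int:
        return self.values.shape[0]

    @property
    def n_u(self) -> int:
        return self.values.shape[1]

    @property
    def z_extent(self) -> float:
        return self.n_z * self.pixel_spacing

    @property
    def u_extent(self) -> float:
        return self.n_u * self.pixel_spacing

    @property
    def z_centers(self) -> np.ndarray:
        return self.z_origin + (np.arange(self.n_z) + 0.5) * self.pixel_spacing

    @property
    def u_centers(self) -> np.ndarray:
        return self.u_origin + (np.arange(self.n_u) + 0.5) * self.pixel_spacing

    @property
    def full_circumference(self) -> bool:
        return bool(self.meta.get("full_circumference", False))


@dataclass
class PlateSet:
    """Ordered collection of per-plate sub-images of one stripe image."""

    plates: List[StripeImage]

    def __post_init__(self):
        if not self.plates:
            raise ValueError("PlateSet requires at least one plate")
        self.plates = sorted(self.plates, key=lambda p: p.meta.get("plate_index", 0))

    def __len__(self) -> int:
        return len(self.plates)

    def __iter__(self):
        return iter(self.plates)

    def __getitem__(self, i):
        return self.plates[i]

    @property
    def pixel_spacing(self) -> float:
        return self.plates[0].pixel_spacing
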