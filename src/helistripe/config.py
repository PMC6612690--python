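"""Run configuration: YAML/JSON schema with strict validation.

Unknown keys are rejected at every level so a typo in a config never
silently falls back to a default.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .geometry import AcquisitionParams, BeamModel, ScannerGeometry, _from_dict
from .simulate import GridSpec

__all__ = ["AnalysisOptions", "SimOptions", "RunConfig"]


@dataclass(frozen=True)
class AnalysisOptions:
    n_stripes: int = 3
    gray_level: float = 1024.0
    smooth: Optional[int] = None
    min_separation: Optional[float] = None
    profile_length: Optional[float] = None
    nominal_bw: Optional[float] = None

    def __post_init__(self):
        if self.n_stripes < 1:
            raise ValueError("n_stripes must be >= 1")
        if self.gray_level <= 0:
            raise ValueError("gray_level must be > 0")
        if self.smooth is not None and (self.smooth < 1 or self.smooth % 2 == 0):
            raise ValueError("smooth must be a positive odd integer")

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisOptions":
        return _from_dict(cls, data)


@dataclass(frozen=True)
class SimOptions:
    noise_sd: float = 0.0
    theta_step_deg: float = 0.5
    lead_rotations: float = 0.5
    start_angle_deg: float = 0.0
    fan_half_value_mm: Optional[float] = 80.0
    exposure_peak: float = 1000.0
    n_plates: int = 5
    overlap_mm: float = 0.0
    bit_depth: int = 16

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_plates < 1:
            raise ValueError("n_plates must be >= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "SimOptions":
        return _from_dict(cls, data)


_SECTIONS = {
    "geometry": ScannerGeometry,
    "acquisition": AcquisitionParams,
    "beam": BeamModel,
    "grid": GridSpec,
    "analysis": AnalysisOptions,
    "sim": SimOptions,
}
_SCALARS = {"seed", "run_id"}


@dataclass
class RunConfig:
    """Fully resolved configuration of one simulate or analyze run."""

    geometry: ScannerGeometry = field(default_factory=ScannerGeometry)
    acquisition: Optional[AcquisitionParams] = None
    beam: Optional[BeamModel] = None
    grid: GridSpec = field(default_factory=GridSpec)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    sim: SimOptions = field(default_factory=SimOptions)
    seed: Optional[int] = None
    run_id: str = "run"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - set(_SECTIONS) - _SCALARS
        if unknown:
            raise ValueError(
                f"RunConfig: unknown keys {sorted(unknown)}; "
                f"expected a subset of {sorted(set(_SECTIONS) | _SCALARS)}"
            )
        kwargs = {}
        for name, typ in _SECTIONS.items():
            if name in data and data[name] is not None:
                kwargs[name] = typ.from_dict(data[name]) if isinstance(data[name], dict) else data[name]
        for name in _SCALARS:
            if name in data:
                kwargs[name] = data[name]
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = {}
        for name in _SECTIONS:
            val = getattr(self, name)
            out[name] = None if val is None else (
                val.to_dict() if hasattr(val, "to_dict") else asdict(val)
            )
        out["seed"] = self.seed
        out["run_id"] = self.run_id
        return out

    def save(self, path: Union[str, Path]) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
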