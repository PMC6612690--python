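"""Readers and writers: TIFF/PNG rasters with JSON sidecars, read-only
DICOM, two-column flat-profile text files, and measurement reports.

The canonical raster is 16-bit grayscale TIFF for pixel-value images and
32-bit float TIFF for exposure images; every raster travels with a JSON
sidecar holding pixel spacing, units, origins and acquisition metadata.
Pixel spacing is never guessed: it must come from the sidecar, a DICOM tag,
or an explicit argument.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from .analysis import MeasurementReport
from .image import PlateSet, StripeImage
from .profiles import Profile

__all__ = [
    "read_image",
    "read_plates",
    "write_stripe_image",
    "read_flat_profile",
    "write_flat_profile",
    "write_report",
    "read_report",
]

REPORT_COLUMNS = [
    "collimation", "pitch", "active_collimator", "bw_mean", "bw_sd",
    "de_mean", "de_sd", "exposure_length", "overranging",
    "reduction_ratio", "dlp_console",
]


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stripe_image(image: StripeImage, path: Union[str, Path],
                       sidecar_path: Optional[Union[str, Path]] = None) -> Path:
    """Write a raster plus its JSON sidecar; returns the sidecar path."""
    path = Path(path)
    values = image.values
    if image.units == "PV":
        values = np.asarray(values, dtype=np.uint16)
    else:
        values = np.asarray(values, dtype=np.float32)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, values)
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio
        if image.units != "PV":
            raise ValueError("PNG output supports only integer pixel-value images")
        iio.imwrite(path, values)
    else:
        raise ValueError(f"unsupported raster format: {path.suffix}")
    sidecar = Path(sidecar_path) if sidecar_path else _sidecar_path(path)
    payload = {
        "pixel_spacing": image.pixel_spacing,
        "units": image.units,
        "z_origin": image.z_origin,
        "u_origin": image.u_origin,
        "shape": list(values.shape),
        "meta": _json_safe(image.meta),
    }
    sidecar.write_text(json.dumps(payload, indent=2))
    return sidecar


def _read_dicom(path: Path, pixel_spacing: Optional[float]) -> StripeImage:
    import pydicom

    ds = pydicom.dcmread(path)
    values = ds.pixel_array
    spacing = None
    for tag in ("PixelSpacing", "ImagerPixelSpacing"):
        val = getattr(ds, tag, None)
        if val:
            spacing = float(val[0])
            break
    if pixel_spacing is not None:
        spacing = float(pixel_spacing)
    if spacing is None:
        raise ValueError(f"{path}: no pixel spacing in DICOM tags and none supplied")
    return StripeImage(np.asarray(values), pixel_spacing=spacing, units="PV",
                       meta={"source": str(path), "format": "dicom"})


def read_image(path: Union[str, Path],
               sidecar_path: Optional[Union[str, Path]] = None,
               pixel_spacing: Optional[float] = None) -> StripeImage:
    """Read one raster (TIFF/PNG with JSON sidecar, or DICOM read-only).

    Pixel spacing resolution order: explicit argument > sidecar > DICOM tag;
    if none is available this is a hard error, never a guess.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    if path.suffix.lower() in (".dcm", ".dicom"):
        return _read_dicom(path, pixel_spacing)
    if path.suffix.lower() in (".tif", ".tiff"):
        values = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio
        values = iio.imread(path)
    else:
        # fall back to DICOM sniffing for extension-less exports
        try:
            return _read_dicom(path, pixel_spacing)
        except Exception as exc:
            raise ValueError(f"unreadable image file: {path} ({exc})") from exc

    sidecar = Path(sidecar_path) if sidecar_path else _sidecar_path(path)
    if sidecar.exists():
        payload = json.loads(sidecar.read_text())
        spacing = pixel_spacing if pixel_spacing is not None else payload.get("pixel_spacing")
        if spacing is None:
            raise ValueError(f"{path}: sidecar {sidecar} lacks pixel_spacing")
        return StripeImage(
            np.asarray(values),
            pixel_spacing=float(spacing),
            units=payload.get("units", "PV"),
            z_origin=float(payload.get("z_origin", 0.0)),
            u_origin=float(payload.get("u_origin", 0.0)),
            meta=payload.get("meta", {}),
        )
    if pixel_spacing is None:
        raise ValueError(
            f"{path}: pixel spacing unavailable (no sidecar {sidecar.name}, no argument)"
        )
    return StripeImage(np.asarray(values), pixel_spacing=float(pixel_spacing),
                       units="PV", meta={"source": str(path)})


def read_plates(paths: Iterable[Union[str, Path]],
                pixel_spacing: Optional[float] = None) -> PlateSet:
    """Read several plate rasters into a PlateSet ordered by layout index."""
    plates = [read_image(p, pixel_spacing=pixel_spacing) for p in paths]
    if not plates:
        raise ValueError("no plate files given")
    return PlateSet(plates)


def write_flat_profile(profile: Profile, path: Union[str, Path]) -> None:
    """Two-column delimited text: position_mm, value."""
    arr = np.column_stack([profile.positions, profile.values])
    np.savetxt(path, arr, fmt="%.6g", delimiter="\t",
               header="position_mm\tvalue", comments="# ")


def read_flat_profile(path: Union[str, Path], units: str = "E") -> Profile:
    """Read a two-column (position_mm, value) delimited text profile.

    Positions must be uniformly spaced (tolerance 1e-6 relative)."""
    arr = np.loadtxt(path, comments="#", delimiter=None)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (position_mm, value)")
    pos, vals = arr[:, 0], arr[:, 1]
    steps = np.diff(pos)
    if steps.size == 0 or np.any(steps <= 0):
        raise ValueError(f"{path}: positions must be strictly increasing")
    spacing = float(np.mean(steps))
    if np.max(np.abs(steps - spacing)) > 1e-6 * max(1.0, abs(spacing)):
        raise ValueError(f"{path}: positions are not uniformly spaced")
    return Profile(vals, spacing=spacing, axis="z", start=float(pos[0]), units=units)


def write_report(reports: Union[MeasurementReport, Sequence[MeasurementReport]],
                 path_base: Union[str, Path],
                 formats: Sequence[str] = ("json", "csv")) -> List[Path]:
    """Emit measurement reports as JSON (raw + rounded) and/or CSV (rounded,
    fixed column schema).  ``path_base`` is the path without extension."""
    if isinstance(reports, MeasurementReport):
        reports = [reports]
    path_base = Path(path_base)
    written = []
    if "json" in formats:
        payload = [{"rounded": r.rounded(), "raw": r.raw()} for r in reports]
        p = path_base.with_suffix(".json")
        p.write_text(json.dumps(_json_safe(payload), indent=2))
        written.append(p)
    if "csv" in formats:
        rows = [{k: r.rounded().get(k) for k in REPORT_COLUMNS} for r in reports]
        df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
        p = path_base.with_suffix(".csv")
        df.to_csv(p, index=False)
        written.append(p)
    return written


def read_report(path: Union[str, Path]) -> List[dict]:
    """Read back a JSON report written by :func:`write_report`."""
    return json.loads(Path(path).read_text())
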