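"""Canonical study conditions for the cylindrical-plate stripe method.

A 250-mm radius plate holder around a 500-mm acrylic phantom, helical
acquisitions at 32 and 80 mm nominal collimation over a 160-mm scan range,
0.5 s rotations.  The actual beam widths (nominal collimation plus
overbeaming) are about 39 mm and 88 mm for the two collimations; the beam
penumbra at the isocenter is about 3 mm (a ~1-mm focal spot magnified by the
focus-to-collimator geometry, plus blur).
"""

from __future__ import annotations

from .geometry import AcquisitionParams, BeamModel, ScannerGeometry

__all__ = [
    "DEFAULT_GEOMETRY",
    "STUDY_PITCHES",
    "SCAN_RANGE_MM",
    "GRAY_LEVEL",
    "study_beam",
    "study_acquisition",
]

DEFAULT_GEOMETRY = ScannerGeometry(
    fid=600.0, plate_radius=250.0, focal_spot_z=1.0, focus_collimator_distance=200.0
)

#: pitches used with each nominal collimation in the study conditions
STUDY_PITCHES = {32.0: (0.83, 1.48), 80.0: (0.87, 0.99)}

SCAN_RANGE_MM = 160.0
GRAY_LEVEL = 1024.0

_ACTUAL_BW = {32.0: 39.0, 80.0: 88.0}
PENUMBRA_ISO_MM = 3.0


def study_beam(nominal_collimation: float) -> BeamModel:
    """Beam model for a study collimation: the actual width is the nominal
    width plus the typical overbeaming of an area-detector scanner."""
    bw = _ACTUAL_BW.get(float(nominal_collimation))
    if bw is None:
        bw = float(nominal_collimation) + 7.0
    return BeamModel(actual_bw_iso=bw, penumbra_iso=PENUMBRA_ISO_MM)


def study_acquisition(
    nominal_collimation: float, pitch: float, active_collimator: bool = False
) -> AcquisitionParams:
    return AcquisitionParams(
        nominal_collimation=float(nominal_collimation),
        pitch=float(pitch),
        scan_range_d=SCAN_RANGE_MM,
        rotation_time=0.5,
        active_collimator=active_collimator,
        ramp_rotations=0.5,
    )
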