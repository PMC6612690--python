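import pytest

from helistripe import (
    AcquisitionParams,
    BeamModel,
    GridSpec,
    simulate_stripe_image,
)
from helistripe.presets import DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def geometry():
    return DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def small_sim(geometry):
    """Noiseless helical acquisition at study-scale geometry with a short
    scan range and a coarse grid: fast, but in the same separability regime
    as the full-size runs."""
    beam = BeamModel(actual_bw_iso=39.0, penumbra_iso=3.0)
    acq = AcquisitionParams(nominal_collimation=32.0, pitch=1.48, scan_range_d=60.0)
    image, truth = simulate_stripe_image(geometry, beam, acq, GridSpec(pixel_spacing=0.4))
    return {"geometry": geometry, "beam": beam, "acquisition": acq,
            "image": image, "truth": truth}


@pytest.fixture(scope="session")
def small_sim_ac(geometry, small_sim):
    """Same acquisition with the active collimator engaged."""
    beam = small_sim["beam"]
    acq = AcquisitionParams(nominal_collimation=32.0, pitch=1.48, scan_range_d=60.0,
                            active_collimator=True)
    image, truth = simulate_stripe_image(geometry, beam, acq, GridSpec(pixel_spacing=0.4))
    return {"geometry": geometry, "beam": beam, "acquisition": acq,
            "image": image, "truth": truth}
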