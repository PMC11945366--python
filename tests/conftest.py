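import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from irsei import pipeline, raster, synth

# Calibration constants used for all synthetic thermal chains (Landsat-5
# band-6 style values; supplied as configuration, as real runs would).
SYNTH_THERMAL = dict(
    gain=0.055, bias=1.18, K1=607.76, K2=1260.56, wavelength_m=11.45e-6, emissivity=0.95
)


@pytest.fixture(scope="session")
def thermal_constants():
    return raster.ThermalConstants(**SYNTH_THERMAL)


@pytest.fixture(scope="session")
def signatures():
    return synth.load_signatures()


@pytest.fixture(scope="session")
def island():
    """Circular island fixture: (scene, landcover, ground-truth water, meta)."""
    return synth.make_island(50.0, grid=(256, 256), seed=11)


@pytest.fixture(scope="session")
def degradation_series(thermal_constants):
    """Five-epoch monotone degradation run: list of EpochProducts."""
    script = synth.degradation_script()
    series = synth.make_timeseries(script, seed=42)
    return [
        pipeline.run_epoch(scene, lcm, thermal_constants, label=label)
        for label, (scene, lcm) in zip(script.epochs, series)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
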