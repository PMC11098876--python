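import numpy as np
import pytest

from spiralpa.array_geometry import build_dense_geometry, device_config, toy_config
from spiralpa.cli_io import run_snr_benchmark
from spiralpa.forward_model import (
    SensorResponse,
    TimeAxis,
    apply_sensor_bandwidth,
    simulate,
    toy_time_axis,
)
from spiralpa.phantoms import SphericalAbsorber, Phantom, evaluation_phantom


@pytest.fixture(scope="session")
def device_bundle():
    return build_dense_geometry(device_config())


@pytest.fixture(scope="session")
def toy_bundle():
    return build_dense_geometry(toy_config())


@pytest.fixture(scope="session")
def device_eval_ideal(device_bundle):
    """Ideal band-limited signals of the 3-cylinder phantom at all 1897 sensors."""
    ta = TimeAxis()
    resp = SensorResponse()
    sim = simulate(
        evaluation_phantom(), device_bundle.dense_coords, ta, sensor_ids=device_bundle.dense_ids
    )
    return apply_sensor_bandwidth(sim, resp)


@pytest.fixture(scope="session")
def snr_benchmark_ci(device_bundle, device_eval_ideal):
    """The four-way S/N benchmark at CI scale (0.4 mm voxels)."""
    return run_snr_benchmark(
        seed=1, scale="ci", _precomputed=(device_bundle, device_eval_ideal)
    )


@pytest.fixture(scope="session")
def toy_ideal_dense(toy_bundle):
    """Ideal band-limited signals of a small sphere phantom at all toy sensors."""
    ph = Phantom(
        absorbers=(
            SphericalAbsorber(center=(1.0, -2.0, 0.5), diameter=1.0, p0=100.0),
            SphericalAbsorber(center=(-2.0, 1.5, -1.0), diameter=0.8, p0=70.0),
        )
    )
    s = simulate(ph, toy_bundle.dense_coords, toy_time_axis(), sensor_ids=toy_bundle.dense_ids)
    return ph, apply_sensor_bandwidth(s, SensorResponse())
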