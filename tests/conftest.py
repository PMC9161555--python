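import numpy as np
import pytest

import lsmkit as L


@pytest.fixture(scope="session")
def phantom():
    """Default-size brain phantom shared across the suite (seeded)."""
    return L.generate_phantom(seed=1)


@pytest.fixture(scope="session")
def small_phantom():
    """Tiny phantom for streaming tests where frame content is incidental."""
    return L.generate_phantom(seed=2, n_nuclei=20, dims=(48, 48, 48), voxel_size=1.0)


@pytest.fixture
def scan():
    return L.ScanConfig()


@pytest.fixture
def small_scan():
    """Scan program matching the tiny phantom's 48 μm extent."""
    return L.ScanConfig(
        n_planes=45,
        plane_spacing=0.8,
        do_start=2.0,
        do_end=40.0,
        beam_volt_start=0.0,
        beam_volt_end=0.4,
        frame_rate=45.0,
        exposure=20.0,
    )


@pytest.fixture
def camera(phantom, scan):
    """Perfectly linear simulated camera on the default phantom."""
    return L.FrameSource(phantom=phantom, scan=scan, seed=1)


def make_camera(phantom, scan, mapping=None, seed=1, **kwargs):
    return L.FrameSource(
        phantom=phantom, scan=scan, true_mapping=mapping, seed=seed, **kwargs
    )


def random_valid_config(rng: np.random.Generator, sample_rate: float = 5000.0) -> L.ScanConfig:
    """Draw a random scan geometry satisfying every ScanConfig invariant."""
    n_planes = int(rng.integers(1, 201))
    frame_rate = float(rng.uniform(10.0, 100.0))
    exposure = float(rng.uniform(0.5, 0.9)) * 1000.0 / frame_rate
    do_start = float(rng.uniform(0.0, 50.0))
    do_end = do_start + float(rng.uniform(10.0, 300.0))
    volume_ms = 1000.0 * n_planes / frame_rate
    return L.ScanConfig(
        n_planes=n_planes,
        plane_spacing=float(rng.uniform(0.5, 5.0)),
        exposure=exposure,
        frame_rate=frame_rate,
        do_start=do_start,
        do_end=do_end,
        beam_volt_start=float(rng.uniform(-1.0, 0.0)),
        beam_volt_end=float(rng.uniform(0.5, 3.0)),
        piezo_delay=float(rng.uniform(0.0, min(20.0, 0.5 * volume_ms))),
        sample_rate=sample_rate,
        trigger_pulse_width=min(1.0, 0.5 * 1000.0 / frame_rate),
    )
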