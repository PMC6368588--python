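"""Shared fixtures: small phantoms and speckle images sized for fast tests."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from heartflow.phantom import (
    AcquisitionProtocol,
    BeatModel,
    ChamberSpec,
    HeartPhantom,
)


def small_chambers() -> tuple[ChamberSpec, ChamberSpec]:
    """Two chambers fitting a 64×64 px / 160 μm field at maximal dilation."""
    return (
        ChamberSpec("ventricle", (100.0, 80.0), (28.0, 22.0), phase_offset=0.0),
        ChamberSpec("atrium", (36.0, 80.0), (14.0, 12.0), phase_offset=np.pi / 2),
    )


def small_protocol(**overrides) -> AcquisitionProtocol:
    kwargs = dict(
        burst_duration_s=5.0,
        burst_interval_s=60.0,
        frame_rate_hz=20.0,
        pixel_size_um=2.5,
        shape=(64, 64),
        noise_sigma=0.02,
        seed=7,
    )
    kwargs.update(overrides)
    return AcquisitionProtocol(**kwargs)


def small_phantom(f0=2.5, a0=0.5, drug=None, **protocol_overrides) -> HeartPhantom:
    return HeartPhantom(
        chambers=small_chambers(),
        beat=BeatModel(f0_hz=f0, a0=a0),
        drug=drug,
        protocol=small_protocol(**protocol_overrides),
    )


@pytest.fixture(scope="session")
def burst_25_05():
    """One 5 s burst of the small phantom at f0 = 2.5 Hz, A0 = 0.5."""
    return small_phantom().generate_burst(0.0)


@pytest.fixture(scope="session")
def burst_flows(burst_25_05):
    """Flow fields for the shared burst (computed once per session)."""
    from heartflow.hsflow import flow_sequence

    seq, _ = burst_25_05
    return flow_sequence(seq)


def speckle(shape=(64, 64), grain_px=2.0, seed=0, lo=0.25, hi=0.75) -> np.ndarray:
    """Band-limited speckle image with unit-order intensities."""
    rng = np.random.default_rng(seed)
    f = gaussian_filter(rng.standard_normal(shape), grain_px)
    f /= f.std()
    return 0.5 * (lo + hi) + 0.5 * (hi - lo) * np.clip(f, -2.5, 2.5) / 2.5


@pytest.fixture
def speckle_img() -> np.ndarray:
    return speckle()
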