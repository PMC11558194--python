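"""Shared fixtures: small synthetic scenes reused across test modules."""

import numpy as np
import pytest
from hypothesis import settings

import casatrack as ct

settings.register_profile("casatrack", derandomize=True, deadline=None)
settings.load_profile("casatrack")


@pytest.fixture(scope="session")
def straight_params():
    """Deterministic straight swimmer: no wobble, no diffusion, no noise."""
    return ct.KinematicsParams(
        progressive_speed_mean=30.0,
        progressive_speed_sd=0.0,
        wobble_amplitude=0.0,
        wobble_frequency=0.0,
        heading_diffusion=0.0,
        immotile_fraction=0.0,
        positional_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def wobbly_params():
    """Progressive swimmer with lateral head wobble (clean coordinates)."""
    return ct.KinematicsParams(
        progressive_speed_mean=30.0,
        progressive_speed_sd=5.0,
        wobble_amplitude=2.0,
        wobble_frequency=5.0,
        heading_diffusion=0.3,
        immotile_fraction=0.0,
        positional_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def small_scene(wobbly_params):
    """10 well-separated wobbly sperm rendered at 100 fps for 0.3 s."""
    tracks = ct.simulate_tracks(
        wobbly_params, 10, 0.3, 100, field_of_view=(400.0, 400.0),
        seed=42, min_separation=60.0, spawn_margin=30.0,
    )
    video = ct.render_video(tracks, ct.OpticsConfig(frame_shape=(800, 800)), seed=7)
    return tracks, video


def zigzag_track(track_id=0):
    """(0,0),(1,1),(2,0),(3,1),(4,0) μm at dt = 0.1 s."""
    return ct.GroundTruthTrack(
        track_id=track_id,
        times=np.arange(5) * 0.1,
        x=np.array([0.0, 1.0, 2.0, 3.0, 4.0]),
        y=np.array([0.0, 1.0, 0.0, 1.0, 0.0]),
    )
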