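"""Shared fixtures: session-scoped synthetic datasets (generation is costly)."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vibrostim.deformation import estimate_displacement
from vibrostim.synthetic import (
    AdhesionSimConfig,
    BeadSimConfig,
    FretSimConfig,
    generate_adhesion_dishes,
    generate_bead_stack,
    generate_fret_stack,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bead_stack_clean():
    """Noise-free default bead simulation (peak strain ~0.5 near the probe)."""
    return generate_bead_stack(BeadSimConfig(noise_sigma=0.0))


@pytest.fixture(scope="session")
def bead_stack_noisy():
    return generate_bead_stack(BeadSimConfig())


@pytest.fixture(scope="session")
def estimated_field_clean(bead_stack_clean):
    """Displacement estimate for the peak-deformation frame pair (clean)."""
    cfg = bead_stack_clean.config
    return estimate_displacement(
        bead_stack_clean.frames[0], bead_stack_clean.frames[1], cfg.pixel_size_um
    )


@pytest.fixture(scope="session")
def fret_stack_default():
    return generate_fret_stack(FretSimConfig())


@pytest.fixture(scope="session")
def small_fret_config():
    """Reduced-geometry FRET config for Monte-Carlo sweeps (default noise)."""
    return FretSimConfig(
        image_size_px=(128, 128),
        cell_center_px=(64.0, 64.0),
        cell_axes_px=(52.0, 44.0),
        stim_xy_px=(64.0, 64.0),
        frame_times_s=(0.0, 30.0, 60.0, 65.0, 70.0, 75.0, 80.0, 85.0, 90.0, 95.0),
        stim_time_s=62.0,
    )


@pytest.fixture(scope="session")
def adhesion_default():
    return generate_adhesion_dishes(AdhesionSimConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
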