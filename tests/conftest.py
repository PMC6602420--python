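"""Shared fixtures: one phantom study reused across the suite.

Renders are session-scoped — they are deterministic pure functions of the
seed, and re-rendering per test would dominate the suite runtime.
"""

import numpy as np
import pytest

from fluoroguide import (
    CArmPose,
    PhantomNoiseSpec,
    default_catheter_curve,
    make_spine_phantom,
    render_fluoroscopy,
    render_reference_projection,
)

STUDY_SEED = 7
SPACING = 0.25
FRAME_SIZE = (640, 640)
POSES = {
    "AP": CArmPose("AP"),
    "LAO30": CArmPose("LAO", 30),
    "RAO30": CArmPose("RAO", 30),
}


@pytest.fixture(scope="session")
def model():
    """Five tapered vertebrae + posterior column + heart, mild jitter."""
    return make_spine_phantom(jitter_mm=0.8, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def catheter():
    return default_catheter_curve()


@pytest.fixture(scope="session")
def noise():
    return PhantomNoiseSpec(
        gaussian_sigma=2.0, background_gradient=(0.01, 0.005), seed=STUDY_SEED
    )


@pytest.fixture(scope="session")
def fluoro_frames(model, catheter, noise):
    return {
        name: render_fluoroscopy(model, catheter, pose, SPACING, FRAME_SIZE, noise)
        for name, pose in POSES.items()
    }


@pytest.fixture(scope="session")
def noiseless_frames(model, catheter):
    return {
        name: render_fluoroscopy(model, catheter, pose, SPACING, FRAME_SIZE)
        for name, pose in POSES.items()
    }


@pytest.fixture(scope="session")
def reference_projections(model):
    return {
        name: render_reference_projection(model, pose, SPACING, FRAME_SIZE)
        for name, pose in POSES.items()
    }


@pytest.fixture(scope="session")
def spine_silhouette(model):
    """512x512 AP silhouette used by the registration recovery suites."""
    return render_reference_projection(model, POSES["AP"], SPACING, (512, 512))


def pytest_configure(config):
    try:
        from hypothesis import HealthCheck, settings

        settings.register_profile(
            "ci",
            derandomize=True,
            deadline=None,
            max_examples=25,
            suppress_health_check=[HealthCheck.too_slow],
        )
        settings.load_profile("ci")
    except ImportError:
        pass
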