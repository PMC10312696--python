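import json

import numpy as np
import pytest

from biomech_autofit.kinematic_fit import default_scaling_prior
from biomech_autofit.skeleton import SkeletonModel, _skeleton_from_dict
from biomech_autofit.synthetic import (
    gait_skeleton,
    generate_gait_motion,
    sample_subject,
    synthesize_consistent_grf,
    synthesize_markers,
)

PENDULUM = {
    "version": 1,
    "gravity": [0.0, -9.81, 0.0],
    "segments": [
        {"name": "base", "mass": 2.0, "com": [0, -0.1, 0], "inertia": [0.02, 0.01, 0.02]},
        {"name": "rod", "mass": 1.0, "com": [0, -0.25, 0], "inertia": [0.03, 0.004, 0.03]},
    ],
    "joints": [
        {"name": "root", "type": "free6", "parent": None, "child": "base"},
        {
            "name": "hinge",
            "type": "revolute1",
            "parent": "base",
            "child": "rod",
            "parent_offset": [0, -0.3, 0],
            "child_offset": [0, 0, 0],
            "axes": [[0, 0, 1]],
        },
    ],
    "markers": [
        {"label": "B1", "segment": "base", "offset": [0.1, 0.0, 0.05], "kind": "anatomical"},
        {"label": "B2", "segment": "base", "offset": [-0.08, -0.05, 0.02], "kind": "tracking"},
        {"label": "R1", "segment": "rod", "offset": [0.02, -0.2, 0.04], "kind": "anatomical"},
    ],
}

CHAIN = {
    "version": 1,
    "segments": [
        {"name": "a", "mass": 3.0, "com": [0, 0.05, 0.02], "inertia": [0.05, 0.04, 0.06]},
        {"name": "b", "mass": 2.0, "com": [0.1, -0.1, 0], "inertia": [0.03, 0.02, 0.04]},
        {"name": "c", "mass": 1.0, "com": [0, -0.15, 0.03], "inertia": [0.01, 0.012, 0.011]},
        {"name": "d", "mass": 0.5, "com": [0.05, 0, 0], "inertia": [0.004, 0.005, 0.003]},
    ],
    "joints": [
        {"name": "root", "type": "free6", "parent": None, "child": "a"},
        {
            "name": "j_ab", "type": "ball3", "parent": "a", "child": "b",
            "parent_offset": [0.1, -0.2, 0.05], "child_offset": [0, 0.1, 0], "axes": [],
        },
        {
            "name": "j_bc", "type": "revolute1", "parent": "b", "child": "c",
            "parent_offset": [0, -0.3, 0.02], "child_offset": [0, 0.05, 0],
            "axes": [[0.0, 0.6, 0.8]],
        },
        {
            "name": "j_cd", "type": "universal2", "parent": "c", "child": "d",
            "parent_offset": [0.02, -0.25, 0], "child_offset": [-0.03, 0, 0],
            "axes": [[0, 0, 1], [1, 0, 0]],
        },
    ],
    "markers": [
        {"label": "MA", "segment": "a", "offset": [0.1, 0.05, 0.08], "kind": "anatomical"},
        {"label": "MB", "segment": "b", "offset": [0.04, -0.1, 0.03], "kind": "tracking"},
        {"label": "MC", "segment": "c", "offset": [0.03, -0.1, -0.02], "kind": "tracking"},
        {"label": "MD", "segment": "d", "offset": [0.08, 0.02, 0.02], "kind": "anatomical"},
    ],
}


@pytest.fixture
def pendulum_dict():
    return json.loads(json.dumps(PENDULUM))


@pytest.fixture
def pendulum(pendulum_dict) -> SkeletonModel:
    return _skeleton_from_dict(pendulum_dict)


@pytest.fixture
def chain() -> SkeletonModel:
    return _skeleton_from_dict(json.loads(json.dumps(CHAIN)))


@pytest.fixture(scope="session")
def gait_model() -> SkeletonModel:
    return gait_skeleton()


@pytest.fixture(scope="session")
def prior(gait_model):
    return default_scaling_prior(gait_model)


@pytest.fixture(scope="session")
def clean_trial(gait_model, prior):
    """Noise-free 1.2 s gait trial with known truth and zero residuals."""
    skel = gait_model
    s_true, p_true, masses_true = sample_subject(prior, offset_sd=0.01, seed=7, skel=skel)
    q, stance = generate_gait_motion(skel, s_true, duration_s=1.2, rate_hz=100.0, seed=8)
    markers = synthesize_markers(skel, s_true, p_true, q)
    force, cop, moment, plates = synthesize_consistent_grf(skel, s_true, masses_true, q, stance)
    return {
        "skel": skel,
        "s": s_true,
        "p": p_true,
        "masses": masses_true,
        "q": q,
        "stance": stance,
        "markers": markers,
        "force": force,
        "cop": cop,
        "moment": moment,
        "plates": plates,
    }


def random_pose(skel, rng, scale=0.4):
    return rng.normal(0.0, scale, skel.n_q)


def random_scales(skel, rng, sd=0.08):
    return 1.0 + rng.normal(0.0, sd, skel.scale_dim)
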