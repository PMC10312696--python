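"""Ground-truth synthetic subjects and dynamically consistent gait trials.

Every downstream stage is validated against data produced here: a known-truth
scaled skeleton, smooth periodic joint trajectories, markers synthesized by
forward kinematics (with optional offset perturbation, noise and occlusion),
and ground loads computed by inverse dynamics of the prescribed motion so
that the root residual wrench is zero by construction at every frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io_formats import (
    ForcePlateRecord,
    MarkerTrajectories,
    TrialData,
    write_grf_mot,
    write_trc,
)
from .kinematic_fit import ScalingPrior
from .skeleton import (
    BodySegment,
    JointDef,
    MarkerDef,
    PoseTrajectory,
    SkeletonModel,
    finite_difference_derivatives,
)

__all__ = [
    "SyntheticTruth",
    "gait_skeleton",
    "segment_mass_fractions",
    "sample_subject",
    "generate_gait_motion",
    "synthesize_markers",
    "synthesize_consistent_grf",
    "make_trial",
    "default_plate_geometry",
]

# --------------------------------------------------------------- the fixture
_SEG_SPECS = [
    # name, mass fraction, com (local), inertia diag (unit-mass gyration-ish, kg m^2 at 1 kg scale)
    ("pelvis", 0.142, (0.0, 0.02, 0.0), (0.060, 0.075, 0.055)),
    ("torso", 0.355, (0.0, 0.22, 0.0), (0.90, 0.35, 0.95)),
    ("headarms", 0.181, (0.0, 0.12, 0.0), (0.25, 0.15, 0.25)),
    ("thigh_l", 0.100, (0.0, -0.18, 0.0), (0.130, 0.030, 0.130)),
    ("shank_l", 0.0465, (0.0, -0.19, 0.0), (0.055, 0.007, 0.055)),
    ("foot_l", 0.0145, (0.07, -0.03, 0.0), (0.0035, 0.0045, 0.0040)),
    ("thigh_r", 0.100, (0.0, -0.18, 0.0), (0.130, 0.030, 0.130)),
    ("shank_r", 0.0465, (0.0, -0.19, 0.0), (0.055, 0.007, 0.055)),
    ("foot_r", 0.0145, (0.07, -0.03, 0.0), (0.0035, 0.0045, 0.0040)),
]

_DEFAULT_TOTAL_MASS = 75.0
_THIGH_LEN = 0.41
_SHANK_LEN = 0.43
_HIP_HALF_WIDTH = 0.09

# lab frame: x forward, y up, z to the subject's left
_MARKER_SPECS = [
    # label, segment, offset, kind
    ("ASIS_L", "pelvis", (0.11, 0.02, 0.12), "anatomical"),
    ("ASIS_R", "pelvis", (0.11, 0.02, -0.12), "anatomical"),
    ("PSIS_L", "pelvis", (-0.12, 0.03, 0.05), "anatomical"),
    ("PSIS_R", "pelvis", (-0.12, 0.03, -0.05), "tracking"),
    ("STRN", "torso", (0.09, 0.25, 0.0), "anatomical"),
    ("C7", "torso", (-0.06, 0.42, 0.0), "anatomical"),
    ("T10", "torso", (-0.09, 0.18, 0.02), "tracking"),
    ("CLAV", "torso", (0.05, 0.38, -0.03), "tracking"),
    ("HEAD_F", "headarms", (0.08, 0.18, 0.0), "anatomical"),
    ("HEAD_B", "headarms", (-0.08, 0.17, 0.02), "anatomical"),
    ("HEAD_L", "headarms", (0.0, 0.15, 0.09), "tracking"),
    ("HEAD_R", "headarms", (0.0, 0.16, -0.09), "tracking"),
]
for side, sgn in (("l", +1.0), ("r", -1.0)):
    S = side.upper()
    _MARKER_SPECS += [
        (f"THI_{S}1", f"thigh_{side}", (0.06, -0.12, sgn * 0.04), "anatomical"),
        (f"THI_{S}2", f"thigh_{side}", (0.02, -0.25, sgn * 0.06), "tracking"),
        (f"THI_{S}3", f"thigh_{side}", (-0.04, -0.18, sgn * 0.05), "tracking"),
        (f"KNE_{S}", f"thigh_{side}", (0.0, -0.40, sgn * 0.06), "anatomical"),
        (f"TIB_{S}1", f"shank_{side}", (0.04, -0.14, sgn * 0.04), "anatomical"),
        (f"TIB_{S}2", f"shank_{side}", (0.01, -0.27, sgn * 0.05), "tracking"),
        (f"TIB_{S}3", f"shank_{side}", (-0.03, -0.20, sgn * 0.04), "tracking"),
        (f"ANK_{S}", f"shank_{side}", (0.0, -0.42, sgn * 0.05), "anatomical"),
        (f"HEE_{S}", f"foot_{side}", (-0.06, 0.03, 0.0), "anatomical"),
        (f"TOE_{S}", f"foot_{side}", (0.16, -0.05, sgn * 0.03), "anatomical"),
        (f"MT5_{S}", f"foot_{side}", (0.10, -0.04, sgn * -0.065), "anatomical"),
        (f"MT1_{S}", f"foot_{side}", (0.10, -0.03, sgn * 0.045), "tracking"),
    ]


def segment_mass_fractions() -> dict[str, float]:
    return {name: frac for name, frac, _, _ in _SEG_SPECS}


def gait_skeleton(total_mass: float = _DEFAULT_TOTAL_MASS) -> SkeletonModel:
    """The 9-segment / 23-DOF legged test skeleton.

    Pelvis root (free6), ball hips, revolute knees, universal ankles, ball
    lumbar joint and universal neck — every supported joint type appears.
    Child offsets are zero, so each segment's origin sits at its parent
    joint and segment scales stretch the distal joint locations, markers
    and COM offsets.
    """
    segments = [
        BodySegment(name, frac * total_mass, np.array(com), np.diag(inert) * (frac * total_mass))
        for name, frac, com, inert in _SEG_SPECS
    ]
    ez = [[0.0, 0.0, 1.0]]
    ezx = [[0.0, 0.0, 1.0], [1.0, 0.0, 0.0]]
    joints = [
        JointDef("root", "free6", None, "pelvis", (0, 0, 0), (0, 0, 0), []),
        JointDef("lumbar", "ball3", "pelvis", "torso", (0.0, 0.09, 0.0), (0, 0, 0), []),
        JointDef("neck", "universal2", "torso", "headarms", (0.0, 0.45, 0.0), (0, 0, 0), ezx),
        JointDef("hip_l", "ball3", "pelvis", "thigh_l", (0.0, -0.06, _HIP_HALF_WIDTH), (0, 0, 0), []),
        JointDef("knee_l", "revolute1", "thigh_l", "shank_l", (0.0, -_THIGH_LEN, 0.0), (0, 0, 0), ez),
        JointDef("ankle_l", "universal2", "shank_l", "foot_l", (0.0, -_SHANK_LEN, 0.0), (0, 0, 0), ezx),
        JointDef("hip_r", "ball3", "pelvis", "thigh_r", (0.0, -0.06, -_HIP_HALF_WIDTH), (0, 0, 0), []),
        JointDef("knee_r", "revolute1", "thigh_r", "shank_r", (0.0, -_THIGH_LEN, 0.0), (0, 0, 0), ez),
        JointDef("ankle_r", "universal2", "shank_r", "foot_r", (0.0, -_SHANK_LEN, 0.0), (0, 0, 0), ezx),
    ]
    markers = [MarkerDef(lbl, seg, np.array(off), kind) for lbl, seg, off, kind in _MARKER_SPECS]
    return SkeletonModel(segments, joints, markers)


def model_height(skel: SkeletonModel, s) -> float:
    """Standing stature of a scaled model (foot sole to head top, metres)."""
    st = skel.fk(s, np.zeros(skel.n_q))
    ss = skel.seg_scales(s)
    head_top = st.o[skel.seg_index["headarms"]][1] + 0.25 * ss[skel.seg_index["headarms"]][1]
    sole = st.o[skel.seg_index["foot_l"]][1] - 0.06 * ss[skel.seg_index["foot_l"]][1]
    return float(head_top - sole)


def default_plate_geometry() -> list[dict]:
    """Two long lane plates (left lane +z, right lane -z) in the ground plane."""
    return [
        {
            "id": 1,
            "column_prefix": "p1_",
            "corners": [[-2.0, 0.0, 0.02], [8.0, 0.0, 0.02], [8.0, 0.0, 0.8], [-2.0, 0.0, 0.8]],
        },
        {
            "id": 2,
            "column_prefix": "p2_",
            "corners": [[-2.0, 0.0, -0.8], [8.0, 0.0, -0.8], [8.0, 0.0, -0.02], [-2.0, 0.0, -0.02]],
        },
    ]


_PLATE_OF_FOOT = {"foot_l": 0, "foot_r": 1}  # lane assignment


# ------------------------------------------------------------------- subject
@dataclass
class SyntheticTruth:
    s_true: np.ndarray
    p_true: np.ndarray
    masses_true: np.ndarray
    q: PoseTrajectory
    foot_force: dict  # foot -> (T,3)
    foot_cop: dict
    foot_moment: dict
    stance: np.ndarray  # (T, 2) stance weights (left, right)
    noise: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def total_mass(self):
        return float(self.masses_true.sum())


def sample_subject(
    prior: ScalingPrior,
    offset_sd: float = 0.01,
    seed: int = 0,
    skel: SkeletonModel | None = None,
):
    """Draw (s_true, p_true, masses_true) for a synthetic subject."""
    skel = skel or gait_skeleton()
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(prior.cov)
    z = np.clip(rng.standard_normal(prior.dim), -3, 3)
    s_true = prior.mean + L @ z
    p_bar = skel.default_offsets()
    # anatomical landmarks are palpated precisely; tracking markers carry the
    # full placement uncertainty
    sds = np.array(
        [offset_sd * (0.25 if m.kind == "anatomical" else 1.0) for m in skel.markers]
    )
    p_true = p_bar + rng.normal(0.0, 1.0, p_bar.shape) * sds[:, None]
    total = float(np.clip(rng.normal(_DEFAULT_TOTAL_MASS, 8.0), 45.0, 110.0))
    fracs = segment_mass_fractions()
    masses_true = np.array([fracs[seg.name] * total for seg in skel.segments])
    return s_true, p_true, masses_true


# -------------------------------------------------------------------- motion
def _smoothstep(u):
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _stance_weights(theta_l, theta_r, lam_min=0.03):
    """Smooth stance-sharing weights; each leg in stance ~60% of its cycle."""
    raw = np.stack(
        [_smoothstep((np.cos(theta_l) + 0.3) / 0.3), _smoothstep((np.cos(theta_r) + 0.3) / 0.3)],
        axis=1,
    )
    lam = raw / raw.sum(axis=1, keepdims=True)
    lam[lam < lam_min] = 0.0
    lam = lam / lam.sum(axis=1, keepdims=True)
    return lam


def generate_gait_motion(
    skel: SkeletonModel,
    s_true: np.ndarray,
    duration_s: float = 2.0,
    rate_hz: float = 100.0,
    seed: int = 0,
):
    """Smooth periodic gait-like joint trajectories with forward progression.

    Left and right leg trajectories are exact half-period phase-shifted
    copies.  Returns ``(PoseTrajectory, stance_weights)`` where the stance
    weights give the smooth force-sharing schedule between the feet.
    """
    rng = np.random.default_rng(seed)
    T = int(round(duration_s * rate_hz))
    dt = 1.0 / rate_hz
    t = np.arange(T) * dt
    # stride frequency, quantized so a half period is a whole frame count
    # (left/right trajectories are then exact shifted copies)
    f_raw = rng.uniform(0.9, 1.1)
    f = rate_hz / (2 * max(1, round(rate_hz / (2 * f_raw))))
    v = rng.uniform(1.0, 1.3)  # forward speed, m/s
    A_hip = rng.uniform(0.30, 0.40)
    A_knee = rng.uniform(0.45, 0.60)
    th_l = 2 * np.pi * f * t
    th_r = th_l + np.pi

    # pelvis height: ankle reach of the true subject plus clearance
    ss = skel.seg_scales(s_true)
    it, ish = skel.seg_index["thigh_l"], skel.seg_index["shank_l"]
    leg = _THIGH_LEN * ss[it][1] + _SHANK_LEN * ss[ish][1] + 0.06 * ss[skel.seg_index["pelvis"]][1]
    h0 = leg + 0.045

    q = np.zeros((T, skel.n_q))
    cols = {n: i for i, n in enumerate(skel.coordinate_names)}
    q[:, cols["root_tx"]] = v * t + 0.008 * np.sin(2 * th_l)
    q[:, cols["root_ty"]] = h0 + 0.012 * np.sin(2 * th_l + 0.6)
    q[:, cols["root_tz"]] = 0.012 * np.sin(th_l)
    q[:, cols["root_rx"]] = 0.02 * np.sin(th_l + 0.3)
    q[:, cols["root_ry"]] = 0.03 * np.sin(th_l + 1.1)
    q[:, cols["root_rz"]] = 0.02 * np.sin(2 * th_l)
    for side, th in (("l", th_l), ("r", th_r)):
        q[:, cols[f"hip_{side}_rx"]] = 0.04 * np.sin(th + 0.4)
        q[:, cols[f"hip_{side}_ry"]] = 0.03 * np.sin(th + 1.2)
        q[:, cols[f"hip_{side}_rz"]] = A_hip * np.sin(th)
        q[:, cols[f"knee_{side}_r0"]] = A_knee * (0.5 - 0.5 * np.cos(th - np.pi / 3)) ** 2
        q[:, cols[f"ankle_{side}_r0"]] = 0.12 * np.sin(th + 0.9)
        q[:, cols[f"ankle_{side}_r1"]] = 0.08 * np.sin(th + 2.0)
    q[:, cols["lumbar_rx"]] = 0.03 * np.sin(th_l + 0.8)
    q[:, cols["lumbar_ry"]] = 0.04 * np.sin(th_l + 2.2)
    q[:, cols["lumbar_rz"]] = 0.03 * np.sin(2 * th_l + 0.2)
    q[:, cols["neck_r0"]] = 0.03 * np.sin(th_l + 1.5)
    q[:, cols["neck_r1"]] = 0.02 * np.sin(th_l)
    return PoseTrajectory(q, dt), _stance_weights(th_l, th_r)


# ------------------------------------------------------------------- markers
def synthesize_markers(
    skel: SkeletonModel,
    s_true,
    p_true,
    q: PoseTrajectory,
    noise_sd: float = 0.0,
    occlusion_rate: float = 0.0,
    seed: int = 0,
) -> MarkerTrajectories:
    """Forward-kinematic marker synthesis with noise and random occlusion."""
    rng = np.random.default_rng(seed)
    T = q.n_frames
    M = len(skel.markers)
    frames = np.empty((T, M, 3))
    for tt in range(T):
        frames[tt] = skel.marker_world_positions(s_true, q.traj[tt], p_true)
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, frames.shape)
    present = np.ones((T, M), dtype=bool)
    if occlusion_rate > 0:
        present = rng.random((T, M)) >= occlusion_rate
        frames = frames.copy()
        frames[~present] = np.nan
    labels = [m.label for m in skel.markers]
    return MarkerTrajectories(labels, frames, present, 1.0 / q.dt)


# ----------------------------------------------------------------------- GRF
def synthesize_consistent_grf(
    skel: SkeletonModel,
    s_true,
    masses_true,
    q: PoseTrajectory,
    stance: np.ndarray,
    plate_geometry: list[dict] | None = None,
):
    """Ground loads that exactly cancel the root residual wrench.

    The required external wrench per frame comes from inverse dynamics of
    the prescribed motion with no external load; it is distributed between
    the stance feet by the smooth schedule, with each foot's COP placed
    under its segment origin (clamped into its lane plate) and the remaining
    moment stored as a free moment.  Frames whose schedule demands support
    from no foot raise.

    Returns (foot_force, foot_cop, foot_moment, plate_records).
    """
    plate_geometry = plate_geometry or default_plate_geometry()
    T = q.n_frames
    qd, qdd = finite_difference_derivatives(q.traj, q.dt)
    feet = ["foot_l", "foot_r"]
    force = {f: np.zeros((T, 3)) for f in feet}
    cop = {f: np.zeros((T, 3)) for f in feet}
    moment = {f: np.zeros((T, 3)) for f in feet}
    for t in range(T):
        tau0 = skel.inverse_dynamics(s_true, masses_true, q.traj[t], qd[t], qdd[t])
        st = skel.fk(s_true, q.traj[t])
        f_req, m0_req = skel.root_generalized_to_wrench(st, tau0[:6])
        lam = stance[t]
        if lam.sum() <= 0 and np.linalg.norm(f_req) > 1e-9:
            raise ValueError(f"frame {t}: support required but no stance foot scheduled")
        for k, foot in enumerate(feet):
            if lam[k] <= 0:
                continue
            fk = lam[k] * f_req
            o_foot = st.o[skel.seg_index[foot]]
            corners = np.asarray(plate_geometry[_PLATE_OF_FOOT[foot]]["corners"], dtype=float)
            cx = np.clip(o_foot[0], corners[:, 0].min() + 0.01, corners[:, 0].max() - 0.01)
            cz = np.clip(o_foot[2], corners[:, 2].min() + 0.01, corners[:, 2].max() - 0.01)
            ck = np.array([cx, 0.0, cz])
            force[foot][t] = fk
            cop[foot][t] = ck
            moment[foot][t] = lam[k] * m0_req - np.cross(ck, fk)
    rate = 1.0 / q.dt
    plates = []
    for foot, geo in zip(feet, plate_geometry):
        plates.append(
            ForcePlateRecord(
                str(geo["id"]),
                np.asarray(geo["corners"], dtype=float),
                force[foot],
                moment[foot],
                cop[foot],
                rate,
            )
        )
    return force, cop, moment, plates


# -------------------------------------------------------------------- trials
def make_trial(
    out_dir,
    prior: ScalingPrior,
    duration_s: float = 2.0,
    rate_hz: float = 100.0,
    noise_sd: float = 0.0,
    occlusion_rate: float = 0.0,
    offset_sd: float = 0.01,
    seed: int = 0,
):
    """Generate a full trial bundle and write it in the standard formats.

    Writes ``markers.trc``, ``grf.mot``, ``plates.yaml`` and ``truth.json``
    under ``out_dir``; returns (TrialData, SyntheticTruth, skeleton).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    skel = gait_skeleton()
    s_true, p_true, masses_true = sample_subject(prior, offset_sd=offset_sd, seed=seed, skel=skel)
    q, stance = generate_gait_motion(skel, s_true, duration_s, rate_hz, seed=seed + 1)
    markers = synthesize_markers(
        skel, s_true, p_true, q, noise_sd=noise_sd, occlusion_rate=occlusion_rate, seed=seed + 2
    )
    plate_geometry = default_plate_geometry()
    force, cop, moment, plates = synthesize_consistent_grf(
        skel, s_true, masses_true, q, stance, plate_geometry
    )
    truth = SyntheticTruth(
        s_true,
        p_true,
        masses_true,
        q,
        force,
        cop,
        moment,
        stance,
        noise={"noise_sd": noise_sd, "occlusion_rate": occlusion_rate, "offset_sd": offset_sd},
        seed=seed,
    )
    write_trc(markers, out_dir / "markers.trc")
    write_grf_mot(plates, out_dir / "grf.mot")
    with open(out_dir / "plates.yaml", "w") as fh:
        yaml.safe_dump({"plates": plate_geometry, "units": {"cop": "m"}}, fh)
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(
            {
                "seed": seed,
                "s_true": s_true.tolist(),
                "p_true": p_true.tolist(),
                "masses_true": masses_true.tolist(),
                "dt": q.dt,
                "q": q.traj.tolist(),
                "stance": stance.tolist(),
                "foot_force": {k: v.tolist() for k, v in force.items()},
                "foot_cop": {k: v.tolist() for k, v in cop.items()},
                "foot_moment": {k: v.tolist() for k, v in moment.items()},
                "noise": truth.noise,
            },
            fh,
        )
    meta = {"weight_kg": float(masses_true.sum()), "height_m": None, "sex": None}
    trial = TrialData(markers, plates, meta)
    return trial, truth, skel
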