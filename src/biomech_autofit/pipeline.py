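"""End-to-end orchestration: configuration, staged execution, reports.

``run_kinematics`` executes functional joint-geometry estimation, scale and
pose initialization and the MAP kinematic fit; ``run_dynamics`` continues
with jerk smoothing, the linear COM fit, the iterative root fit, the final
residual-minimizing tuning and the residual report.  Every stage writes its
artifacts under the run directory so later stages can be re-run from disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dynamics_fit as dyn
from . import io_formats as iof
from . import joint_geometry as jg
from . import kinematic_fit as kf
from .skeleton import PoseTrajectory, SkeletonModel, load_skeleton
from .synthetic import gait_skeleton

log = logging.getLogger("biomech_autofit")

__all__ = [
    "PipelineConfig",
    "run_kinematics",
    "run_dynamics",
    "compare_to_reference",
    "write_angles_mot",
    "read_angles_mot",
]


@dataclass
class PipelineConfig:
    """All knobs of the sequential pipeline; every default documented."""

    # inputs
    skeleton: str | None = None  # None -> built-in gait fixture
    skeleton_format: str = "native_json"
    trc: str = ""
    grf: str | None = None
    plates: str | None = None  # plate geometry YAML
    height_m: float | None = None
    weight_kg: float | None = None
    sex: str | None = None
    # stage toggles
    kinematics_only: bool = False
    # io / assignment
    force_threshold_n: float = 10.0  # plate force magnitude gate
    cutoff_hz: float = 15.0  # GRF low-pass before resampling
    max_foot_height_m: float = 0.25  # "foot near ground" gate
    # kinematic fit
    marker_sd_m: float = 0.01
    anatomical_offset_sd_m: float = 0.005
    tracking_offset_sd_m: float = 0.05
    # frames entering the joint MAP NLP (every k-th frame; k is logged).
    # 40 recovers scales/offsets as well as denser sampling at a fraction of
    # the cost; the per-frame IK polish covers the full trajectory anyway.
    max_map_frames: int = 40
    map_max_nfev: int = 400
    # dynamics fit
    jerk_tracking_weight: float = 1e10
    residual_force_sd_n: float = 1.0
    residual_torque_sd_nm: float = 1.0
    angular_tol: float = 1e-6
    angular_max_iter: int = 100
    dynamics_passes: int = 2
    residual_force_threshold_pct: float = 5.0
    residual_torque_threshold_pct: float = 1.0
    # misc
    out_dir: str = "run_output"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def content_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _load_model(config: PipelineConfig) -> SkeletonModel:
    if config.skeleton is None:
        return gait_skeleton()
    return load_skeleton(config.skeleton, config.skeleton_format)


def write_angles_mot(skel: SkeletonModel, q: PoseTrajectory, path, name="joint angles"):
    """Write a pose trajectory as MOT (rotational columns in degrees)."""
    cols = {"time": np.arange(q.n_frames) * q.dt}
    for j, cname in enumerate(skel.coordinate_names):
        v = q.traj[:, j]
        cols[cname] = np.rad2deg(v) if skel.rotational_dofs[j] else v
    iof.write_mot_table(pd.DataFrame(cols), path, name=name, in_degrees=True)


def read_angles_mot(skel: SkeletonModel, path) -> PoseTrajectory:
    df, header = iof.read_mot_table(path)
    t = df["time"].to_numpy()
    dt = float(np.mean(np.diff(t))) if len(t) > 1 else 1.0
    traj = np.zeros((len(df), skel.n_q))
    in_deg = header.get("inDegrees", "no").lower() == "yes"
    for j, cname in enumerate(skel.coordinate_names):
        v = df[cname].to_numpy()
        if in_deg and skel.rotational_dofs[j]:
            v = np.deg2rad(v)
        traj[:, j] = v
    return PoseTrajectory(traj, dt)


@dataclass
class KinematicsStage:
    result: kf.KinematicFitResult
    skel: SkeletonModel
    traj: iof.MarkerTrajectories
    prior: kf.ScalingPrior
    timings: dict = field(default_factory=dict)


def run_kinematics(config: PipelineConfig, prior: kf.ScalingPrior | None = None) -> KinematicsStage:
    """Stages 4.1-4.3: joint geometry, scale/pose initialization, MAP fit."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    skel = _load_model(config)
    traj = iof.read_trc(config.trc)
    prior = prior or kf.default_scaling_prior(skel)
    prior = kf.condition_prior(prior, config.height_m, config.weight_kg, config.sex)
    timings = {}

    t0 = time.time()
    geom = jg.estimate_joint_geometry(traj, jg.groups_from_skeleton(skel))
    timings["joint_geometry_s"] = time.time() - t0
    with open(out / "joint_geometry.json", "w") as fh:
        json.dump({k: {kk: vv for kk, vv in g.to_report().items() if kk != "centers_m"} for k, g in geom.items()}, fh, indent=1)

    p0 = kf.init_marker_offsets(skel)
    t0 = time.time()
    s0, alphas = kf.init_scales(skel, geom, traj, p0, prior)
    timings["init_scales_s"] = time.time() - t0
    t0 = time.time()
    q0, ik_flags = kf.init_poses(skel, s0, p0, traj)
    timings["init_poses_s"] = time.time() - t0

    cfg = kf.MapFitConfig(
        marker_sd=config.marker_sd_m,
        anatomical_offset_sd=config.anatomical_offset_sd_m,
        tracking_offset_sd=config.tracking_offset_sd_m,
        max_map_frames=config.max_map_frames,
        max_nfev=config.map_max_nfev,
    )
    t0 = time.time()
    result = kf.bilevel_map_fit(skel, prior, traj, s0, p0, q0, cfg)
    timings["map_fit_s"] = time.time() - t0
    for t in ik_flags:
        result.flags.append(f"init frame {t}: <3 visible markers")
    log.info(
        "kinematics: marker RMSE %.2f mm, max %.2f mm, stationarity %.1e",
        1e3 * result.marker_rmse, 1e3 * result.marker_max, result.stationarity_norm,
    )

    fitted = skel.to_json_dict()
    fitted["fitted"] = {"scales": result.s.tolist(), "marker_offsets": result.p.tolist()}
    with open(out / "model_fitted.json", "w") as fh:
        json.dump(fitted, fh, indent=1)
    write_angles_mot(skel, result.q, out / "angles.mot")
    report = {
        "config_hash": config.content_hash(),
        "marker_rmse_m": result.marker_rmse,
        "marker_max_m": result.marker_max,
        "stationarity_norm": result.stationarity_norm,
        "objective_init": result.objective_init,
        "objective_final": result.objective_final,
        "per_marker_rmse_m": result.per_marker_rmse,
        "timings_s": timings,
        "flags": result.flags,
    }
    with open(out / "kinematics_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return KinematicsStage(result, skel, traj, prior, timings)


@dataclass
class DynamicsStage:
    result: dyn.DynamicsFitResult
    report: dict
    foot_wrenches: iof.FootWrenches
    timings: dict = field(default_factory=dict)


def _load_cached_kinematics(config: PipelineConfig) -> KinematicsStage | None:
    """Reload the kinematics stage from its written artifacts, if they match
    the current configuration (content-hash keyed stage cache)."""
    out = Path(config.out_dir)
    report_path = out / "kinematics_report.json"
    model_path = out / "model_fitted.json"
    angles_path = out / "angles.mot"
    if not (report_path.exists() and model_path.exists() and angles_path.exists()):
        return None
    report = json.loads(report_path.read_text())
    if report.get("config_hash") != config.content_hash():
        return None
    skel = _load_model(config)
    traj = iof.read_trc(config.trc)
    prior = kf.condition_prior(
        kf.default_scaling_prior(skel), config.height_m, config.weight_kg, config.sex
    )
    fitted = json.loads(model_path.read_text())["fitted"]
    q = read_angles_mot(skel, angles_path)
    result = kf.KinematicFitResult(
        np.asarray(fitted["scales"]),
        np.asarray(fitted["marker_offsets"]),
        q,
        report["marker_rmse_m"],
        report["marker_max_m"],
        report["stationarity_norm"],
        report["per_marker_rmse_m"],
        report["objective_init"],
        report["objective_final"],
        list(report["flags"]),
    )
    log.info("kinematics stage reloaded from cache (%s)", out)
    return KinematicsStage(result, skel, traj, prior, report.get("timings_s", {}))


def run_dynamics(config: PipelineConfig, kin: KinematicsStage | None = None) -> DynamicsStage:
    """Stages 4.4-4.5: COM fit, root fit, mass tuning, residual report."""
    if config.grf is None or config.plates is None:
        raise ValueError("dynamics requested but no GRF file / plate geometry configured")
    out = Path(config.out_dir)
    if kin is None:
        kin = _load_cached_kinematics(config)
    if kin is None:
        kin = run_kinematics(config)
    skel, traj, result = kin.skel, kin.traj, kin.result
    timings = {}

    plates = iof.read_grf_mot(config.grf, iof.load_plate_config(config.plates))
    trial = iof.synchronize(iof.TrialData(traj, plates), cutoff_hz=config.cutoff_hz)

    t0 = time.time()
    q_s = dyn.smooth_min_jerk(result.q.traj, result.q.dt, config.jerk_tracking_weight)
    q_smooth = PoseTrajectory(q_s, result.q.dt)
    timings["smoothing_s"] = time.time() - t0

    foot_wrenches = iof.assign_forces_to_feet(
        trial, skel, result.s, q_smooth.traj,
        force_threshold=config.force_threshold_n,
        max_foot_height=config.max_foot_height_m,
    )
    f_tot = foot_wrenches.total_force()

    # linear COM fit; iterate once so the COM observation uses the fitted mass
    t0 = time.time()
    masses = skel.default_masses()
    fracs = masses / masses.sum()
    A, b = dyn.build_com_system(f_tot, q_smooth.dt, skel.gravity)
    for _ in range(2):
        Z_hat = skel.com_trajectory(result.s, masses, q_smooth.traj)
        com_fit = dyn.com_linear_fit(Z_hat, A, b)
        if not com_fit.mu_valid:
            break
        masses = fracs * com_fit.mass
    timings["com_fit_s"] = time.time() - t0
    log.info("COM fit: mass %.2f kg, residual %.2f mm", com_fit.mass, 1e3 * com_fit.lsq_residual)

    q_com = dyn.apply_root_translation(skel, result.s, masses, q_smooth, com_fit.Z)
    Theta_hat = q_smooth.traj[:, 3:6]

    t0 = time.time()
    mu = 1.0 / masses.sum()
    root_fit = dyn.root_angular_fit(
        skel, result.s, masses, q_com, foot_wrenches, mu, com_fit.Z, Theta_hat,
        tol=config.angular_tol, max_iter=config.angular_max_iter,
    )
    timings["root_fit_s"] = time.time() - t0
    log.info("root angular fit: %d iterations, converged=%s", root_fit.iterations, root_fit.converged)

    t0 = time.time()
    dres = dyn.final_dynamics_map(
        skel, kin.prior, traj, foot_wrenches, result.s, result.p, root_fit.q, masses, mu,
        com_fit.Z, Theta_hat,
        residual_force_sd=config.residual_force_sd_n,
        residual_torque_sd=config.residual_torque_sd_nm,
        marker_sd=config.marker_sd_m,
        anatomical_offset_sd=config.anatomical_offset_sd_m,
        tracking_offset_sd=config.tracking_offset_sd_m,
        n_passes=config.dynamics_passes,
        angular_tol=config.angular_tol,
        angular_max_iter=config.angular_max_iter,
    )
    timings["final_map_s"] = time.time() - t0

    report = dyn.residual_report(
        dres,
        {
            "force_pct": config.residual_force_threshold_pct,
            "torque_pct": config.residual_torque_threshold_pct,
        },
    )
    report.update(
        {
            "config_hash": config.content_hash(),
            "total_mass_kg": float(dres.masses.sum()),
            "com_fit_mass_kg": com_fit.mass,
            "root_fit_iterations": root_fit.iterations,
            "root_fit_converged": root_fit.converged,
            "marker_rmse_m": dres.marker_rmse,
            "timings_s": timings,
            "flags": dres.flags,
        }
    )

    torques = dyn.joint_torque_series(skel, dres.s, dres.masses, dres.q, foot_wrenches)
    cols = {"time": np.arange(dres.q.n_frames) * dres.q.dt}
    for j, cname in enumerate(skel.coordinate_names[6:]):
        cols[cname + "_moment"] = torques[:, j]
    iof.write_mot_table(pd.DataFrame(cols), out / "torques.mot", name="joint torques")
    write_angles_mot(skel, dres.q, out / "angles_dynamics.mot")
    with open(out / "residuals.json", "w") as fh:
        json.dump(
            {
                "residual_force_n": dres.residual_force.tolist(),
                "residual_torque_nm": dres.residual_torque.tolist(),
                **{k: v for k, v in report.items() if not isinstance(v, dict)},
            },
            fh,
        )
    with open(out / "dynamics_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    with open(out / "residual_summary.txt", "w") as fh:
        fh.write(
            "Residual check\n"
            f"  RMS residual force : {dres.residual_force_pct:.4f}% of peak GRF "
            f"(threshold {config.residual_force_threshold_pct}%) -> "
            f"{'PASS' if report['force_pass'] else 'FAIL'}\n"
            f"  RMS residual torque: {dres.residual_torque_pct:.4f}% of peak GRF x COM height "
            f"(threshold {config.residual_torque_threshold_pct}%) -> "
            f"{'PASS' if report['torque_pass'] else 'FAIL'}\n"
        )
    return DynamicsStage(dres, report, foot_wrenches, timings)


def compare_to_reference(ours: pd.DataFrame, reference: pd.DataFrame) -> dict:
    """Per-coordinate RMSE between two MOT-style tables on a common grid."""
    shared = [c for c in ours.columns if c != "time" and c in reference.columns]
    if not shared:
        raise ValueError("no overlapping coordinates to compare")
    t_ours = ours["time"].to_numpy()
    t_ref = reference["time"].to_numpy()
    t0, t1 = max(t_ours[0], t_ref[0]), min(t_ours[-1], t_ref[-1])
    if t1 <= t0:
        raise ValueError("no overlapping time range")
    grid = t_ours[(t_ours >= t0) & (t_ours <= t1)]
    per = {}
    for c in shared:
        a = np.interp(grid, t_ours, ours[c].to_numpy())
        b = np.interp(grid, t_ref, reference[c].to_numpy())
        per[c] = float(np.sqrt(np.mean((a - b) ** 2)))
    return {"per_coordinate_rmse": per, "mean_rmse": float(np.mean(list(per.values())))}
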