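"""Dynamic-consistency fitting: jerk smoothing, linear COM fit, iterative
root-rotation fit, mass tuning and residual reporting.

The stages run in sequence on the kinematic solution:

1. :func:`smooth_min_jerk` removes acceleration artifacts.
2. :func:`com_linear_fit` recovers total mass and COM initial conditions
   from the semi-explicit-Euler linear system built by
   :func:`build_com_system`; :func:`apply_root_translation` moves the pelvis
   so the model COM follows the fitted trajectory.
3. :func:`root_angular_fit` iterates the linearized root-rotation system of
   :func:`build_root_system` until the stacked (COM, root-rotation)
   trajectory converges.
4. :func:`final_dynamics_map` tunes segment masses (linear in the residual
   wrench) alternating with root-trajectory refits, keeping the best
   iterate of the full MAP objective.
5. :func:`residual_report` normalizes residuals against peak ground
   reaction force (and times mean COM height for torques) and compares to
   recommended thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import lsq_linear

from .io_formats import FootWrenches
from .kinematic_fit import ScalingPrior, marker_error_report
from .skeleton import PoseTrajectory, SkeletonModel, finite_difference_derivatives

__all__ = [
    "ComFitResult",
    "RootFitResult",
    "DynamicsFitResult",
    "MassUnidentifiableError",
    "smooth_min_jerk",
    "build_com_system",
    "com_linear_fit",
    "apply_root_translation",
    "build_root_system",
    "root_angular_fit",
    "final_dynamics_map",
    "residual_wrench_series",
    "joint_torque_series",
    "residual_report",
]

_PINV_RCOND = 1e-10


class MassUnidentifiableError(RuntimeError):
    """Raised when the GRF data carry no information about the subject mass."""


@dataclass
class ComFitResult:
    zeta: np.ndarray  # (7,) = [z1 (3), zdot1 (3), mu]
    mass: float  # kg, 1 / mu
    Z: np.ndarray  # (T, 3) fitted COM trajectory
    lsq_residual: float  # RMS metres
    mu_valid: bool


@dataclass
class RootFitResult:
    xi: np.ndarray  # (12,) = [z1, zdot1, theta1, thetadot1]
    Z: np.ndarray  # (T, 3)
    Theta: np.ndarray  # (T, 3)
    q: PoseTrajectory  # trajectory with the fitted root written in
    iterations: int
    converged: bool


@dataclass
class DynamicsFitResult:
    s: np.ndarray
    p: np.ndarray
    q: PoseTrajectory
    masses: np.ndarray
    residual_force: np.ndarray  # (T, 3) world N
    residual_torque: np.ndarray  # (T, 3) world N m, about the root joint
    residual_force_pct: float  # RMS force, % of peak GRF
    residual_torque_pct: float  # RMS torque, % of (peak GRF x mean COM height)
    marker_rmse: float
    objective_init: float = np.nan
    objective_final: float = np.nan
    flags: list = field(default_factory=list)


# ------------------------------------------------------------ jerk smoothing
def smooth_min_jerk(traj: np.ndarray, dt: float, tracking_weight: float = 1.0) -> np.ndarray:
    """Per-coordinate quadratic smoothing: minimize sum of squared third
    differences (jerk) plus ``tracking_weight`` times squared deviation from
    the input.  Deterministic banded linear solve."""
    traj = np.atleast_2d(np.asarray(traj, dtype=float))
    T = traj.shape[0]
    if T < 4:
        return traj.copy()
    e = np.ones(T - 3)
    D3 = sp.diags([-e, 3 * e, -3 * e, e], [0, 1, 2, 3], shape=(T - 3, T)) / dt**3
    sqw = np.sqrt(tracking_weight)
    # stacked least-squares form: far better conditioned than the normal
    # equations (exact on jerk-free inputs)
    A = np.vstack([D3.toarray(), sqw * np.eye(T)])
    rhs = np.vstack([np.zeros((T - 3, traj.shape[1])), sqw * traj])
    out, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    return out


# --------------------------------------------------------------- linear COM
def build_com_system(forces: np.ndarray, dt: float, gravity: np.ndarray):
    """Linear map from [z1, zdot1, mu] to the stacked COM trajectory.

    Semi-explicit Euler: zdot_{t+1} = zdot_t + (mu f_t + g) dt;
    z_{t+1} = z_t + zdot_{t+1} dt, which makes row block t
    ``z_t = z1 + (t-1) dt zdot1 + dt^2 sum_{i<t} (t-i)(mu f_i + g)``.
    Returns (A, b) with A of shape (3T, 7) and b of shape (3T,).
    """
    forces = np.atleast_2d(np.asarray(forces, dtype=float))
    T = forces.shape[0]
    if T < 1:
        raise ValueError("need at least one frame")
    g = np.asarray(gravity, dtype=float)
    A = np.zeros((3 * T, 7))
    b = np.zeros(3 * T)
    fcum = np.zeros(3)  # sum_{i<t} (t-i) f_i, updated incrementally
    frun = np.zeros(3)  # sum_{i<t} f_i
    gcount = 0  # sum_{i<t} (t-i)
    grun = 0
    for t in range(T):
        if t > 0:
            fcum += frun + forces[t - 1]
            frun += forces[t - 1]
            gcount += grun + 1
            grun += 1
        r = slice(3 * t, 3 * t + 3)
        A[r, 0:3] = np.eye(3)
        A[r, 3:6] = t * dt * np.eye(3)
        A[r, 6] = dt**2 * fcum
        b[r] = dt**2 * gcount * g
    return A, b


def com_linear_fit(Z_hat: np.ndarray, A: np.ndarray, b: np.ndarray) -> ComFitResult:
    """Minimum-norm least-squares fit of [z1, zdot1, mu] (truncated SVD)."""
    Z_hat = np.atleast_2d(np.asarray(Z_hat, dtype=float))
    target = Z_hat.ravel() - b
    if np.linalg.norm(A[:, 6]) < 1e-12:
        raise MassUnidentifiableError(
            "all ground reaction forces are zero; subject mass is unidentifiable"
        )
    zeta, *_ = np.linalg.lstsq(A, target, rcond=_PINV_RCOND)
    mu = zeta[6]
    valid = mu > 0
    if not valid:
        warnings.warn(f"COM fit produced non-physical inverse mass mu={mu:.3g}")
    Z = (A @ zeta + b).reshape(-1, 3)
    rms = float(np.sqrt(np.mean((Z - Z_hat) ** 2)))
    return ComFitResult(zeta, float(1.0 / mu) if valid else np.nan, Z, rms, bool(valid))


def apply_root_translation(
    skel: SkeletonModel, s, masses, q: PoseTrajectory, Z: np.ndarray
) -> PoseTrajectory:
    """Shift the root translation per frame so the model COM follows ``Z``;
    all other coordinates are untouched."""
    out = q.traj.copy()
    for t in range(q.n_frames):
        com = skel.com_position(s, masses, out[t])
        out[t, 0:3] += Z[t] - com
    return PoseTrajectory(out, q.dt)


# ------------------------------------------------------------- angular fit
def _total_wrench(foot_wrenches: FootWrenches):
    """Total external force and origin-moment per frame, (T,3) each."""
    w = foot_wrenches.wrenches_about_origin()
    f = sum(v[0] for v in w.values())
    m0 = sum(v[1] for v in w.values())
    return f, m0


def _skew(v):
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])


def build_root_system(
    skel: SkeletonModel,
    s,
    masses,
    q: PoseTrajectory,
    foot_wrenches: FootWrenches,
    mu: float,
):
    """Assemble the linearized (COM, root-rotation) system at the current
    trajectory estimate.

    The upper quadrants integrate the COM exactly (mass fixed at 1/mu, so
    the force contribution moves into the constant term).  The lower-left
    quadrant chains the per-frame sensitivity of the root-rotation
    accelerations to COM displacement (moment-arm change of the ground
    forces against the root block of the mass matrix); the lower-right
    quadrant integrates the rotation initial conditions.  The constant term
    carries gravity, applied moments and Coriolis effects evaluated at the
    current estimate.

    Returns (A_tilde (6T, 12), b_tilde (6T,)).
    """
    T, dt = q.n_frames, q.dt
    g = skel.gravity
    f_tot, _ = _total_wrench(foot_wrenches)
    qd, qdd = finite_difference_derivatives(q.traj, dt)

    # per-frame rotational acceleration at the current estimate and its
    # sensitivity to COM displacement
    theta_acc0 = np.zeros((T, 3))
    G = np.zeros((T, 3, 3))
    z_cur = np.zeros((T, 3))
    for t in range(T):
        st = skel.fk(s, q.traj[t])
        z_cur[t] = skel.com_position(s, masses, q.traj[t], fkstate=st)
        M = skel.mass_matrix(s, masses, q.traj[t], fkstate=st)
        bias = skel.inverse_dynamics(s, masses, q.traj[t], qd[t], np.zeros(skel.n_q))
        Q_ext = skel.generalized_external_forces(st, foot_wrenches.external_wrenches_frame(t))
        rhs = Q_ext[:6] - bias[:6] - M[:6, 6:] @ qdd[t, 6:]
        M_rr = M[:6, :6]
        acc_root = np.linalg.solve(M_rr, rhs)
        theta_acc0[t] = acc_root[3:6]
        W = st.dof_axis[3:6]  # rows: world axes of the root Euler dofs
        Minv_rr = np.linalg.inv(M_rr)
        # dQ_rot = W^T (f x dz); dtheta_acc = Minv[3:,3:] W^T [f]x dz
        G[t] = Minv_rr[3:6, 3:6] @ W.T @ _skew(f_tot[t])

    A = np.zeros((6 * T, 12))
    b = np.zeros(6 * T)
    # COM part (rows 0..3T): z_t = z1 + (t)dt zdot1 + d_t
    d = np.zeros((T, 3))
    acc = mu * f_tot + g  # fixed-mass COM acceleration per frame
    fcum = np.zeros(3)
    frun = np.zeros(3)
    for t in range(T):
        if t > 0:
            fcum += frun + acc[t - 1]
            frun += acc[t - 1]
        r = slice(3 * t, 3 * t + 3)
        d[t] = dt**2 * fcum
        A[r, 0:3] = np.eye(3)
        A[r, 3:6] = t * dt * np.eye(3)
        b[r] = d[t]
    # rotation part (rows 3T..6T)
    h = theta_acc0 + np.einsum("tij,tj->ti", G, d - z_cur)  # constant accel parts
    Hcum = np.zeros(3)
    Hrun = np.zeros(3)
    Gz = np.zeros((3, 3))  # sum (t-i) G_i
    Gz_run = np.zeros((3, 3))
    Gzd = np.zeros((3, 3))  # sum (t-i)(i)dt G_i
    Gzd_run = np.zeros((3, 3))
    for t in range(T):
        if t > 0:
            Hcum = Hcum + Hrun + h[t - 1]
            Hrun = Hrun + h[t - 1]
            Gz = Gz + Gz_run + G[t - 1]
            Gz_run = Gz_run + G[t - 1]
            Gzd = Gzd + Gzd_run + (t - 1) * dt * G[t - 1]
            Gzd_run = Gzd_run + (t - 1) * dt * G[t - 1]
        r = slice(3 * T + 3 * t, 3 * T + 3 * t + 3)
        A[r, 0:3] = dt**2 * Gz
        A[r, 3:6] = dt**2 * Gzd
        A[r, 6:9] = np.eye(3)
        A[r, 9:12] = t * dt * np.eye(3)
        b[r] = dt**2 * Hcum
    return A, b


def root_angular_fit(
    skel: SkeletonModel,
    s,
    masses,
    q: PoseTrajectory,
    foot_wrenches: FootWrenches,
    mu: float,
    Z_hat: np.ndarray,
    Theta_hat: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> RootFitResult:
    """Iteratively rebuild and solve the linearized root system until the
    stacked trajectory converges (max-norm change below ``tol``)."""
    q_cur = PoseTrajectory(q.traj.copy(), q.dt)
    target = np.concatenate([np.asarray(Z_hat).ravel(), np.asarray(Theta_hat).ravel()])
    Xi_prev = None
    converged = False
    iterations = 0
    xi = np.zeros(12)
    T = q.n_frames
    Z = np.asarray(Z_hat).copy()
    Theta = np.asarray(Theta_hat).copy()
    for it in range(max_iter):
        iterations = it + 1
        A, b = build_root_system(skel, s, masses, q_cur, foot_wrenches, mu)
        xi, *_ = np.linalg.lstsq(A, target - b, rcond=_PINV_RCOND)
        Xi = A @ xi + b
        Z = Xi[: 3 * T].reshape(T, 3)
        Theta = Xi[3 * T :].reshape(T, 3)
        new_traj = q_cur.traj.copy()
        new_traj[:, 3:6] = Theta
        q_cur = apply_root_translation(skel, s, masses, PoseTrajectory(new_traj, q.dt), Z)
        if Xi_prev is not None and np.max(np.abs(Xi - Xi_prev)) <= tol:
            converged = True
            break
        Xi_prev = Xi
    if not converged:
        warnings.warn(f"root angular fit did not converge in {max_iter} iterations")
    return RootFitResult(xi, Z, Theta, q_cur, iterations, converged)


# -------------------------------------------------------------- residuals
def residual_wrench_series(skel, s, masses, q: PoseTrajectory, foot_wrenches: FootWrenches):
    """Root residual (force, torque-about-root-joint) per frame, world frame."""
    qd, qdd = finite_difference_derivatives(q.traj, q.dt)
    T = q.n_frames
    f_res = np.zeros((T, 3))
    t_res = np.zeros((T, 3))
    for t in range(T):
        tau = skel.inverse_dynamics(
            s, masses, q.traj[t], qd[t], qdd[t], foot_wrenches.external_wrenches_frame(t)
        )
        st = skel.fk(s, q.traj[t])
        f, m0 = skel.root_generalized_to_wrench(st, tau[:6])
        pt = st.dof_point[3]
        f_res[t] = f
        t_res[t] = m0 - np.cross(pt, f)  # torque about the root joint origin
    return f_res, t_res


def joint_torque_series(skel, s, masses, q: PoseTrajectory, foot_wrenches: FootWrenches):
    """Generalized forces for the non-root coordinates, (T, n_q - 6)."""
    qd, qdd = finite_difference_derivatives(q.traj, q.dt)
    out = np.zeros((q.n_frames, skel.n_q - 6))
    for t in range(q.n_frames):
        tau = skel.inverse_dynamics(
            s, masses, q.traj[t], qd[t], qdd[t], foot_wrenches.external_wrenches_frame(t)
        )
        out[t] = tau[6:]
    return out


def polish_root_residuals(
    skel: SkeletonModel,
    s,
    masses,
    q: PoseTrajectory,
    foot_wrenches: FootWrenches,
    n_iter: int = 3,
    damping: float = 1e-4,
) -> PoseTrajectory:
    """Gauss-Newton reduction of the root residual over the root coordinates.

    The residual's dominant sensitivity to the root trajectory is through the
    finite-difference accelerations, giving a banded approximate Jacobian
    ``M_rr(t) * stencil / dt^2``.  A few damped iterations drive the residual
    toward zero everywhere, including the trial edges where the one-sided
    difference convention conflicts with forward integration.  The implied
    trajectory adjustments are O(residual * dt^2 / mass) — micrometres — so
    the marker fit is unaffected.
    """
    traj = q.traj.copy()
    T, dt = q.n_frames, q.dt
    if T < 4:
        return PoseTrajectory(traj, dt)

    def residual_gen(traj_):
        qd, qdd = finite_difference_derivatives(traj_, dt)
        r = np.zeros((T, 6))
        for t in range(T):
            tau = skel.inverse_dynamics(
                s, masses, traj_[t], qd[t], qdd[t], foot_wrenches.external_wrenches_frame(t)
            )
            r[t] = tau[:6]
        return r

    # second-difference stencil rows of the shared convention
    def stencil(t):
        if t == 0:
            return [(0, 1.0), (1, -2.0), (2, 1.0)]
        if t == T - 1:
            return [(T - 3, 1.0), (T - 2, -2.0), (T - 1, 1.0)]
        return [(t - 1, 1.0), (t, -2.0), (t + 1, 1.0)]

    best = traj
    best_cost = None
    for _ in range(n_iter):
        r = residual_gen(traj)
        cost = float(np.sum(r**2))
        if best_cost is None or cost < best_cost:
            best, best_cost = traj.copy(), cost
        rowsA, colsA, data = [], [], []
        for t in range(T):
            M_rr = skel.mass_matrix(s, masses, traj[t])[:6, :6]
            for tau_f, w in stencil(t):
                B = M_rr * (w / dt**2)
                rr, cc = np.meshgrid(
                    np.arange(6 * t, 6 * t + 6), np.arange(6 * tau_f, 6 * tau_f + 6), indexing="ij"
                )
                rowsA.append(rr.ravel())
                colsA.append(cc.ravel())
                data.append(B.ravel())
        A = sp.coo_matrix(
            (np.concatenate(data), (np.concatenate(rowsA), np.concatenate(colsA))),
            shape=(6 * T, 6 * T),
        ).tocsr()
        H = (A.T @ A + damping * (1.0 / dt**4) * sp.eye(6 * T)).tocsc()
        from scipy.sparse.linalg import spsolve

        delta = spsolve(H, -A.T @ r.ravel())
        traj = traj.copy()
        traj[:, :6] += delta.reshape(T, 6)
    r = residual_gen(traj)
    if float(np.sum(r**2)) > best_cost:
        traj = best
    return PoseTrajectory(traj, dt)


# ----------------------------------------------------------- final MAP step
def _unit_mass_columns(skel, s, q_traj, qd, qdd):
    """Per-frame root-6 generalized inertial+gravity force per unit segment mass."""
    T = q_traj.shape[0]
    cols = np.zeros((T, 6, skel.n_seg))
    for t in range(T):
        cols[t] = skel.unit_mass_root_columns(s, q_traj[t], qd[t], qdd[t])
    return cols


def _map_objective(skel, prior, traj, s, p, q, masses, foot_wrenches, config):
    """Full final-stage MAP objective: marker term + priors + residual penalty."""
    from .kinematic_fit import _match_marker_columns

    cols = _match_marker_columns(skel, traj)
    w_x = 1.0 / config["marker_sd"]
    obj = 0.0
    for t in range(traj.n_frames):
        x = skel.marker_world_positions(s, q.traj[t], p)
        for mi, ci in cols.items():
            if traj.present[t, ci]:
                obj += 0.5 * w_x**2 * float(np.sum((x[mi] - traj.frames[t, ci]) ** 2))
    obj += prior.neg_log(s)
    p_bar = skel.default_offsets()
    for i, m in enumerate(skel.markers):
        sd = config["anatomical_offset_sd"] if m.kind == "anatomical" else config["tracking_offset_sd"]
        obj += 0.5 * float(np.sum((p[i] - p_bar[i]) ** 2)) / sd**2
    f_res, t_res = residual_wrench_series(skel, s, masses, q, foot_wrenches)
    obj += 0.5 * float(np.sum(f_res**2)) / config["residual_force_sd"] ** 2
    obj += 0.5 * float(np.sum(t_res**2)) / config["residual_torque_sd"] ** 2
    return obj


def final_dynamics_map(
    skel: SkeletonModel,
    prior: ScalingPrior,
    traj,
    foot_wrenches: FootWrenches,
    s,
    p,
    q: PoseTrajectory,
    masses0: np.ndarray,
    mu: float,
    Z_hat: np.ndarray,
    Theta_hat: np.ndarray,
    residual_force_sd: float = 1.0,
    residual_torque_sd: float = 1.0,
    marker_sd: float = 0.01,
    anatomical_offset_sd: float = 0.005,
    tracking_offset_sd: float = 0.05,
    mass_prior_sd_frac: float = 0.25,
    n_passes: int = 2,
    angular_tol: float = 1e-6,
    angular_max_iter: int = 100,
) -> DynamicsFitResult:
    """Final residual-minimizing tuning of segment masses and root kinematics.

    The root residual wrench is affine in the segment masses at fixed
    kinematics, so the mass step is an exact bounded linear least-squares
    solve (residual penalty + Gaussian prior on masses around the
    linear-stage estimate).  Mass steps alternate with root-trajectory
    refits; the iterate with the best full MAP objective is returned, which
    guarantees the objective never increases relative to the initialization.
    """
    config = {
        "marker_sd": marker_sd,
        "anatomical_offset_sd": anatomical_offset_sd,
        "tracking_offset_sd": tracking_offset_sd,
        "residual_force_sd": residual_force_sd,
        "residual_torque_sd": residual_torque_sd,
    }
    flags = []
    masses = masses0.copy().astype(float)
    q_cur = PoseTrajectory(q.traj.copy(), q.dt)
    obj_init = _map_objective(skel, prior, traj, s, p, q_cur, masses, foot_wrenches, config)
    best = (obj_init, masses.copy(), q_cur)

    T = q.n_frames
    for it in range(n_passes):
        qd, qdd = finite_difference_derivatives(q_cur.traj, q.dt)
        cols = _unit_mass_columns(skel, s, q_cur.traj, qd, qdd)
        rhs = np.zeros((T, 6))
        for t in range(T):
            st = skel.fk(s, q_cur.traj[t])
            rhs[t] = skel.generalized_external_forces(
                st, foot_wrenches.external_wrenches_frame(t)
            )[:6]
        w = np.concatenate(
            [np.full(3, 1.0 / residual_force_sd), np.full(3, 1.0 / residual_torque_sd)]
        )
        Amat = (cols * w[None, :, None]).reshape(T * 6, skel.n_seg)
        bvec = (rhs * w[None, :]).reshape(T * 6)
        prior_w = 1.0 / (mass_prior_sd_frac * masses)
        Amat = np.vstack([Amat, np.diag(prior_w)])
        bvec = np.concatenate([bvec, prior_w * masses])
        sol = lsq_linear(Amat, bvec, bounds=(0.2 * masses0, 5.0 * masses0))
        masses_new = sol.x
        mu_new = 1.0 / masses_new.sum()
        rf = root_angular_fit(
            skel, s, masses_new, q_cur, foot_wrenches, mu_new, Z_hat, Theta_hat,
            tol=angular_tol, max_iter=angular_max_iter,
        )
        q_pol = polish_root_residuals(skel, s, masses_new, rf.q, foot_wrenches)
        masses, q_cur, mu = masses_new, q_pol, mu_new
        obj = _map_objective(skel, prior, traj, s, p, q_cur, masses, foot_wrenches, config)
        if obj < best[0]:
            best = (obj, masses.copy(), q_cur)
        if not rf.converged:
            flags.append(f"pass {it}: angular refit not converged")

    obj_final, masses, q_cur = best
    f_res, t_res = residual_wrench_series(skel, s, masses, q_cur, foot_wrenches)
    fpct, tpct = _normalized_residuals(skel, s, masses, q_cur, foot_wrenches, f_res, t_res)
    rmse, _, _ = marker_error_report(skel, s, p, q_cur, traj)
    return DynamicsFitResult(
        s, p, q_cur, masses, f_res, t_res, fpct, tpct, rmse, obj_init, obj_final, flags
    )


def _normalized_residuals(skel, s, masses, q, foot_wrenches, f_res, t_res):
    f_tot, _ = _total_wrench(foot_wrenches)
    peak = float(np.max(np.linalg.norm(f_tot, axis=1)))
    if peak <= 0:
        raise ValueError("zero peak ground reaction force; normalization undefined")
    com = np.array([skel.com_position(s, masses, qt) for qt in q.traj])
    h = float(np.mean(com[:, 1]))
    f_rms = float(np.sqrt(np.mean(np.sum(f_res**2, axis=1))))
    t_rms = float(np.sqrt(np.mean(np.sum(t_res**2, axis=1))))
    return 100.0 * f_rms / peak, 100.0 * t_rms / (peak * h)


def residual_report(result: DynamicsFitResult, thresholds=None) -> dict:
    """Pass/fail summary of normalized residuals against thresholds
    (defaults: force 5% of peak GRF, torque 1% of peak GRF x COM height)."""
    thresholds = thresholds or {"force_pct": 5.0, "torque_pct": 1.0}
    force_ok = result.residual_force_pct <= thresholds["force_pct"]
    torque_ok = result.residual_torque_pct <= thresholds["torque_pct"]
    return {
        "residual_force_pct": result.residual_force_pct,
        "residual_torque_pct": result.residual_torque_pct,
        "force_threshold_pct": thresholds["force_pct"],
        "torque_threshold_pct": thresholds["torque_pct"],
        "force_pass": bool(force_ok),
        "torque_pass": bool(torque_ok),
        "pass": bool(force_ok and torque_ok),
    }
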