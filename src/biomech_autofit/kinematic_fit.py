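"""Scaling, marker registration and inverse kinematics.

Pipeline order: condition the anthropometric scale prior on subject
covariates, initialize marker offsets from the measured marker set,
initialize scales from the functional joint geometry, initialize poses by
per-frame inverse kinematics, then jointly refine (s, p, q) in a MAP
least-squares problem whose data term is the marker reconstruction error and
whose priors are Gaussians over scales and marker offsets.

The joint problem is the single-level reformulation of the bilevel fit: at a
solution of the full nonlinear least-squares problem the gradient of the
marker term with respect to each frame's pose vanishes, which is exactly the
inner-IK stationarity condition.  After the joint solve every frame is
polished by damped Gauss-Newton IK at the fitted (s, p), so the reported
per-frame stationarity norm is driven below tolerance explicitly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import least_squares

from .io_formats import MarkerTrajectories
from .joint_geometry import JointGeometryEstimate
from .skeleton import PoseTrajectory, SkeletonModel

__all__ = [
    "ScalingPrior",
    "MapFitConfig",
    "KinematicFitResult",
    "default_scaling_prior",
    "condition_prior",
    "init_marker_offsets",
    "init_scales",
    "init_poses",
    "solve_ik_frame",
    "bilevel_map_fit",
    "marker_error_report",
]


# ------------------------------------------------------------------- prior
@dataclass
class ScalingPrior:
    """Multivariate Gaussian over the scale vector, with an optional joint
    (scales, height, weight) block per sex for covariate conditioning."""

    mean: np.ndarray  # (d,)
    cov: np.ndarray  # (d, d) SPD
    covariate_mean: dict = field(default_factory=dict)  # sex -> (d+2,)
    covariate_cov: dict = field(default_factory=dict)  # sex -> (d+2, d+2)

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if np.any(np.linalg.eigvalsh(self.cov) <= 0):
            raise ValueError("scale prior covariance must be SPD")

    @property
    def dim(self):
        return len(self.mean)

    def whitener(self):
        """Matrix W whose rows whiten: ||W (s - mean)||^2 = (s-mean)' cov^-1 (s-mean)."""
        L = np.linalg.cholesky(self.cov)
        return np.linalg.inv(L)

    def neg_log(self, s):
        d = s - self.mean
        return 0.5 * d @ np.linalg.solve(self.cov, d)


def default_scaling_prior(
    skel: SkeletonModel,
    scale_sd: float = 0.05,
    shared_frac: float = 0.5,
    height_mean: float = 1.72,
    height_sd: float = 0.09,
    weight_mean: float = 74.0,
    weight_sd: float = 12.0,
) -> ScalingPrior:
    """Synthetic anthropometric prior built from a one-factor stature model.

    Scales share a latent overall-size factor (fraction ``shared_frac`` of
    the variance), which also drives height and weight — giving realistic
    correlations without redistributing any survey data.  Survey-derived
    parameters can be substituted via a config file at the CLI level.
    """
    d = skel.scale_dim
    beta = np.full(d, scale_sd * np.sqrt(shared_frac))
    resid = scale_sd**2 * (1 - shared_frac)
    cov = np.outer(beta, beta) + resid * np.eye(d)
    mean = np.ones(d)
    cov_h, cov_w = 0.85 * height_sd, 0.6 * weight_sd  # loadings of the latent factor
    full_mean = {
        None: np.concatenate([mean, [height_mean, weight_mean]]),
        "male": np.concatenate([mean, [height_mean + 0.06, weight_mean + 6.0]]),
        "female": np.concatenate([mean, [height_mean - 0.06, weight_mean - 6.0]]),
    }
    top = np.column_stack([beta * cov_h, beta * cov_w])
    hw = np.array([[height_sd**2, cov_h * cov_w], [cov_h * cov_w, weight_sd**2]])
    full_cov = np.block([[cov, top], [top.T, hw]])
    return ScalingPrior(
        mean,
        cov,
        covariate_mean=dict(full_mean),
        covariate_cov={k: full_cov.copy() for k in full_mean},
    )


def condition_prior(
    prior: ScalingPrior,
    height: float | None = None,
    weight: float | None = None,
    sex: str | None = None,
) -> ScalingPrior:
    """Condition the scale prior on observed subject covariates.

    Standard partitioned-Gaussian conditioning of the scale block on the
    observed height/weight entries; absent covariates leave the prior
    unchanged.  Covariates further than 5 SD from the marginal are clamped
    with a warning.
    """
    if height is None and weight is None:
        return prior
    key = sex if sex in prior.covariate_mean else None
    mu = prior.covariate_mean[key]
    cov = prior.covariate_cov[key]
    d = prior.dim
    obs_idx, obs_val = [], []
    for k, val in (("height", height), ("weight", weight)):
        if val is None:
            continue
        i = d if k == "height" else d + 1
        sd = np.sqrt(cov[i, i])
        if abs(val - mu[i]) > 5 * sd:
            warnings.warn(f"{k} {val} is >5 SD from the prior; clamping")
            val = mu[i] + np.clip(val - mu[i], -5 * sd, 5 * sd)
        obs_idx.append(i)
        obs_val.append(val)
    a = np.arange(d)
    b = np.array(obs_idx)
    S_ab = cov[np.ix_(a, b)]
    S_bb = cov[np.ix_(b, b)]
    K = S_ab @ np.linalg.inv(S_bb)
    new_mean = mu[a] + K @ (np.array(obs_val) - mu[b])
    new_cov = cov[np.ix_(a, a)] - K @ S_ab.T
    new_cov = 0.5 * (new_cov + new_cov.T)
    return ScalingPrior(new_mean, new_cov, prior.covariate_mean, prior.covariate_cov)


# ------------------------------------------------------------ configuration
@dataclass
class MapFitConfig:
    marker_sd: float = 0.01  # observation noise SD, metres
    anatomical_offset_sd: float = 0.005
    tracking_offset_sd: float = 0.05
    max_map_frames: int = 500  # frame-subsampling cap for the joint NLP
    max_nfev: int = 400
    ik_grad_tol: float = 5e-7
    ik_max_iter: int = 200
    stationarity_tol: float = 1e-6


@dataclass
class KinematicFitResult:
    s: np.ndarray
    p: np.ndarray
    q: PoseTrajectory
    marker_rmse: float
    marker_max: float
    stationarity_norm: float
    per_marker_rmse: dict
    objective_init: float = np.nan
    objective_final: float = np.nan
    flags: list = field(default_factory=list)


# --------------------------------------------------------------- init steps
def init_marker_offsets(skel: SkeletonModel) -> np.ndarray:
    """Step 1: start from the marker offsets measured by the experimenter."""
    return skel.default_offsets()


def _match_marker_columns(skel: SkeletonModel, traj: MarkerTrajectories):
    """Model-marker index -> trajectory column, for labels present in both."""
    col = {}
    for i, m in enumerate(skel.markers):
        if m.label in traj.labels:
            col[i] = traj.labels.index(m.label)
        else:
            warnings.warn(f"marker {m.label!r} not in trajectory; ignored")
    return col


def solve_ik_frame(skel, s, p, q0, obs, obs_cols, present, grad_tol=5e-7, max_iter=200):
    """Damped Gauss-Newton IK for one frame.

    ``obs`` is the (M_traj, 3) observation row, ``obs_cols`` maps model
    marker index -> observation column, ``present`` the observation mask.
    Returns (q, marker-term gradient norm at q); the norm is NaN when fewer
    than three markers are visible and the frame cannot be solved.
    """
    q = np.asarray(q0, dtype=float).copy()
    rows = [(mi, ci) for mi, ci in obs_cols.items() if present[ci]]
    if len(rows) < 3:
        return q, np.nan
    midx = np.array([mi for mi, _ in rows])
    target = np.stack([obs[ci] for _, ci in rows])
    lam = 1e-6
    x, Jq, _, _ = skel.marker_jacobians(s, q, p)
    r = (x[midx] - target).ravel()
    cost = r @ r
    for _ in range(max_iter):
        J = Jq[midx].reshape(-1, skel.n_q)
        g = 2.0 * J.T @ r
        if np.linalg.norm(g) <= grad_tol:
            break
        H = J.T @ J
        for _ in range(25):
            try:
                dq = np.linalg.solve(H + lam * np.eye(skel.n_q), -J.T @ r)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            q_new = q + dq
            x_new, Jq_new, _, _ = skel.marker_jacobians(s, q_new, p)
            r_new = (x_new[midx] - target).ravel()
            c_new = r_new @ r_new
            if c_new <= cost + 1e-18:
                q, r, cost, Jq = q_new, r_new, c_new, Jq_new
                lam = max(lam * 0.3, 1e-10)
                break
            lam *= 10
        else:
            break
    J = Jq[midx].reshape(-1, skel.n_q)
    return q, float(np.linalg.norm(2.0 * J.T @ r))


def _root_translation_guess(skel, s, p, obs_row, present_row, cols):
    q0 = np.zeros(skel.n_q)
    mi = [m for m, c in cols.items() if present_row[c]]
    ci = [cols[m] for m in mi]
    if mi:
        model = skel.marker_world_positions(s, q0, p)
        q0[:3] = obs_row[ci].mean(axis=0) - model[mi].mean(axis=0)
    return q0


def init_poses(
    skel: SkeletonModel,
    s,
    p,
    traj: MarkerTrajectories,
    q0: np.ndarray | None = None,
    config: MapFitConfig | None = None,
):
    """Step 3: per-frame IK, warm-started from the previous frame.

    Frames with fewer than three visible markers inherit their neighbour's
    pose and are flagged.
    """
    config = config or MapFitConfig()
    cols = _match_marker_columns(skel, traj)
    T = traj.n_frames
    qs = np.zeros((T, skel.n_q))
    flags = []
    if q0 is None:
        q0 = _root_translation_guess(skel, s, p, traj.frames[0], traj.present[0], cols)
    q_prev = np.asarray(q0, dtype=float)
    for t in range(T):
        q_t, g = solve_ik_frame(
            skel, s, p, q_prev, traj.frames[t], cols, traj.present[t],
            grad_tol=config.ik_grad_tol, max_iter=config.ik_max_iter,
        )
        if np.isnan(g):
            qs[t] = q_prev
            flags.append(t)
        else:
            qs[t] = q_t
            q_prev = q_t
    return PoseTrajectory(qs, traj.dt), flags


def _joint_points_and_jacs(skel: SkeletonModel, s, joint_names, fkstate):
    """World positions and (q, s)-Jacobians of the named joint centres."""
    st = fkstate
    ss = skel.seg_scales(s)
    out = {}
    for name in joint_names:
        j = next(jj for jj in skel.joints if jj.name == name)
        ic = skel.seg_index[j.child]
        x = st.o[ic] + st.R[ic] @ (ss[ic] * j.child_offset)
        Jq = skel.point_jacobian_q(st, j.child, x)
        Js = st.D[ic].copy()
        for a in range(3):
            Js[:, 3 * ic + a] += st.R[ic][:, a] * j.child_offset[a]
        out[name] = (x, Jq, Js)
    return out


# ------------------------------------------------- shared NLP assembly
class _MarkerNLP:
    """Sparse-Jacobian least-squares over (s [, p] [, alpha], q-frames).

    Residual blocks: weighted marker reconstruction errors on a frame
    subsample, optional joint-centre/axis geometry terms, a whitened scale
    prior, and (when p is free) per-marker offset priors.
    """

    def __init__(
        self,
        skel,
        traj,
        sel,
        cols,
        prior,
        w_x,
        p_fixed=None,
        offset_inv_sd=None,
        prior_scale=1.0,
        geom_terms=None,  # list of (frame_k, joint_name, center, axis or None)
        axis_joints=(),
        w_joint=100.0,
    ):
        self.skel = skel
        self.traj = traj
        self.sel = np.asarray(sel)
        self.F = len(sel)
        self.prior = prior
        self.w_x = w_x
        self.p_fixed = p_fixed
        self.free_p = p_fixed is None
        self.offset_inv_sd = offset_inv_sd
        self.Ws = prior.whitener() * prior_scale
        self.geom_terms = geom_terms or []
        self.axis_joints = list(axis_joints)
        self.w_joint = w_joint
        self.n_s = skel.scale_dim
        self.n_q = skel.n_q
        self.M = len(skel.markers)
        self.n_p = 3 * self.M if self.free_p else 0
        self.n_a = len(self.axis_joints)
        self.frame_rows = []
        for k in range(self.F):
            pr = self.traj.present[self.sel[k]]
            mi = np.array([m for m, c in cols.items() if pr[c]], dtype=int)
            ci = np.array([cols[m] for m in mi], dtype=int)
            self.frame_rows.append((mi, ci))
        self.geom_by_frame = {}
        for k, name, c, a in self.geom_terms:
            self.geom_by_frame.setdefault(k, []).append((name, c, a))
        self.n_marker_res = sum(3 * len(mi) for mi, _ in self.frame_rows)
        self.n_geom_res = 3 * len(self.geom_terms)
        self.n_res = self.n_marker_res + self.n_geom_res + self.n_s + self.n_p
        self.n_var = self.n_s + self.n_p + self.n_a + self.F * self.n_q
        self.p_bar = skel.default_offsets()
        self._fk_key = None
        self._fk_states = None

    def _frame_states(self, z, s, qs):
        """Per-frame FK states, shared between residual and Jacobian calls."""
        key = z.tobytes()
        if self._fk_key != key:
            self._fk_states = [self.skel.fk(s, qs[k]) for k in range(self.F)]
            self._fk_key = key
        return self._fk_states

    # variable layout: [s, (p), (alpha), q_1..q_F]
    def unpack(self, z):
        s = z[: self.n_s]
        o = self.n_s
        p = z[o : o + self.n_p].reshape(self.M, 3) if self.free_p else self.p_fixed
        o += self.n_p
        alpha = z[o : o + self.n_a]
        o += self.n_a
        qs = z[o:].reshape(self.F, self.n_q)
        return s, p, alpha, qs

    def pack(self, s, p, alpha, qs):
        parts = [np.asarray(s, dtype=float)]
        if self.free_p:
            parts.append(np.asarray(p, dtype=float).ravel())
        parts.append(np.asarray(alpha, dtype=float))
        parts.append(np.asarray(qs, dtype=float).ravel())
        return np.concatenate(parts)

    def residuals(self, z):
        s, p, alpha, qs = self.unpack(z)
        res = np.empty(self.n_res)
        sts = self._frame_states(z, s, qs)
        i = 0
        for k in range(self.F):
            st = sts[k]
            mi, ci = self.frame_rows[k]
            x = self.skel.marker_world_positions(s, qs[k], p, fkstate=st)
            n = 3 * len(mi)
            res[i : i + n] = (self.w_x * (x[mi] - self.traj.frames[self.sel[k], ci])).ravel()
            i += n
            for name, c, a in self.geom_by_frame.get(k, ()):
                xj = _joint_points_and_jacs(self.skel, s, [name], st)[name][0]
                if a is None:
                    r = xj - c
                else:
                    r = xj - (c + alpha[self.axis_joints.index(name)] * a)
                res[i : i + 3] = self.w_joint * r
                i += 3
        res[i : i + self.n_s] = self.Ws @ (s - self.prior.mean)
        i += self.n_s
        if self.free_p:
            res[i:] = (self.offset_inv_sd[:, None] * (p - self.p_bar)).ravel()
        return res

    def jacobian(self, z):
        s, p, alpha, qs = self.unpack(z)
        data, rows, colsJ = [], [], []
        ns, np_, na, nq = self.n_s, self.n_p, self.n_a, self.n_q
        qoff = ns + np_ + na

        def add_block(r0, c0, B):
            # B: (nr, nc) dense block at (r0, c0)
            nr, nc = B.shape
            rr, cc = np.meshgrid(np.arange(r0, r0 + nr), np.arange(c0, c0 + nc), indexing="ij")
            data.append(B.ravel())
            rows.append(rr.ravel())
            colsJ.append(cc.ravel())

        sts = self._frame_states(z, s, qs)
        i = 0
        for k in range(self.F):
            st = sts[k]
            mi, ci = self.frame_rows[k]
            x, Jq, Js, Jp = self.skel.marker_jacobians(s, qs[k], p, fkstate=st)
            nm = len(mi)
            add_block(i, 0, self.w_x * Js[mi].reshape(3 * nm, ns))
            add_block(i, qoff + k * nq, self.w_x * Jq[mi].reshape(3 * nm, nq))
            if self.free_p:
                for jj, m in enumerate(mi):
                    add_block(i + 3 * jj, ns + 3 * m, self.w_x * Jp[m])
            i += 3 * nm
            for name, c, a in self.geom_by_frame.get(k, ()):
                xj, Jq_j, Js_j = _joint_points_and_jacs(self.skel, s, [name], st)[name]
                add_block(i, 0, self.w_joint * Js_j)
                add_block(i, qoff + k * nq, self.w_joint * Jq_j)
                if a is not None:
                    ai = self.axis_joints.index(name)
                    add_block(i, ns + np_ + ai, self.w_joint * (-a[:, None]))
                i += 3
        add_block(i, 0, self.Ws)
        i += ns
        if self.free_p:
            for m in range(self.M):
                add_block(i + 3 * m, ns + 3 * m, self.offset_inv_sd[m] * np.eye(3))
        J = sp.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(colsJ))),
            shape=(self.n_res, self.n_var),
        )
        return J.tocsr()

    def solve(self, z0, max_nfev=1000):
        return least_squares(
            self.residuals,
            z0,
            jac=self.jacobian,
            method="trf",
            tr_solver="lsmr",
            x_scale="jac",
            xtol=1e-10,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=max_nfev,
        )


def init_scales(
    skel: SkeletonModel,
    geometry: dict[str, JointGeometryEstimate],
    traj: MarkerTrajectories,
    p: np.ndarray,
    prior: ScalingPrior,
    n_frames: int = 10,
    prior_weight: float = 1.0,
    w_joint: float = 30.0,
    max_nfev: int = 150,
):
    """Step 2: fit the scale vector to markers and functional joint geometry.

    A small nonlinear least squares over (s, per-axis-joint alpha, and the
    poses of a representative frame subsample): marker residuals pull the
    scaled skeleton onto the observations while sphere-mode joints pin the
    model joint centres to the estimated centres and axis-mode joints pin
    them to the estimated axis lines (at line coordinate alpha).

    Returns (s, alphas dict).  With no usable geometry and too few markers
    the prior mean is returned unchanged.
    """
    geom = {k: g for k, g in geometry.items() if g.mode in ("sphere", "axis")}
    cols = _match_marker_columns(skel, traj)
    if not geom and len(cols) < 4:
        warnings.warn("no joint geometry and <4 markers; falling back to prior mean scales")
        return prior.mean.copy(), {}

    usable = np.arange(traj.n_frames)
    for g in geom.values():
        usable = np.intersect1d(usable, g.frame_indices)
    if len(usable) == 0:
        usable = np.arange(traj.n_frames)
    sel = usable[np.linspace(0, len(usable) - 1, min(n_frames, len(usable))).astype(int)]

    axis_joints = sorted(k for k, g in geom.items() if g.mode == "axis")
    geom_terms = []
    for name, g in geom.items():
        lookup = {fi: i for i, fi in enumerate(g.frame_indices)}
        for k, t in enumerate(sel):
            i = lookup.get(t)
            if i is None:
                continue
            geom_terms.append((k, name, g.centers[i], g.axis[i] if g.mode == "axis" else None))

    s0 = prior.mean.copy()
    q_init = np.zeros((len(sel), skel.n_q))
    q_prev = None
    for k, t in enumerate(sel):
        if q_prev is None:
            q_prev = _root_translation_guess(skel, s0, p, traj.frames[t], traj.present[t], cols)
        q_init[k], _ = solve_ik_frame(
            skel, s0, p, q_prev, traj.frames[t], cols, traj.present[t], grad_tol=1e-5, max_iter=60
        )
        q_prev = q_init[k]

    nlp = _MarkerNLP(
        skel,
        traj,
        sel,
        cols,
        prior,
        w_x=100.0,
        p_fixed=np.asarray(p, dtype=float),
        prior_scale=prior_weight,
        geom_terms=geom_terms,
        axis_joints=axis_joints,
        w_joint=w_joint,
    )
    z0 = nlp.pack(s0, None, np.zeros(len(axis_joints)), q_init)
    out = nlp.solve(z0, max_nfev=max_nfev)
    s_fit, _, alpha_fit, _ = nlp.unpack(out.x)
    if np.any(s_fit <= 0.2) or np.any(s_fit >= 5.0):
        warnings.warn("init_scales produced implausible scales; falling back to prior mean")
        return prior.mean.copy(), {}
    return s_fit, dict(zip(axis_joints, alpha_fit))


# ----------------------------------------------------------------- MAP fit
def bilevel_map_fit(
    skel: SkeletonModel,
    prior: ScalingPrior,
    traj: MarkerTrajectories,
    s0,
    p0,
    q0: PoseTrajectory,
    config: MapFitConfig | None = None,
) -> KinematicFitResult:
    """Joint MAP refinement of scales, marker offsets and poses.

    Minimizes the whitened marker data term plus the scale and offset priors
    over (s, p, q) on a frame subsample, then re-solves IK on every frame at
    the fitted (s, p) so the inner stationarity condition holds per frame.
    """
    config = config or MapFitConfig()
    cols = _match_marker_columns(skel, traj)
    T = traj.n_frames
    stride = max(1, int(np.ceil(T / config.max_map_frames)))
    sel = np.arange(0, T, stride)
    if stride > 1:
        logging.getLogger("biomech_autofit").info(
            "MAP fit subsampling: every %d-th frame (%d of %d)", stride, len(sel), T
        )
    inv_sd = np.array(
        [
            1.0 / (config.anatomical_offset_sd if m.kind == "anatomical" else config.tracking_offset_sd)
            for m in skel.markers
        ]
    )
    nlp = _MarkerNLP(
        skel,
        traj,
        sel,
        cols,
        prior,
        w_x=1.0 / config.marker_sd,
        p_fixed=None,
        offset_inv_sd=inv_sd,
    )
    z0 = nlp.pack(s0, p0, np.zeros(0), q0.traj[sel])
    r0 = nlp.residuals(z0)
    obj_init = 0.5 * r0 @ r0
    out = nlp.solve(z0, max_nfev=config.max_nfev)
    s_fit, p_fit, _, _ = nlp.unpack(out.x)
    flags = []
    if out.status <= 0:
        flags.append(f"map solver status {out.status}: {out.message}")

    # full-trajectory IK polish at the fitted (s, p): enforces the per-frame
    # inner stationarity and fills in the frames dropped by subsampling
    qs = np.zeros((T, skel.n_q))
    stat_norms = np.full(T, np.nan)
    q_prev = nlp.unpack(out.x)[3][0]
    for t in range(T):
        q_t, g = solve_ik_frame(
            skel, s_fit, p_fit, q_prev, traj.frames[t], cols, traj.present[t],
            grad_tol=config.ik_grad_tol, max_iter=config.ik_max_iter,
        )
        if np.isnan(g):
            qs[t] = q_prev
            flags.append(f"frame {t}: <3 visible markers, pose copied")
        else:
            qs[t] = q_t
            stat_norms[t] = g
            q_prev = q_t
    q_fit = PoseTrajectory(qs, traj.dt)
    rz = nlp.residuals(nlp.pack(s_fit, p_fit, np.zeros(0), q_fit.traj[sel]))
    obj_final = 0.5 * rz @ rz
    stationarity = float(np.nanmax(stat_norms)) if np.any(~np.isnan(stat_norms)) else np.nan
    if stationarity > config.stationarity_tol:
        flags.append(f"stationarity {stationarity:.2e} above tolerance {config.stationarity_tol:.0e}")

    rmse, mmax, per_marker = marker_error_report(skel, s_fit, p_fit, q_fit, traj)
    return KinematicFitResult(
        s_fit, p_fit, q_fit, rmse, mmax, stationarity, per_marker, obj_init, obj_final, flags
    )


def marker_error_report(skel, s, p, q: PoseTrajectory, traj: MarkerTrajectories):
    """(RMSE, max, per-marker RMSE dict) over all present marker-frames."""
    cols = _match_marker_columns(skel, traj)
    sq_sum, n, worst = 0.0, 0, 0.0
    per = {m.label: [0.0, 0] for m in skel.markers}
    for t in range(traj.n_frames):
        x = skel.marker_world_positions(s, q.traj[t], p)
        for mi, ci in cols.items():
            if not traj.present[t, ci]:
                continue
            d2 = float(np.sum((x[mi] - traj.frames[t, ci]) ** 2))
            sq_sum += d2
            n += 1
            worst = max(worst, d2)
            per[skel.markers[mi].label][0] += d2
            per[skel.markers[mi].label][1] += 1
    rmse = float(np.sqrt(sq_sum / max(n, 1)))
    per_marker = {k: float(np.sqrt(v[0] / v[1])) for k, v in per.items() if v[1]}
    return rmse, float(np.sqrt(worst)), per_marker
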