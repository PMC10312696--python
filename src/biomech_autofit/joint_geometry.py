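"""Functional joint-center and joint-axis estimation from marker motion.

For each joint we take the markers on the two adjacent segments, build a
rigid "cluster" frame from the parent-segment markers (orthogonal Procrustes
against a reference frame), and express the child markers in that frame.
The joint centre is parameterized as a single point, constant in the cluster
frame, mapped back to the world per frame — the rigid-body assumption that
stabilizes the per-frame centre of Eq-style moving-sphere fits.

Three estimators are chained: a deterministic linear least-squares centre
(initial guess), a nonlinear moving-sphere refinement, and a joint-axis fit
that resolves the sagittal-plane ambiguity of sphere fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .io_formats import MarkerTrajectories

__all__ = [
    "JointMarkerGroup",
    "JointGeometryEstimate",
    "GeometryError",
    "closed_form_centers",
    "sphere_fit",
    "axis_fit",
    "classify_joint_geometry",
    "estimate_joint_geometry",
    "groups_from_skeleton",
]

MIN_COVISIBLE_FRAMES = 30


class GeometryError(ValueError):
    pass


@dataclass
class JointMarkerGroup:
    joint_name: str
    parent_markers: list[str]  # labels on the parent segment (cluster frame)
    child_markers: list[str]  # labels on the child segment (moving markers)


@dataclass
class JointGeometryEstimate:
    joint_name: str
    frame_indices: np.ndarray  # frames used (all group markers present)
    centers: np.ndarray  # (Tc, 3) world
    radii: np.ndarray  # per child marker (m)
    axis: np.ndarray | None = None  # (Tc, 3) unit world vectors
    u: np.ndarray | None = None  # axial offsets per child marker
    v: np.ndarray | None = None  # radial offsets per child marker
    sphere_residual: float = np.inf  # RMS m
    axis_residual: float = np.inf  # RMS m
    mode: str = "none"  # sphere | axis | none
    sphere_converged: bool = False
    axis_converged: bool = False
    sphere_condition: float = np.inf  # cond of the Gauss-Newton Hessian
    center_local: np.ndarray | None = field(default=None, repr=False)
    axis_local: np.ndarray | None = field(default=None, repr=False)

    def to_report(self) -> dict:
        return {
            "joint": self.joint_name,
            "mode": self.mode,
            "sphere_residual_m": float(self.sphere_residual),
            "axis_residual_m": float(self.axis_residual),
            "sphere_condition": float(self.sphere_condition),
            "radii_m": self.radii.tolist() if self.radii is not None else None,
            "centers_m": self.centers.tolist(),
            "axis": self.axis.tolist() if self.axis is not None else None,
        }


def _kabsch(ref, cur):
    """Rigid transform (R, t) with cur ~= ref @ R.T + t."""
    c_ref, c_cur = ref.mean(axis=0), cur.mean(axis=0)
    H = (ref - c_ref).T @ (cur - c_cur)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return R, c_cur - R @ c_ref


class _ClusterFrames:
    """Per-frame rigid frames built from the parent marker cluster."""

    def __init__(self, traj: MarkerTrajectories, group: JointMarkerGroup):
        idx = {lbl: i for i, lbl in enumerate(traj.labels)}
        missing = [m for m in group.parent_markers + group.child_markers if m not in idx]
        if missing:
            raise GeometryError(f"joint {group.joint_name}: unknown markers {missing}")
        if len(group.parent_markers) < 3:
            raise GeometryError(
                f"joint {group.joint_name}: need >= 3 parent markers for a cluster frame"
            )
        pi = [idx[m] for m in group.parent_markers]
        ci = [idx[m] for m in group.child_markers]
        vis = traj.present[:, pi + ci].all(axis=1)
        self.frames = np.flatnonzero(vis)
        if len(self.frames) < MIN_COVISIBLE_FRAMES:
            raise GeometryError(
                f"joint {group.joint_name}: only {len(self.frames)} co-visible frames "
                f"(need >= {MIN_COVISIBLE_FRAMES})"
            )
        parent = traj.frames[self.frames][:, pi]
        ref = parent[0]
        self.R = np.empty((len(self.frames), 3, 3))
        self.t = np.empty((len(self.frames), 3))
        for k in range(len(self.frames)):
            self.R[k], self.t[k] = _kabsch(ref, parent[k])
        child = traj.frames[self.frames][:, ci]  # (Tc, C, 3) world
        # child markers expressed in the cluster frame
        self.child_local = np.einsum("tji,tcj->tci", self.R, child - self.t[:, None, :])
        self.n_child = len(ci)

    def to_world_point(self, c_local):
        return np.einsum("tij,j->ti", self.R, c_local) + self.t

    def to_world_dir(self, a_local):
        return np.einsum("tij,j->ti", self.R, a_local)


def closed_form_centers(traj: MarkerTrajectories, group: JointMarkerGroup):
    """Deterministic linear least-squares centre-of-rotation estimate.

    Solves the algebraic sphere-fit system ``|y|^2 - 2 y.c = k_i`` jointly
    over all child markers in the parent cluster frame.  Used purely as the
    initial guess for :func:`sphere_fit`.
    """
    cf = _ClusterFrames(traj, group)
    Tc, C = cf.child_local.shape[:2]
    rows = []
    rhs = []
    for i in range(C):
        y = cf.child_local[:, i]
        block = np.zeros((Tc, 3 + C))
        block[:, :3] = -2.0 * y
        block[:, 3 + i] = 1.0
        rows.append(block)
        rhs.append(-np.einsum("ij,ij->i", y, y))
    A = np.vstack(rows)
    b = np.concatenate(rhs)
    sol, _, rank, sv = np.linalg.lstsq(A, b, rcond=1e-9)
    # a pure hinge is deficient by exactly one (centre slides along the axis);
    # the minimum-norm solution is still a valid initial guess.  Two or more
    # deficient directions mean the markers carry no rotation information.
    if rank < 2 + C:
        raise GeometryError(
            f"joint {group.joint_name}: rank-deficient centre system (markers static?)"
        )
    c_local = sol[:3]
    k = sol[3:]
    r2 = k + c_local @ c_local
    if np.any(r2 <= 0):
        raise GeometryError(f"joint {group.joint_name}: degenerate closed-form radii")
    radii = np.sqrt(r2)
    est = JointGeometryEstimate(
        group.joint_name, cf.frames, cf.to_world_point(c_local), radii, center_local=c_local
    )
    est._cluster = cf
    return est


def _sphere_residuals(theta, child_local):
    Tc, C = child_local.shape[:2]
    c, r = theta[:3], theta[3:]
    d = np.linalg.norm(child_local - c, axis=2)  # (Tc, C)
    return (d - r).ravel()


def sphere_fit(traj: MarkerTrajectories, group: JointMarkerGroup, init=None) -> JointGeometryEstimate:
    """Moving-sphere refinement: each child marker keeps a constant distance
    (radius) from a centre fixed in the parent cluster frame."""
    if init is None:
        init = closed_form_centers(traj, group)
    cf = getattr(init, "_cluster", None) or _ClusterFrames(traj, group)
    theta0 = np.concatenate([init.center_local, init.radii])
    res = least_squares(
        _sphere_residuals, theta0, args=(cf.child_local,), method="lm", xtol=1e-14, ftol=1e-14
    )
    converged = res.status > 0
    if not converged:
        warnings.warn(f"joint {group.joint_name}: sphere fit did not converge; keeping init")
        res.x = theta0
    c_local, radii = res.x[:3], res.x[3:]
    rms = float(np.sqrt(np.mean(_sphere_residuals(res.x, cf.child_local) ** 2)))
    # conditioning of the centre after eliminating the radii (Schur
    # complement of the Gauss-Newton Hessian): near-singular for planar data
    JtJ = res.jac.T @ res.jac
    H_cc, H_cr, H_rr = JtJ[:3, :3], JtJ[:3, 3:], JtJ[3:, 3:]
    H_c = H_cc - H_cr @ np.linalg.solve(H_rr + 1e-12 * np.eye(len(H_rr)), H_cr.T)
    sv = np.linalg.svd(H_c, compute_uv=False)
    cond = float(sv[0] / max(sv[-1], 1e-300))
    est = JointGeometryEstimate(
        group.joint_name,
        cf.frames,
        cf.to_world_point(c_local),
        radii,
        sphere_residual=rms,
        sphere_converged=bool(converged),
        sphere_condition=cond,
        center_local=c_local,
    )
    est._cluster = cf
    if cond > 1e3:
        warnings.warn(
            f"joint {group.joint_name}: sphere-fit centre ill-conditioned "
            f"(cond {cond:.1e}); likely planar marker motion"
        )
    return est


def _axis_residuals(theta, child_local):
    Tc, C = child_local.shape[:2]
    c = theta[:3]
    a = theta[3:6]
    a = a / np.linalg.norm(a)
    u, v = theta[6 : 6 + C], theta[6 + C :]
    d = child_local - c  # (Tc, C, 3)
    para = d @ a  # (Tc, C)
    perp = np.linalg.norm(d - para[..., None] * a, axis=2)
    return np.concatenate([(para - u).ravel(), (perp - v).ravel()])


def axis_fit(traj: MarkerTrajectories, group: JointMarkerGroup, init=None) -> JointGeometryEstimate:
    """Joint-axis fit: decompose each child marker's offset from the centre
    into components parallel and perpendicular to a unit axis, both required
    to stay constant over time.

    The axis is parameterized as a constant direction in the parent cluster
    frame (mapped per frame), so the unit-norm constraint holds exactly at
    every frame; its sign is canonicalized against the previous frame.
    """
    sph = init if init is not None and init.sphere_converged else sphere_fit(traj, group, init)
    cf = getattr(sph, "_cluster", None) or _ClusterFrames(traj, group)
    d = cf.child_local - sph.center_local
    # initial axis: each child marker of a hinge traces a circle; average the
    # per-marker circle-plane normals (smallest-variance directions)
    normals = []
    for i in range(cf.n_child):
        pts = d[:, i]
        _, _, Vt = np.linalg.svd(pts - pts.mean(axis=0), full_matrices=False)
        n = Vt[-1]
        if normals and n @ normals[0] < 0:
            n = -n
        normals.append(n)
    a0 = np.mean(normals, axis=0)
    a0 = a0 / np.linalg.norm(a0)
    u0 = (d @ a0).mean(axis=0)
    v0 = np.linalg.norm(d - (d @ a0)[..., None] * a0, axis=2).mean(axis=0)
    theta0 = np.concatenate([sph.center_local, a0, u0, v0])
    res = least_squares(
        _axis_residuals, theta0, args=(cf.child_local,), method="lm", xtol=1e-14, ftol=1e-14
    )
    converged = res.status > 0
    if not converged:
        warnings.warn(f"joint {group.joint_name}: axis fit did not converge")
        res.x = theta0
    C = cf.n_child
    c_local = res.x[:3]
    a_local = res.x[3:6] / np.linalg.norm(res.x[3:6])
    rms = float(np.sqrt(np.mean(_axis_residuals(res.x, cf.child_local) ** 2)))
    axis_world = cf.to_world_dir(a_local)
    for t in range(1, len(axis_world)):  # sign continuity
        if axis_world[t] @ axis_world[t - 1] < 0:
            axis_world[t] = -axis_world[t]
    est = JointGeometryEstimate(
        group.joint_name,
        cf.frames,
        cf.to_world_point(c_local),
        sph.radii,
        axis=axis_world,
        u=res.x[6 : 6 + C],
        v=np.abs(res.x[6 + C :]),
        sphere_residual=sph.sphere_residual,
        axis_residual=rms,
        mode=sph.mode,
        sphere_converged=sph.sphere_converged,
        axis_converged=bool(converged),
        sphere_condition=sph.sphere_condition,
        center_local=c_local,
        axis_local=a_local,
    )
    est._cluster = cf
    return est


def classify_joint_geometry(
    est: JointGeometryEstimate, tol_abs: float = 0.003, tol_ratio: float = 1.5
) -> str:
    """Decide which geometric constraint the joint supports.

    ``axis`` when the (strictly more demanding) axis fit performs comparably
    to the sphere fit — within ``max(tol_abs, tol_ratio * sphere_residual)``;
    ``sphere`` when only the sphere fit succeeded; ``none`` otherwise.
    """
    axis_ok = est.axis_converged and est.axis is not None and est.axis_residual <= max(
        tol_abs, tol_ratio * est.sphere_residual
    )
    if axis_ok:
        est.mode = "axis"
    elif est.sphere_converged:
        est.mode = "sphere"
    else:
        est.mode = "none"
    return est.mode


def groups_from_skeleton(skel, min_parent=3, min_child=1) -> list[JointMarkerGroup]:
    """Build per-joint marker groups from the skeleton's marker set."""
    by_seg = {}
    for m in skel.markers:
        by_seg.setdefault(m.segment, []).append(m.label)
    groups = []
    for j in skel.joints:
        if j.parent is None:
            continue
        pm = by_seg.get(j.parent, [])
        cm = by_seg.get(j.child, [])
        if len(pm) >= min_parent and len(cm) >= min_child:
            groups.append(JointMarkerGroup(j.name, pm, cm))
    return groups


def estimate_joint_geometry(
    traj: MarkerTrajectories, groups: list[JointMarkerGroup]
) -> dict[str, JointGeometryEstimate]:
    """Run the full chain (closed form -> sphere -> axis -> classify) per joint.

    Joints whose data are degenerate come back with mode ``none`` rather than
    raising, so a single bad joint cannot abort a whole pipeline run.
    """
    out = {}
    for g in groups:
        try:
            init = closed_form_centers(traj, g)
            sph = sphere_fit(traj, g, init)
            est = axis_fit(traj, g, sph)
        except GeometryError as e:
            warnings.warn(str(e))
            est = JointGeometryEstimate(
                g.joint_name, np.array([], dtype=int), np.zeros((0, 3)), np.zeros(0)
            )
        classify_joint_geometry(est)
        out[g.joint_name] = est
    return out
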