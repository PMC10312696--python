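"""Articulated rigid-body skeleton: kinematics, Jacobians, dynamics.

The skeleton is a tree of body segments connected by joints of four types
(``free6``, ``ball3``, ``universal2``, ``revolute1``).  Each segment carries a
3-vector of per-axis scale factors; the concatenation over segments forms the
scale vector ``s``.  Scales act componentwise on joint offsets, marker
offsets and centre-of-mass offsets; inertia tensors are rescaled with the
point-mass rule (second moments scale with the squared axis lengths).

Rotational coordinates use intrinsic XYZ Euler angles.  Generalized
coordinates ``q`` are the joint coordinates concatenated in tree order, with
the 6-DOF root joint first (3 translations, then 3 rotations).
"""

from __future__ import annotations

import json
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BodySegment",
    "JointDef",
    "MarkerDef",
    "Pose",
    "PoseTrajectory",
    "SkeletonModel",
    "SkeletonError",
    "load_skeleton",
    "finite_difference_derivatives",
]

JOINT_NDOF = {"free6": 6, "ball3": 3, "universal2": 2, "revolute1": 1}

GIMBAL_WARN_RAD = np.deg2rad(80.0)


class SkeletonError(ValueError):
    """Raised for invalid skeleton definitions or dimension mismatches."""


@dataclass
class BodySegment:
    name: str
    mass: float
    local_com: np.ndarray  # (3,) metres, unscaled segment frame
    inertia: np.ndarray  # (3,3) kg m^2 about COM, unscaled

    def __post_init__(self):
        self.local_com = np.asarray(self.local_com, dtype=float)
        self.inertia = np.asarray(self.inertia, dtype=float)
        if self.mass <= 0:
            raise SkeletonError(f"segment {self.name!r}: mass must be > 0")
        if self.local_com.shape != (3,):
            raise SkeletonError(f"segment {self.name!r}: local_com must be 3-vector")
        if self.inertia.shape != (3, 3):
            raise SkeletonError(f"segment {self.name!r}: inertia must be 3x3")
        if not np.allclose(self.inertia, self.inertia.T, atol=1e-12):
            raise SkeletonError(f"segment {self.name!r}: inertia not symmetric")
        if np.any(np.linalg.eigvalsh(self.inertia) <= 0):
            raise SkeletonError(f"segment {self.name!r}: inertia not positive definite")


@dataclass
class JointDef:
    name: str
    type: str
    parent: str | None  # parent segment name, None for root joint
    child: str
    parent_offset: np.ndarray  # (3,) metres, unscaled parent frame
    child_offset: np.ndarray  # (3,) metres, unscaled child frame
    axes: np.ndarray  # (k,3) unit axes for universal2/revolute1
    dof_slice: slice = field(default=None, repr=False)  # set by SkeletonModel

    def __post_init__(self):
        if self.type not in JOINT_NDOF:
            raise SkeletonError(f"joint {self.name!r}: unsupported joint type {self.type!r}")
        self.parent_offset = np.asarray(self.parent_offset, dtype=float)
        self.child_offset = np.asarray(self.child_offset, dtype=float)
        self.axes = np.atleast_2d(np.asarray(self.axes, dtype=float)) if np.size(self.axes) else np.zeros((0, 3))
        if self.type == "revolute1" and len(self.axes) < 1:
            raise SkeletonError(f"joint {self.name!r}: revolute1 requires one axis")
        if self.type == "universal2":
            if len(self.axes) < 2:
                raise SkeletonError(f"joint {self.name!r}: universal2 requires two axes")
            if abs(np.linalg.det(np.vstack([self.axes[0], self.axes[1], np.cross(self.axes[0], self.axes[1])]))) < 1e-8:
                raise SkeletonError(f"joint {self.name!r}: universal2 axes must be independent")
        for a in self.axes:
            n = np.linalg.norm(a)
            if not np.isclose(n, 1.0, atol=1e-6):
                raise SkeletonError(f"joint {self.name!r}: axes must be unit norm")

    @property
    def ndof(self) -> int:
        return JOINT_NDOF[self.type]


@dataclass
class MarkerDef:
    label: str
    segment: str
    offset: np.ndarray  # nominal local offset p-bar, (3,) metres, unscaled
    kind: str = "tracking"  # "anatomical" | "tracking"

    def __post_init__(self):
        self.offset = np.asarray(self.offset, dtype=float)
        if self.kind not in ("anatomical", "tracking"):
            raise SkeletonError(f"marker {self.label!r}: kind must be anatomical|tracking")


@dataclass
class Pose:
    q: np.ndarray

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)


@dataclass
class PoseTrajectory:
    traj: np.ndarray  # (T, nq)
    dt: float

    def __post_init__(self):
        self.traj = np.atleast_2d(np.asarray(self.traj, dtype=float))
        if self.traj.shape[0] < 1:
            raise SkeletonError("trajectory must have T >= 1")
        if self.dt <= 0:
            raise SkeletonError("dt must be > 0")

    @property
    def n_frames(self) -> int:
        return self.traj.shape[0]


def finite_difference_derivatives(traj: np.ndarray, dt: float):
    """Velocities and accelerations of a sampled trajectory.

    Central differences in the interior, forward/backward one-sided at the
    trial ends.  This is the single finite-difference convention used
    throughout the package (inverse dynamics, residual computation and the
    synthetic-data generator all share it).
    """
    traj = np.atleast_2d(np.asarray(traj, dtype=float))
    T = traj.shape[0]
    qd = np.zeros_like(traj)
    qdd = np.zeros_like(traj)
    if T == 1:
        return qd, qdd
    qd[1:-1] = (traj[2:] - traj[:-2]) / (2 * dt)
    qd[0] = (traj[1] - traj[0]) / dt
    qd[-1] = (traj[-1] - traj[-2]) / dt
    if T >= 3:
        qdd[1:-1] = (traj[2:] - 2 * traj[1:-1] + traj[:-2]) / dt**2
        qdd[0] = (traj[2] - 2 * traj[1] + traj[0]) / dt**2
        qdd[-1] = (traj[-1] - 2 * traj[-2] + traj[-3]) / dt**2
    return qd, qdd


def _rot_x(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _cr(a, b):
    # np.cross has high call overhead for single 3-vectors
    return np.array(
        (
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        )
    )


def _rot_axis(axis, a):
    """Rodrigues rotation about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


_EULER_AXES = (np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0]))


def scale_inertia(inertia: np.ndarray, s_seg: np.ndarray) -> np.ndarray:
    """Rescale an inertia tensor for per-axis scale factors.

    Uses the point-mass rule: the second-moment matrix
    Sigma = 0.5*tr(I)*eye - I scales as Sigma'_ij = s_i s_j Sigma_ij, and the
    inertia is rebuilt as I' = tr(Sigma')*eye - Sigma'.  Exact for any rigid
    point-mass distribution whose coordinates are scaled componentwise.
    """
    s_seg = np.asarray(s_seg, dtype=float)
    sigma = 0.5 * np.trace(inertia) * np.eye(3) - inertia
    sigma = np.outer(s_seg, s_seg) * sigma
    return np.trace(sigma) * np.eye(3) - sigma


class FKState:
    """Forward-kinematics evaluation at one pose.

    Holds world transforms per segment, per-DOF world axes/points for
    geometric Jacobians, and the translation sensitivities w.r.t. the scale
    vector (rotations do not depend on ``s``).
    """

    __slots__ = ("R", "o", "dof_kind", "dof_axis", "dof_point", "D", "kind_t")

    def __init__(self, n_seg, n_q, scale_dim):
        self.R = np.zeros((n_seg, 3, 3))
        self.o = np.zeros((n_seg, 3))
        self.dof_kind = [""] * n_q  # "t" translational, "r" rotational
        self.kind_t = np.zeros(n_q, dtype=bool)
        self.dof_axis = np.zeros((n_q, 3))
        self.dof_point = np.zeros((n_q, 3))
        self.D = np.zeros((n_seg, 3, scale_dim))  # d(origin)/d(s)


class SkeletonModel:
    """Tree-structured rigid-body skeleton with markers and scaling."""

    def __init__(self, segments, joints, markers, gravity=(0.0, -9.81, 0.0)):
        self.segments: list[BodySegment] = list(segments)
        self.joints: list[JointDef] = list(joints)
        self.markers: list[MarkerDef] = list(markers)
        self.gravity = np.asarray(gravity, dtype=float)
        self._validate_and_index()

    # ------------------------------------------------------------------ setup
    def _validate_and_index(self):
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise SkeletonError("duplicate segment names")
        self.seg_index = {n: i for i, n in enumerate(names)}

        roots = [j for j in self.joints if j.parent is None]
        if len(roots) != 1:
            raise SkeletonError("skeleton must have exactly one root joint")
        if roots[0].type != "free6":
            raise SkeletonError("root joint must be free6")

        # order joints so each child appears after its parent segment; detect
        # cycles / unreachable segments
        by_child = {}
        for j in self.joints:
            if j.child not in self.seg_index:
                raise SkeletonError(f"joint {j.name!r}: unknown child segment {j.child!r}")
            if j.parent is not None and j.parent not in self.seg_index:
                raise SkeletonError(f"joint {j.name!r}: unknown parent segment {j.parent!r}")
            if j.child in by_child:
                raise SkeletonError(f"segment {j.child!r} has two parent joints")
            by_child[j.child] = j
        ordered, placed = [], set()
        frontier = [roots[0]]
        while frontier:
            j = frontier.pop(0)
            ordered.append(j)
            placed.add(j.child)
            frontier.extend(jj for jj in self.joints if jj.parent == j.child and jj.child not in placed)
        if len(ordered) != len(self.joints):
            raise SkeletonError("joint graph is not a tree (cycle or disconnected joint)")
        if placed != set(names):
            raise SkeletonError("unreachable segments: " + ", ".join(sorted(set(names) - placed)))
        self.joints = ordered

        # assign dof slices
        k = 0
        for j in self.joints:
            j.dof_slice = slice(k, k + j.ndof)
            k += j.ndof
        self.n_q = k
        self.n_seg = len(self.segments)
        self.scale_dim = 3 * self.n_seg
        self.root_segment = roots[0].child
        self.root_dofs = slice(0, 6)

        labels = [m.label for m in self.markers]
        if len(set(labels)) != len(labels):
            raise SkeletonError("duplicate marker labels")
        for m in self.markers:
            if m.segment not in self.seg_index:
                raise SkeletonError(f"marker {m.label!r}: unknown segment {m.segment!r}")
        self.marker_index = {m.label: i for i, m in enumerate(self.markers)}

        # per-segment parent joint and ancestor dof list
        self._joint_of_child = {j.child: j for j in self.joints}
        self._ancestor_dofs = {}
        for j in self.joints:
            parent_dofs = [] if j.parent is None else self._ancestor_dofs[j.parent]
            self._ancestor_dofs[j.child] = parent_dofs + list(range(j.dof_slice.start, j.dof_slice.stop))
        self._ancestor_arr = {k: np.array(v, dtype=int) for k, v in self._ancestor_dofs.items()}
        self._markers_by_seg = {
            k: np.array([i for i, m in enumerate(self.markers) if m.segment == n], dtype=int)
            for n, k in self.seg_index.items()
        }

        # coordinate names (for MOT output)
        self.coordinate_names = []
        for j in self.joints:
            if j.type == "free6":
                self.coordinate_names += [f"{j.name}_{sfx}" for sfx in ("tx", "ty", "tz", "rx", "ry", "rz")]
            elif j.type == "ball3":
                self.coordinate_names += [f"{j.name}_{sfx}" for sfx in ("rx", "ry", "rz")]
            else:
                self.coordinate_names += [f"{j.name}_r{i}" for i in range(j.ndof)]
        self.rotational_dofs = np.array(
            [not n.rsplit("_", 1)[1].startswith("t") for n in self.coordinate_names], dtype=bool
        )

    # ------------------------------------------------------------- parameters
    def default_scales(self) -> np.ndarray:
        return np.ones(self.scale_dim)

    def default_masses(self) -> np.ndarray:
        return np.array([s.mass for s in self.segments])

    def default_offsets(self) -> np.ndarray:
        return np.array([m.offset for m in self.markers])

    def seg_scales(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        if s.shape != (self.scale_dim,):
            raise SkeletonError(f"scale vector must have length {self.scale_dim}")
        return s.reshape(self.n_seg, 3)

    # ------------------------------------------------------------- kinematics
    def fk(self, s: np.ndarray, q: np.ndarray, check_gimbal: bool = False) -> FKState:
        """World transforms and Jacobian bookkeeping for one pose."""
        q = np.asarray(q, dtype=float)
        if q.shape != (self.n_q,):
            raise SkeletonError(f"q must have length {self.n_q}")
        ss = self.seg_scales(s)
        st = FKState(self.n_seg, self.n_q, self.scale_dim)
        for j in self.joints:
            qj = q[j.dof_slice]
            if j.parent is None:
                Rp, op = np.eye(3), np.zeros(3)
                Dp = np.zeros((3, self.scale_dim))
                ip = None
            else:
                ip = self.seg_index[j.parent]
                Rp, op, Dp = st.R[ip], st.o[ip], st.D[ip]
            ic = self.seg_index[j.child]
            D = Dp.copy()
            # parent-side offset, scaled by parent scales
            if ip is not None:
                sp = ss[ip]
                o = op + Rp @ (sp * j.parent_offset)
                for a in range(3):
                    if j.parent_offset[a] != 0.0:
                        D[:, 3 * ip + a] += Rp[:, a] * j.parent_offset[a]
            else:
                o = op.copy()
            R = Rp
            base = j.dof_slice.start
            k = 0
            if j.type == "free6":
                for a in range(3):  # world-aligned translations at the root
                    w = _EULER_AXES[a]
                    st.dof_kind[base + k] = "t"
                    st.kind_t[base + k] = True
                    st.dof_axis[base + k] = w
                    k += 1
                o = o + qj[:3]
            if j.type in ("free6", "ball3"):
                rot = qj[3:] if j.type == "free6" else qj
                if check_gimbal and abs(((rot[1] + np.pi) % (2 * np.pi)) - np.pi) > GIMBAL_WARN_RAD:
                    warnings.warn(f"joint {j.name!r}: middle Euler angle near gimbal lock")
                for a in range(3):
                    w = R @ _EULER_AXES[a]
                    st.dof_kind[base + k] = "r"
                    st.dof_axis[base + k] = w
                    st.dof_point[base + k] = o
                    R = R @ _rot_axis(_EULER_AXES[a], rot[a])
                    k += 1
            elif j.type in ("universal2", "revolute1"):
                for a in range(j.ndof):
                    w = R @ j.axes[a]
                    st.dof_kind[base + k] = "r"
                    st.dof_axis[base + k] = w
                    st.dof_point[base + k] = o
                    R = R @ _rot_axis(j.axes[a], qj[a])
                    k += 1
            # child-side offset, scaled by child scales
            sc = ss[ic]
            o = o - R @ (sc * j.child_offset)
            for a in range(3):
                if j.child_offset[a] != 0.0:
                    D[:, 3 * ic + a] -= R[:, a] * j.child_offset[a]
            st.R[ic] = R
            st.o[ic] = o
            st.D[ic] = D
        return st

    def segment_transforms(self, s, q):
        """Per-segment world (R, o) as arrays of shape (n_seg,3,3), (n_seg,3)."""
        st = self.fk(s, q)
        return st.R, st.o

    def marker_world_positions(self, s, q, p=None, fkstate: FKState | None = None) -> np.ndarray:
        """World positions of all markers, (M, 3).

        ``p`` are the per-marker local offsets (defaults to the nominal
        marker set); each offset is scaled componentwise by its segment's
        scale factors before being mapped through the segment transform.
        """
        p = self.default_offsets() if p is None else np.asarray(p, dtype=float)
        if p.shape != (len(self.markers), 3):
            raise SkeletonError("p must be (M, 3)")
        st = fkstate if fkstate is not None else self.fk(s, q)
        ss = self.seg_scales(s)
        out = np.empty((len(self.markers), 3))
        for i, m in enumerate(self.markers):
            k = self.seg_index[m.segment]
            out[i] = st.o[k] + st.R[k] @ (ss[k] * p[i])
        return out

    def marker_jacobians(self, s, q, p=None, fkstate: FKState | None = None):
        """Analytic partials of marker world positions.

        Returns ``(x, Jq, Js, Jp)`` where ``x`` is (M,3), ``Jq`` is
        (M,3,n_q), ``Js`` is (M,3,scale_dim) and ``Jp`` is (M,3,3) — the
        block-diagonal per-marker d(x_i)/d(p_i) = R_seg @ diag(s_seg).
        """
        p = self.default_offsets() if p is None else np.asarray(p, dtype=float)
        st = fkstate if fkstate is not None else self.fk(s, q)
        ss = self.seg_scales(s)
        M = len(self.markers)
        x = np.empty((M, 3))
        Jq = np.zeros((M, 3, self.n_q))
        Js = np.zeros((M, 3, self.scale_dim))
        Jp = np.zeros((M, 3, 3))
        for seg_name, k in self.seg_index.items():
            midx = self._markers_by_seg[k]
            if len(midx) == 0:
                continue
            R, o = st.R[k], st.o[k]
            pm = p[midx]
            xm = o + (ss[k] * pm) @ R.T
            x[midx] = xm
            A = self._ancestor_arr[seg_name]
            axes, pts = st.dof_axis[A], st.dof_point[A]
            block = np.cross(axes[None, :, :], xm[:, None, :] - pts[None, :, :])  # (m, d, 3)
            tmask = st.kind_t[A]
            if tmask.any():
                block[:, tmask, :] = axes[tmask][None, :, :]
            Jq[np.ix_(midx, range(3), A)] = block.transpose(0, 2, 1)
            Js[midx] = st.D[k][None, :, :]
            Js[midx, :, 3 * k : 3 * k + 3] += R[None, :, :] * pm[:, None, :]
            Jp[midx] = R[None, :, :] * ss[k][None, None, :]
        return x, Jq, Js, Jp

    def point_jacobian_q(self, st: FKState, segment: str, x_world: np.ndarray) -> np.ndarray:
        """d(world position)/dq for a point rigidly attached to ``segment``."""
        J = np.zeros((3, self.n_q))
        A = self._ancestor_arr[segment]
        axes = st.dof_axis[A]
        cols = np.cross(axes, x_world[None, :] - st.dof_point[A])
        tmask = st.kind_t[A]
        if tmask.any():
            cols[tmask] = axes[tmask]
        J[:, A] = cols.T
        return J

    # ---------------------------------------------------------------- COM
    def com_position(self, s, masses, q, fkstate=None) -> np.ndarray:
        masses = np.asarray(masses, dtype=float)
        if np.any(masses <= 0):
            raise SkeletonError("masses must be positive")
        total = masses.sum()
        if total <= 0:
            raise SkeletonError("zero total mass")
        st = fkstate if fkstate is not None else self.fk(s, q)
        ss = self.seg_scales(s)
        acc = np.zeros(3)
        for k, seg in enumerate(self.segments):
            acc += masses[k] * (st.o[k] + st.R[k] @ (ss[k] * seg.local_com))
        return acc / total

    def com_trajectory(self, s, masses, traj: np.ndarray) -> np.ndarray:
        return np.array([self.com_position(s, masses, qt) for qt in np.atleast_2d(traj)])

    # ------------------------------------------------------------- dynamics
    def _body_jacobians(self, st: FKState):
        """Per-segment angular Jacobian and COM-point linear Jacobian columns."""
        Jw = np.zeros((self.n_seg, 3, self.n_q))
        for k, seg in enumerate(self.segments):
            A = self._ancestor_arr[seg.name]
            rot = A[~st.kind_t[A]]
            Jw[k][:, rot] = st.dof_axis[rot].T
        return Jw

    def _local_inertias(self, s, masses):
        """Scaled local inertia tensors; cached on (s, masses) since frame
        loops reuse them thousands of times."""
        key = (np.asarray(s).tobytes(), np.asarray(masses, dtype=float).tobytes())
        cached = getattr(self, "_inertia_cache", None)
        if cached is not None and cached[0] == key:
            return cached[1]
        ss = self.seg_scales(s)
        out = np.empty((self.n_seg, 3, 3))
        for k, seg in enumerate(self.segments):
            out[k] = scale_inertia(seg.inertia, ss[k]) * (masses[k] / seg.mass)
        self._inertia_cache = (key, out)
        return out

    def _world_inertias(self, st: FKState, s, masses):
        I_local = self._local_inertias(s, masses)
        return np.einsum("kij,kjl,kml->kim", st.R, I_local, st.R)

    def _com_points(self, st: FKState, s):
        ss = self.seg_scales(s)
        return np.array(
            [st.o[k] + st.R[k] @ (ss[k] * seg.local_com) for k, seg in enumerate(self.segments)]
        )

    def mass_matrix(self, s, masses, q, fkstate=None) -> np.ndarray:
        """Generalized mass matrix M(q), symmetric positive definite."""
        masses = np.asarray(masses, dtype=float)
        st = fkstate if fkstate is not None else self.fk(s, q)
        Jw = self._body_jacobians(st)
        Iw = self._world_inertias(st, s, masses)
        coms = self._com_points(st, s)
        M = np.zeros((self.n_q, self.n_q))
        for k, seg in enumerate(self.segments):
            Jv = self.point_jacobian_q(st, seg.name, coms[k])
            M += masses[k] * Jv.T @ Jv + Jw[k].T @ Iw[k] @ Jw[k]
        return 0.5 * (M + M.T)

    def _body_velocities(self, s, q, qd, qdd, st: FKState):
        """Propagate spatial velocity/acceleration down the tree.

        Returns per-segment (omega, alpha, v_o, a_o) at the segment origin.
        """
        ss = self.seg_scales(s)
        omega = np.zeros((self.n_seg, 3))
        alpha = np.zeros((self.n_seg, 3))
        v_o = np.zeros((self.n_seg, 3))
        a_o = np.zeros((self.n_seg, 3))
        for j in self.joints:
            if j.parent is None:
                w_, al_, v_, a_ = np.zeros(3), np.zeros(3), np.zeros(3), np.zeros(3)
                o = np.zeros(3)
                ip = None
            else:
                ip = self.seg_index[j.parent]
                w_, al_, v_, a_ = omega[ip].copy(), alpha[ip].copy(), v_o[ip].copy(), a_o[ip].copy()
                o = st.o[ip]
            if ip is not None:
                d = st.R[ip] @ (ss[ip] * j.parent_offset)
                o = o + d
                v_ = v_ + _cr(w_, d)
                a_ = a_ + _cr(al_, d) + _cr(w_, _cr(w_, d))
            for k in range(j.dof_slice.start, j.dof_slice.stop):
                wld = st.dof_axis[k]
                if st.dof_kind[k] == "t":
                    # translational dofs occur only at the root where omega = 0
                    o = o + q[k] * wld
                    v_ = v_ + qd[k] * wld
                    a_ = a_ + qdd[k] * wld + _cr(w_, 2 * qd[k] * wld)
                else:
                    al_ = al_ + qdd[k] * wld + _cr(w_, qd[k] * wld)
                    w_ = w_ + qd[k] * wld
                    # rotation about a point on the axis: v, a at that point unchanged
            ic = self.seg_index[j.child]
            d = st.o[ic] - o  # child-side scaled offset in world frame
            v_ = v_ + _cr(w_, d)
            a_ = a_ + _cr(al_, d) + _cr(w_, _cr(w_, d))
            omega[ic], alpha[ic], v_o[ic], a_o[ic] = w_, al_, v_, a_
        return omega, alpha, v_o, a_o

    def inverse_dynamics(self, s, masses, q, qd, qdd, external_wrenches=None, gravity=True):
        """Generalized forces realizing (q, qd, qdd) under the given loads.

        ``external_wrenches`` maps segment name -> (force, moment) with the
        moment taken about the world origin.  The first six entries of the
        returned vector are the root free-joint forces — the residual wrench.
        """
        masses = np.asarray(masses, dtype=float)
        q = np.asarray(q, dtype=float)
        qd = np.asarray(qd, dtype=float)
        qdd = np.asarray(qdd, dtype=float)
        if q.shape != (self.n_q,) or qd.shape != (self.n_q,) or qdd.shape != (self.n_q,):
            raise SkeletonError("q, qd, qdd must all have length n_q")
        st = self.fk(s, q)
        omega, alpha, v_o, a_o = self._body_velocities(s, q, qd, qdd, st)
        Iw = self._world_inertias(st, s, masses)
        coms = self._com_points(st, s)
        g = self.gravity if gravity else np.zeros(3)
        tau = np.zeros(self.n_q)
        for k, seg in enumerate(self.segments):
            r = coms[k] - st.o[k]
            a_c = a_o[k] + _cr(alpha[k], r) + _cr(omega[k], _cr(omega[k], r))
            F = masses[k] * (a_c - g)  # net force required at COM
            N = Iw[k] @ alpha[k] + _cr(omega[k], Iw[k] @ omega[k])
            tau += self._project_wrench(st, seg.name, coms[k], F, N)
        if external_wrenches:
            tau -= self.generalized_external_forces(st, external_wrenches)
        return tau

    def _project_wrench(self, st: FKState, seg_name, point, F, N):
        """Generalized forces of (force F at ``point``, couple N) on a segment."""
        out = np.zeros(self.n_q)
        A = self._ancestor_arr[seg_name]
        axes = st.dof_axis[A]
        m = np.cross(point[None, :] - st.dof_point[A], F[None, :]) + N
        vals = np.einsum("dj,dj->d", axes, m)
        tmask = st.kind_t[A]
        if tmask.any():
            vals[tmask] = axes[tmask] @ F
        out[A] = vals
        return out

    def unit_mass_root_columns(self, s, q, qd, qdd, gravity=True):
        """Root-6 generalized inertial+gravity force per unit mass of each
        segment, (6, n_seg) — one kinematics pass instead of n_seg inverse
        dynamics calls.  The root residual wrench is affine in the segment
        masses with these columns (inertia scales proportionally to mass)."""
        st = self.fk(s, q)
        unit = np.ones(self.n_seg)
        omega, alpha, _, a_o = self._body_velocities(s, q, qd, qdd, st)
        Iw = self._world_inertias(st, s, unit)
        coms = self._com_points(st, s)
        g = self.gravity if gravity else np.zeros(3)
        cols = np.zeros((6, self.n_seg))
        for k, seg in enumerate(self.segments):
            r = coms[k] - st.o[k]
            a_c = a_o[k] + _cr(alpha[k], r) + _cr(omega[k], _cr(omega[k], r))
            F = a_c - g
            N = Iw[k] @ alpha[k] + _cr(omega[k], Iw[k] @ omega[k])
            cols[:, k] = self._project_wrench(st, seg.name, coms[k], F, N)[:6]
        return cols

    def generalized_external_forces(self, st: FKState, external_wrenches) -> np.ndarray:
        """Generalized forces of world wrenches (force, moment about origin)."""
        Q = np.zeros(self.n_q)
        for seg_name, (f_ext, m0_ext) in external_wrenches.items():
            if seg_name not in self.seg_index:
                raise SkeletonError(f"external wrench on unknown segment {seg_name!r}")
            f_ext = np.asarray(f_ext, dtype=float)
            m0_ext = np.asarray(m0_ext, dtype=float)
            A = self._ancestor_arr[seg_name]
            axes = st.dof_axis[A]
            m = m0_ext[None, :] - np.cross(st.dof_point[A], f_ext[None, :])
            vals = np.einsum("dj,dj->d", axes, m)
            tmask = st.kind_t[A]
            if tmask.any():
                vals[tmask] = axes[tmask] @ f_ext
            Q[A] += vals
        return Q

    def forward_dynamics(self, s, masses, q, qd, tau, external_wrenches=None, gravity=True):
        """Accelerations from applied generalized forces (validation helper)."""
        bias = self.inverse_dynamics(s, masses, q, qd, np.zeros(self.n_q), external_wrenches, gravity)
        M = self.mass_matrix(s, masses, q)
        return np.linalg.solve(M, np.asarray(tau, dtype=float) - bias)

    def kinetic_energy(self, s, masses, q, qd):
        st = self.fk(s, q)
        omega, _, v_o, _ = self._body_velocities(s, q, qd, np.zeros(self.n_q), st)
        coms = self._com_points(st, s)
        Iw = self._world_inertias(st, s, masses)
        e = 0.0
        for k in range(self.n_seg):
            v_c = v_o[k] + _cr(omega[k], coms[k] - st.o[k])
            e += 0.5 * masses[k] * v_c @ v_c + 0.5 * omega[k] @ Iw[k] @ omega[k]
        return e

    def root_generalized_to_wrench(self, st: FKState, tau_root6: np.ndarray):
        """Convert root generalized forces to a world wrench about the origin.

        The root translations are world-aligned, so the force is the first
        three components directly.  The rotational components are torques
        about the (non-orthogonal) Euler axes; inverting the axis matrix
        recovers the Cartesian torque about the root joint origin, which is
        then shifted to the world origin.
        """
        W = st.dof_axis[3:6]  # rows: world axes of the root Euler dofs
        f = np.asarray(tau_root6[:3], dtype=float)
        m_about_point = np.linalg.solve(W, tau_root6[3:6])
        pt = st.dof_point[3]
        m0 = m_about_point + np.cross(pt, f)
        return f, m0

    # --------------------------------------------------------------- export
    def to_json_dict(self) -> dict:
        def inertia6(I):
            return [I[0, 0], I[1, 1], I[2, 2], I[0, 1], I[0, 2], I[1, 2]]

        return {
            "version": 1,
            "gravity": self.gravity.tolist(),
            "segments": [
                {
                    "name": s.name,
                    "mass": s.mass,
                    "com": s.local_com.tolist(),
                    "inertia": inertia6(s.inertia),
                }
                for s in self.segments
            ],
            "joints": [
                {
                    "name": j.name,
                    "type": j.type,
                    "parent": j.parent,
                    "child": j.child,
                    "parent_offset": j.parent_offset.tolist(),
                    "child_offset": j.child_offset.tolist(),
                    "axes": j.axes.tolist(),
                }
                for j in self.joints
            ],
            "markers": [
                {"label": m.label, "segment": m.segment, "offset": m.offset.tolist(), "kind": m.kind}
                for m in self.markers
            ],
        }

    def save_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    def copy(self) -> "SkeletonModel":
        return _skeleton_from_dict(self.to_json_dict())


# --------------------------------------------------------------------- loaders
def _inertia_from_spec(v):
    v = np.asarray(v, dtype=float)
    if v.shape == (3, 3):
        return v
    if v.shape == (3,):
        return np.diag(v)
    if v.shape == (6,):
        xx, yy, zz, xy, xz, yz = v
        return np.array([[xx, xy, xz], [xy, yy, yz], [xz, yz, zz]])
    raise SkeletonError("inertia must be 3, 6 or 3x3 values")


def _skeleton_from_dict(d: dict) -> SkeletonModel:
    segments = [
        BodySegment(s["name"], float(s["mass"]), s["com"], _inertia_from_spec(s["inertia"]))
        for s in d["segments"]
    ]
    joints = [
        JointDef(
            j["name"],
            j["type"],
            j.get("parent"),
            j["child"],
            j.get("parent_offset", (0, 0, 0)),
            j.get("child_offset", (0, 0, 0)),
            j.get("axes", []),
        )
        for j in d["joints"]
    ]
    markers = [
        MarkerDef(m["label"], m["segment"], m["offset"], m.get("kind", "tracking"))
        for m in d.get("markers", [])
    ]
    return SkeletonModel(segments, joints, markers, d.get("gravity", (0.0, -9.81, 0.0)))


_OSIM_JOINT_MAP = {
    "PinJoint": "revolute1",
    "FreeJoint": "free6",
    "BallJoint": "ball3",
    "UniversalJoint": "universal2",
}


def _load_osim_subset(path) -> SkeletonModel:
    """Restricted OpenSim-XML reader: Body/Pin/Ball/Free/Universal/Marker only.

    Muscles and constraints are ignored with a warning; any other joint type
    (CustomJoint in particular) is rejected.
    """
    tree = ET.parse(path)
    root = tree.getroot()
    model = root.find("Model")
    if model is None:
        raise SkeletonError("osim file has no <Model> element")

    def vec(el, tag, default="0 0 0"):
        t = el.find(tag)
        txt = t.text if t is not None and t.text else default
        return np.array([float(x) for x in txt.split()])

    segments = []
    for body in model.iter("Body"):
        name = body.get("name")
        mass = float(body.findtext("mass", "0"))
        com = vec(body, "mass_center")
        in_el = body.find("inertia")
        if in_el is not None and in_el.text:
            inertia = _inertia_from_spec([float(x) for x in in_el.text.split()])
        else:
            diag = [float(body.findtext(f"inertia_{ax}{ax}", "0.01")) for ax in "xyz"]
            inertia = np.diag(diag)
        segments.append(BodySegment(name, mass, com, inertia))

    joints = []
    jointset = model.find("JointSet")
    joint_parent = jointset.find("objects") if jointset is not None else None
    if joint_parent is None:
        raise SkeletonError("osim file has no JointSet")
    for el in joint_parent:
        if el.tag not in _OSIM_JOINT_MAP:
            raise SkeletonError(f"unsupported joint type {el.tag!r} in osim_subset")
        parent = el.findtext("socket_parent_frame", "").replace("/ground", "ground").split("/")[-1]
        parent = parent.removesuffix("_offset")
        child = el.findtext("socket_child_frame", "").split("/")[-1].removesuffix("_offset")
        p_off = vec(el, "location_in_parent")
        c_off = vec(el, "location_in_child")
        axes = []
        if el.tag == "PinJoint":
            axes = [vec(el, "axis", "0 0 1")]
        elif el.tag == "UniversalJoint":
            axes = [np.array([1.0, 0, 0]), np.array([0, 1.0, 0])]
        joints.append(
            JointDef(
                el.get("name"),
                _OSIM_JOINT_MAP[el.tag],
                None if parent in ("ground", "") else parent,
                child,
                p_off,
                c_off,
                axes,
            )
        )

    markers = []
    for mk in model.iter("Marker"):
        seg = mk.findtext("socket_parent_frame", mk.findtext("body", "")).split("/")[-1]
        kind = "anatomical" if mk.findtext("fixed", "false").strip() == "true" else "tracking"
        markers.append(MarkerDef(mk.get("name"), seg, vec(mk, "location"), kind))

    for skipped in ("ForceSet", "ConstraintSet"):
        el = model.find(skipped)
        if el is not None and len(el.findall(".//*")):
            warnings.warn(f"osim_subset: ignoring {skipped} contents")
    return SkeletonModel(segments, joints, markers)


def load_skeleton(path, format: str = "native_json") -> SkeletonModel:
    """Load a skeleton from the native JSON dialect or the OpenSim subset."""
    if format == "native_json":
        with open(path) as fh:
            return _skeleton_from_dict(json.load(fh))
    if format == "osim_subset":
        return _load_osim_subset(path)
    raise SkeletonError(f"unknown skeleton format {format!r}")
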