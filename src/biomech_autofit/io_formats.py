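"""Motion-capture file I/O, stream synchronization and foot-load assignment.

Supported text formats:

* TRC marker trajectories (tab-delimited, standard two-row column header).
* MOT-style tab-delimited tables with an ``nRows``/``nColumns``/``endheader``
  header, used both for ground-reaction-force input and joint angle/torque
  output.
* YAML force-plate geometry configuration (corners and column prefixes).

All downstream math sees SI units (metres, newtons, seconds) regardless of
the units declared in the files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.signal import butter, filtfilt

__all__ = [
    "MarkerTrajectories",
    "ForcePlateRecord",
    "TrialData",
    "FootWrenches",
    "read_trc",
    "write_trc",
    "read_grf_mot",
    "write_grf_mot",
    "read_mot_table",
    "write_mot_table",
    "load_plate_config",
    "synchronize",
    "assign_forces_to_feet",
    "FormatError",
    "FootAssignmentError",
]

_LENGTH_UNITS = {"m": 1.0, "mm": 0.001, "cm": 0.01}


class FormatError(ValueError):
    pass


class FootAssignmentError(RuntimeError):
    """Both feet found on a single force plate, violating the assignment assumption."""


@dataclass
class MarkerTrajectories:
    labels: list[str]
    frames: np.ndarray  # (T, M, 3) metres; NaN where absent
    present: np.ndarray  # (T, M) bool
    rate: float  # Hz

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        if self.rate <= 0:
            raise FormatError("marker rate must be > 0")
        T, M, _ = self.frames.shape
        if self.present.shape != (T, M) or len(self.labels) != M:
            raise FormatError("inconsistent marker trajectory shapes")

    @property
    def n_frames(self):
        return self.frames.shape[0]

    @property
    def dt(self):
        return 1.0 / self.rate

    @property
    def times(self):
        return np.arange(self.n_frames) / self.rate


@dataclass
class ForcePlateRecord:
    plate_id: str
    corners: np.ndarray  # (4, 3) metres, lab frame
    force: np.ndarray  # (Tf, 3) N
    moment: np.ndarray  # (Tf, 3) N m (free moment, about the COP)
    cop: np.ndarray  # (Tf, 3) metres
    rate: float

    def __post_init__(self):
        self.corners = np.asarray(self.corners, dtype=float)
        self.force = np.atleast_2d(np.asarray(self.force, dtype=float))
        self.moment = np.atleast_2d(np.asarray(self.moment, dtype=float))
        self.cop = np.atleast_2d(np.asarray(self.cop, dtype=float))
        if self.corners.shape != (4, 3):
            raise FormatError(f"plate {self.plate_id}: need 4 corner points")
        # coplanarity within 1 mm
        v1, v2 = self.corners[1] - self.corners[0], self.corners[2] - self.corners[0]
        n = np.cross(v1, v2)
        nn = np.linalg.norm(n)
        if nn < 1e-12:
            raise FormatError(f"plate {self.plate_id}: degenerate corners")
        if abs((self.corners[3] - self.corners[0]) @ (n / nn)) > 1e-3:
            raise FormatError(f"plate {self.plate_id}: corners not coplanar within 1 mm")
        if self.rate <= 0:
            raise FormatError("plate rate must be > 0")

    @property
    def n_frames(self):
        return self.force.shape[0]

    def wrench_about_origin(self):
        """(force, moment-about-world-origin) time series, each (Tf, 3)."""
        m0 = np.cross(self.cop, self.force) + self.moment
        return self.force, m0


@dataclass
class TrialData:
    markers: MarkerTrajectories
    plates: list[ForcePlateRecord] = field(default_factory=list)
    meta: dict = field(default_factory=dict)  # height_m, weight_kg, sex


# ----------------------------------------------------------------------- TRC
def read_trc(path) -> MarkerTrajectories:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6:
        raise FormatError("TRC file too short")
    keys = lines[1].split("\t")
    vals = lines[2].split("\t")
    hdr = dict(zip(keys, vals))
    try:
        rate = float(hdr["DataRate"])
        units = hdr["Units"].strip()
    except KeyError as e:
        raise FormatError(f"TRC header missing {e}") from e
    if units not in _LENGTH_UNITS:
        raise FormatError(f"unknown TRC units {units!r}")
    scale = _LENGTH_UNITS[units]
    labels = [c for c in lines[3].split("\t")[2:] if c.strip()]
    M = len(labels)
    rows = []
    for ln in lines[5:]:
        if not ln.strip():
            continue
        cells = ln.split("\t")[2:]
        if len(cells) < 3 * M:
            cells = cells + [""] * (3 * M - len(cells))
        row = [float(c) if c.strip() else np.nan for c in cells[: 3 * M]]
        rows.append(row)
    data = np.asarray(rows, dtype=float).reshape(len(rows), M, 3) * scale
    present = ~np.isnan(data).any(axis=2)
    data[~present] = np.nan
    return MarkerTrajectories(labels, data, present, rate)


def write_trc(traj: MarkerTrajectories, path, units="mm"):
    scale = 1.0 / _LENGTH_UNITS[units]
    T, M, _ = traj.frames.shape
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(f"{traj.rate:g}\t{traj.rate:g}\t{T}\t{M}\t{units}\t{traj.rate:g}\t1\t{T}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(traj.labels) + "\t\t\t\n")
        sub = "\t\t" + "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(M))
        fh.write(sub + "\n\n")
        for t in range(T):
            cells = [str(t + 1), f"{t / traj.rate:.6f}"]
            for i in range(M):
                if traj.present[t, i]:
                    cells += [f"{v * scale:.8f}" for v in traj.frames[t, i]]
                else:
                    cells += ["", "", ""]
            fh.write("\t".join(cells) + "\n")


# ----------------------------------------------------------------------- MOT
def read_mot_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a tab-delimited MOT-style table; returns (dataframe, header dict)."""
    header = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    body_start = None
    for i, ln in enumerate(lines):
        if ln.strip().lower() == "endheader":
            body_start = i + 1
            break
        if "=" in ln:
            k, v = ln.split("=", 1)
            header[k.strip()] = v.strip()
    if body_start is None:
        raise FormatError("MOT file missing 'endheader'")
    cols = lines[body_start].rstrip("\n").split("\t")
    rows = [
        [float(c) if c.strip() else np.nan for c in ln.split("\t")]
        for ln in lines[body_start + 1 :]
        if ln.strip()
    ]
    df = pd.DataFrame(rows, columns=cols)
    return df, header


def write_mot_table(df: pd.DataFrame, path, name="motion", in_degrees=False):
    with open(path, "w") as fh:
        fh.write(f"{name}\nversion=1\n")
        fh.write(f"nRows={len(df)}\nnColumns={len(df.columns)}\n")
        fh.write(f"inDegrees={'yes' if in_degrees else 'no'}\nendheader\n")
        fh.write("\t".join(df.columns) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(f"{v:.10g}" for v in row.values) + "\n")


def load_plate_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if "plates" not in cfg:
        raise FormatError("plate config must have a 'plates' list")
    return cfg


_GRF_SUFFIXES = {
    "force": ("force_x", "force_y", "force_z"),
    "moment": ("torque_x", "torque_y", "torque_z"),
    "cop": ("cop_x", "cop_y", "cop_z"),
}


def read_grf_mot(path, plate_config: dict) -> list[ForcePlateRecord]:
    """Read per-plate ground reaction forces from a tab-delimited MOT file.

    ``plate_config`` (from :func:`load_plate_config`) gives, per plate, the
    corner geometry and the column prefix; an optional ``units`` mapping
    declares the file units for ``cop`` (m/mm/cm), ``force`` and ``moment``.
    """
    df, _ = read_mot_table(path)
    if "time" not in df.columns:
        raise FormatError("GRF file needs a 'time' column")
    time = df["time"].to_numpy()
    if len(time) > 1:
        dts = np.diff(time)
        if np.any(dts <= 0):
            raise FormatError("GRF time column must be strictly increasing")
        rate = 1.0 / np.mean(dts)
    else:
        rate = 1.0
    units = plate_config.get("units", {})
    cop_scale = _LENGTH_UNITS[units.get("cop", "m")]
    force_scale = {"N": 1.0, "kN": 1000.0}[units.get("force", "N")]
    moment_scale = {"Nm": 1.0, "Nmm": 0.001}[units.get("moment", "Nm")]
    records = []
    for plate in plate_config["plates"]:
        prefix = plate.get("column_prefix", f"p{plate['id']}_")
        data = {}
        for kind, sfx in _GRF_SUFFIXES.items():
            names = [prefix + s for s in sfx]
            missing = [n for n in names if n not in df.columns]
            if missing:
                raise FormatError(f"GRF file missing columns {missing}")
            data[kind] = df[names].to_numpy()
        records.append(
            ForcePlateRecord(
                str(plate["id"]),
                np.asarray(plate["corners"], dtype=float),
                data["force"] * force_scale,
                data["moment"] * moment_scale,
                data["cop"] * cop_scale,
                rate,
            )
        )
    return records


def write_grf_mot(plates: list[ForcePlateRecord], path):
    cols = {"time": np.arange(plates[0].n_frames) / plates[0].rate}
    for pl in plates:
        prefix = f"p{pl.plate_id}_"
        for kind, sfx in _GRF_SUFFIXES.items():
            arr = getattr(pl, {"force": "force", "moment": "moment", "cop": "cop"}[kind])
            for j, s in enumerate(sfx):
                cols[prefix + s] = arr[:, j]
    write_mot_table(pd.DataFrame(cols), path, name="ground reaction forces")


# -------------------------------------------------------------- synchronize
def _lowpass(x, rate, cutoff_hz):
    ny = rate / 2.0
    if cutoff_hz >= ny:
        return x
    b, a = butter(4, cutoff_hz / ny)
    return filtfilt(b, a, x, axis=0)


def synchronize(trial: TrialData, cutoff_hz: float = 15.0) -> TrialData:
    """Resample force-plate channels onto the marker time grid.

    Channels are zero-phase low-pass filtered (4th-order Butterworth,
    ``cutoff_hz``) before linear interpolation.  Plates already sampled at
    the marker rate with matching length pass through untouched.
    """
    mk = trial.markers
    t_mk = mk.times
    new_plates = []
    for pl in trial.plates:
        if np.isclose(pl.rate, mk.rate) and pl.n_frames == mk.n_frames:
            new_plates.append(pl)
            continue
        if pl.rate < mk.rate:
            raise FormatError("plate rate must be >= marker rate")
        t_pl = np.arange(pl.n_frames) / pl.rate
        if t_pl[-1] < t_mk[-1] - 1e-9:
            raise FormatError("plate recording does not cover the marker time range")
        chans = {}
        for attr in ("force", "moment", "cop"):
            filt = _lowpass(getattr(pl, attr), pl.rate, cutoff_hz)
            chans[attr] = np.column_stack(
                [np.interp(t_mk, t_pl, filt[:, j]) for j in range(3)]
            )
        new_plates.append(
            ForcePlateRecord(pl.plate_id, pl.corners, chans["force"], chans["moment"], chans["cop"], mk.rate)
        )
    return TrialData(mk, new_plates, dict(trial.meta))


# ------------------------------------------------------- foot assignment
def _point_in_polygon_2d(pt, poly):
    """Ray-casting test in the horizontal (x, z) plane."""
    x, z = pt
    inside = False
    n = len(poly)
    for i in range(n):
        x1, z1 = poly[i]
        x2, z2 = poly[(i + 1) % n]
        if (z1 > z) != (z2 > z):
            xin = x1 + (z - z1) / (z2 - z1) * (x2 - x1)
            if x < xin:
                inside = not inside
    return inside


@dataclass
class FootWrenches:
    """Per-foot assigned ground loads at the marker rate."""

    feet: list[str]
    force: dict  # foot -> (T, 3)
    cop: dict  # foot -> (T, 3)
    moment: dict  # foot -> (T, 3) free moment about the COP
    assignment: np.ndarray  # (T, n_plates) index into feet, -1 if unassigned

    def wrenches_about_origin(self):
        """foot -> (force (T,3), moment about world origin (T,3))."""
        out = {}
        for foot in self.feet:
            f = self.force[foot]
            m0 = np.cross(self.cop[foot], f) + self.moment[foot]
            out[foot] = (f, m0)
        return out

    def total_force(self):
        return sum(self.force[f] for f in self.feet)

    def external_wrenches_frame(self, t):
        """Segment->wrench dict for :meth:`SkeletonModel.inverse_dynamics`."""
        out = {}
        for foot in self.feet:
            f = self.force[foot][t]
            if np.linalg.norm(f) > 0 or np.linalg.norm(self.moment[foot][t]) > 0:
                m0 = np.cross(self.cop[foot][t], f) + self.moment[foot][t]
                out[foot] = (f, m0)
        return out


def assign_forces_to_feet(
    trial: TrialData,
    skel,
    s,
    q_traj,
    force_threshold: float = 10.0,
    foot_segments: list[str] | None = None,
    max_foot_height: float = 0.12,
) -> FootWrenches:
    """Assign each plate's wrench to a foot, frame by frame.

    A plate frame whose force magnitude exceeds ``force_threshold`` is
    assigned to the foot whose segment origin projects inside the plate
    polygon while below ``max_foot_height``; if no foot is inside, the
    horizontally nearest foot takes the load.  Two feet inside the same
    plate raise :class:`FootAssignmentError`.
    """
    if foot_segments is None:
        foot_segments = [seg.name for seg in skel.segments if "foot" in seg.name.lower()]
    if not foot_segments:
        raise FootAssignmentError("skeleton declares no foot segments")
    q_traj = np.atleast_2d(q_traj)
    T = q_traj.shape[0]
    plates = trial.plates
    for pl in plates:
        if pl.n_frames != T:
            raise FormatError("plates must be synchronized to the marker rate first")
    feet_pos = np.zeros((T, len(foot_segments), 3))
    for t in range(T):
        st = skel.fk(s, q_traj[t])
        for k, foot in enumerate(foot_segments):
            feet_pos[t, k] = st.o[skel.seg_index[foot]]
    force = {f: np.zeros((T, 3)) for f in foot_segments}
    cop = {f: np.zeros((T, 3)) for f in foot_segments}
    moment = {f: np.zeros((T, 3)) for f in foot_segments}
    assignment = -np.ones((T, len(plates)), dtype=int)
    polys = [pl.corners[:, [0, 2]] for pl in plates]
    for t in range(T):
        for ip, pl in enumerate(plates):
            if np.linalg.norm(pl.force[t]) <= force_threshold:
                continue
            inside = [
                k
                for k in range(len(foot_segments))
                if feet_pos[t, k, 1] <= max_foot_height
                and _point_in_polygon_2d(feet_pos[t, k, [0, 2]], polys[ip])
            ]
            if len(inside) > 1:
                raise FootAssignmentError(
                    f"frame {t}: both feet inside plate {pl.plate_id} with force above threshold"
                )
            if inside:
                k = inside[0]
            else:
                centroid = polys[ip].mean(axis=0)
                d = np.linalg.norm(feet_pos[t, :, [0, 2]].T - centroid, axis=1)
                k = int(np.argmin(d))
                warnings.warn(
                    f"frame {t}: no foot inside plate {pl.plate_id}; assigning to nearest foot"
                )
            foot = foot_segments[k]
            if np.any(assignment[t] == k):
                # foot straddling two plates: combine the wrenches about the
                # existing COP so the total origin-moment is preserved
                m0 = (
                    np.cross(cop[foot][t], force[foot][t])
                    + moment[foot][t]
                    + np.cross(pl.cop[t], pl.force[t])
                    + pl.moment[t]
                )
                force[foot][t] += pl.force[t]
                moment[foot][t] = m0 - np.cross(cop[foot][t], force[foot][t])
            else:
                force[foot][t] = pl.force[t]
                cop[foot][t] = pl.cop[t]
                moment[foot][t] = pl.moment[t]
            assignment[t, ip] = k
    return FootWrenches(foot_segments, force, cop, moment, assignment)
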