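"""Jerk smoothing, linear COM fitting, angular fit and residual tuning.

Column oracles: every column of the COM system matrix equals the
finite-difference sensitivity of the step-by-step integrator; the angular
system is checked against explicit integration of its own linearized
dynamics.
"""

import numpy as np
import pytest

from biomech_autofit import dynamics_fit as dyn
from biomech_autofit.io_formats import FootWrenches, TrialData, assign_forces_to_feet
from biomech_autofit.kinematic_fit import default_scaling_prior
from biomech_autofit.skeleton import PoseTrajectory, _skeleton_from_dict
from biomech_autofit.synthetic import synthesize_markers

GRAVITY = np.array([0.0, -9.81, 0.0])


def _integrate_com(zeta, forces, dt, g):
    """Independent step-by-step semi-explicit Euler oracle."""
    z, zd, mu = zeta[0:3].copy(), zeta[3:6].copy(), zeta[6]
    out = [z.copy()]
    for t in range(len(forces) - 1):
        zd = zd + (mu * forces[t] + g) * dt
        z = z + zd * dt
        out.append(z.copy())
    return np.array(out)


# ------------------------------------------------------------- smoothing
class TestSmoothMinJerk:
    def test_linear_input_unchanged(self):
        t = np.linspace(0, 1, 60)[:, None]
        traj = np.hstack([2 * t + 1, -0.5 * t])
        out = dyn.smooth_min_jerk(traj, 0.01, tracking_weight=1.0)
        assert np.abs(out - traj).max() <= 1e-8

    def test_weight_sweep_monotone_jerk(self):
        rng = np.random.default_rng(0)
        traj = np.cumsum(rng.normal(0, 0.01, (80, 2)), axis=0)
        dt = 0.01
        jerks = []
        for w in (1e12, 1e9, 1e6):
            out = dyn.smooth_min_jerk(traj, dt, tracking_weight=w)
            d3 = np.diff(out, n=3, axis=0) / dt**3
            jerks.append(np.sum(d3**2))
        assert jerks[0] >= jerks[1] >= jerks[2]

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(1)
        T, dt, w = 50, 0.2, 3.0  # well-conditioned regime for the dense oracle
        traj = rng.normal(0, 1, (T, 1))
        D3 = np.zeros((T - 3, T))
        for i in range(T - 3):
            D3[i, i : i + 4] = np.array([-1, 3, -3, 1]) / dt**3
        A = D3.T @ D3 + w * np.eye(T)
        oracle = np.linalg.solve(A, w * traj[:, 0])
        out = dyn.smooth_min_jerk(traj, dt, tracking_weight=w)
        assert np.allclose(out[:, 0], oracle, atol=1e-8)


# ----------------------------------------------------------- COM system
class TestBuildComSystem:
    def test_single_frame(self):
        A, b = dyn.build_com_system(np.zeros((1, 3)), 0.01, GRAVITY)
        assert A.shape == (3, 7)
        assert np.allclose(A[:, 0:3], np.eye(3))
        assert np.allclose(A[:, 3:], 0.0)
        assert np.allclose(b, 0.0)

    def test_zero_forces_structure(self):
        A, b = dyn.build_com_system(np.zeros((10, 3)), 0.01, GRAVITY)
        assert np.allclose(A[:, 6], 0.0)
        zeta = np.concatenate([[1, 2, 3], [0.1, -0.2, 0.3], [1 / 70]])
        Z = (A @ zeta + b).reshape(10, 3)
        oracle = _integrate_com(zeta, np.zeros((10, 3)), 0.01, GRAVITY)
        assert np.allclose(Z, oracle, atol=1e-12)

    def test_matches_integrator_oracle(self):
        rng = np.random.default_rng(2)
        forces = rng.normal(0, 300, (40, 3))
        dt = 0.01
        A, b = dyn.build_com_system(forces, dt, GRAVITY)
        for _ in range(5):
            zeta = np.concatenate([rng.normal(0, 1, 6), [1 / rng.uniform(50, 90)]])
            Z = (A @ zeta + b).reshape(-1, 3)
            assert np.abs(Z - _integrate_com(zeta, forces, dt, GRAVITY)).max() < 1e-12

    def test_columns_are_fd_sensitivities(self):
        rng = np.random.default_rng(3)
        forces = rng.normal(0, 200, (25, 3))
        dt = 0.01
        A, _ = dyn.build_com_system(forces, dt, GRAVITY)
        zeta0 = np.concatenate([rng.normal(0, 1, 6), [1 / 75]])
        h = 1e-6
        for j in range(7):
            zp, zm = zeta0.copy(), zeta0.copy()
            zp[j] += h
            zm[j] -= h
            col = (_integrate_com(zp, forces, dt, GRAVITY) - _integrate_com(zm, forces, dt, GRAVITY)).ravel() / (2 * h)
            assert np.abs(A[:, j] - col).max() <= 1e-8


class TestComLinearFit:
    def test_exact_recovery_self_consistent(self):
        rng = np.random.default_rng(4)
        forces = rng.normal(0, 250, (60, 3)) + [0, 700, 0]
        dt = 0.01
        zeta_true = np.concatenate([[0.1, 0.9, -0.2], [1.1, 0.0, 0.1], [1 / 70]])
        Z_hat = _integrate_com(zeta_true, forces, dt, GRAVITY)
        A, b = dyn.build_com_system(forces, dt, GRAVITY)
        fit = dyn.com_linear_fit(Z_hat, A, b)
        assert np.abs(fit.zeta - zeta_true).max() <= 1e-9
        assert abs(fit.mass - 70.0) < 1e-6

    def test_doubling_forces_doubles_mass(self):
        rng = np.random.default_rng(5)
        forces = rng.normal(0, 250, (60, 3)) + [0, 700, 0]
        dt = 0.01
        zeta_true = np.concatenate([[0, 1, 0], [1, 0, 0], [1 / 70]])
        Z_hat = _integrate_com(zeta_true, forces, dt, GRAVITY)
        A1, b1 = dyn.build_com_system(forces, dt, GRAVITY)
        A2, b2 = dyn.build_com_system(2 * forces, dt, GRAVITY)
        m1 = dyn.com_linear_fit(Z_hat, A1, b1).mass
        m2 = dyn.com_linear_fit(Z_hat, A2, b2).mass
        assert abs(m2 - 2 * m1) / m1 < 1e-9

    def test_noisy_mass_recovery_monte_carlo(self):
        dt, T = 0.01, 300
        masses = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            forces = rng.normal(0, 150, (T, 3)) + [0, 690, 0]
            zeta_true = np.concatenate([[0, 1, 0], [1.2, 0, 0], [1 / 70]])
            Z_hat = _integrate_com(zeta_true, forces, dt, GRAVITY)
            Z_noisy = Z_hat + rng.normal(0, 0.005, Z_hat.shape)
            A, b = dyn.build_com_system(forces, dt, GRAVITY)
            masses.append(dyn.com_linear_fit(Z_noisy, A, b).mass)
        assert abs(np.mean(masses) - 70.0) / 70.0 < 0.05

    def test_zero_forces_mass_unidentifiable(self):
        A, b = dyn.build_com_system(np.zeros((30, 3)), 0.01, GRAVITY)
        with pytest.raises(dyn.MassUnidentifiableError):
            dyn.com_linear_fit(np.zeros((30, 3)), A, b)


class TestApplyRootTranslation:
    def test_identity_when_target_matches(self, clean_trial):
        ct = clean_trial
        Z = ct["skel"].com_trajectory(ct["s"], ct["masses"], ct["q"].traj)
        out = dyn.apply_root_translation(ct["skel"], ct["s"], ct["masses"], ct["q"], Z)
        assert np.abs(out.traj - ct["q"].traj).max() <= 1e-9

    def test_constant_offset_shifts_root(self, clean_trial):
        ct = clean_trial
        Z = ct["skel"].com_trajectory(ct["s"], ct["masses"], ct["q"].traj)
        d = np.array([0.05, -0.02, 0.01])
        out = dyn.apply_root_translation(ct["skel"], ct["s"], ct["masses"], ct["q"], Z + d)
        assert np.allclose(out.traj[:, :3] - ct["q"].traj[:, :3], d, atol=1e-9)
        assert np.allclose(out.traj[:, 3:], ct["q"].traj[:, 3:], atol=1e-14)

    def test_postcondition_com_matches(self, clean_trial):
        ct = clean_trial
        rng = np.random.default_rng(6)
        Z = ct["skel"].com_trajectory(ct["s"], ct["masses"], ct["q"].traj)
        Z = Z + rng.normal(0, 0.01, Z.shape)
        out = dyn.apply_root_translation(ct["skel"], ct["s"], ct["masses"], ct["q"], Z)
        Z2 = ct["skel"].com_trajectory(ct["s"], ct["masses"], out.traj)
        assert np.abs(Z2 - Z).max() <= 1e-9


# ---------------------------------------------------------- angular system
def _foot_wrenches(ct):
    return FootWrenches(
        ["foot_l", "foot_r"], dict(ct["force"]), dict(ct["cop"]), dict(ct["moment"]),
        np.zeros((ct["q"].n_frames, 2), dtype=int),
    )


def _integrate_xi(A, b, xi, T):
    return (A @ xi + b)[: 3 * T].reshape(T, 3), (A @ xi + b)[3 * T :].reshape(T, 3)


class TestBuildRootSystem:
    def test_zero_forces_lower_left_zero(self, clean_trial):
        ct = clean_trial
        T = 30
        q = PoseTrajectory(ct["q"].traj[:T], ct["q"].dt)
        fw = FootWrenches(
            ["foot_l", "foot_r"],
            {f: np.zeros((T, 3)) for f in ("foot_l", "foot_r")},
            {f: np.zeros((T, 3)) for f in ("foot_l", "foot_r")},
            {f: np.zeros((T, 3)) for f in ("foot_l", "foot_r")},
            np.zeros((T, 2), dtype=int),
        )
        A, b = dyn.build_root_system(ct["skel"], ct["s"], ct["masses"], q, fw, 1.0 / ct["masses"].sum())
        assert np.allclose(A[3 * T :, 0:6], 0.0, atol=1e-12)

    def test_upper_blocks_match_com_system(self, clean_trial):
        ct = clean_trial
        T = 30
        q = PoseTrajectory(ct["q"].traj[:T], ct["q"].dt)
        fw = _foot_wrenches(ct)
        fw_t = FootWrenches(
            fw.feet,
            {f: fw.force[f][:T] for f in fw.feet},
            {f: fw.cop[f][:T] for f in fw.feet},
            {f: fw.moment[f][:T] for f in fw.feet},
            np.zeros((T, 2), dtype=int),
        )
        mu = 1.0 / ct["masses"].sum()
        A, b = dyn.build_root_system(ct["skel"], ct["s"], ct["masses"], q, fw_t, mu)
        Ac, bc = dyn.build_com_system(fw_t.total_force(), q.dt, ct["skel"].gravity)
        # upper-left initial-condition blocks identical; upper-right zero
        assert np.allclose(A[: 3 * T, 0:6], Ac[:, 0:6], atol=1e-12)
        assert np.allclose(A[: 3 * T, 6:12], 0.0, atol=1e-12)
        # the fixed-mass force term folds into b: A_com zeta = A xi + b check
        zeta = np.concatenate([[0.1, 1, 0], [1.2, 0, 0.05], [mu]])
        xi = np.concatenate([zeta[:6], np.zeros(6)])
        assert np.allclose((Ac @ zeta + bc), (A @ xi + b)[: 3 * T], atol=1e-10)

    def test_linearized_integrator_oracle(self, clean_trial):
        # A xi + b must equal explicit step-by-step integration of the
        # linearized dynamics the builder encodes
        ct = clean_trial
        T = 25
        skel, s, masses = ct["skel"], ct["s"], ct["masses"]
        q = PoseTrajectory(ct["q"].traj[:T], ct["q"].dt)
        fw = _foot_wrenches(ct)
        fw_t = FootWrenches(
            fw.feet,
            {f: fw.force[f][:T] for f in fw.feet},
            {f: fw.cop[f][:T] for f in fw.feet},
            {f: fw.moment[f][:T] for f in fw.feet},
            np.zeros((T, 2), dtype=int),
        )
        mu = 1.0 / masses.sum()
        A, b = dyn.build_root_system(skel, s, masses, q, fw_t, mu)

        # reconstruct the same linearization ingredients independently
        from biomech_autofit.skeleton import finite_difference_derivatives

        qd, qdd = finite_difference_derivatives(q.traj, q.dt)
        f_tot = fw_t.total_force()
        rng = np.random.default_rng(8)
        xi = rng.normal(0, 0.3, 12)
        dt = q.dt
        # explicit integration of: zdd = mu f + g ; thdd = th0dd + G (z - z_cur)
        theta0 = np.zeros((T, 3))
        G = np.zeros((T, 3, 3))
        z_cur = np.zeros((T, 3))
        for t in range(T):
            st = skel.fk(s, q.traj[t])
            z_cur[t] = skel.com_position(s, masses, q.traj[t], fkstate=st)
            M = skel.mass_matrix(s, masses, q.traj[t], fkstate=st)
            bias = skel.inverse_dynamics(s, masses, q.traj[t], qd[t], np.zeros(skel.n_q))
            Q_ext = skel.generalized_external_forces(st, fw_t.external_wrenches_frame(t))
            acc_root = np.linalg.solve(M[:6, :6], Q_ext[:6] - bias[:6] - M[:6, 6:] @ qdd[t, 6:])
            theta0[t] = acc_root[3:6]
            W = st.dof_axis[3:6]
            sk = np.array(
                [[0, -f_tot[t][2], f_tot[t][1]], [f_tot[t][2], 0, -f_tot[t][0]], [-f_tot[t][1], f_tot[t][0], 0]]
            )
            G[t] = np.linalg.inv(M[:6, :6])[3:6, 3:6] @ W.T @ sk
        z, zdot = xi[0:3].copy(), xi[3:6].copy()
        th, thdot = xi[6:9].copy(), xi[9:12].copy()
        Z_o, Th_o = [z.copy()], [th.copy()]
        for t in range(T - 1):
            thdd = theta0[t] + G[t] @ (z - z_cur[t])
            zdot = zdot + (mu * f_tot[t] + skel.gravity) * dt
            z = z + zdot * dt
            thdot = thdot + thdd * dt
            th = th + thdot * dt
            Z_o.append(z.copy())
            Th_o.append(th.copy())
        Z, Th = _integrate_xi(A, b, xi, T)
        assert np.abs(Z - np.array(Z_o)).max() <= 1e-10
        assert np.abs(Th - np.array(Th_o)).max() <= 1e-10


class TestRootAngularFit:
    def test_self_consistency_one_extra_iteration(self, clean_trial):
        # data generated by the linear model itself: the second solve changes
        # nothing beyond numerical tolerance
        ct = clean_trial
        skel, s, masses = ct["skel"], ct["s"], ct["masses"]
        q = ct["q"]
        fw = _foot_wrenches(ct)
        mu = 1.0 / masses.sum()
        Z_hat = skel.com_trajectory(s, masses, q.traj)
        rf = dyn.root_angular_fit(
            skel, s, masses, q, fw, mu, Z_hat, q.traj[:, 3:6], tol=1e-6, max_iter=50
        )
        assert rf.converged
        assert rf.iterations <= 5

    def test_consistent_trial_converges_quickly(self, clean_trial):
        ct = clean_trial
        skel, s, masses = ct["skel"], ct["s"], ct["masses"]
        fw = _foot_wrenches(ct)
        mu = 1.0 / masses.sum()
        Z_hat = skel.com_trajectory(s, masses, ct["q"].traj)
        rf = dyn.root_angular_fit(skel, s, masses, ct["q"], fw, mu, Z_hat, ct["q"].traj[:, 3:6])
        assert rf.converged and rf.iterations < 30
        assert np.rad2deg(np.abs(rf.Theta - ct["q"].traj[:, 3:6])).max() < 0.1

    def test_translating_free_body_zero_rotation(self):
        # force through the COM of a single body, COP at the COM: rotations
        # stay identically at the initial-condition integration (zero)
        skel = _skeleton_from_dict(
            {
                "segments": [{"name": "foot_x", "mass": 10.0, "com": [0, 0, 0], "inertia": [0.1, 0.1, 0.1]}],
                "joints": [{"name": "root", "type": "free6", "parent": None, "child": "foot_x"}],
                "markers": [],
            }
        )
        T, dt = 40, 0.01
        t = np.arange(T) * dt
        traj = np.zeros((T, 6))
        # vertical oscillation driven by a known force; horizontal rest
        amp, om = 0.02, 8.0
        traj[:, 1] = 1.0 + amp * np.sin(om * t)
        q = PoseTrajectory(traj, dt)
        acc = -amp * om**2 * np.sin(om * t)
        force = np.zeros((T, 3))
        force[:, 1] = 10.0 * (acc + 9.81)
        cop = traj[:, 0:3].copy()  # COP at the COM every frame
        fw = FootWrenches(
            ["foot_x"], {"foot_x": force}, {"foot_x": cop}, {"foot_x": np.zeros((T, 3))},
            np.zeros((T, 1), dtype=int),
        )
        Z_hat = traj[:, 0:3]
        rf = dyn.root_angular_fit(skel, skel.default_scales(), [10.0], q, fw, 0.1, Z_hat, traj[:, 3:6])
        assert rf.converged
        assert np.abs(rf.Theta).max() <= 1e-6


# ---------------------------------------------------------- residuals/final
class TestResidualReport:
    def _result(self, f_res, t_res, fw, skel, s, masses, q):
        fpct, tpct = dyn._normalized_residuals(skel, s, masses, q, fw, f_res, t_res)
        return dyn.DynamicsFitResult(
            s, None, q, masses, f_res, t_res, fpct, tpct, 0.0
        )

    def test_zero_residual_passes(self, clean_trial):
        ct = clean_trial
        T = ct["q"].n_frames
        fw = _foot_wrenches(ct)
        res = self._result(np.zeros((T, 3)), np.zeros((T, 3)), fw, ct["skel"], ct["s"], ct["masses"], ct["q"])
        rep = dyn.residual_report(res)
        assert rep["pass"] and rep["residual_force_pct"] == 0.0

    def test_constant_force_arithmetic(self, clean_trial):
        ct = clean_trial
        T = ct["q"].n_frames
        fw = _foot_wrenches(ct)
        peak = np.max(np.linalg.norm(fw.total_force(), axis=1))
        f_res = np.tile([0.0, 0.02 * peak, 0.0], (T, 1))
        res = self._result(f_res, np.zeros((T, 3)), fw, ct["skel"], ct["s"], ct["masses"], ct["q"])
        assert np.isclose(res.residual_force_pct, 2.0, atol=1e-9)

    def test_matches_flat_loop_oracle(self, clean_trial):
        ct = clean_trial
        rng = np.random.default_rng(9)
        T = ct["q"].n_frames
        fw = _foot_wrenches(ct)
        f_res = rng.normal(0, 5, (T, 3))
        t_res = rng.normal(0, 2, (T, 3))
        res = self._result(f_res, t_res, fw, ct["skel"], ct["s"], ct["masses"], ct["q"])
        peak = max(np.linalg.norm(fw.total_force()[t]) for t in range(T))
        com_h = np.mean([ct["skel"].com_position(ct["s"], ct["masses"], ct["q"].traj[t])[1] for t in range(T)])
        f_rms = np.sqrt(sum(f_res[t] @ f_res[t] for t in range(T)) / T)
        t_rms = np.sqrt(sum(t_res[t] @ t_res[t] for t in range(T)) / T)
        assert np.isclose(res.residual_force_pct, 100 * f_rms / peak, atol=1e-9)
        assert np.isclose(res.residual_torque_pct, 100 * t_rms / (peak * com_h), atol=1e-9)

    def test_zero_peak_grf_rejected(self, clean_trial):
        ct = clean_trial
        T = 5
        fw = FootWrenches(
            ["foot_l"], {"foot_l": np.zeros((T, 3))}, {"foot_l": np.zeros((T, 3))},
            {"foot_l": np.zeros((T, 3))}, np.zeros((T, 1), dtype=int),
        )
        q = PoseTrajectory(ct["q"].traj[:T], ct["q"].dt)
        with pytest.raises(ValueError, match="zero peak"):
            dyn._normalized_residuals(ct["skel"], ct["s"], ct["masses"], q, fw,
                                      np.zeros((T, 3)), np.zeros((T, 3)))


@pytest.fixture(scope="module")
def final_map_inputs():
    from biomech_autofit.kinematic_fit import default_scaling_prior
    from biomech_autofit.synthetic import (
        gait_skeleton, generate_gait_motion, sample_subject, synthesize_consistent_grf,
    )

    skel = gait_skeleton()
    prior = default_scaling_prior(skel)
    s, p, masses = sample_subject(prior, seed=31, skel=skel)
    q, stance = generate_gait_motion(skel, s, 0.8, 100.0, seed=32)
    force, cop, moment, plates = synthesize_consistent_grf(skel, s, masses, q, stance)
    traj = synthesize_markers(skel, s, p, q)
    fw = FootWrenches(
        ["foot_l", "foot_r"], force, cop, moment, np.zeros((q.n_frames, 2), dtype=int)
    )
    Z_hat = skel.com_trajectory(s, masses, q.traj)
    return {
        "skel": skel, "prior": prior, "s": s, "p": p, "masses": masses, "q": q,
        "fw": fw, "traj": traj, "Z_hat": Z_hat,
    }


class TestFinalDynamicsMap:
    def test_fixed_point_on_consistent_data(self, final_map_inputs):
        d = final_map_inputs
        res = dyn.final_dynamics_map(
            d["skel"], d["prior"], d["traj"], d["fw"], d["s"], d["p"], d["q"],
            d["masses"], 1.0 / d["masses"].sum(), d["Z_hat"], d["q"].traj[:, 3:6],
            n_passes=1,
        )
        assert np.abs(res.masses - d["masses"]).max() / d["masses"].max() <= 0.01
        assert res.residual_force_pct <= 0.01
        assert res.objective_final <= res.objective_init + 1e-9

    def test_inflated_mass_recovered(self, final_map_inputs):
        d = final_map_inputs
        res = dyn.final_dynamics_map(
            d["skel"], d["prior"], d["traj"], d["fw"], d["s"], d["p"], d["q"],
            1.1 * d["masses"], 1.0 / (1.1 * d["masses"].sum()), d["Z_hat"], d["q"].traj[:, 3:6],
            n_passes=2,
        )
        true_total = d["masses"].sum()
        assert abs(res.masses.sum() - true_total) / true_total <= 0.02

    def test_residual_weight_monotonicity(self, final_map_inputs):
        # stronger residual penalty never increases the final RMS residual
        d = final_map_inputs
        rms = []
        for sd in (10.0, 1.0, 0.1):
            res = dyn.final_dynamics_map(
                d["skel"], d["prior"], d["traj"], d["fw"], d["s"], d["p"], d["q"],
                1.05 * d["masses"], 1.0 / (1.05 * d["masses"].sum()), d["Z_hat"],
                d["q"].traj[:, 3:6], residual_force_sd=sd, residual_torque_sd=sd,
                n_passes=1,
            )
            rms.append(np.sqrt(np.mean(np.sum(res.residual_force**2, axis=1))))
        # monotone within solver tolerance (the residual sits at its floor)
        assert rms[1] <= rms[0] * (1 + 1e-3)
        assert rms[2] <= rms[1] * (1 + 1e-3)
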