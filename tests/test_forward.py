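import numpy as np
import pytest

from emflowtomo.forward import (
    ConductionSolver,
    MeasurementVector,
    SimulationConfig,
    add_noise,
    assemble_weight_matrix,
    electrode_voltages,
    generate_dataset,
    load_dataset,
    reciprocal_field,
    save_dataset,
    solve_flow_potential,
)
from emflowtomo.phantom import (
    FlowConfig,
    PhantomConfig,
    StenosisConfig,
    VelocityField,
    velocity_field,
)


class TestFlowPotential:
    def test_zero_velocity_gives_zero_potential(self, small_phantom, small_solver):
        vf = VelocityField(
            vz=np.zeros_like(small_phantom.sigma),
            stenosis_mask=np.zeros_like(small_phantom.artery_mask),
            time=0.0,
        )
        u = solve_flow_potential(small_phantom, vf, 0.1, solver=small_solver)
        assert np.allclose(u.u, 0.0)

    def test_linearity_in_field_strength_and_velocity(self, small_phantom, small_solver):
        vf = velocity_field(small_phantom, StenosisConfig(0.2, "+x"), t=0.1)
        u1 = solve_flow_potential(small_phantom, vf, 0.05, solver=small_solver).u
        u2 = solve_flow_potential(small_phantom, vf, 0.10, solver=small_solver).u
        assert np.allclose(u2, 2 * u1, rtol=1e-6, atol=1e-18)
        vf2 = VelocityField(vz=3.0 * vf.vz, stenosis_mask=vf.stenosis_mask, time=vf.time)
        u3 = solve_flow_potential(small_phantom, vf2, 0.05, solver=small_solver).u
        assert np.allclose(u3, 3 * u1, rtol=1e-6, atol=1e-18)

    def test_reference_electrode_gauged_to_zero(self, small_phantom, small_solver):
        vf = velocity_field(small_phantom, StenosisConfig(0.0), t=0.1)
        u = solve_flow_potential(small_phantom, vf, 0.1, solver=small_solver)
        assert u.u.ravel()[small_phantom.electrodes[0]] == 0.0

    def test_manufactured_solution_second_order_convergence(self, uniform_phantom_factory):
        # u*(x,y) = cos(pi x) cos(pi y) on the unit square satisfies the
        # zero-flux boundary condition; feed the matching source and check
        # the max-norm error decays ~ O(h^2)
        errs = []
        for n in (16, 32, 64):
            ph = uniform_phantom_factory(n)
            s = ConductionSolver(ph)
            X, Y = ph.grid.coords()
            ustar = np.cos(np.pi * X) * np.cos(np.pi * Y)
            f = -2 * np.pi**2 * ustar
            u = s.solve(-f.ravel() * ph.grid.cell_area).reshape(n, n)
            diff = u - ustar
            diff -= diff.mean()
            errs.append(np.abs(diff).max())
        assert errs[0] / errs[1] > 3.5
        assert errs[1] / errs[2] > 3.5

    def test_all_zero_conductivity_rejected(self, uniform_phantom_factory):
        ph = uniform_phantom_factory(16, sigma=0.0)
        with pytest.raises(ValueError, match="singular"):
            ConductionSolver(ph)


class TestElectrodeVoltages:
    def test_eleven_measuring_channels(self, small_phantom, small_solver):
        vf = velocity_field(small_phantom, StenosisConfig(0.0), t=0.1)
        u = solve_flow_potential(small_phantom, vf, 0.1, solver=small_solver)
        U = electrode_voltages(u, small_phantom)
        assert U.U.shape == (11,)

    def test_constant_potential_reads_zero(self, small_phantom):
        from emflowtomo.forward import PotentialMap

        u = PotentialMap(u=np.full(small_phantom.grid.n_cells, 3.7))
        assert np.allclose(electrode_voltages(u, small_phantom).U, 0.0)

    def test_field_reversal_negates_voltages(self, small_phantom, small_solver):
        vf = velocity_field(small_phantom, StenosisConfig(0.3, "-y"), t=0.2)
        Up = electrode_voltages(
            solve_flow_potential(small_phantom, vf, 0.1, solver=small_solver), small_phantom
        ).U
        Um = electrode_voltages(
            solve_flow_potential(small_phantom, vf, -0.1, solver=small_solver), small_phantom
        ).U
        assert np.allclose(Um, -Up, rtol=1e-10, atol=1e-18)


class TestReciprocalField:
    def test_reference_electrode_rejected(self, small_phantom, small_solver):
        with pytest.raises(ValueError, match="reference"):
            reciprocal_field(small_phantom, 0, solver=small_solver)

    def test_kirchhoff_balance_away_from_injection(self, small_phantom, small_solver):
        k = 4
        uA = small_solver.solve(small_solver.rhs_injection(k))
        div = small_solver.face_divergence(uA).ravel()
        inj = {int(small_phantom.electrodes[k]), int(small_phantom.electrodes[0])}
        mask = np.ones(div.size, dtype=bool)
        mask[list(inj)] = False
        assert np.abs(div[mask]).max() < 1e-9

    def test_unit_current_crosses_separating_contour(self, small_phantom, small_solver):
        # net current through any closed cell-boundary box around e_k must
        # be 1 A per unit depth
        ph = small_phantom
        k = 6
        uA = small_solver.solve(small_solver.rhs_injection(k))
        div = small_solver.face_divergence(uA)
        ek = int(ph.electrodes[k])
        iy, ix = divmod(ek, ph.grid.nx)
        # sum of divergences inside a box equals the net boundary current
        for half in (2, 4, 7):
            y0, y1 = max(0, iy - half), min(ph.grid.ny, iy + half + 1)
            x0, x1 = max(0, ix - half), min(ph.grid.nx, ix + half + 1)
            box = div[y0:y1, x0:x1]
            e0 = int(ph.electrodes[0])
            e0y, e0x = divmod(e0, ph.grid.nx)
            if y0 <= e0y < y1 and x0 <= e0x < x1:
                continue  # box must separate e_k from the ground electrode
            assert box.sum() == pytest.approx(1.0, abs=1e-9)

    def test_mirror_symmetric_phantom_gives_mirror_symmetric_field(self, uniform_phantom_factory):
        # electrodes placed symmetrically about the vertical mid-line
        ph = uniform_phantom_factory(33)
        n = 33
        mid = n // 2
        ph.electrodes = np.array(
            [0 * n + mid, (n - 1) * n + mid] + list(range(2, 12)), dtype=np.int64
        )
        s = ConductionSolver(ph)
        rf = reciprocal_field(ph, 1, solver=s)
        Jx, Jy = rf.J[:, :, 0], rf.J[:, :, 1]
        assert np.allclose(Jy, Jy[:, ::-1], atol=1e-9)
        assert np.allclose(Jx, -Jx[:, ::-1], atol=1e-9)


class TestWeightMatrix:
    def test_shape_matches_roi(self, small_phantom, small_solver):
        W = assemble_weight_matrix(small_phantom, solver=small_solver)
        assert W.shape == (11, small_phantom.n_units)

    def test_zero_field_gives_zero_matrix(self, small_phantom, small_solver):
        W = assemble_weight_matrix(
            small_phantom, SimulationConfig(weight_B=1e-300), solver=small_solver
        )
        assert np.allclose(W.W, 0.0)

    def test_reciprocity_consistency_with_full_pde(self, small_phantom, small_solver):
        # Wv must reproduce the PDE electrode voltages for velocity fields
        # supported on the reconstruction window (stenosis-free phantom)
        W = assemble_weight_matrix(small_phantom, solver=small_solver)
        roi_flat = small_phantom.roi_flat_indices()
        for t in (0.05, 0.12, 0.4):
            vf = velocity_field(small_phantom, StenosisConfig(0.0), t)
            U_pde = electrode_voltages(
                solve_flow_potential(small_phantom, vf, 0.1, solver=small_solver),
                small_phantom,
            ).U
            U_w = W.W @ vf.vz.ravel()[roi_flat]
            assert np.linalg.norm(U_w - U_pde) / np.linalg.norm(U_pde) <= 0.05


class TestAddNoise:
    def test_noise_scale_follows_snr_definition(self):
        rng = np.random.default_rng(0)
        U = MeasurementVector(U=rng.normal(size=20000))
        rms = np.sqrt(np.mean(U.U**2))
        noisy = add_noise(U, snr_db=20.0, rng_seed=7)
        sd = np.std(noisy.U - U.U)
        assert sd == pytest.approx(rms * 10 ** (-20 / 20), rel=0.05)

    def test_infinite_snr_is_identity(self):
        U = MeasurementVector(U=np.arange(5.0))
        assert np.array_equal(add_noise(U, np.inf, 1).U, U.U)

    def test_determinism_and_seed_sensitivity(self):
        U = MeasurementVector(U=np.ones(11))
        a = add_noise(U, 30.0, rng_seed=5).U
        b = add_noise(U, 30.0, rng_seed=5).U
        c = add_noise(U, 30.0, rng_seed=6).U
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            add_noise(MeasurementVector(U=np.zeros(11)), 20.0, 0)


class TestGenerateDataset:
    def test_degenerate_loop_count(self, coarse_phantom):
        ds = generate_dataset(
            coarse_phantom,
            SimulationConfig(B_values=(0.1,), stenosis_rates=(0.0,)),
            FlowConfig(dt=0.085),  # 11 samples: floor(0.85/0.085) + 1
        )
        assert ds.n_samples == 11

    def test_labels_have_roi_length_and_split_is_80_20(self, coarse_phantom):
        ds = generate_dataset(
            coarse_phantom,
            SimulationConfig(B_values=(0.05, 0.1), stenosis_rates=(0.0, 0.5), seed=2),
            FlowConfig(dt=0.17),
        )
        # 2 B x 3 configs (rate 0 once, rate .5 twice) x 6 times
        assert ds.n_samples == 36
        assert ds.V.shape[1] == coarse_phantom.n_units
        assert len(ds.train_idx) == round(0.8 * 36)
        both = np.sort(np.concatenate([ds.train_idx, ds.test_idx]))
        assert np.array_equal(both, np.arange(36))

    def test_bit_reproducible_for_fixed_seed(self, coarse_phantom):
        cfg = SimulationConfig(B_values=(0.1,), stenosis_rates=(0.0, 0.3), seed=9)
        flow = FlowConfig(dt=0.2)
        a = generate_dataset(coarse_phantom, cfg, flow)
        b = generate_dataset(coarse_phantom, cfg, flow)
        assert np.array_equal(a.U, b.U)
        assert np.array_equal(a.V, b.V)
        assert np.array_equal(a.train_idx, b.train_idx)

    def test_measurements_scale_linearly_across_B_sweep(self, coarse_phantom):
        ds = generate_dataset(
            coarse_phantom,
            SimulationConfig(B_values=(0.02, 0.04), stenosis_rates=(0.0,)),
            FlowConfig(dt=0.2),
        )
        n_t = 5
        U1, U2 = ds.U[:n_t], ds.U[n_t : 2 * n_t]
        assert np.allclose(U2, 2 * U1, rtol=1e-12)

    def test_conductivity_removal_flag_changes_stenosed_samples_only(self, coarse_phantom):
        cfg_kw = dict(B_values=(0.1,), stenosis_rates=(0.0, 0.6), directions=("+x",), seed=1)
        flow = FlowConfig(dt=0.2)
        a = generate_dataset(coarse_phantom, SimulationConfig(**cfg_kw), flow)
        b = generate_dataset(
            coarse_phantom,
            SimulationConfig(**cfg_kw, stenosis_removes_conductivity=True),
            flow,
        )
        n_t = 5
        assert np.allclose(a.U[:n_t], b.U[:n_t])       # rate 0: same model
        assert not np.allclose(a.U[n_t:], b.U[n_t:])   # rate 0.6: sigma differs

    def test_roundtrip_container(self, tmp_path, coarse_phantom):
        ds = generate_dataset(
            coarse_phantom,
            SimulationConfig(B_values=(0.1,), stenosis_rates=(0.0,), seed=4),
            FlowConfig(dt=0.2),
        )
        path = tmp_path / "ds.npz"
        save_dataset(ds, path)
        back = load_dataset(path)
        assert np.array_equal(back.U, ds.U)
        assert np.array_equal(back.V, ds.V)
        assert np.array_equal(back.W.W, ds.W.W)
        assert back.config["seed"] == 4
        assert back.meta[0]["B"] == 0.1
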