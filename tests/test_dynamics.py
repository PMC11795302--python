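import warnings

import numpy as np
import pytest

import actinshape.dynamics as dyn
from actinshape.dynamics import (FIBER_DT, MONOMER_BEAD_RADIUS,
                                 CompressionProtocol, SimulationBlowupError,
                                 ThermalModel, simulate_compression,
                                 simulate_free, step_overdamped, stokes_drag)
from actinshape.forcefield import (ForceField, build_fiber_chain,
                                   build_monomer_chain, compute_forces)
from actinshape.frames import FilamentFrame
from actinshape.geometry import HelixGeometry


def free_particles_ff(n):
    """Force field with no bonded terms (free Brownian particles)."""
    return ForceField(
        n_particles=n, neighbor_orders=(1,),
        bond_idx=np.empty((0, 2)), bond_k=[], bond_r0=[],
        angle_idx=np.empty((0, 3)), angle_k=[], angle_theta0=[],
        dihedral_idx=np.empty((0, 4)), dihedral_k=[], dihedral_phi0=[])


class TestProtocolArithmetic:
    @pytest.mark.parametrize("velocity, expected_um", [
        (15.0, 7.5e-5), (150.0, 7.5e-4)])
    def test_per_cycle_displacement_matches_printed_values(self, velocity,
                                                           expected_um):
        prot = CompressionProtocol(velocity=velocity, timestep=5e-7)
        assert prot.displacement_per_cycle * 1e-3 == pytest.approx(
            expected_um, rel=1e-12)

    def test_cycle_structure(self):
        prot = CompressionProtocol()
        assert prot.cycle_steps == 10
        assert prot.target_end_to_end == pytest.approx(350.0)

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            CompressionProtocol(compression_fraction=1.2)
        with pytest.raises(ValueError):
            CompressionProtocol(timestep=-1.0)


class TestStepOverdamped:
    def test_zero_temperature_zero_force_is_identity(self, straight_rod):
        th = ThermalModel(kT=0.0, drag_per_particle=1.0, seed=0)
        out = step_overdamped(straight_rod, np.zeros((50, 3)), th, 1e-6)
        assert np.array_equal(out.points, straight_rod.points)

    def test_deterministic_drift_is_f_dt_over_gamma(self, straight_rod):
        gamma = stokes_drag(2.0)
        th = ThermalModel(kT=0.0, drag_per_particle=gamma, seed=0)
        forces = np.zeros((50, 3))
        forces[7] = [0.0, 3.0, -1.0]
        out = step_overdamped(straight_rod, forces, th, 1e-6)
        disp = out.points - straight_rod.points
        assert np.allclose(disp[7], np.array([0.0, 3.0, -1.0]) * 1e-6 / gamma)
        disp[7] = 0
        assert np.allclose(disp, 0.0)

    def test_fixed_particles_do_not_move(self, straight_rod):
        th = ThermalModel(kT=4.1, drag_per_particle=1e-8, seed=3)
        out = step_overdamped(straight_rod, np.zeros((50, 3)), th, 1e-9,
                              fixed=[0, 49])
        assert np.array_equal(out.points[[0, 49]],
                              straight_rod.points[[0, 49]])
        assert not np.allclose(out.points[1:49], straight_rod.points[1:49])


class TestFreeDiffusion:
    def test_msd_matches_2_kT_t_over_gamma(self):
        """Free particles diffuse with per-coordinate MSD = 2 (kT/gamma) t."""
        n = 30
        pts = np.zeros((n, 3))
        pts[:, 0] = np.arange(n) * 10.0
        frame = FilamentFrame(pts)
        ff = free_particles_ff(n)
        gamma = stokes_drag(2.0)
        kT = 4.1
        th = ThermalModel(kT=kT, drag_per_particle=gamma, seed=42)
        n_steps, dt = 4000, 1e-9
        traj = simulate_free(frame, ff, th, dt=dt, n_steps=n_steps,
                             n_frames_out=2)
        t = n_steps * dt
        sq = (traj.frames[-1].points - pts) ** 2     # (n, 3) samples
        expected = 2.0 * kT / gamma * t
        se = expected * np.sqrt(2.0 / sq.size)       # var(chi2_1) = 2
        assert sq.mean() == pytest.approx(expected, abs=3 * se)


class TestCompression:
    def test_fiber_reaches_target_at_zero_temperature(self):
        frame, ff = build_fiber_chain(50)
        prot = CompressionProtocol(velocity=150.0, initial_end_to_end=500.0)
        th = ThermalModel(kT=0.0, drag_per_particle=stokes_drag(5.0), seed=1)
        traj = simulate_compression(frame, ff, prot, th, n_frames_out=20)
        final = traj.frames[-1].end_to_end
        assert traj.metadata["stopped_on_target"]
        # within one per-cycle displacement of the 350 nm target
        assert 350.0 - prot.displacement_per_cycle <= final <= 350.0

    def test_zero_temperature_compression_rate_matches_velocity(self):
        """x-projected end-to-end decreases at the protocol velocity.

        Stiff anchors are used so the bead-to-anchor lag (force/stiffness)
        is negligible against the per-cycle displacement.
        """
        frame, ff = build_fiber_chain(50)
        prot = CompressionProtocol(velocity=150.0, initial_end_to_end=500.0,
                                   anchor_stiffness=1e4)
        th = ThermalModel(kT=0.0, drag_per_particle=stokes_drag(5.0), seed=1)
        traj = simulate_compression(frame, ff, prot, th, n_frames_out=40)
        e2e_x = np.array([f.points[-1, 0] - f.points[0, 0]
                          for f in traj.frames])
        # discard the initial transient while the anchor lag builds up
        sel = slice(10, 30)
        rates = -np.diff(e2e_x[sel]) / np.diff(traj.times[sel])  # nm/s
        assert np.mean(rates) == pytest.approx(150.0 * 1e3, rel=0.05)

    def test_velocity_zero_zero_temperature_keeps_frames_identical(self):
        frame, ff = build_fiber_chain(10)
        prot = CompressionProtocol(velocity=0.0, initial_end_to_end=100.0)
        th = ThermalModel(kT=0.0, drag_per_particle=stokes_drag(5.0), seed=1)
        traj = simulate_compression(frame, ff, prot, th, n_frames_out=5,
                                    max_cycles=50)
        for f in traj.frames[1:]:
            assert np.allclose(f.points, traj.frames[0].points, atol=1e-12)

    def test_excessive_displacement_warns(self):
        frame, ff = build_fiber_chain(10)
        prot = CompressionProtocol(velocity=5e6, initial_end_to_end=100.0)
        th = ThermalModel(kT=0.0, drag_per_particle=stokes_drag(5.0), seed=1)
        with pytest.warns(RuntimeWarning, match="displacement"):
            simulate_compression(frame, ff, prot, th, n_frames_out=3)

    def test_monomer_blowup_raises_with_step_index(self):
        frame, ff = build_monomer_chain(HelixGeometry.for_length(50.0))
        th = ThermalModel(kT=4.1,
                          drag_per_particle=stokes_drag(MONOMER_BEAD_RADIUS),
                          seed=2)
        with pytest.raises(SimulationBlowupError) as err:
            simulate_free(frame, ff, th, dt=1e-8, n_steps=50_000,
                          n_frames_out=3)
        assert err.value.step > 0

    def test_determinism_same_seed_bitwise_identical(self):
        frame, ff = build_monomer_chain(HelixGeometry.for_length(60.0))
        e2e0 = float(frame.points[-1, 0] - frame.points[0, 0])
        prot = CompressionProtocol(
            velocity=2000.0, timestep=2.5e-11, initial_end_to_end=e2e0,
            fixed_end_particles=3, moved_end_particles=3)
        th = ThermalModel(drag_per_particle=stokes_drag(MONOMER_BEAD_RADIUS),
                          seed=77)
        t1 = simulate_compression(frame, ff, prot, th, n_frames_out=10)
        t2 = simulate_compression(frame, ff, prot, th, n_frames_out=10)
        assert t1.n_frames == t2.n_frames
        for a, b in zip(t1.frames, t2.frames):
            assert np.array_equal(a.points, b.points)

    def test_different_seeds_differ(self):
        frame, ff = build_fiber_chain(20)
        prot = CompressionProtocol(velocity=150.0, initial_end_to_end=200.0)
        t1 = simulate_compression(frame, ff, prot,
                                  ThermalModel(seed=1), n_frames_out=5)
        t2 = simulate_compression(frame, ff, prot,
                                  ThermalModel(seed=2), n_frames_out=5)
        assert not np.allclose(t1.frames[-1].points, t2.frames[-1].points)


class TestKernelConsistency:
    """The compiled kernels must reproduce the NumPy reference dynamics."""

    def test_chain_and_generic_kernels_agree(self, monomer_chain, rng):
        frame, ff = monomer_chain
        pts = frame.points + rng.normal(scale=0.3, size=frame.points.shape)
        perturbed = frame.with_points(pts)
        th = ThermalModel(kT=0.0,
                          drag_per_particle=stokes_drag(MONOMER_BEAD_RADIUS),
                          seed=5)
        fast = simulate_free(perturbed, ff, th, dt=1e-12, n_steps=500,
                             n_frames_out=4)
        orig = dyn._chain_class_constants
        dyn._chain_class_constants = lambda ff: None
        try:
            generic = simulate_free(perturbed, ff, th, dt=1e-12, n_steps=500,
                                    n_frames_out=4)
        finally:
            dyn._chain_class_constants = orig
        for a, b in zip(fast.frames, generic.frames):
            assert np.allclose(a.points, b.points, atol=1e-12)

    def test_kernel_single_step_matches_reference_integrator(
            self, monomer_chain, rng):
        frame, ff = monomer_chain
        pts = frame.points + rng.normal(scale=0.2, size=frame.points.shape)
        perturbed = frame.with_points(pts)
        th = ThermalModel(kT=0.0,
                          drag_per_particle=stokes_drag(MONOMER_BEAD_RADIUS),
                          seed=5)
        dt = 1e-12
        kernel = simulate_free(perturbed, ff, th, dt=dt, n_steps=1,
                               n_frames_out=1)
        reference = step_overdamped(perturbed, compute_forces(perturbed, ff),
                                    th, dt)
        assert np.allclose(kernel.frames[-1].points, reference.points,
                           atol=1e-10)
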