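import copy

import numpy as np
import pytest

from actinshape.forcefield import (ForceField, build_fiber_chain,
                                   build_monomer_chain, compute_forces,
                                   derive_topology_targets, measure_angles,
                                   measure_dihedrals, total_energy)
from actinshape.frames import FilamentFrame
from actinshape.geometry import HelixGeometry, build_ideal_helix


def numerical_forces(pts, ff, h=1e-6):
    out = np.zeros_like(pts)
    for i in range(pts.shape[0]):
        for c in range(3):
            p = pts.copy()
            p[i, c] += h
            ep = total_energy(p, ff)
            p[i, c] -= 2 * h
            em = total_energy(p, ff)
            out[i, c] = -(ep - em) / (2 * h)
    return out


class TestTopologyTargets:
    def test_straight_chain_angles_pi_dihedrals_flagged(self):
        pts = np.zeros((8, 3))
        pts[:, 0] = np.arange(8) * 3.0
        targets = derive_topology_targets(FilamentFrame(pts), (1, 2))
        assert targets["angle_theta0"][1] == pytest.approx(np.pi)
        assert targets["angle_theta0"][2] == pytest.approx(np.pi)
        assert targets["dihedral_defined"] is False
        assert targets["dihedral_phi0"] is None

    def test_helix_targets_uniform_by_screw_symmetry(self):
        ideal = build_ideal_helix(HelixGeometry(n_subunits=30))
        # every order-1 bond, angle and dihedral is identical along the chain
        from actinshape.forcefield import chain_term_indices, measure_bonds
        b, a, d = chain_term_indices(30, (1,), True)
        assert np.ptp(measure_bonds(ideal.points, b)) < 1e-9
        assert np.ptp(measure_angles(ideal.points, a)) < 1e-9
        assert np.ptp(measure_dihedrals(ideal.points, d)) < 1e-9

    def test_too_short_chain_rejected(self):
        pts = np.zeros((3, 3))
        pts[:, 0] = [0, 1, 2]
        with pytest.raises(ValueError):
            derive_topology_targets(FilamentFrame(pts))


class TestForces:
    def test_ideal_structures_are_zero_force(self, monomer_chain,
                                             fiber_chain):
        for frame, ff in (monomer_chain, fiber_chain):
            F = compute_forces(frame, ff)
            assert np.abs(F).max() < 1e-6  # pN

    def test_single_stretched_bond_follows_hooke(self):
        ff = ForceField(
            n_particles=3, neighbor_orders=(1,),
            bond_idx=[[0, 1], [1, 2]], bond_k=[100.0, 100.0],
            bond_r0=[1.0, 1.0],
            angle_idx=np.empty((0, 3)), angle_k=[], angle_theta0=[],
            dihedral_idx=np.empty((0, 4)), dihedral_k=[], dihedral_phi0=[])
        pts = np.array([[0.0, 0, 0], [1.2, 0, 0], [2.2, 0, 0]])
        F = compute_forces(pts, ff)
        assert F[0, 0] == pytest.approx(100.0 * 0.2)
        assert F[1, 0] == pytest.approx(-100.0 * 0.2)
        assert F[2, 0] == pytest.approx(0.0)

    @pytest.mark.parametrize("chain", ["monomer", "fiber"])
    def test_forces_match_numerical_gradient(self, chain, monomer_chain,
                                             fiber_chain, rng):
        frame, ff = monomer_chain if chain == "monomer" else fiber_chain
        pts = frame.points + rng.normal(scale=0.3, size=frame.points.shape)
        F = compute_forces(pts, ff)
        Fn = numerical_forces(pts, ff)
        assert np.abs(F - Fn).max() / np.abs(F).max() < 1e-6

    def test_internal_forces_have_zero_net_force_and_torque(
            self, monomer_chain, rng):
        frame, ff = monomer_chain
        pts = frame.points + rng.normal(scale=0.5, size=frame.points.shape)
        F = compute_forces(pts, ff)
        assert np.abs(F.sum(axis=0)).max() < 1e-8
        assert np.abs(np.cross(pts, F).sum(axis=0)).max() < 1e-6

    def test_coincident_points_error_names_particle(self, monomer_chain):
        frame, ff = monomer_chain
        pts = frame.points.copy()
        pts[5] = pts[6]
        with pytest.raises(ValueError, match="5"):
            compute_forces(pts, ff)

    def test_dihedral_minimum_at_phi0(self):
        """Cosine dihedral energy is zero (minimal) at the target angle."""
        frame, ff = build_monomer_chain(HelixGeometry(n_subunits=8))
        only_dih = copy.copy(ff)
        only_dih.bond_k = np.zeros_like(ff.bond_k)
        only_dih.angle_k = np.zeros_like(ff.angle_k)
        e0 = total_energy(frame, only_dih)
        assert e0 == pytest.approx(0.0, abs=1e-9)


class TestChainBuilders:
    def test_fiber_chain_contour_and_flags(self):
        frame, ff = build_fiber_chain(n_segments=50, segment_length=10.0)
        assert frame.contour_length == pytest.approx(500.0)
        assert not ff.chiral
        assert ff.bend_model == "curvature"
        # k_angle = kappa / segment_length
        assert ff.angle_k[0] == pytest.approx(ff.bend_rigidity / 10.0)

    def test_monomer_chain_is_chiral(self, monomer_chain):
        _, ff = monomer_chain
        assert ff.chiral
        assert ff.neighbor_orders == (1, 2)

    def test_fiber_chain_too_short_rejected(self):
        with pytest.raises(ValueError):
            build_fiber_chain(n_segments=2)

    def test_mirrored_helix_has_opposite_dihedral_target(self):
        right = build_ideal_helix(HelixGeometry(twist_per_subunit=166.7,
                                                n_subunits=12))
        left = build_ideal_helix(HelixGeometry(twist_per_subunit=-166.7,
                                               n_subunits=12))
        tr = derive_topology_targets(right)
        tl = derive_topology_targets(left)
        assert tr["dihedral_phi0"] == pytest.approx(-tl["dihedral_phi0"])
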