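"""Bonded force fields for the two filament resolutions.

Monomer scale (chiral): harmonic bonds and harmonic angles between each bead
and each of its two neighbours in each chain direction, plus cosine dihedrals
on every four consecutive beads. Equilibrium targets are measured from the
ideal helix, so the ideal structure is a zero-force configuration and the
dihedral terms encode its chirality.

Fiber scale (achiral): harmonic stretching between consecutive beads and a
quadratic curvature (second-difference) bending energy

    U_bend = kappa / (2 l^3) * sum_i |p_{i-1} - 2 p_i + p_{i+1}|^2,

which is the standard discretisation of worm-like-chain bending with rigidity
kappa and is equivalent to a harmonic angle constant k_angle = kappa / l near
the straight state. It carries no dihedral terms and no chirality.

Units: nm, pN, pN*nm (energy), angles in radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frames import FilamentFrame
from .geometry import HelixGeometry, build_ideal_helix

#: Thermal energy at room temperature, pN*nm.
KT_ROOM = 4.1

#: Calibrated monomer-scale defaults (see scripts/calibrate_forcefield.py and
#: docs/methods.md): chosen so the relaxed chiral chain's persistence length
#: lands in the 10-25 um range at kT = 4.1 pN*nm (measured: ~12 um) while
#: remaining stable at the default 2.5e-11 s timestep.
MONOMER_BOND_K = {1: 250.0, 2: 250.0}          # pN/nm
MONOMER_ANGLE_K = {1: 2000.0, 2: 7000.0}       # pN*nm/rad^2
MONOMER_DIHEDRAL_K = 7000.0                    # pN*nm


@dataclass
class ForceField:
    """Bonded-interaction constants and equilibrium targets for one chain.

    Term index arrays are explicit so the same container drives both the
    reference NumPy force routine and the compiled integrator kernel.
    """

    n_particles: int
    neighbor_orders: tuple[int, ...]
    bond_idx: np.ndarray        # (nb, 2) int
    bond_k: np.ndarray          # (nb,) pN/nm
    bond_r0: np.ndarray         # (nb,) nm
    angle_idx: np.ndarray       # (na, 3) int
    angle_k: np.ndarray         # (na,) pN*nm/rad^2
    angle_theta0: np.ndarray    # (na,) rad
    dihedral_idx: np.ndarray    # (nd, 4) int
    dihedral_k: np.ndarray      # (nd,) pN*nm
    dihedral_phi0: np.ndarray   # (nd,) rad
    bend_model: str = "harmonic"       # "harmonic" (angles) | "curvature"
    bend_rigidity: float = 0.0         # kappa, pN*nm^2 (curvature model)
    segment_length: float = 0.0        # nm (curvature model)
    class_constants: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("bond_idx", "angle_idx", "dihedral_idx"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        for name in ("bond_k", "bond_r0", "angle_k", "angle_theta0",
                     "dihedral_k", "dihedral_phi0"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if np.any(self.bond_k < 0) or np.any(self.angle_k < 0) or \
                np.any(self.dihedral_k < 0):
            raise ValueError("stiffnesses must be >= 0")
        for arr in (self.bond_r0, self.angle_theta0, self.dihedral_phi0):
            if not np.all(np.isfinite(arr)):
                raise ValueError("equilibrium targets must be finite")
        if self.bend_model not in ("harmonic", "curvature"):
            raise ValueError(f"unknown bend_model {self.bend_model!r}")

    @property
    def chiral(self) -> bool:
        """True iff dihedral terms are present."""
        return self.dihedral_idx.shape[0] > 0


# ---------------------------------------------------------------------------
# geometry measurements (shared by target derivation and force routines)
# ---------------------------------------------------------------------------

def bond_vectors(points: np.ndarray, idx: np.ndarray) -> np.ndarray:
    return points[idx[:, 1]] - points[idx[:, 0]]


def measure_bonds(points: np.ndarray, idx: np.ndarray) -> np.ndarray:
    return np.linalg.norm(bond_vectors(points, idx), axis=1)


def measure_angles(points: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Interior angle at the middle particle of each (a, b, c) triplet."""
    u = points[idx[:, 0]] - points[idx[:, 1]]
    v = points[idx[:, 2]] - points[idx[:, 1]]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cosang = np.einsum("ij,ij->i", u, v) / (nu * nv)
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def measure_dihedrals(points: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Signed dihedral angle of each (a, b, c, d) quadruplet, in (-pi, pi].

    Sign convention: phi = atan2((n1 x n2) . b2_hat, n1 . n2) with
    b1 = b - a, b2 = c - b, b3 = d - c, n1 = b1 x b2, n2 = b2 x b3.
    """
    a, b, c, d = (points[idx[:, k]] for k in range(4))
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / np.where(b2n > 0, b2n, 1.0)
    x = np.einsum("ij,ij->i", n1, n2)
    return np.arctan2(y, x)


def chain_term_indices(n: int, orders: tuple[int, ...], with_dihedrals: bool
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index arrays for a linear chain of n beads.

    Bonds (i, i+o) and angles (i, i+o, i+2o) for each neighbour order o;
    dihedrals (i, i+1, i+2, i+3) on consecutive beads only.
    """
    bonds, angles = [], []
    for o in sorted(orders):
        for i in range(n - o):
            bonds.append((i, i + o, o))
        for i in range(n - 2 * o):
            angles.append((i, i + o, i + 2 * o, o))
    dihedrals = [(i, i + 1, i + 2, i + 3) for i in range(n - 3)] if with_dihedrals else []
    return (np.array([b[:2] for b in bonds], dtype=np.int64).reshape(-1, 2),
            np.array([a[:3] for a in angles], dtype=np.int64).reshape(-1, 3),
            np.array(dihedrals, dtype=np.int64).reshape(-1, 4))


def derive_topology_targets(ideal: FilamentFrame,
                            neighbor_orders: tuple[int, ...] = (1, 2),
                            with_dihedrals: bool = True,
                            collinear_tol: float = 1e-9) -> dict:
    """Measure equilibrium bond/angle/dihedral targets from an ideal chain.

    Returns a dict with per-class targets keyed by neighbour order (bonds,
    angles) plus the dihedral target. For a collinear input all angles are
    pi and dihedrals are undefined: they are flagged (``dihedral_defined``
    False) rather than assigned a value.
    """
    n = ideal.n_points
    if n < 4:
        raise ValueError("need at least 4 points to derive dihedral targets")
    if n < 2 * max(neighbor_orders) + 1:
        raise ValueError("chain too short for the requested neighbour orders")
    pts = ideal.points
    out: dict = {"bond_r0": {}, "angle_theta0": {}, "neighbor_orders":
                 tuple(sorted(neighbor_orders))}
    for o in sorted(neighbor_orders):
        b_idx, a_idx, _ = chain_term_indices(n, (o,), False)
        out["bond_r0"][o] = float(measure_bonds(pts, b_idx).mean())
        out["angle_theta0"][o] = float(measure_angles(pts, a_idx).mean())
    if with_dihedrals:
        _, _, d_idx = chain_term_indices(n, (1,), True)
        b1 = pts[d_idx[:, 1]] - pts[d_idx[:, 0]]
        b2 = pts[d_idx[:, 2]] - pts[d_idx[:, 1]]
        cross = np.linalg.norm(np.cross(b1, b2), axis=1)
        if np.all(cross < collinear_tol * np.linalg.norm(b1, axis=1) ** 2):
            out["dihedral_defined"] = False
            out["dihedral_phi0"] = None
        else:
            phi = measure_dihedrals(pts, d_idx)
            # circular mean guards against wrap at +/-pi
            out["dihedral_defined"] = True
            out["dihedral_phi0"] = float(np.arctan2(np.sin(phi).mean(),
                                                    np.cos(phi).mean()))
    else:
        out["dihedral_defined"] = False
        out["dihedral_phi0"] = None
    return out


# ---------------------------------------------------------------------------
# chain builders
# ---------------------------------------------------------------------------

def build_monomer_chain(geometry: HelixGeometry | None = None,
                        bond_k: dict[int, float] | None = None,
                        angle_k: dict[int, float] | None = None,
                        dihedral_k: float = MONOMER_DIHEDRAL_K,
                        ) -> tuple[FilamentFrame, ForceField]:
    """Chiral monomer-scale chain: ideal helix plus its zero-force field.

    Equilibrium targets are measured from the ideal helix so the helix is a
    minimum of the total bonded energy; the cosine dihedrals make the field
    chiral (they remember the helix handedness).
    """
    geometry = geometry or HelixGeometry()
    bond_k = dict(bond_k or MONOMER_BOND_K)
    angle_k = dict(angle_k or MONOMER_ANGLE_K)
    orders = tuple(sorted(bond_k))
    ideal = build_ideal_helix(geometry)
    targets = derive_topology_targets(ideal, orders, with_dihedrals=True)
    n = ideal.n_points
    b_idx, a_idx, d_idx = chain_term_indices(n, orders, targets["dihedral_defined"])
    bond_k_arr, bond_r0 = [], []
    for o in orders:
        m = n - o
        bond_k_arr += [bond_k[o]] * m
        bond_r0 += [targets["bond_r0"][o]] * m
    angle_k_arr, angle_t0 = [], []
    for o in orders:
        m = n - 2 * o
        angle_k_arr += [angle_k[o]] * m
        angle_t0 += [targets["angle_theta0"][o]] * m
    nd = d_idx.shape[0]
    ff = ForceField(
        n_particles=n, neighbor_orders=orders,
        bond_idx=b_idx, bond_k=bond_k_arr, bond_r0=bond_r0,
        angle_idx=a_idx, angle_k=angle_k_arr, angle_theta0=angle_t0,
        dihedral_idx=d_idx, dihedral_k=[dihedral_k] * nd,
        dihedral_phi0=[targets["dihedral_phi0"]] * nd,
        bend_model="harmonic",
        class_constants={"bond_k": bond_k, "angle_k": angle_k,
                         "dihedral_k": dihedral_k,
                         "geometry": geometry},
    )
    return ideal, ff


#: Fiber-scale defaults: actin bending rigidity kappa = 0.075 pN*um^2
#: (Lp = kappa/kT ~ 18 um at kT = 4.1 pN*nm), 10 nm segments.
FIBER_SEGMENT_NM = 10.0
FIBER_BEND_RIGIDITY = 7.5e4   # pN*nm^2
FIBER_STRETCH_K = 100.0       # pN/nm


def build_fiber_chain(n_segments: int = 50,
                      segment_length: float = FIBER_SEGMENT_NM,
                      bend_rigidity: float = FIBER_BEND_RIGIDITY,
                      stretch_k: float = FIBER_STRETCH_K,
                      ) -> tuple[FilamentFrame, ForceField]:
    """Achiral fiber-scale chain: straight rod along +x.

    Bending uses the curvature model with rigidity ``bend_rigidity``
    (equivalently k_angle = kappa / segment_length); no dihedrals, so the
    chain has no preferred handedness.
    """
    if n_segments < 3:
        raise ValueError("n_segments must be >= 3")
    n = n_segments + 1
    pts = np.zeros((n, 3))
    pts[:, 0] = np.arange(n) * segment_length
    frame = FilamentFrame(pts, metadata={"kind": "fiber_chain"})
    b_idx, a_idx, _ = chain_term_indices(n, (1,), False)
    k_angle = bend_rigidity / segment_length
    ff = ForceField(
        n_particles=n, neighbor_orders=(1,),
        bond_idx=b_idx, bond_k=[stretch_k] * b_idx.shape[0],
        bond_r0=[segment_length] * b_idx.shape[0],
        angle_idx=a_idx, angle_k=[k_angle] * a_idx.shape[0],
        angle_theta0=[np.pi] * a_idx.shape[0],
        dihedral_idx=np.empty((0, 4)), dihedral_k=[], dihedral_phi0=[],
        bend_model="curvature", bend_rigidity=bend_rigidity,
        segment_length=segment_length,
        class_constants={"stretch_k": stretch_k,
                         "bend_rigidity": bend_rigidity,
                         "segment_length": segment_length},
    )
    return frame, ff


# ---------------------------------------------------------------------------
# energies and forces (reference NumPy implementation)
# ---------------------------------------------------------------------------

def total_energy(frame: FilamentFrame | np.ndarray, ff: ForceField) -> float:
    """Total bonded energy, pN*nm."""
    pts = frame.points if isinstance(frame, FilamentFrame) else np.asarray(frame)
    e = 0.0
    if ff.bond_idx.size:
        r = measure_bonds(pts, ff.bond_idx)
        e += 0.5 * np.sum(ff.bond_k * (r - ff.bond_r0) ** 2)
    if ff.bend_model == "harmonic":
        if ff.angle_idx.size:
            th = measure_angles(pts, ff.angle_idx)
            e += 0.5 * np.sum(ff.angle_k * (th - ff.angle_theta0) ** 2)
    else:
        e += _curvature_energy(pts, ff)
    if ff.dihedral_idx.size:
        phi = measure_dihedrals(pts, ff.dihedral_idx)
        # U = k (1 + cos(phi - phi0 - pi)) = k (1 - cos(phi - phi0));
        # minimum (U = 0) at phi = phi0
        e += np.sum(ff.dihedral_k * (1.0 - np.cos(phi - ff.dihedral_phi0)))
    return float(e)


def _curvature_energy(pts: np.ndarray, ff: ForceField) -> float:
    c = ff.bend_rigidity / (2.0 * ff.segment_length ** 3)
    d2 = pts[:-2] - 2.0 * pts[1:-1] + pts[2:]
    return float(c * np.sum(d2 * d2))


def compute_forces(frame: FilamentFrame | np.ndarray, ff: ForceField
                   ) -> np.ndarray:
    """Per-particle forces (pN), the exact negative gradient of the energy.

    Raises if consecutive bonded particles coincide (degenerate geometry),
    naming the particle index.
    """
    pts = frame.points if isinstance(frame, FilamentFrame) else np.asarray(frame)
    n = pts.shape[0]
    if n != ff.n_particles:
        raise ValueError(f"frame has {n} points, force field expects "
                         f"{ff.n_particles}")
    forces = np.zeros_like(pts)

    if ff.bond_idx.size:
        vec = bond_vectors(pts, ff.bond_idx)
        r = np.linalg.norm(vec, axis=1)
        if np.any(r == 0.0):
            bad = int(ff.bond_idx[np.argmin(r), 0])
            raise ValueError(f"degenerate geometry: particles at index {bad} "
                             "coincide with a bonded neighbour")
        f = (ff.bond_k * (r - ff.bond_r0) / r)[:, None] * vec
        np.add.at(forces, ff.bond_idx[:, 0], f)
        np.add.at(forces, ff.bond_idx[:, 1], -f)

    if ff.bend_model == "harmonic":
        if ff.angle_idx.size:
            _add_angle_forces(pts, ff, forces)
    else:
        _add_curvature_forces(pts, ff, forces)

    if ff.dihedral_idx.size:
        _add_dihedral_forces(pts, ff, forces)
    return forces


def _add_angle_forces(pts: np.ndarray, ff: ForceField, forces: np.ndarray
                      ) -> None:
    ia, ib, ic = ff.angle_idx[:, 0], ff.angle_idx[:, 1], ff.angle_idx[:, 2]
    u = pts[ia] - pts[ib]
    v = pts[ic] - pts[ib]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    cosang = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
    theta = np.arccos(cosang)
    sin = np.sqrt(np.maximum(1.0 - cosang * cosang, 1e-16))
    coeff = -ff.angle_k * (theta - ff.angle_theta0)   # -dU/dtheta
    # dtheta/da = (cos * u_hat - v_hat) / (|u| sin); symmetric for c
    ga = (cosang[:, None] * uh - vh) / (nu * sin)[:, None]
    gc = (cosang[:, None] * vh - uh) / (nv * sin)[:, None]
    fa = coeff[:, None] * ga
    fc = coeff[:, None] * gc
    np.add.at(forces, ia, fa)
    np.add.at(forces, ic, fc)
    np.add.at(forces, ib, -(fa + fc))


def _add_curvature_forces(pts: np.ndarray, ff: ForceField, forces: np.ndarray
                          ) -> None:
    c = ff.bend_rigidity / ff.segment_length ** 3
    d2 = pts[:-2] - 2.0 * pts[1:-1] + pts[2:]
    g = c * d2                        # dU/d(d2_i)
    forces[:-2] -= g
    forces[1:-1] += 2.0 * g
    forces[2:] -= g


def _add_dihedral_forces(pts: np.ndarray, ff: ForceField, forces: np.ndarray
                         ) -> None:
    ia, ib, ic, idd = (ff.dihedral_idx[:, k] for k in range(4))
    b1 = pts[ib] - pts[ia]
    b2 = pts[ic] - pts[ib]
    b3 = pts[idd] - pts[ic]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    b2n = np.linalg.norm(b2, axis=1)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / b2n
    x = np.einsum("ij,ij->i", n1, n2)
    phi = np.arctan2(y, x)
    dU = ff.dihedral_k * np.sin(phi - ff.dihedral_phi0)   # dU/dphi
    # standard analytic gradient of the torsion angle
    dphi_da = (-b2n / n1sq)[:, None] * n1
    dphi_dd = (b2n / n2sq)[:, None] * n2
    s12 = (np.einsum("ij,ij->i", b1, b2) / b2n ** 2)[:, None]
    s32 = (np.einsum("ij,ij->i", b3, b2) / b2n ** 2)[:, None]
    dphi_db = -(1.0 + s12) * dphi_da + s32 * dphi_dd
    dphi_dc = s12 * dphi_da - (1.0 + s32) * dphi_dd
    np.add.at(forces, ia, -dU[:, None] * dphi_da)
    np.add.at(forces, ib, -dU[:, None] * dphi_db)
    np.add.at(forces, ic, -dU[:, None] * dphi_dc)
    np.add.at(forces, idd, -dU[:, None] * dphi_dd)
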