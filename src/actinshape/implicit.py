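"""Semi-implicit integrator for the fiber-scale chain.

At the fiber timestep of 5e-7 s, an explicit overdamped update is
unconditionally unstable for actin-like bending rigidity (the stiffest
bending mode has k_max ~ 16*kappa/l^3 ~ 1e3 pN/nm, while explicit stability
requires k_max < 2*gamma/dt ~ 0.4 pN/nm). Fiber-scale engines in this field
solve the same problem with implicit integration of the elastic forces; we
do the same: one backward-Euler step per update, with the force linearized
about the current configuration,

    (gamma/dt * I + K_bend + J_stretch(x)) dx = F(x) + xi,

where K_bend is the (exactly linear, constant) curvature stiffness matrix,
J_stretch is the analytic Jacobian of the harmonic springs and xi is the
Brownian force with std sqrt(2 kT gamma / dt) per coordinate. The system is
banded (coupling range two particles), so each step is one
``scipy.linalg.solve_banded`` call.

Anchoring follows the source protocol: the end beads are tethered by
harmonic springs to anchor points, and the moved end's anchor points are
translated kinematically once per cycle, so the filament relaxes against
its linkers and the ends can pivot. The anchor springs are linear, so they
join the constant part of the banded matrix.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_banded

from .forcefield import ForceField, compute_forces

_BW = 6  # dof bandwidth: particle coupling range 2 -> |3*di + dc| <= 6


class _ImplicitWorkspace:
    """Precomputed constant parts of the banded system for one force field."""

    def __init__(self, ff: ForceField, gamma: float, dt: float,
                 anchor_idx=None, anchor_k: float = 0.0):
        if ff.bend_model != "curvature":
            raise ValueError("implicit integrator requires the curvature "
                             "bending model")
        self.ff = ff
        n = ff.n_particles
        self.n = n
        ndof = 3 * n
        # constant banded part: gamma/dt on the diagonal + bending stiffness
        c = ff.bend_rigidity / ff.segment_length ** 3
        D2 = np.zeros((n - 2, n))
        rows = np.arange(n - 2)
        D2[rows, rows] = 1.0
        D2[rows, rows + 1] = -2.0
        D2[rows, rows + 2] = 1.0
        K = c * (D2.T @ D2)          # per-coordinate bending stiffness
        ab = np.zeros((2 * _BW + 1, ndof))
        ab[_BW, :] = gamma / dt
        if anchor_idx is not None and anchor_k > 0.0:
            for i in np.asarray(anchor_idx, dtype=np.int64):
                ab[_BW, 3 * i:3 * i + 3] += anchor_k
        # banded fill of A[3i+c, 3j+c] = K[i, j]
        ii, jj = np.nonzero(K)
        for coord in range(3):
            r = 3 * ii + coord
            s = 3 * jj + coord
            ab[_BW + r - s, s] += K[ii, jj]
        self.ab_const = ab
        # scatter indices for the 3x3 stretch-Jacobian blocks of each bond
        bi = ff.bond_idx[:, 0]
        bj = ff.bond_idx[:, 1]
        nb = bi.size
        a = np.arange(3)
        ar, ac = np.meshgrid(a, a, indexing="ij")       # block-local (row, col)
        rows_l, cols_l, signs_l, blocks = [], [], [], []
        for (p, q, sign) in ((bi, bi, 1.0), (bj, bj, 1.0),
                             (bi, bj, -1.0), (bj, bi, -1.0)):
            r = (3 * p)[:, None, None] + ar[None, :, :]
            s = (3 * q)[:, None, None] + ac[None, :, :]
            rows_l.append(r)
            cols_l.append(s)
            signs_l.append(np.full((nb, 3, 3), sign))
        rows_ = np.concatenate(rows_l).reshape(-1)
        cols_ = np.concatenate(cols_l).reshape(-1)
        self._band_rows = _BW + rows_ - cols_
        self._cols = cols_
        self._signs = np.concatenate(signs_l)
        self._nb = nb

    def assemble(self, pos: np.ndarray) -> np.ndarray:
        """Banded matrix gamma/dt*I + K_bend + J_stretch(pos)."""
        ff = self.ff
        ab = self.ab_const.copy()
        vec = pos[ff.bond_idx[:, 1]] - pos[ff.bond_idx[:, 0]]
        r = np.linalg.norm(vec, axis=1)
        rh = vec / r[:, None]
        k = ff.bond_k
        ft = k * (r - ff.bond_r0) / r           # transverse stiffness term
        eye = np.eye(3)
        H = (k - ft)[:, None, None] * np.einsum("bi,bj->bij", rh, rh) \
            + ft[:, None, None] * eye[None, :, :]
        vals = (self._signs * np.tile(H, (4, 1, 1))).reshape(-1)
        np.add.at(ab, (self._band_rows, self._cols), vals)
        return ab


def run_implicit(pos: np.ndarray, ff: ForceField,
                 gamma: float, kT: float, dt: float,
                 anchor_idx: np.ndarray, anchor_moved: np.ndarray,
                 anchor_pos: np.ndarray, anchor_k: float,
                 dx_cycle: float, cycle_len: int,
                 n_steps: int, target_x_e2e: float,
                 sample_steps: np.ndarray,
                 rng: np.random.Generator,
                 ) -> tuple[np.ndarray, int, int, int, bool]:
    """Backward-Euler loop with the translate/relax compression protocol.

    ``pos`` is modified in place. Beads listed in ``anchor_idx`` are
    tethered to ``anchor_pos`` with stiffness ``anchor_k``; anchor points
    flagged in ``anchor_moved`` are displaced kinematically by
    ``dx_cycle`` along x at the first step of each cycle. Returns
    (frames, n_recorded, last_step, status, stopped) with status -1 = ok,
    else the step index of a numerical blow-up.
    """
    ws = _ImplicitWorkspace(ff, gamma, dt, anchor_idx, anchor_k)
    n = ff.n_particles
    noise_std = np.sqrt(2.0 * kT * gamma / dt)
    frames_out = np.empty((sample_steps.size, n, 3))
    n_rec = 0
    status = -1
    stopped = False
    last_step = 0
    for step in range(n_steps):
        if dx_cycle != 0.0 and step % cycle_len == 0:
            anchor_pos[anchor_moved, 0] += dx_cycle
        F = compute_forces(pos, ff)
        if anchor_idx.size:
            F[anchor_idx] += anchor_k * (anchor_pos - pos[anchor_idx])
        if kT > 0.0:
            F = F + rng.normal(scale=noise_std, size=(n, 3))
        ab = ws.assemble(pos)
        delta = solve_banded((_BW, _BW), ab, F.reshape(-1))
        pos.reshape(-1)[:] += delta
        last_step = step + 1
        if n_rec < sample_steps.size and last_step == sample_steps[n_rec]:
            frames_out[n_rec] = pos
            n_rec += 1
        if last_step % cycle_len == 0:
            if not np.all(np.isfinite(pos)):
                status = last_step
                break
            if target_x_e2e > 0.0 and abs(pos[-1, 0] - pos[0, 0]) <= target_x_e2e:
                stopped = True
                break
    return frames_out, n_rec, last_step, status, stopped
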