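"""Compiled inner loops for the explicit overdamped integrator.

The monomer-scale chain needs ~1e7-1e8 Euler-Maruyama steps per compression
run at its stable timestep, so the force evaluation and update loop are JIT
compiled. The NumPy implementation in ``forcefield.compute_forces`` is the
reference; the test suite checks the two agree.

Anchoring follows the source protocol: end particles are tethered by
harmonic springs to anchor points; the moved end's anchor points are
translated kinematically once per cycle and the chain relaxes against the
springs, so the ends can pivot (they are not rigidly clamped).

Thermal noise is pre-generated in chunks by the caller with a seeded
``numpy.random.Generator`` (vectorised generation is much faster than
drawing scalars in the loop) and consumed positionally, so trajectories are
bit-reproducible for a given seed.

Note: the kernels run with fastmath, so NaN checks inside them are
unreliable; numerical blow-up detection lives in the chunk driver.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True, error_model="numpy")
def _accumulate_forces(pos, forces,
                       bond_idx, bond_k, bond_r0,
                       ang_idx, ang_k, ang_t0,
                       dih_idx, dih_k, dih_cos0, dih_sin0):
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    # harmonic bonds
    for b in range(bond_idx.shape[0]):
        i = bond_idx[b, 0]
        j = bond_idx[b, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        f = bond_k[b] * (r - bond_r0[b]) / r
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz
    # harmonic angles
    for a in range(ang_idx.shape[0]):
        ia = ang_idx[a, 0]
        ib = ang_idx[a, 1]
        ic = ang_idx[a, 2]
        ux = pos[ia, 0] - pos[ib, 0]
        uy = pos[ia, 1] - pos[ib, 1]
        uz = pos[ia, 2] - pos[ib, 2]
        vx = pos[ic, 0] - pos[ib, 0]
        vy = pos[ic, 1] - pos[ib, 1]
        vz = pos[ic, 2] - pos[ib, 2]
        inu = 1.0 / np.sqrt(ux * ux + uy * uy + uz * uz)
        inv = 1.0 / np.sqrt(vx * vx + vy * vy + vz * vz)
        uhx, uhy, uhz = ux * inu, uy * inu, uz * inu
        vhx, vhy, vhz = vx * inv, vy * inv, vz * inv
        c = uhx * vhx + uhy * vhy + uhz * vhz
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        s2 = 1.0 - c * c
        if s2 < 1e-16:
            s2 = 1e-16
        inv_s = 1.0 / np.sqrt(s2)
        coeff = -ang_k[a] * (theta - ang_t0[a]) * inv_s
        inv_a = coeff * inu
        inv_c = coeff * inv
        fax = (c * uhx - vhx) * inv_a
        fay = (c * uhy - vhy) * inv_a
        faz = (c * uhz - vhz) * inv_a
        fcx = (c * vhx - uhx) * inv_c
        fcy = (c * vhy - uhy) * inv_c
        fcz = (c * vhz - uhz) * inv_c
        forces[ia, 0] += fax
        forces[ia, 1] += fay
        forces[ia, 2] += faz
        forces[ic, 0] += fcx
        forces[ic, 1] += fcy
        forces[ic, 2] += fcz
        forces[ib, 0] -= fax + fcx
        forces[ib, 1] -= fay + fcy
        forces[ib, 2] -= faz + fcz
    # cosine dihedrals: U = k (1 - cos(phi - phi0));
    # dU/dphi = k sin(phi - phi0) expanded via sin/cos of phi so the loop
    # avoids atan2 and sin
    for d in range(dih_idx.shape[0]):
        ia = dih_idx[d, 0]
        ib = dih_idx[d, 1]
        ic = dih_idx[d, 2]
        id_ = dih_idx[d, 3]
        b1x = pos[ib, 0] - pos[ia, 0]
        b1y = pos[ib, 1] - pos[ia, 1]
        b1z = pos[ib, 2] - pos[ia, 2]
        b2x = pos[ic, 0] - pos[ib, 0]
        b2y = pos[ic, 1] - pos[ib, 1]
        b2z = pos[ic, 2] - pos[ib, 2]
        b3x = pos[id_, 0] - pos[ic, 0]
        b3y = pos[id_, 1] - pos[ic, 1]
        b3z = pos[id_, 2] - pos[ic, 2]
        m1x = b1y * b2z - b1z * b2y
        m1y = b1z * b2x - b1x * b2z
        m1z = b1x * b2y - b1y * b2x
        m2x = b2y * b3z - b2z * b3y
        m2y = b2z * b3x - b2x * b3z
        m2z = b2x * b3y - b2y * b3x
        m1sq = m1x * m1x + m1y * m1y + m1z * m1z
        m2sq = m2x * m2x + m2y * m2y + m2z * m2z
        b2n = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        cxx = m1y * m2z - m1z * m2y
        cxy = m1z * m2x - m1x * m2z
        cxz = m1x * m2y - m1y * m2x
        yv = (cxx * b2x + cxy * b2y + cxz * b2z) / b2n
        xv = m1x * m2x + m1y * m2y + m1z * m2z
        h2 = xv * xv + yv * yv
        if h2 < 1e-300:
            continue
        ih = 1.0 / np.sqrt(h2)
        dU = dih_k[d] * (yv * ih * dih_cos0[d] - xv * ih * dih_sin0[d])
        ca = -b2n / m1sq * dU
        cd = b2n / m2sq * dU
        dax = ca * m1x
        day = ca * m1y
        daz = ca * m1z
        ddx = cd * m2x
        ddy = cd * m2y
        ddz = cd * m2z
        ib2sq = 1.0 / (b2n * b2n)
        s12 = (b1x * b2x + b1y * b2y + b1z * b2z) * ib2sq
        s32 = (b3x * b2x + b3y * b2y + b3z * b2z) * ib2sq
        dbx = -(1.0 + s12) * dax + s32 * ddx
        dby = -(1.0 + s12) * day + s32 * ddy
        dbz = -(1.0 + s12) * daz + s32 * ddz
        dcx = s12 * dax - (1.0 + s32) * ddx
        dcy = s12 * day - (1.0 + s32) * ddy
        dcz = s12 * daz - (1.0 + s32) * ddz
        forces[ia, 0] -= dax
        forces[ia, 1] -= day
        forces[ia, 2] -= daz
        forces[ib, 0] -= dbx
        forces[ib, 1] -= dby
        forces[ib, 2] -= dbz
        forces[ic, 0] -= dcx
        forces[ic, 1] -= dcy
        forces[ic, 2] -= dcz
        forces[id_, 0] -= ddx
        forces[id_, 1] -= ddy
        forces[id_, 2] -= ddz


@njit(cache=True, fastmath=True, error_model="numpy")
def _chain_forces(pos, forces, n,
                  k_b1, r0_b1, k_b2, r0_b2,
                  k_a1, t0_a1, k_a2, t0_a2,
                  k_d, cos0_d, sin0_d,
                  bv, ib_n):
    """Chain-specialised bonded forces.

    Topology is the standard filament chain: order-1/2 bonds, order-1/2
    angles, consecutive dihedrals, one constant per class. Order-1 bond
    vectors and inverse norms are cached in ``bv``/``ib_n`` and reused by
    every other term, which roughly halves the cost of the generic
    per-term loop.
    """
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        bv[i, 0] = dx
        bv[i, 1] = dy
        bv[i, 2] = dz
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        ib_n[i] = 1.0 / r
        f = k_b1 * (r - r0_b1) * ib_n[i]
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[i + 1, 0] -= f * dx
        forces[i + 1, 1] -= f * dy
        forces[i + 1, 2] -= f * dz
    for i in range(n - 2):
        dx = bv[i, 0] + bv[i + 1, 0]
        dy = bv[i, 1] + bv[i + 1, 1]
        dz = bv[i, 2] + bv[i + 1, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        f = k_b2 * (r - r0_b2) / r
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[i + 2, 0] -= f * dx
        forces[i + 2, 1] -= f * dy
        forces[i + 2, 2] -= f * dz
    for i in range(1, n - 1):
        iu = ib_n[i - 1]
        iv = ib_n[i]
        uhx = -bv[i - 1, 0] * iu
        uhy = -bv[i - 1, 1] * iu
        uhz = -bv[i - 1, 2] * iu
        vhx = bv[i, 0] * iv
        vhy = bv[i, 1] * iv
        vhz = bv[i, 2] * iv
        c = uhx * vhx + uhy * vhy + uhz * vhz
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        s2 = 1.0 - c * c
        if s2 < 1e-16:
            s2 = 1e-16
        coeff = -k_a1 * (np.arccos(c) - t0_a1) / np.sqrt(s2)
        ca = coeff * iu
        cc = coeff * iv
        fax = (c * uhx - vhx) * ca
        fay = (c * uhy - vhy) * ca
        faz = (c * uhz - vhz) * ca
        fcx = (c * vhx - uhx) * cc
        fcy = (c * vhy - uhy) * cc
        fcz = (c * vhz - uhz) * cc
        forces[i - 1, 0] += fax
        forces[i - 1, 1] += fay
        forces[i - 1, 2] += faz
        forces[i + 1, 0] += fcx
        forces[i + 1, 1] += fcy
        forces[i + 1, 2] += fcz
        forces[i, 0] -= fax + fcx
        forces[i, 1] -= fay + fcy
        forces[i, 2] -= faz + fcz
    for i in range(2, n - 2):
        ux = -(bv[i - 2, 0] + bv[i - 1, 0])
        uy = -(bv[i - 2, 1] + bv[i - 1, 1])
        uz = -(bv[i - 2, 2] + bv[i - 1, 2])
        vx = bv[i, 0] + bv[i + 1, 0]
        vy = bv[i, 1] + bv[i + 1, 1]
        vz = bv[i, 2] + bv[i + 1, 2]
        iu = 1.0 / np.sqrt(ux * ux + uy * uy + uz * uz)
        iv = 1.0 / np.sqrt(vx * vx + vy * vy + vz * vz)
        uhx, uhy, uhz = ux * iu, uy * iu, uz * iu
        vhx, vhy, vhz = vx * iv, vy * iv, vz * iv
        c = uhx * vhx + uhy * vhy + uhz * vhz
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        s2 = 1.0 - c * c
        if s2 < 1e-16:
            s2 = 1e-16
        coeff = -k_a2 * (np.arccos(c) - t0_a2) / np.sqrt(s2)
        ca = coeff * iu
        cc = coeff * iv
        fax = (c * uhx - vhx) * ca
        fay = (c * uhy - vhy) * ca
        faz = (c * uhz - vhz) * ca
        fcx = (c * vhx - uhx) * cc
        fcy = (c * vhy - uhy) * cc
        fcz = (c * vhz - uhz) * cc
        forces[i - 2, 0] += fax
        forces[i - 2, 1] += fay
        forces[i - 2, 2] += faz
        forces[i + 2, 0] += fcx
        forces[i + 2, 1] += fcy
        forces[i + 2, 2] += fcz
        forces[i, 0] -= fax + fcx
        forces[i, 1] -= fay + fcy
        forces[i, 2] -= faz + fcz
    for i in range(n - 3):
        b1x, b1y, b1z = bv[i, 0], bv[i, 1], bv[i, 2]
        b2x, b2y, b2z = bv[i + 1, 0], bv[i + 1, 1], bv[i + 1, 2]
        b3x, b3y, b3z = bv[i + 2, 0], bv[i + 2, 1], bv[i + 2, 2]
        m1x = b1y * b2z - b1z * b2y
        m1y = b1z * b2x - b1x * b2z
        m1z = b1x * b2y - b1y * b2x
        m2x = b2y * b3z - b2z * b3y
        m2y = b2z * b3x - b2x * b3z
        m2z = b2x * b3y - b2y * b3x
        m1sq = m1x * m1x + m1y * m1y + m1z * m1z
        m2sq = m2x * m2x + m2y * m2y + m2z * m2z
        ib2 = ib_n[i + 1]
        b2n = 1.0 / ib2
        cxx = m1y * m2z - m1z * m2y
        cxy = m1z * m2x - m1x * m2z
        cxz = m1x * m2y - m1y * m2x
        yv = (cxx * b2x + cxy * b2y + cxz * b2z) * ib2
        xv = m1x * m2x + m1y * m2y + m1z * m2z
        h2 = xv * xv + yv * yv
        if h2 < 1e-300:
            continue
        ih = 1.0 / np.sqrt(h2)
        dU = k_d * (yv * ih * cos0_d - xv * ih * sin0_d)
        ca = -b2n / m1sq * dU
        cd = b2n / m2sq * dU
        dax = ca * m1x
        day = ca * m1y
        daz = ca * m1z
        ddx = cd * m2x
        ddy = cd * m2y
        ddz = cd * m2z
        ib2sq = ib2 * ib2
        s12 = (b1x * b2x + b1y * b2y + b1z * b2z) * ib2sq
        s32 = (b3x * b2x + b3y * b2y + b3z * b2z) * ib2sq
        dbx = -(1.0 + s12) * dax + s32 * ddx
        dby = -(1.0 + s12) * day + s32 * ddy
        dbz = -(1.0 + s12) * daz + s32 * ddz
        dcx = s12 * dax - (1.0 + s32) * ddx
        dcy = s12 * day - (1.0 + s32) * ddy
        dcz = s12 * daz - (1.0 + s32) * ddz
        forces[i, 0] -= dax
        forces[i, 1] -= day
        forces[i, 2] -= daz
        forces[i + 1, 0] -= dbx
        forces[i + 1, 1] -= dby
        forces[i + 1, 2] -= dbz
        forces[i + 2, 0] -= dcx
        forces[i + 2, 1] -= dcy
        forces[i + 2, 2] -= dcz
        forces[i + 3, 0] -= ddx
        forces[i + 3, 1] -= ddy
        forces[i + 3, 2] -= ddz


@njit(cache=True, fastmath=True, error_model="numpy")
def run_chain_chunk(pos, forces,
                    k_b1, r0_b1, k_b2, r0_b2,
                    k_a1, t0_a1, k_a2, t0_a2,
                    k_d, cos0_d, sin0_d,
                    anchor_idx, anchor_moved, anchor_pos, anchor_k,
                    dt_over_gamma, noise,
                    dx_cycle, cycle_len,
                    step_offset, n_steps_chunk,
                    target_x_e2e,
                    sample_steps, frames_out, n_rec,
                    bv, ib_n):
    """One chunk of the Euler-Maruyama translate/relax loop (chain layout).

    ``noise`` is (n_steps_chunk, n, 3) pre-scaled thermal displacements (or
    a (0, n, 3) array at zero temperature). ``anchor_pos`` holds the anchor
    points tethering beads ``anchor_idx`` with spring constant
    ``anchor_k``; anchor points flagged in ``anchor_moved`` are displaced
    by ``dx_cycle`` along x at the first step of each ``cycle_len``-step
    cycle. Frames are recorded into ``frames_out`` when the completed
    global step count reaches the next entry of ``sample_steps``.

    Returns (n_rec, last_global_step, stopped); stopped = True when the
    x-projected end-to-end distance reached ``target_x_e2e`` (checked once
    per cycle, disabled when <= 0).
    """
    n = pos.shape[0]
    na = anchor_idx.shape[0]
    use_noise = noise.shape[0] > 0
    stopped = False
    gstep = step_offset
    for s in range(n_steps_chunk):
        gstep = step_offset + s
        if dx_cycle != 0.0 and gstep % cycle_len == 0:
            for a in range(na):
                if anchor_moved[a]:
                    anchor_pos[a, 0] += dx_cycle
        _chain_forces(pos, forces, n,
                      k_b1, r0_b1, k_b2, r0_b2,
                      k_a1, t0_a1, k_a2, t0_a2,
                      k_d, cos0_d, sin0_d, bv, ib_n)
        for a in range(na):
            i = anchor_idx[a]
            forces[i, 0] += anchor_k * (anchor_pos[a, 0] - pos[i, 0])
            forces[i, 1] += anchor_k * (anchor_pos[a, 1] - pos[i, 1])
            forces[i, 2] += anchor_k * (anchor_pos[a, 2] - pos[i, 2])
        if use_noise:
            for i in range(n):
                pos[i, 0] += forces[i, 0] * dt_over_gamma + noise[s, i, 0]
                pos[i, 1] += forces[i, 1] * dt_over_gamma + noise[s, i, 1]
                pos[i, 2] += forces[i, 2] * dt_over_gamma + noise[s, i, 2]
        else:
            for i in range(n):
                pos[i, 0] += forces[i, 0] * dt_over_gamma
                pos[i, 1] += forces[i, 1] * dt_over_gamma
                pos[i, 2] += forces[i, 2] * dt_over_gamma
        gstep += 1
        if n_rec < sample_steps.shape[0] and gstep == sample_steps[n_rec]:
            frames_out[n_rec, :, :] = pos
            n_rec += 1
        if target_x_e2e > 0.0 and gstep % cycle_len == 0:
            if abs(pos[n - 1, 0] - pos[0, 0]) <= target_x_e2e:
                stopped = True
                break
    return n_rec, gstep, stopped


@njit(cache=True, fastmath=True, error_model="numpy")
def run_explicit_chunk(pos, forces,
                       bond_idx, bond_k, bond_r0,
                       ang_idx, ang_k, ang_t0,
                       dih_idx, dih_k, dih_cos0, dih_sin0,
                       anchor_idx, anchor_moved, anchor_pos, anchor_k,
                       dt_over_gamma, noise,
                       dx_cycle, cycle_len,
                       step_offset, n_steps_chunk,
                       target_x_e2e,
                       sample_steps, frames_out, n_rec,
                       ):
    """Generic-topology variant of :func:`run_chain_chunk`."""
    n = pos.shape[0]
    na = anchor_idx.shape[0]
    use_noise = noise.shape[0] > 0
    stopped = False
    gstep = step_offset
    for s in range(n_steps_chunk):
        gstep = step_offset + s
        if dx_cycle != 0.0 and gstep % cycle_len == 0:
            for a in range(na):
                if anchor_moved[a]:
                    anchor_pos[a, 0] += dx_cycle
        _accumulate_forces(pos, forces,
                           bond_idx, bond_k, bond_r0,
                           ang_idx, ang_k, ang_t0,
                           dih_idx, dih_k, dih_cos0, dih_sin0)
        for a in range(na):
            i = anchor_idx[a]
            forces[i, 0] += anchor_k * (anchor_pos[a, 0] - pos[i, 0])
            forces[i, 1] += anchor_k * (anchor_pos[a, 1] - pos[i, 1])
            forces[i, 2] += anchor_k * (anchor_pos[a, 2] - pos[i, 2])
        if use_noise:
            for i in range(n):
                pos[i, 0] += forces[i, 0] * dt_over_gamma + noise[s, i, 0]
                pos[i, 1] += forces[i, 1] * dt_over_gamma + noise[s, i, 1]
                pos[i, 2] += forces[i, 2] * dt_over_gamma + noise[s, i, 2]
        else:
            for i in range(n):
                pos[i, 0] += forces[i, 0] * dt_over_gamma
                pos[i, 1] += forces[i, 1] * dt_over_gamma
                pos[i, 2] += forces[i, 2] * dt_over_gamma
        gstep += 1
        if n_rec < sample_steps.shape[0] and gstep == sample_steps[n_rec]:
            frames_out[n_rec, :, :] = pos
            n_rec += 1
        if target_x_e2e > 0.0 and gstep % cycle_len == 0:
            if abs(pos[n - 1, 0] - pos[0, 0]) <= target_x_e2e:
                stopped = True
                break
    return n_rec, gstep, stopped
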