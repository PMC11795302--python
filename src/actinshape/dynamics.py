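"""Brownian dynamics of filament chains under the compression protocol.

The protocol mirrors the one used in the source engines: the anchored
particles at the moved end are translated along -x for one time step, then
the chain relaxes for nine; the per-cycle displacement is
velocity * timestep * 10, and the run stops at the first cycle where the
x-projected end-to-end distance reaches ``compression_fraction`` times its
initial value.

Two integration paths share this protocol:

* monomer-scale (harmonic angles + dihedrals): explicit Euler-Maruyama in a
  compiled kernel (``_kernels.run_explicit``);
* fiber-scale (curvature bending): semi-implicit backward Euler
  (``implicit.run_implicit``), which is what makes the printed 5e-7 s fiber
  timestep usable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .frames import FilamentFrame
from .forcefield import ForceField, KT_ROOM

#: Water viscosity, pN*s/nm^2 (1 mPa*s).
VISCOSITY = 1e-9

#: Default bead hydrodynamic radius at monomer scale, nm (half the
#: ~5.5 nm monomer spacing along the genetic helix).
MONOMER_BEAD_RADIUS = 2.75

#: Paper-printed fiber timestep; monomer default from the stability sweep
#: (see scripts/calibrate_forcefield.py).
FIBER_DT = 5e-7
MONOMER_DT = 2.5e-11


def stokes_drag(radius_nm: float, viscosity: float = VISCOSITY) -> float:
    """Isotropic Stokes drag 6*pi*eta*r, pN*s/nm."""
    return 6.0 * math.pi * viscosity * radius_nm


@dataclass(frozen=True)
class ThermalModel:
    """Overdamped Langevin bath: thermal energy, per-particle drag, seed."""

    kT: float = KT_ROOM                     # pN*nm
    drag_per_particle: float = stokes_drag(MONOMER_BEAD_RADIUS)  # pN*s/nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kT < 0:
            raise ValueError("kT must be >= 0")
        if self.drag_per_particle <= 0:
            raise ValueError("drag_per_particle must be > 0")


@dataclass(frozen=True)
class CompressionProtocol:
    """Translate/relax compression of an anchored filament.

    velocity : um/s           compression speed of the moved end
    timestep : s              integration timestep
    translate_steps, relax_steps : cycle structure (1 + 9 by default)
    initial_end_to_end : nm   starting end-to-end distance along x
    compression_fraction :    stop when x-projected end-to-end reaches this
                              fraction of the initial value (0.7)
    fixed_end_particles, moved_end_particles : anchor counts at each end
    anchor_stiffness : pN/nm  spring tethering each anchored bead to its
                              anchor point; the points at the moved end are
                              what the protocol translates, so the filament
                              relaxes against its linkers and the ends can
                              pivot rather than being rigidly clamped
    """

    velocity: float = 15.0
    timestep: float = FIBER_DT
    translate_steps: int = 1
    relax_steps: int = 9
    initial_end_to_end: float = 500.0
    compression_fraction: float = 0.7
    fixed_end_particles: int = 2
    moved_end_particles: int = 2
    anchor_stiffness: float = 10.0      # pN/nm, bead-to-anchor-point spring

    def __post_init__(self) -> None:
        if self.velocity < 0:
            raise ValueError("velocity must be >= 0")
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if not 0.0 < self.compression_fraction < 1.0:
            raise ValueError("compression_fraction must be in (0, 1)")
        if self.translate_steps != 1:
            raise ValueError("protocol translates for exactly one step")
        if self.fixed_end_particles < 1 or self.moved_end_particles < 1:
            raise ValueError("each end needs at least one anchor particle")

    @property
    def cycle_steps(self) -> int:
        return self.translate_steps + self.relax_steps

    @property
    def displacement_per_cycle(self) -> float:
        """Anchor displacement per translate step, nm (= v * dt * cycle)."""
        return self.velocity * 1e3 * self.timestep * self.cycle_steps

    @property
    def target_end_to_end(self) -> float:
        return self.compression_fraction * self.initial_end_to_end

    @property
    def total_time(self) -> float:
        """Time to reach the target compression at the protocol velocity, s."""
        travel = (1.0 - self.compression_fraction) * self.initial_end_to_end
        return travel / (self.velocity * 1e3)


@dataclass
class Trajectory:
    """Downsampled output of one simulation run."""

    frames: list[FilamentFrame]
    times: np.ndarray                 # s, strictly increasing
    protocol: CompressionProtocol | None
    resolution_label: str             # "monomer" | "fiber"
    replicate: int = 0
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        if len(self.frames) != self.times.size:
            raise ValueError("times and frames length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        counts = {f.n_points for f in self.frames}
        if len(counts) > 1:
            raise ValueError("all frames must share one particle count")
        if self.resolution_label not in ("monomer", "fiber", "external"):
            raise ValueError(f"unknown resolution {self.resolution_label!r}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


class SimulationBlowupError(RuntimeError):
    """A coordinate became non-finite during integration."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"numerical blow-up at step {step}; "
                         "reduce the timestep or soften the force field")


def step_overdamped(frame: FilamentFrame, forces: np.ndarray,
                    thermal: ThermalModel, dt: float,
                    fixed: Sequence[int] = (),
                    rng: np.random.Generator | None = None) -> FilamentFrame:
    """One Euler-Maruyama update: dx = F/gamma dt + sqrt(2 kT dt/gamma) xi.

    Reference (NumPy) implementation of the integrator; the long production
    loops use the compiled/implicit equivalents. Particles listed in
    ``fixed`` do not move.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = rng or np.random.default_rng(thermal.seed)
    gamma = thermal.drag_per_particle
    disp = np.asarray(forces, dtype=np.float64) * (dt / gamma)
    if thermal.kT > 0:
        disp = disp + rng.normal(scale=np.sqrt(2.0 * thermal.kT * dt / gamma),
                                 size=disp.shape)
    if len(fixed):
        disp[np.asarray(fixed, dtype=np.intp)] = 0.0
    return frame.with_points(frame.points + disp, time=frame.time + dt)


#: Steps per kernel chunk; noise for a chunk is generated in one vectorised
#: draw. Fixed so the noise stream for a given seed does not depend on run
#: length.
_CHUNK_STEPS = 4_000


def _chain_class_constants(ff: ForceField):
    """Per-class constants when ``ff`` is the standard monomer chain.

    The chain-specialised kernel assumes the exact term layout produced by
    :func:`forcefield.chain_term_indices` with neighbour orders (1, 2),
    one constant per class and dihedrals on consecutive beads; returns
    None (generic kernel) otherwise.
    """
    n = ff.n_particles
    if ff.bend_model != "harmonic" or ff.neighbor_orders != (1, 2):
        return None
    if (ff.bond_idx.shape[0] != 2 * n - 3
            or ff.angle_idx.shape[0] != 2 * n - 6
            or ff.dihedral_idx.shape[0] != n - 3):
        return None
    b1, b2 = ff.bond_k[:n - 1], ff.bond_k[n - 1:]
    r1, r2 = ff.bond_r0[:n - 1], ff.bond_r0[n - 1:]
    a1, a2 = ff.angle_k[:n - 2], ff.angle_k[n - 2:]
    t1, t2 = ff.angle_theta0[:n - 2], ff.angle_theta0[n - 2:]
    for arr in (b1, b2, r1, r2, a1, a2, t1, t2, ff.dihedral_k,
                ff.dihedral_phi0):
        if arr.size == 0 or np.ptp(arr) != 0.0:
            return None
    return (float(b1[0]), float(r1[0]), float(b2[0]), float(r2[0]),
            float(a1[0]), float(t1[0]), float(a2[0]), float(t2[0]),
            float(ff.dihedral_k[0]), float(np.cos(ff.dihedral_phi0[0])),
            float(np.sin(ff.dihedral_phi0[0])))


def _run_explicit_driver(pos: np.ndarray, ff: ForceField,
                         anchor_idx: np.ndarray, anchor_moved: np.ndarray,
                         anchor_pos: np.ndarray, anchor_k: float,
                         dt: float, gamma: float, kT: float,
                         dx_cycle: float, cycle_len: int,
                         n_steps: int, target: float,
                         sample_steps: np.ndarray, seed: int
                         ) -> tuple[np.ndarray, int, int, int, bool]:
    """Chunked explicit Euler-Maruyama run (monomer-scale path)."""
    from ._kernels import run_chain_chunk, run_explicit_chunk

    n = pos.shape[0]
    chain = _chain_class_constants(ff)
    frames_out = np.empty((sample_steps.size, n, 3))
    forces = np.empty((n, 3))
    dih_cos0 = np.cos(ff.dihedral_phi0)
    dih_sin0 = np.sin(ff.dihedral_phi0)
    noise_amp = math.sqrt(2.0 * kT * dt / gamma)
    rng = np.random.default_rng(seed)
    buf = np.empty((min(_CHUNK_STEPS, n_steps), n, 3))
    zero_noise = np.empty((0, n, 3))
    bv = np.empty((n - 1, 3))
    ib_n = np.empty(n - 1)
    n_rec = 0
    done = 0
    last = 0
    stopped = False
    while done < n_steps:
        m = min(_CHUNK_STEPS, n_steps - done)
        if noise_amp > 0.0:
            noise = buf[:m]
            rng.standard_normal(out=noise)
            noise *= noise_amp
        else:
            noise = zero_noise
        if chain is not None:
            n_rec, last, stopped = run_chain_chunk(
                pos, forces, *chain,
                anchor_idx, anchor_moved, anchor_pos, anchor_k,
                dt / gamma, noise, dx_cycle, cycle_len,
                done, m, target, sample_steps, frames_out, n_rec,
                bv, ib_n)
        else:
            n_rec, last, stopped = run_explicit_chunk(
                pos, forces, ff.bond_idx, ff.bond_k, ff.bond_r0,
                ff.angle_idx, ff.angle_k, ff.angle_theta0,
                ff.dihedral_idx, ff.dihedral_k, dih_cos0, dih_sin0,
                anchor_idx, anchor_moved, anchor_pos, anchor_k,
                dt / gamma, noise, dx_cycle, cycle_len,
                done, m, target, sample_steps, frames_out, n_rec)
        done = last
        # blow-up detection lives here: the kernels are compiled with
        # fastmath, which cannot be trusted to observe NaNs
        if not np.all(np.isfinite(pos)):
            return frames_out, n_rec, last, last, stopped
        if stopped:
            break
    return frames_out, n_rec, last, -1, stopped


def _sample_schedule(n_steps: int, n_frames_out: int) -> np.ndarray:
    """Strictly increasing step counts at which to record (last = n_steps)."""
    n_out = max(min(n_frames_out - 1, n_steps), 1)
    steps = np.unique(np.round(np.linspace(1, n_steps, n_out)).astype(np.int64))
    steps[-1] = n_steps
    return steps


def simulate_compression(initial: FilamentFrame, ff: ForceField,
                         protocol: CompressionProtocol,
                         thermal: ThermalModel,
                         n_frames_out: int = 100,
                         replicate: int = 0,
                         max_cycles: int | None = None) -> Trajectory:
    """Run the translate/relax compression protocol to the target fraction.

    The chain must start along +x with the fixed end at low x; the first
    ``fixed_end_particles`` and last ``moved_end_particles`` beads are
    tethered to anchor points with ``anchor_stiffness`` springs, and the
    moved end's anchor points are translated. Output is downsampled to
    ~``n_frames_out`` evenly spaced frames (always including the initial
    and the exact stopping frame). Deterministic for a given
    ``thermal.seed``.
    """
    pos = initial.points.copy()
    n = pos.shape[0]
    nf, nm = protocol.fixed_end_particles, protocol.moved_end_particles
    if nf + nm >= n:
        raise ValueError("anchors overlap: chain too short for the protocol")
    e2e0 = abs(pos[-1, 0] - pos[0, 0])
    dx_cycle = protocol.displacement_per_cycle
    target = protocol.compression_fraction * e2e0
    if dx_cycle > 0:
        min_bond = float(np.min(np.linalg.norm(np.diff(pos, axis=0), axis=1)))
        if dx_cycle > min_bond:
            warnings.warn(
                f"per-cycle displacement {dx_cycle:.3g} nm exceeds the "
                f"shortest bond ({min_bond:.3g} nm); the protocol may tear "
                "the chain", RuntimeWarning)
        n_cycles = math.ceil((e2e0 - target) / dx_cycle)
        # the spring-anchored ends lag the anchor points slightly, so allow
        # head-room beyond the kinematic stop estimate
        n_cycles_max = int(1.5 * n_cycles) + 100
    else:
        if max_cycles is None:
            raise ValueError("velocity 0 needs an explicit max_cycles")
        n_cycles = n_cycles_max = max_cycles
    if max_cycles is not None:
        n_cycles_max = min(n_cycles_max, max_cycles)
    n_steps = n_cycles * protocol.cycle_steps
    n_steps_max = n_cycles_max * protocol.cycle_steps

    anchor_idx = np.concatenate([np.arange(nf), np.arange(n - nm, n)])
    anchor_moved = np.zeros(nf + nm, dtype=bool)
    if dx_cycle > 0:
        anchor_moved[nf:] = True
    anchor_pos = pos[anchor_idx].copy()

    sample_steps = _sample_schedule(n_steps, n_frames_out)
    dt = protocol.timestep
    gamma = thermal.drag_per_particle

    if ff.bend_model == "curvature":
        from .implicit import run_implicit
        rng = np.random.default_rng(thermal.seed)
        frames_out, n_rec, last_step, status, stopped = run_implicit(
            pos, ff, gamma, thermal.kT, dt,
            anchor_idx, anchor_moved, anchor_pos, protocol.anchor_stiffness,
            -dx_cycle, protocol.cycle_steps, n_steps_max,
            target if dx_cycle else -1.0, sample_steps, rng)
    else:
        frames_out, n_rec, last_step, status, stopped = _run_explicit_driver(
            pos, ff, anchor_idx, anchor_moved, anchor_pos,
            protocol.anchor_stiffness, dt, gamma, thermal.kT,
            -dx_cycle, protocol.cycle_steps, n_steps_max,
            target if dx_cycle else -1.0, sample_steps, thermal.seed)
    if status >= 0:
        raise SimulationBlowupError(status)
    if dx_cycle > 0 and not stopped:
        warnings.warn("compression target not reached within the step "
                      "budget; the anchored ends lag the protocol",
                      RuntimeWarning)

    label = "fiber" if ff.bend_model == "curvature" else "monomer"
    rec = list(sample_steps[:n_rec])
    frames = [FilamentFrame(frames_out[i].copy(), time=float(rec[i] * dt))
              for i in range(n_rec)]
    if not rec or rec[-1] != last_step:
        # exact state at the stopping step
        frames.append(FilamentFrame(pos.copy(), time=float(last_step * dt)))
        rec.append(last_step)
    frames.insert(0, initial.with_points(initial.points, time=0.0))
    times = np.concatenate([[0.0], np.asarray(rec, dtype=np.float64) * dt])
    return Trajectory(frames=frames, times=times, protocol=protocol,
                      resolution_label=label, replicate=replicate,
                      seed=thermal.seed,
                      metadata={"initial_end_to_end": e2e0,
                                "n_steps": int(last_step),
                                "stopped_on_target": bool(stopped)})


def simulate_free(initial: FilamentFrame, ff: ForceField,
                  thermal: ThermalModel, dt: float,
                  n_steps: int, n_frames_out: int = 50,
                  replicate: int = 0) -> Trajectory:
    """Free (un-anchored, uncompressed) relaxation run.

    Used for equilibration and persistence-length estimation.
    """
    pos = initial.points.copy()
    n = pos.shape[0]
    sample_steps = _sample_schedule(n_steps, n_frames_out)
    gamma = thermal.drag_per_particle
    no_anchors = np.empty(0, dtype=np.int64)
    no_moved = np.empty(0, dtype=bool)
    no_pos = np.empty((0, 3))
    if ff.bend_model == "curvature":
        from .implicit import run_implicit
        rng = np.random.default_rng(thermal.seed)
        frames_out, n_rec, last_step, status, _ = run_implicit(
            pos, ff, gamma, thermal.kT, dt,
            no_anchors, no_moved, no_pos, 0.0, 0.0, 10,
            n_steps, -1.0, sample_steps, rng)
    else:
        frames_out, n_rec, last_step, status, _ = _run_explicit_driver(
            pos, ff, no_anchors, no_moved, no_pos, 0.0, dt, gamma,
            thermal.kT, 0.0, 10, n_steps, -1.0, sample_steps, thermal.seed)
    if status >= 0:
        raise SimulationBlowupError(status)
    label = "fiber" if ff.bend_model == "curvature" else "monomer"
    frames = [FilamentFrame(frames_out[i].copy(),
                            time=float(sample_steps[i] * dt))
              for i in range(n_rec)]
    frames.insert(0, initial.with_points(initial.points, time=0.0))
    times = np.concatenate([[0.0], sample_steps[:n_rec] * dt])
    return Trajectory(frames=frames, times=times, protocol=None,
                      resolution_label=label, replicate=replicate,
                      seed=thermal.seed, metadata={"free_run": True})
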