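#!/usr/bin/env python
"""Calibration tools for the monomer-scale force field.

The source engines' force constants are not published, so the defaults in
``actinshape.forcefield`` were chosen with this script:

1. ``--sweep-dt``: find the largest explicit timestep at which a free
   thermal chain stays at a bounded, near-equipartition energy (the top
   Hessian eigenvalue of the bonded energy sets the scale via
   dt < 2*gamma/eig_max).
2. ``--hessian``: report that eigenvalue for the current constants.
3. ``--persistence-length``: measure the relaxed chain's persistence
   length, the quantity the calibration targets (10-25 um at
   kT = 4.1 pN nm, bracketing the 9-11 um measured for ADP-actin).

Usage:
    python scripts/calibrate_forcefield.py --sweep-dt
    python scripts/calibrate_forcefield.py --hessian
    python scripts/calibrate_forcefield.py --persistence-length --replicates 3
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np  # noqa: E402

from actinshape.analysis import estimate_persistence_length  # noqa: E402
from actinshape.dynamics import (MONOMER_BEAD_RADIUS, SimulationBlowupError,
                                 ThermalModel, simulate_free,
                                 stokes_drag)  # noqa: E402
from actinshape.forcefield import (build_monomer_chain, compute_forces,
                                   total_energy)  # noqa: E402
from actinshape.geometry import HelixGeometry  # noqa: E402


def sweep_dt(args) -> None:
    frame, ff = build_monomer_chain(HelixGeometry.for_length(args.length))
    gamma = stokes_drag(MONOMER_BEAD_RADIUS)
    th = ThermalModel(drag_per_particle=gamma, seed=args.seed)
    equip = (3 * frame.n_points - 6) / 2 * th.kT
    print(f"equipartition scale ~{equip:.0f} pN nm")
    for dt in (1e-11, 1.5e-11, 2e-11, 2.5e-11, 3e-11, 4e-11):
        try:
            tr = simulate_free(frame, ff, th, dt=dt, n_steps=400_000,
                               n_frames_out=6)
            e = np.mean([total_energy(f, ff) for f in tr.frames[2:]])
            verdict = "ok" if e < 3 * equip else "HOT (unstable modes)"
            print(f"dt = {dt:.1e} s  <E> = {e:9.0f} pN nm  {verdict}")
        except SimulationBlowupError as err:
            print(f"dt = {dt:.1e} s  BLOW-UP at step {err.step}")


def hessian(args) -> None:
    frame, ff = build_monomer_chain(HelixGeometry.for_length(args.length))
    pts = frame.points
    n = pts.shape[0]
    h = 1e-6
    H = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for c in range(3):
            p = pts.copy()
            p[i, c] += h
            fp = compute_forces(p, ff)
            p[i, c] -= 2 * h
            fm = compute_forces(p, ff)
            H[:, 3 * i + c] = -((fp - fm) / (2 * h)).ravel()
    eig = np.linalg.eigvalsh(0.5 * (H + H.T))[-1]
    gamma = stokes_drag(MONOMER_BEAD_RADIUS)
    print(f"top Hessian eigenvalue: {eig:.0f} pN/nm")
    print(f"explicit stability bound 2*gamma/eig: {2 * gamma / eig:.2e} s")


def persistence(args) -> None:
    est = estimate_persistence_length("monomer", seed=args.seed,
                                      length_nm=250.0,
                                      replicates=args.replicates)
    print(est.summary())
    print("per replicate (um):",
          ", ".join(f"{x:.1f}" for x in est.per_replicate))


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sweep-dt", action="store_true")
    parser.add_argument("--hessian", action="store_true")
    parser.add_argument("--persistence-length", action="store_true")
    parser.add_argument("--length", type=float, default=100.0)
    parser.add_argument("--replicates", type=int, default=3)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()
    if args.sweep_dt:
        sweep_dt(args)
    if args.hessian:
        hessian(args)
    if args.persistence_length:
        persistence(args)
    if not (args.sweep_dt or args.hessian or args.persistence_length):
        parser.print_help()


if __name__ == "__main__":
    main()
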