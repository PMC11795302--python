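# Methods

## The two filament models

Both models represent a single actin filament as a bead chain in an
overdamped Langevin bath (k_BT = 4.1 pN nm, water viscosity 1 mPa s,
isotropic Stokes drag per bead). All lengths are in nm, forces in pN,
energies in pN nm.

### Monomer scale (chiral)

One bead per actin subunit, placed on the ideal genetic helix: rise
2.74 nm/subunit, twist −166.7°/subunit, and the subunit centre of mass
2.5 nm off the filament axis. The off-axis radius matters: it sets the
lever arm through which bending the filament distorts the helical lattice,
i.e. the twist–bend coupling that produces directional supertwist. With
beads placed nearly on-axis the chiral response all but vanishes.

The structure is enforced by topology potentials:

* harmonic bonds ½k(r−r₀)² between each bead and its two neighbours in
  each chain direction (orders 1 and 2);
* harmonic angles ½k(θ−θ₀)² on the triplets (i−o, i, i+o) for both orders;
* cosine dihedrals k(1 − cos(φ−φ₀)) on each four consecutive beads — the
  convention is stated explicitly because "cosine dihedral" is ambiguous:
  φ = φ₀ is the (zero-energy) minimum.

Equilibrium targets r₀, θ₀, φ₀ are *measured from the ideal helix*, so the
ideal structure is an exact zero-force configuration and the dihedral
targets (±φ₀) encode its handedness; mirroring the geometry flips their
sign. The order-2 terms run along the two long-pitch (protofilament-like)
strands of the two-start helix.

Force constants are not dictated by the modelled system's published record,
so they are calibrated (see `scripts/calibrate_forcefield.py`): bonds
250 pN/nm, angles k₁ = 2000 and k₂ = 7000 pN nm/rad², dihedral
k = 7000 pN nm. Two considerations shaped the split. First, the top
Hessian eigenvalue of the bonded energy — which bounds the stable explicit
timestep via dt < 2γ/λ_max — is controlled almost entirely by the order-2
angle constant (λ_max ≈ 0.5 k₂), while dihedral stiffness adds bending
rigidity *and* chiral coupling essentially for free; the rigidity is
therefore carried by the dihedrals as much as possible. Second, the
resulting persistence length of the relaxed chain (measured on the smoothed
axis by the package's own estimator) lands at ≈ 12 µm, inside the 10–25 µm
window bracketing experimental ADP-actin (9–11 µm). The bead drag radius is
2.75 nm, half the ~5.5 nm subunit spacing.

Integration is explicit Euler–Maruyama,
x ← x + (F/γ)dt + √(2k_BT dt/γ)ξ, in a compiled (numba) kernel. A timestep
sweep (energy stationarity of a free thermal chain vs equipartition) gives
dt = 2.5 × 10⁻¹¹ s as the largest safe step for these constants
(λ_max·dt/γ ≈ 1.8 < 2); the stiff lattice modes run slightly warm at this
step, the bending and twisting modes that set filament shape are far below
the stability bound and sample accurately. Thermal noise is pre-generated
in fixed-size chunks with a seeded PCG64 generator, so trajectories are
bit-reproducible for a given seed.

### Fiber scale (achiral)

A worm-like chain of 10 nm segments: harmonic stretching (100 pN/nm) and
the quadratic curvature energy U = κ/(2l³) Σ|p_{i−1} − 2p_i + p_{i+1}|²
with κ = 0.075 pN µm² (L_p = κ/k_BT ≈ 18 µm). The curvature form is the
standard fiber-scale discretisation and is equivalent to a harmonic angle
constant k_angle = κ/l near the straight state; it carries no chirality.

At the fiber timestep of 5 × 10⁻⁷ s an explicit update is unconditionally
unstable for actin-like κ (the stiffest bending mode needs dt ≲ 10⁻⁹ s), so
the fiber chain is integrated semi-implicitly — one backward-Euler step
with the force linearised about the current state,
(γ/dt + K_bend + J_stretch)δx = F + ξ, a banded solve per step. This is the
same resolution strategy fiber-scale simulation engines use. A known
side-effect of large implicit steps is that thermal fluctuations of modes
with relaxation times below dt are filtered; shape-scale modes are
unaffected, but the persistence-length *measurement* of the fiber chain is
run at dt = 10⁻⁹ s so the estimator sees genuine short-wavelength bending.

### Anchoring and the compression protocol

Each end of the filament is tethered by harmonic springs (default
10 pN/nm) to anchor points: two linkers 10 nm apart per end at fiber
scale, the three end beads at monomer scale. The protocol translates the
moved end's *anchor points* along −x for one time step and lets the chain
relax for nine; the displacement per ten-step cycle is v·dt·10. The
filament therefore relaxes against its linkers and the ends can pivot —
they are not rigidly clamped, which matters: rigid clamps force planar
buckles whose end tangents are locked antiparallel, erasing exactly the
supertwist signal being measured. The run stops at the first cycle where
the x-projected end-to-end distance reaches the target fraction (0.7) of
its initial value; because the ends lag the anchors by force/stiffness,
the stop time exceeds the kinematic estimate by a few percent, and the
recorded final frame is the exact stopping state.

## Shape metrics

All metrics operate on a bare point chain. Raw monomer frames are first
smoothed to the filament axis (centered 13-bead sliding mean, covering ~6
periods of the helical zigzag); fiber frames get a light 3-bead smoothing
so the clamped end bonds do not dominate the end tangents. Chains are then
resampled to 50 points at equal arc length (matching 10 nm sampling of a
500 nm filament).

* **compression ratio** 1 − d/d₀ against the initial end-to-end distance,
  with the baseline measured on the identically processed first frame.
* **peak asymmetry** |2s* − 1|, s* the arc-length fraction of the maximum
  deviation from the end-to-end chord; defined as 0 for straight chains so
  time series start cleanly.
* **non-coplanarity** λ₃/(λ₁+λ₂+λ₃) of the single frame's 3 × 3 positional
  covariance; 0 for planar shapes, at most 1/3.
* **supertwist angle**: the signed angle between the first and last
  tangent's projections perpendicular to the compression axis, positive =
  right-handed, *accumulated along the chain* (summing the signed azimuth
  increments of successive segment projections). The spatial accumulation
  makes the value single-valued — a coil through several turns reports its
  full winding — and resolves the ±180° ambiguity of a deeply buckled
  C-shape (whose end tangents are antiparallel) by the side on which the
  filament's mid-chain tangent actually sweeps past the axis, which is the
  chirality-bearing feature. For this reason the per-trajectory series is
  *not* re-unwrapped in time: each frame's value is an independent
  geometric reading, which the late-time sign statistics require
  (`unwrap_angles` remains available for end-tangent-only series). Frames
  whose end tangents are within tolerance of the axis are flagged NaN
  (undefined), not zero; the pipeline tolerance is 2 % of the tangent norm,
  above the smoothed lattice's residual wiggle.
* **persistence length**: least-squares fit of ln⟨t(s)·t(s+Δs)⟩ against Δs
  (lags up to ~120 nm), pooled over frames, reported as mean ± SD across
  replicates; a chain whose correlations never decay below 1 − 10⁻⁴ is
  flagged rigid (L_p = ∞) rather than assigned a number.

## Shape space

Frames are processed as above, translated so the fixed end sits at the
origin, and rotated about x so the furthest yz-point lies on +y — a proper
rotation, so chirality and supertwist sign survive. PCA is fitted on the
flattened coordinates pooled across simulators, velocities, replicates and
time points (centred, unscaled: coordinates share units). Component signs
are fixed deterministically — PC1 to correlate positively with compression
ratio, PC2 with the chiral model's supertwist, further components by their
largest loading — so plots and scores are reproducible. Latent walks
inverse-transform mean ± 2 SD along one component into 3D chains.

## The desk-scale study and what it shows

The full-scale study (500 nm filament; 4.7, 15, 47, 150 µm/s; five
replicates) is available as the `paper` preset, but its monomer-scale runs
cost hours each. The package's default experiment is a scaled-down
analogue chosen to preserve the protocol, both resolutions and the
statistical design while fitting in minutes: a 100 nm filament, the two
fastest velocities (47 and 150 µm/s), five replicates each, 80 frames kept
per run. Statistics use the late-time window (normalized compression time
≥ 0.75): per replicate the mean supertwist and the pooled median
non-coplanarity, an exact binomial sign test for the achiral model's
winding direction (α = 0.05), and a Mann–Whitney rank-sum test for
late-time PC2 separation between the models. Whether compression is PC1's
dominant correlate is judged among the shape metrics (compression ratio,
supertwist, non-coplanarity, peak asymmetry); normalized time is reported
alongside them but is a deterministic covariate of compression under the
protocol, not a competing shape feature. In the pooled desk-scale space,
PC2 absorbs the between-model compression lag (the fiber chain's soft
linkers let it trail the protocol slightly more than the monomer chain),
which is also why corr(PC1, compression) sits near 0.7 rather than 1.

At this scale the buckles are single-lobed and nearly planar
(non-coplanarity ~10⁻⁵; out-of-plane amplitudes of a few Å), so the
divergence between the models appears as the *direction* of the tangent
winding: the chiral chain sweeps past the axis on its preferred
(right-handed, positive) side in every replicate, while the achiral chain
picks a side at random. The large coiled shapes of the full-scale study
are not reproduced at desk scale — only the directional signature and the
ordering of non-coplanarity between the models, which is what the
acceptance statistics test.

## Synthetic fixtures

The parametric generator provides analytic oracles: straight rods
(degenerate metrics), symmetric planar circular arcs (planarity and
symmetry by construction; end tangents antiparallel, so the supertwist
magnitude is 180° with degenerate sign), and helical coils whose winding
angle — including beyond ±180° — is known in closed form, with the exact
chord-sampled value ψ(n−2)/(n−1) used where machine-precision agreement is
asserted. These fixtures emulate compressed-filament geometries but not
thermal roughness, anchoring artifacts or lattice wiggle; tests passing on
them validate the metric implementations, not the realism of the
simulations.

## Numerical choices and limitations

* Degenerate inputs: coincident consecutive points raise with the particle
  index; collinear chains have undefined dihedral targets (flagged, not
  assigned); straight filaments have undefined supertwist (NaN) and zero
  peak asymmetry by convention.
* The monomer kernel runs with fastmath; NaN detection therefore lives in
  the chunk driver, which checks every 4000 steps and reports the step of
  a blow-up.
* Determinism: the explicit path consumes a seeded PCG64 noise stream
  positionally in fixed-size chunks; the implicit path draws from a seeded
  generator per step. Identical seeds give bit-identical trajectories,
  metrics and manifests.
* No excluded volume, no hydrodynamic coupling, no monomer kinetics, no
  crosslinkers; the filament cannot self-avoid, which at 70 % compression
  of long filaments would matter.
* The spring-anchored ends make the compression rate lag the nominal
  velocity by the anchor lag; the stop criterion guarantees the target
  end-to-end distance regardless.
* Persistence-length estimates on ~100-250 nm chains carry replicate SDs
  of 15-25 %; the calibration targets a window, not a point value.
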