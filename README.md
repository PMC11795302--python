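# actinshape

Coarse-grained Brownian-dynamics simulation and shape analysis of
compressed actin filaments at two resolutions, built for the question:
*which filament behaviours does a cheap fiber-scale model capture, and
which require monomer-scale resolution?*

Actin filaments are helical polymers (persistence length ~10-20 µm) whose
compression in cells involves bending, twisting and their coupling. The
package implements two models of a single filament under the same
compression protocol:

* **monomer scale (chiral)** — one bead per actin subunit placed on the
  F-actin genetic helix (rise 2.74 nm, twist −166.7°, radius 2.5 nm), held
  together by harmonic bonds and angles to the two nearest neighbours in
  each direction plus cosine dihedrals on each four consecutive beads, so
  the chain remembers the helix handedness. Integrated by explicit
  Euler–Maruyama (compiled kernel, timestep 2.5 × 10⁻¹¹ s).
* **fiber scale (achiral)** — a worm-like chain of 10 nm segments with
  harmonic stretching and quadratic curvature bending (κ = 0.075 pN µm²,
  L_p = κ/k_BT ≈ 18 µm), no dihedrals and hence no chirality. Integrated
  semi-implicitly (backward Euler with linearised forces) at the 5 × 10⁻⁷ s
  timestep fiber-scale engines use.

**Compression protocol.** The filament lies along +x; each end is tethered
by harmonic linkers to anchor points. The moved end's anchor points are
translated along −x for one time step and the chain relaxes for nine; the
per-cycle displacement is v·Δt·10 (e.g. 7.5 × 10⁻⁵ µm per cycle at
15 µm/s and Δt = 5 × 10⁻⁷ s). The run stops when the x-projected
end-to-end distance reaches 70 % of its initial value (500 nm → 350 nm at
full scale).

**Shape metrics** (simulator-independent, computed on the smoothed filament
axis): compression ratio `1 − d/d₀`; peak asymmetry `|2s* − 1|` of the
maximum chord deviation; non-coplanarity (variance fraction of the third
principal axis of one frame's points, 0 for planar, ≤ 1/3); signed
supertwist angle (tangent winding about the compression axis, accumulated
along the chain, positive = right-handed coil); worm-like-chain persistence
length from the tangent correlation ⟨t(s)·t(s+Δs)⟩ = e^(−Δs/L_p).

**Shape space.** Every frame is smoothed, resampled to 50 points, rotated
about x so its furthest yz-point lies on +y (chirality-preserving), and
pooled across simulators/velocities/replicates into a PCA
(`ShapeSpacePCA(...).fit()` → `ShapeSpaceResults` with `summary()`,
`project()`, `latent_walk()`, `feature_correlations()`).

## Worked example

```python
from actinshape import run_comparison

res = run_comparison(seed=0)     # ~15 min on one CPU
print(res.summary())
```

prints (seed 0):

```
Two-resolution compression comparison
  runs: 20 (5 replicates x 2 velocities x 2 resolutions)
  chiral late supertwist per replicate (deg): 182, 181, 181, 163, 164, 164, 181, 164, 182, 164
  achiral late supertwist per replicate (deg): 26, 43, -9, -77, -77, -9, 26, -9, -8, -60
  chiral supertwist sign-consistent: True
  achiral sign-test p = 0.344 (indistinguishable from 0 when > 0.05)
  median non-coplanarity: chiral 7.15e-06 vs achiral 2.49e-07
  corr(PC1, compression ratio) = 0.682 (dominant in PC1 row: True)
  late-time PC2 separation rank-sum p = 2.61e-70
```

Reading: the chiral monomer-scale model winds right-handed (positive) in
every replicate while the achiral fiber-scale model's winding direction is
a coin flip around zero, its late-time non-coplanarity sits ~30x above the
achiral model's, and the pooled shape space puts compression in PC1 and
the model divergence in PC2 — the monomer model expresses the helical
supertwist that the fiber model cannot.

A full pipeline (trajectory CSVs, metrics table, shape-space JSON, PC
scores, latent walks, a markdown report with figures, and a manifest of
seeds and content hashes) is one command:

```bash
actinshape run --preset desk --seed 0 --out run0
```

`--preset paper` selects the full-scale study (500 nm filament, velocities
4.7/15/47/150 µm/s, 5 replicates); its monomer-scale runs take hours.
Externally produced filament centerlines can be analysed by writing the
documented trajectory CSV (`time_s,point_index,x_nm,y_nm,z_nm` plus a JSON
sidecar) and running `actinshape measure` / `actinshape pca`.

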