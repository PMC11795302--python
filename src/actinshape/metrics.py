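"""Per-frame shape metrics for filament point chains.

All metrics operate on a bare ordered point chain and are therefore
simulator-independent: they apply equally to the monomer-scale chain (after
axis smoothing), the fiber-scale chain, and externally supplied centerlines.

Definitions
-----------
compression ratio
    1 - (end-to-end distance) / (initial end-to-end distance).
peak asymmetry
    |2 s* - 1| where s* is the arc-length fraction at which the chain
    deviates most from its end-to-end chord; 0 for a symmetric buckle,
    -> 1 for an end-localised bulge. Defined as 0 for straight chains.
non-coplanarity
    Fraction of positional variance along the third principal axis of the
    single frame's point cloud; 0 for planar shapes, at most 1/3.
supertwist angle
    Signed angle (degrees, right-handed about the compression axis) between
    the projections of the first and last tangent onto the plane
    perpendicular to that axis, accumulated along the chain so that
    coiling beyond +/-180 deg is tracked and the rotation sense is taken
    from the filament's actual geometry; positive = right-handed coil.
    Undefined (NaN) when either end tangent is parallel to the axis.
persistence length
    Decay length of tangent-tangent correlations <t(s) . t(s+ds)> =
    exp(-ds/Lp), fitted on the log of the pooled correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frames import FilamentFrame

#: Default smoothing window (beads) for monomer chains: covers several
#: periods of the genetic-helix zigzag so the output follows the filament
#: axis rather than the monomer lattice.
DEFAULT_AXIS_WINDOW = 13

#: Light smoothing for fiber chains: blends the clamped end bonds with their
#: mobile neighbours so the end tangents carry real shape information.
DEFAULT_FIBER_WINDOW = 3

#: Points per resampled chain used throughout the shape-space analysis
#: (10 nm sampling of a 500 nm filament).
DEFAULT_RESAMPLE_POINTS = 50


@dataclass
class MetricRecord:
    """Scalar shape metrics of one frame."""

    time: float
    normalized_time: float
    end_to_end: float
    compression_ratio: float
    peak_asymmetry: float
    non_coplanarity: float
    supertwist_angle: float      # degrees; NaN when undefined
    contour_length: float


def resample_polyline(frame: FilamentFrame, n_points: int) -> FilamentFrame:
    """Resample to ``n_points`` at equal arc-length spacing.

    Linear interpolation along the polyline; the endpoints are preserved
    exactly and resampling an already-uniform chain of the same size is the
    identity (up to float rounding).
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    pts = frame.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("cannot resample a zero-length chain")
    si = np.linspace(0.0, total, n_points)
    out = np.column_stack([np.interp(si, s, pts[:, c]) for c in range(3)])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return frame.with_points(out)


def monomers_to_axis(frame: FilamentFrame,
                     window: int = DEFAULT_AXIS_WINDOW) -> FilamentFrame:
    """Smoothed axis curve: centered sliding-window mean of bead positions.

    The window must be odd and span at least one period of the monomer
    helix's transverse zigzag; output has ``n - window + 1`` points and is
    flagged as an axis curve.
    """
    if window % 2 != 1 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if window > frame.n_points:
        raise ValueError(f"window {window} exceeds chain length "
                         f"{frame.n_points}")
    pts = frame.points
    kernel = np.ones(window) / window
    sm = np.column_stack([np.convolve(pts[:, c], kernel, mode="valid")
                          for c in range(3)])
    return frame.with_points(sm, is_axis_curve=True)


def compression_metrics(frame: FilamentFrame,
                        initial_end_to_end: float) -> tuple[float, float]:
    """(end_to_end, compression_ratio) relative to the initial distance."""
    if initial_end_to_end <= 0:
        raise ValueError("initial_end_to_end must be > 0")
    e2e = frame.end_to_end
    return e2e, 1.0 - e2e / initial_end_to_end


def peak_asymmetry(frame: FilamentFrame, rel_tol: float = 1e-6) -> float:
    """Normalised off-center position of the maximum chord deviation.

    |2 s* - 1| with s* the arc-length fraction of the point furthest from
    the end-to-end chord. Straight chains (max deviation below
    ``rel_tol * contour_length``) return 0 so time series start cleanly at
    the uncompressed state.
    """
    pts = frame.points
    chord = pts[-1] - pts[0]
    cn = np.linalg.norm(chord)
    rel = pts - pts[0]
    if cn > 0:
        ch = chord / cn
        perp = rel - np.outer(rel @ ch, ch)
    else:
        perp = rel
    d = np.linalg.norm(perp, axis=1)
    if d.max() < rel_tol * max(frame.contour_length, 1.0):
        return 0.0
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s_star = s[int(np.argmax(d))] / s[-1]
    return float(abs(2.0 * s_star - 1.0))


def non_coplanarity(frame: FilamentFrame) -> float:
    """Variance fraction along the third principal axis, in [0, 1/3]."""
    pts = frame.points - frame.points.mean(axis=0)
    cov = pts.T @ pts / pts.shape[0]
    lam = np.linalg.eigvalsh(cov)
    tot = lam.sum()
    if tot <= 0:
        return 0.0
    return float(max(lam[0], 0.0) / tot)


def supertwist_angle(frame: FilamentFrame,
                     axis_direction: np.ndarray = (1.0, 0.0, 0.0),
                     rel_tol: float = 1e-6) -> float:
    """Signed tangent winding about the compression axis, degrees.

    The signed angle from the first to the last segment-tangent projection
    onto the plane perpendicular to ``axis_direction``, measured
    right-handed about the axis (positive = right-handed coil). The angle
    is accumulated segment-by-segment along the chain (each increment in
    (-180, 180]), so it is single-valued: a coil winding through several
    turns reports its full accumulated angle rather than a wrapped value,
    and the direction in which the tangent sweeps past the axis is taken
    from the chain's actual geometry.

    Returns NaN (metric undefined) when the first or last projection is
    below ``rel_tol`` of its tangent's norm, e.g. for a straight chain
    along the axis; interior segments with exactly vanishing projection
    are skipped.
    """
    axis = np.asarray(axis_direction, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    t = np.diff(frame.points, axis=0)
    proj = t - np.outer(t @ axis, axis)
    pn = np.linalg.norm(proj, axis=1)
    tn = np.linalg.norm(t, axis=1)
    if pn[0] < rel_tol * tn[0] or pn[-1] < rel_tol * tn[-1]:
        return float("nan")
    p = proj[pn > 0]
    y = np.cross(p[:-1], p[1:]) @ axis
    x = np.einsum("ij,ij->i", p[:-1], p[1:])
    return float(np.degrees(np.arctan2(y, x)).sum())


def unwrap_angles(angles_deg: np.ndarray) -> np.ndarray:
    """Nearest-branch unwrapping of a signed-angle series with NaN gaps.

    Consecutive defined values are continued on the branch that minimises
    the frame-to-frame jump, so accumulated coiling beyond +/-180 deg is
    tracked. NaNs (undefined frames) are preserved and skipped over.
    """
    out = np.asarray(angles_deg, dtype=np.float64).copy()
    prev = None
    for i in range(out.size):
        if np.isnan(out[i]):
            continue
        if prev is not None:
            k = np.round((prev - out[i]) / 360.0)
            out[i] += 360.0 * k
        prev = out[i]
    return out


def normalized_time(times: np.ndarray, protocol) -> np.ndarray:
    """t / t_total clipped to [0, 1].

    t_total = (1 - fraction) * initial end-to-end / velocity, the time the
    protocol needs to reach the target compression.
    """
    t_total = protocol.total_time
    return np.clip(np.asarray(times, dtype=np.float64) / t_total, 0.0, 1.0)


#: Pipeline tolerance for "tangent parallel to the compression axis": the
#: supertwist azimuth is meaningless while the transverse tangent component
#: is within the smoothed monomer lattice's residual wiggle (~1%), so such
#: frames are flagged undefined rather than contributing noise to the
#: unwrapped series.
SUPERTWIST_PIPELINE_TOL = 0.02


def measure_frame(frame: FilamentFrame, initial_end_to_end: float,
                  n_resample: int = DEFAULT_RESAMPLE_POINTS,
                  smoothing_window: int | None = None,
                  normalized_t: float = float("nan"),
                  supertwist_tol: float = SUPERTWIST_PIPELINE_TOL
                  ) -> MetricRecord:
    """All shape metrics of one frame.

    Raw monomer chains should pass a ``smoothing_window`` so metrics are
    computed on the filament axis rather than the helical bead lattice;
    axis curves and fiber chains are used as-is. The chain is resampled to
    ``n_resample`` equal-arc-length points first.
    """
    work = frame
    if smoothing_window is not None and not frame.is_axis_curve:
        work = monomers_to_axis(work, smoothing_window)
    work = resample_polyline(work, n_resample)
    e2e, cr = compression_metrics(work, initial_end_to_end)
    return MetricRecord(
        time=frame.time,
        normalized_time=normalized_t,
        end_to_end=e2e,
        compression_ratio=cr,
        peak_asymmetry=peak_asymmetry(work),
        non_coplanarity=non_coplanarity(work),
        supertwist_angle=supertwist_angle(work, rel_tol=supertwist_tol),
        contour_length=work.contour_length,
    )


def measure_trajectory(traj, n_resample: int = DEFAULT_RESAMPLE_POINTS,
                       smoothing_window: int | None = None,
                       initial_end_to_end: float | None = None
                       ) -> pd.DataFrame:
    """Per-frame metric table for a trajectory, with unwrapped supertwist.

    ``smoothing_window`` defaults to :data:`DEFAULT_AXIS_WINDOW` for
    monomer-resolution trajectories and to no smoothing otherwise. The
    compression baseline defaults to the first frame's end-to-end distance.
    """
    if smoothing_window is None:
        if traj.resolution_label == "monomer":
            smoothing_window = DEFAULT_AXIS_WINDOW
        elif traj.resolution_label == "fiber":
            smoothing_window = DEFAULT_FIBER_WINDOW
    if initial_end_to_end is None:
        # baseline measured exactly like the per-frame values (smoothed and
        # resampled), so compression_ratio starts at 0
        first = traj.frames[0]
        if smoothing_window is not None and not first.is_axis_curve:
            first = monomers_to_axis(first, smoothing_window)
        initial_end_to_end = resample_polyline(
            first, n_resample).end_to_end
    if traj.protocol is not None:
        norm_t = normalized_time(traj.times, traj.protocol)
    else:
        norm_t = np.full(traj.n_frames, np.nan)
    records = [measure_frame(f, initial_end_to_end, n_resample,
                             smoothing_window, normalized_t=float(norm_t[i]))
               for i, f in enumerate(traj.frames)]
    df = pd.DataFrame([r.__dict__ for r in records])
    df["resolution"] = traj.resolution_label
    df["replicate"] = traj.replicate
    if traj.protocol is not None:
        df["velocity_um_s"] = traj.protocol.velocity
    else:
        df["velocity_um_s"] = np.nan
    return df


# ---------------------------------------------------------------------------
# persistence length
# ---------------------------------------------------------------------------

@dataclass
class PersistenceLengthEstimate:
    """Worm-like-chain persistence length from tangent correlations.

    Lp is in micrometres; ``infinite`` flags a chain whose tangent
    correlations never decay measurably (rigid rod).
    """

    Lp: float                      # um; inf when flagged rigid
    n_samples: int                 # frames pooled across replicates
    standard_deviation: float      # um, across replicates (0 if single)
    per_replicate: tuple = ()

    @property
    def infinite(self) -> bool:
        return not np.isfinite(self.Lp)

    def summary(self) -> str:
        if self.infinite:
            return ("Persistence length: not measurable (rigid rod; "
                    f"n = {self.n_samples} frames)")
        return (f"Persistence length: {self.Lp:.1f} +/- "
                f"{self.standard_deviation:.1f} um "
                f"(n = {self.n_samples} frames)")


def tangent_correlation(frames: list[FilamentFrame], max_lag: int
                        ) -> tuple[np.ndarray, np.ndarray]:
    """(separation nm, pooled <t.t>) for lags 1..max_lag."""
    corr_sum = np.zeros(max_lag)
    counts = np.zeros(max_lag)
    ds_sum = 0.0
    for f in frames:
        t = np.diff(f.points, axis=0)
        t /= np.linalg.norm(t, axis=1)[:, None]
        ds_sum += f.segment_lengths.mean()
        for k in range(1, max_lag + 1):
            dots = np.einsum("ij,ij->i", t[:-k], t[k:])
            corr_sum[k - 1] += dots.sum()
            counts[k - 1] += dots.size
    ds = ds_sum / len(frames)
    lags = ds * np.arange(1, max_lag + 1)
    return lags, corr_sum / np.maximum(counts, 1)


def persistence_length(replicate_frames: list[list[FilamentFrame]],
                       max_lag: int | None = None,
                       min_lag: int = 1,
                       rigid_tol: float = 1e-4) -> PersistenceLengthEstimate:
    """Fit <t(s) . t(s+ds)> = exp(-ds/Lp) pooled over frames.

    ``replicate_frames`` is a list of replicates, each a list of
    (axis-curve) frames; raw monomer chains must be smoothed first. The
    fit is least squares on ln C over lags ``min_lag``..``max_lag`` where
    the pooled correlation is positive; Lp is reported per replicate and
    summarised as mean +/- SD. If no correlation falls below
    ``1 - rigid_tol`` the chain is flagged rigid (Lp = inf).
    """
    lp_list = []
    n_frames_total = 0
    for frames in replicate_frames:
        n_seg = frames[0].n_points - 1
        ml = max_lag if max_lag is not None else max(n_seg - 1, 1)
        ml = min(ml, n_seg - 1)
        lags, corr = tangent_correlation(frames, ml)
        n_frames_total += len(frames)
        sel = slice(min_lag - 1, None)
        lags_f, corr_f = lags[sel], corr[sel]
        pos = corr_f > 0
        if np.all(corr_f[pos] > 1.0 - rigid_tol):
            lp_list.append(np.inf)
            continue
        x = lags_f[pos]
        y = np.log(corr_f[pos])
        slope = np.polyfit(x, y, 1)[0]
        lp_list.append(np.inf if slope >= 0 else -1.0 / slope / 1e3)  # um
    lp = np.asarray(lp_list, dtype=np.float64)
    if np.any(~np.isfinite(lp)):
        return PersistenceLengthEstimate(np.inf, n_frames_total, 0.0,
                                         tuple(lp_list))
    return PersistenceLengthEstimate(float(lp.mean()), n_frames_total,
                                     float(lp.std(ddof=1)) if lp.size > 1
                                     else 0.0,
                                     tuple(lp_list))
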