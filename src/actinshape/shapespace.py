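"""Shape-space analysis: alignment, pooled PCA, latent walks.

Every filament snapshot is reduced to a fixed-length aligned chain and the
pooled set (both resolutions, all velocities, replicates and time points) is
decomposed by PCA on the flattened coordinates. The alignment removes the
one symmetry the compression protocol does not fix - the azimuth about the
compression axis - by rotating each snapshot about x so its furthest point
in the yz-plane lies on the positive y-axis. Rotation about x is proper
(chirality-preserving), so supertwist sign survives alignment.

The model/results split follows statsmodels: :class:`ShapeSpacePCA` holds
the data and fit options, ``fit()`` returns :class:`ShapeSpaceResults` with
the mean shape, components, explained variance, per-sample scores, latent
walks (inverse transforms) and feature correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .frames import FilamentFrame
from .metrics import (DEFAULT_AXIS_WINDOW, DEFAULT_FIBER_WINDOW,
                      DEFAULT_RESAMPLE_POINTS, measure_trajectory,
                      monomers_to_axis, resample_polyline)

#: Metric columns carried alongside scores for correlation analysis.
FEATURE_COLUMNS = ("compression_ratio", "supertwist_angle",
                   "non_coplanarity", "peak_asymmetry", "normalized_time")


@dataclass
class ShapeSample:
    """One aligned, resampled filament snapshot ready for PCA."""

    aligned_points: np.ndarray        # (n_points, 3), nm
    source: str                       # "monomer" | "fiber" | "external"
    velocity: float                   # um/s (NaN for static shapes)
    replicate: int
    normalized_time: float

    @property
    def flattened(self) -> np.ndarray:
        return self.aligned_points.reshape(-1)


def align_filament(frame: FilamentFrame) -> FilamentFrame:
    """Rotate about +x so the furthest yz-point lies on the +y axis.

    The frame is first translated so its fixed end (first point) sits at the
    origin. Only y and z change; x-coordinates, arc length, end-to-end
    distance, planarity and |supertwist| are untouched, and supertwist keeps
    its sign (the rotation is proper). Chains lying exactly on the x-axis
    are returned unrotated.
    """
    pts = frame.points - frame.points[0]
    r_yz = np.hypot(pts[:, 1], pts[:, 2])
    k = int(np.argmax(r_yz))
    if r_yz[k] <= 1e-12:
        return frame.with_points(pts)
    alpha = np.arctan2(pts[k, 2], pts[k, 1])
    ca, sa = np.cos(alpha), np.sin(alpha)
    out = pts.copy()
    out[:, 1] = pts[:, 1] * ca + pts[:, 2] * sa
    out[:, 2] = -pts[:, 1] * sa + pts[:, 2] * ca
    return frame.with_points(out)


def _crop_ends(frame: FilamentFrame, trim_nm: float) -> FilamentFrame:
    """Drop ``trim_nm`` of arc length from each end (linear interpolation)."""
    if trim_nm <= 0:
        return frame
    pts = frame.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    lo, hi = trim_nm, s[-1] - trim_nm
    if hi - lo < 3 * np.mean(seg):
        raise ValueError("crop leaves too little of the chain")
    keep = (s > lo) & (s < hi)
    ends = np.column_stack([np.interp([lo, hi], s, pts[:, c])
                            for c in range(3)])
    out = np.vstack([ends[0], pts[keep], ends[1]])
    return frame.with_points(out)


def collect_shape_samples(trajectories,
                          n_points: int = DEFAULT_RESAMPLE_POINTS,
                          ) -> tuple[list[ShapeSample], pd.DataFrame]:
    """Aligned samples plus a per-sample metric table for a set of runs.

    Each trajectory contributes one sample per frame, processed as in the
    metric pipeline (axis smoothing for raw bead chains, equal arc-length
    resampling), then aligned. Because the smoothing trims a
    resolution-dependent amount from the chain ends, every processed chain
    is additionally cropped to the *largest common end-trim fraction* of
    its nominal length before resampling: without this the pooled PCA's
    leading mode is the systematic span difference between simulators
    rather than filament shape. The returned table carries the shape
    metrics of the same frames, row-aligned with the samples.
    """
    prep = []
    trim_frac = 0.0
    for traj in trajectories:
        window = None
        if traj.resolution_label == "monomer":
            window = DEFAULT_AXIS_WINDOW
        elif traj.resolution_label == "fiber":
            window = DEFAULT_FIBER_WINDOW
        nominal = abs(traj.frames[0].points[-1, 0]
                      - traj.frames[0].points[0, 0])
        smooth_trim = 0.0
        if window is not None and not traj.frames[0].is_axis_curve:
            # the sliding mean drops (window-1)/2 beads per end; the span
            # lost is their axial extent (not the zigzag arc length)
            smooth_trim = (window - 1) / 2 * nominal \
                / (traj.frames[0].n_points - 1)
        prep.append((traj, window, nominal, smooth_trim))
        trim_frac = max(trim_frac, smooth_trim / nominal)

    samples: list[ShapeSample] = []
    tables = []
    for traj, window, nominal, smooth_trim in prep:
        df = measure_trajectory(traj, n_resample=n_points)
        extra = max(trim_frac * nominal - smooth_trim, 0.0)
        for i, f in enumerate(traj.frames):
            work = f
            if window is not None and not work.is_axis_curve:
                work = monomers_to_axis(work, window)
            work = _crop_ends(work, extra)
            work = resample_polyline(work, n_points)
            aligned = align_filament(work)
            samples.append(ShapeSample(
                aligned_points=aligned.points,
                source=traj.resolution_label,
                velocity=df["velocity_um_s"].iloc[i],
                replicate=traj.replicate,
                normalized_time=df["normalized_time"].iloc[i]))
        tables.append(df)
    table = pd.concat(tables, ignore_index=True)
    return samples, table


class ShapeSpacePCA:
    """PCA model of aligned filament shapes.

    Parameters
    ----------
    samples : list of ShapeSample (or (n_samples, 3*n_points) array)
        Aligned, resampled shapes pooled across simulators and conditions.
    metrics : DataFrame, optional
        Row-aligned shape metrics; needed for the sign convention and for
        feature correlations.
    n_components : int
        Number of principal components to retain.

    Coordinates are centred but not scaled (they share units, nm).
    Component signs are fixed deterministically: PC1 to correlate
    positively with compression ratio, PC2 with the chiral (monomer-scale)
    supertwist, any further component so its largest-magnitude loading is
    positive.
    """

    def __init__(self, samples, metrics: pd.DataFrame | None = None,
                 n_components: int = 8):
        if len(samples) and isinstance(samples[0], ShapeSample):
            X = np.stack([s.flattened for s in samples])
            meta = pd.DataFrame({
                "source": [s.source for s in samples],
                "velocity_um_s": [s.velocity for s in samples],
                "replicate": [s.replicate for s in samples],
                "normalized_time": [s.normalized_time for s in samples]})
        else:
            X = np.asarray(samples, dtype=np.float64)
            meta = pd.DataFrame(index=range(X.shape[0]))
        if X.ndim != 2:
            raise ValueError("samples must flatten to a 2D matrix")
        if metrics is not None and len(metrics) != X.shape[0]:
            raise ValueError("metrics table must be row-aligned with samples")
        self.X = X
        self.meta = meta
        self.metrics = metrics.reset_index(drop=True) if metrics is not None \
            else None
        self.n_components = min(n_components, X.shape[1])
        if X.shape[0] <= self.n_components:
            raise ValueError(f"need more than {self.n_components} samples, "
                             f"got {X.shape[0]}")

    def fit(self) -> "ShapeSpaceResults":
        pca = PCA(n_components=self.n_components, svd_solver="full")
        scores = pca.fit_transform(self.X)
        components = pca.components_.copy()
        # deterministic sign convention
        for k in range(self.n_components):
            flip = None
            if self.metrics is not None:
                if k == 0:
                    flip = _corr_sign(scores[:, 0],
                                      self.metrics["compression_ratio"])
                elif k == 1 and "source" in self.meta:
                    chiral = (self.meta["source"] == "monomer").to_numpy()
                    if chiral.any():
                        flip = _corr_sign(
                            scores[chiral, 1],
                            self.metrics.loc[chiral, "supertwist_angle"])
            if flip is None:
                flip = 1.0 if components[k][np.argmax(np.abs(components[k]))] \
                    >= 0 else -1.0
            components[k] *= flip
            scores[:, k] *= flip
        return ShapeSpaceResults(
            model=self, mean_shape=pca.mean_, components=components,
            explained_variance=pca.explained_variance_.copy(),
            explained_variance_ratio=pca.explained_variance_ratio_.copy(),
            scores=scores)


def _corr_sign(x: np.ndarray, y: pd.Series) -> float | None:
    y = pd.to_numeric(y, errors="coerce").to_numpy()
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        return None
    r = np.corrcoef(x[ok], y[ok])[0, 1]
    return -1.0 if r < 0 else 1.0


@dataclass
class ShapeSpaceResults:
    """Fitted filament shape space.

    ``components`` are orthonormal rows over the flattened (x, y, z)
    coordinates; ``explained_variance_ratio`` is non-increasing and sums to
    at most 1.
    """

    model: ShapeSpacePCA
    mean_shape: np.ndarray                # (3*n_points,)
    components: np.ndarray                # (n_components, 3*n_points)
    explained_variance: np.ndarray        # score variances, nm^2
    explained_variance_ratio: np.ndarray
    scores: np.ndarray = field(repr=False)

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def n_points(self) -> int:
        return self.mean_shape.size // 3

    # -- projection ------------------------------------------------------

    def project(self, samples=None) -> pd.DataFrame:
        """Score table (PC1..PCk), joined with metrics when available.

        With no argument, returns the fitted samples' scores together with
        their metric columns, ready for feature-correlation analysis.
        """
        if samples is None:
            scores = self.scores
            parts = [self.model.meta.reset_index(drop=True)]
            if self.model.metrics is not None:
                cols = [c for c in self.model.metrics.columns
                        if c not in self.model.meta.columns]
                parts.append(self.model.metrics[cols])
        else:
            if len(samples) and isinstance(samples[0], ShapeSample):
                X = np.stack([s.flattened for s in samples])
            else:
                X = np.atleast_2d(np.asarray(samples, dtype=np.float64))
            if X.shape[1] != self.mean_shape.size:
                raise ValueError(
                    f"sample dimensionality {X.shape[1]} does not match "
                    f"the fitted space ({self.mean_shape.size})")
            scores = (X - self.mean_shape) @ self.components.T
            parts = []
        out = pd.DataFrame(
            scores, columns=[f"PC{k + 1}" for k in range(self.n_components)])
        for p in parts:
            out = pd.concat([out, p.reset_index(drop=True)], axis=1)
        return out

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
        return self.mean_shape + scores @ self.components

    # -- latent walks ----------------------------------------------------

    def latent_walk(self, component_index: int,
                    score_values: np.ndarray | None = None
                    ) -> list[FilamentFrame]:
        """Shapes along one component (default -2..+2 SD in 5 steps)."""
        if not 0 <= component_index < self.n_components:
            raise ValueError(f"component_index {component_index} out of "
                             f"range (n_components={self.n_components})")
        if score_values is None:
            sd = np.sqrt(self.explained_variance[component_index])
            score_values = np.linspace(-2.0, 2.0, 5) * sd
        frames = []
        for s in np.asarray(score_values, dtype=np.float64):
            flat = self.mean_shape + s * self.components[component_index]
            frames.append(FilamentFrame(
                flat.reshape(-1, 3), is_axis_curve=True,
                metadata={"latent_walk_component": component_index,
                          "score": float(s)}))
        return frames

    # -- feature analysis ------------------------------------------------

    def feature_correlations(self, features=FEATURE_COLUMNS) -> pd.DataFrame:
        """Pearson correlation of each PC score with each shape metric.

        Pairwise-complete over flagged-missing (NaN) values; correlations
        against a constant column are reported as NaN (undefined), never 0.
        """
        if self.model.metrics is None:
            raise ValueError("model was built without a metrics table")
        table = self.project()
        pcs = [f"PC{k + 1}" for k in range(self.n_components)]
        feats = [f for f in features if f in table.columns]
        sub = table[pcs + feats].apply(pd.to_numeric, errors="coerce")
        corr = sub.corr(min_periods=3).loc[pcs, feats]
        return corr

    # -- reporting -------------------------------------------------------

    def summary(self) -> str:
        lines = ["Filament shape space (PCA on aligned coordinates)",
                 f"  samples: {self.scores.shape[0]}, "
                 f"points per shape: {self.n_points}",
                 "  component  explained var. ratio"]
        for k in range(self.n_components):
            lines.append(f"  PC{k + 1:<8d} {self.explained_variance_ratio[k]:.4f}")
        if self.model.metrics is not None:
            corr = self.feature_correlations()
            lines.append("")
            lines.append("  feature correlations:")
            lines.append("  " + corr.round(3).to_string().replace("\n", "\n  "))
        return "\n".join(lines)
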