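"""Filament frames: the ordered 3D point chain that every stage consumes.

All coordinates are in nanometres, times in seconds. A frame is either a raw
bead chain (monomer positions) or a smoothed axis curve; downstream metrics
treat the two identically but the ``is_axis_curve`` flag records provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np


@dataclass
class FilamentFrame:
    """An ordered chain of 3D points for one filament at one time point.

    Parameters
    ----------
    points : (n, 3) float array, nm
        Ordered from the fixed end to the moved end.
    time : float, s
        Simulation time of the snapshot (0 for static shapes).
    is_axis_curve : bool
        True if the chain is already a smoothed centerline rather than raw
        monomer beads.
    metadata : dict
        Free-form annotations (ground-truth metrics for parametric shapes,
        resolution labels, ...).
    """

    points: np.ndarray
    time: float = 0.0
    is_axis_curve: bool = False
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {pts.shape}")
        if pts.shape[0] < 3:
            raise ValueError("a filament frame needs at least 3 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points contain non-finite values")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0.0):
            idx = int(np.argmin(seg))
            raise ValueError(f"consecutive points {idx} and {idx + 1} coincide")
        self.points = pts

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def contour_length(self) -> float:
        """Total polyline arc length in nm."""
        return float(self.segment_lengths.sum())

    @property
    def end_to_end(self) -> float:
        """Euclidean distance between first and last point, nm."""
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    def with_points(self, points: np.ndarray, **updates: Any) -> "FilamentFrame":
        """Copy of this frame with new coordinates (metadata preserved)."""
        return replace(self, points=np.asarray(points, dtype=np.float64),
                       metadata=dict(self.metadata), **updates)

    def translated(self, offset: np.ndarray) -> "FilamentFrame":
        return self.with_points(self.points + np.asarray(offset, dtype=np.float64))

    def rotated(self, rotation: np.ndarray) -> "FilamentFrame":
        """Apply a 3x3 rotation matrix about the origin."""
        R = np.asarray(rotation, dtype=np.float64)
        return self.with_points(self.points @ R.T)

    def mirrored(self, axis: int = 2) -> "FilamentFrame":
        """Reflection through a coordinate plane (default z -> -z).

        Flips chirality: supertwist changes sign, achiral metrics do not.
        """
        pts = self.points.copy()
        pts[:, axis] *= -1.0
        return self.with_points(pts)
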