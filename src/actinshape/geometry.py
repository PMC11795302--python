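"""Ideal helix construction and parametric fixture shapes.

The monomer-scale chain is initialized on an ideal actin-like helix
(rise 2.74 nm/subunit, twist -166.7 deg/subunit, radius 2.5 nm by default;
classic structural values for the F-actin genetic helix). The
parametric shapes (straight rod, planar arc, helical coil) are analytic
polylines with known ground-truth metrics, used as oracles for the metric
implementations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import FilamentFrame

#: Canonical F-actin geometry: genetic (short-pitch) helix. The radius is
#: the distance of a subunit's centre of mass from the filament axis
#: (~2.5 nm); it sets the strength of the twist-bend coupling that drives
#: supertwist, so it is kept structurally accurate rather than nominal.
DEFAULT_RISE_NM = 2.74
DEFAULT_TWIST_DEG = -166.7
DEFAULT_RADIUS_NM = 2.5


@dataclass(frozen=True)
class HelixGeometry:
    """Geometry of the ideal monomer helix.

    rise_per_subunit : nm of axial translation per subunit (> 0)
    twist_per_subunit : signed rotation per subunit in degrees; the sign sets
        the chirality of the chain (negative = left-handed genetic helix,
        as in F-actin)
    helix_radius : nm distance of each bead from the helix axis (>= 0)
    n_subunits : number of beads (>= 4, the minimum for one dihedral)
    """

    rise_per_subunit: float = DEFAULT_RISE_NM
    twist_per_subunit: float = DEFAULT_TWIST_DEG
    helix_radius: float = DEFAULT_RADIUS_NM
    n_subunits: int = 64

    def __post_init__(self) -> None:
        if self.rise_per_subunit <= 0:
            raise ValueError("rise_per_subunit must be > 0")
        if self.helix_radius < 0:
            raise ValueError("helix_radius must be >= 0")
        if self.n_subunits < 4:
            raise ValueError("n_subunits must be >= 4 (one dihedral)")

    @property
    def contour_rise(self) -> float:
        """Axial extent covered by the chain, nm."""
        return self.rise_per_subunit * (self.n_subunits - 1)

    @classmethod
    def for_length(cls, length_nm: float, **kwargs) -> "HelixGeometry":
        """Geometry whose axial extent is closest to ``length_nm``."""
        rise = kwargs.pop("rise_per_subunit", DEFAULT_RISE_NM)
        n = int(round(length_nm / rise)) + 1
        return cls(rise_per_subunit=rise, n_subunits=max(n, 4), **kwargs)


def build_ideal_helix(geometry: HelixGeometry) -> FilamentFrame:
    """Beads on an ideal helix whose axis is +x, starting at the origin.

    Bead ``k`` sits at x = k * rise, with the transverse position rotated by
    k * twist about +x (right-handed). Consecutive bead spacing is the helix
    chord length, constant along the chain.
    """
    k = np.arange(geometry.n_subunits, dtype=np.float64)
    theta = np.deg2rad(geometry.twist_per_subunit) * k
    pts = np.empty((geometry.n_subunits, 3))
    pts[:, 0] = geometry.rise_per_subunit * k
    pts[:, 1] = geometry.helix_radius * np.cos(theta)
    pts[:, 2] = geometry.helix_radius * np.sin(theta)
    return FilamentFrame(pts, metadata={"kind": "ideal_helix",
                                        "geometry": geometry})


def helix_chord_length(geometry: HelixGeometry) -> float:
    """Closed-form distance between consecutive beads of the ideal helix."""
    dtheta = np.deg2rad(geometry.twist_per_subunit)
    transverse = 2.0 * geometry.helix_radius * np.sin(abs(dtheta) / 2.0)
    return float(np.hypot(geometry.rise_per_subunit, transverse))


def generate_parametric_shape(kind: str, **params) -> FilamentFrame:
    """Analytic polylines with ground-truth metrics in ``metadata``.

    kind = "straight":
        length_nm (500), n_points (50): rod along +x.
        Ground truth: compression_ratio 0, supertwist undefined,
        non_coplanarity 0, peak_asymmetry 0.
    kind = "planar_arc":
        end_to_end_nm (350), height_nm (75), n_points (50): symmetric
        circular arc in the xy-plane from the origin to (end_to_end, 0, 0),
        bulging toward +y.
        Ground truth: non_coplanarity 0, peak_asymmetry 0; the supertwist
        magnitude is 180 deg (antiparallel end tangents) with degenerate
        sign.
    kind = "helical_coil":
        length_nm (350), coil_radius_nm (40), winding_deg (+60), n_points
        (50), phase_deg (0): helix around the +x axis whose tangent
        projection onto the yz-plane winds by ``winding_deg`` (signed,
        right-handed about +x; positive = right-handed coil) between the
        first and last point.
        Ground truth: supertwist = winding_deg (wrapped to (-180, 180]),
        non_coplanarity > 0.
    """
    if kind == "straight":
        length = params.pop("length_nm", 500.0)
        n = params.pop("n_points", 50)
        _reject_extra(params)
        pts = np.zeros((n, 3))
        pts[:, 0] = np.linspace(0.0, length, n)
        meta = {"kind": kind, "compression_ratio": 0.0, "peak_asymmetry": 0.0,
                "non_coplanarity": 0.0, "supertwist_deg": None,
                "end_to_end_nm": length}
        return FilamentFrame(pts, metadata=meta)

    if kind == "planar_arc":
        chord = params.pop("end_to_end_nm", 350.0)
        h = params.pop("height_nm", 75.0)
        n = params.pop("n_points", 50)
        _reject_extra(params)
        if h <= 0:
            raise ValueError("height_nm must be > 0")
        # circle through (0,0) and (chord,0) with sagitta h
        R = (h * h + (chord / 2.0) ** 2) / (2.0 * h)
        half = np.arcsin((chord / 2.0) / R)
        phi = np.linspace(-half, half, n)
        pts = np.zeros((n, 3))
        pts[:, 0] = chord / 2.0 + R * np.sin(phi)
        pts[:, 1] = h - R * (1.0 - np.cos(phi))
        # the arc's end tangents are antiparallel in projection, so the
        # supertwist magnitude is 180 deg with a degenerate (undefined) sign
        meta = {"kind": kind, "peak_asymmetry": 0.0, "non_coplanarity": 0.0,
                "supertwist_deg": None, "supertwist_abs_deg": 180.0,
                "end_to_end_nm": chord}
        return FilamentFrame(pts, metadata=meta)

    if kind == "helical_coil":
        length = params.pop("length_nm", 350.0)
        rc = params.pop("coil_radius_nm", 40.0)
        winding = params.pop("winding_deg", 60.0)
        n = params.pop("n_points", 50)
        phase = np.deg2rad(params.pop("phase_deg", 0.0))
        _reject_extra(params)
        if rc <= 0 or winding == 0.0:
            raise ValueError("helical_coil needs coil_radius_nm > 0 and "
                             "winding_deg != 0")
        u = np.linspace(0.0, 1.0, n)
        psi = np.deg2rad(winding)
        ang = phase + psi * u
        pts = np.empty((n, 3))
        pts[:, 0] = length * u
        pts[:, 1] = rc * np.cos(ang)
        pts[:, 2] = rc * np.sin(ang)
        # tangent yz-projection is d/du (cos, sin) -> winds by exactly psi
        wrapped = (np.rad2deg(psi) + 180.0) % 360.0 - 180.0
        if wrapped == -180.0:
            wrapped = 180.0
        meta = {"kind": kind, "supertwist_deg": float(wrapped),
                "winding_deg": float(winding), "end_to_end_nm": None}
        return FilamentFrame(pts, metadata=meta)

    raise ValueError(f"unknown parametric shape kind: {kind!r}")


def _reject_extra(params: dict) -> None:
    if params:
        raise TypeError(f"unexpected parameters: {sorted(params)}")
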