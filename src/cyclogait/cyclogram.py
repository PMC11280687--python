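"""Hip-knee cyclogram construction and geometric features.

A cyclogram is the closed curve traced by plotting the hip angle against
the knee angle over one gait cycle, starting at heel strike and
progressing from stance into swing. Twelve features are computed per
plane (range of motion, area centroid, time-average means, and
stance/swing/total perimeter and area), giving 36 features over the
sagittal, transverse and coronal planes.

Conventions for the open stance/swing sub-curves: each sub-curve is
closed by a chord from its last to its first point before the shoelace
formula is applied; that chord is *excluded* from the stance/swing
perimeters, while the curve-closure segment (last point back to heel
strike) *is* included in the total perimeter. Areas are reported as
absolute values because transverse/coronal cyclograms commonly
self-intersect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import N_POINTS, GaitCycle
from .synthetic import CHANNEL_ORDER, PLANES, ValidationError

SEGMENTS = ("stance", "swing", "total")

#: Per-plane feature order, frozen; full 36-vector is this list repeated
#: for each plane in PLANES order, names ``<plane>_<feature>``.
PLANE_FEATURES = (
    "rom_hip",
    "rom_knee",
    "com_hip",
    "com_knee",
    "mean_hip",
    "mean_knee",
    "perimeter_stance",
    "perimeter_swing",
    "perimeter_total",
    "area_stance",
    "area_swing",
    "area_total",
)

FEATURE_NAMES = tuple(f"{p}_{f}" for p in PLANES for f in PLANE_FEATURES)

_DEGENERATE_AREA = 1e-9


@dataclass
class Cyclogram:
    """Paired (hip, knee) angle trajectory for one plane and one cycle."""

    points: np.ndarray  # (n, 2): columns (hip, knee), degrees
    plane: str
    stance_boundary: int
    dt: float  # seconds between consecutive points (cycle duration / n)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError("cyclogram points must be (n, 2)")
        if not 0 <= self.stance_boundary < len(self.points):
            raise ValidationError("stance_boundary out of range")

    @property
    def hip(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def knee(self) -> np.ndarray:
        return self.points[:, 1]


def build_cyclogram(cycle: GaitCycle, plane: str) -> Cyclogram:
    """Extract the (hip, knee) pair for one plane from a 6-channel cycle."""
    if plane not in PLANES:
        raise ValidationError(f"unknown plane {plane!r}; expected one of {PLANES}")
    hip_c = CHANNEL_ORDER.index(f"hip_{plane}")
    knee_c = CHANNEL_ORDER.index(f"knee_{plane}")
    pts = cycle.angles[:, [hip_c, knee_c]]
    return Cyclogram(
        points=pts,
        plane=plane,
        stance_boundary=cycle.stance_boundary,
        dt=cycle.duration_s / N_POINTS,
    )


def _segment_points(cg: Cyclogram, segment: str) -> np.ndarray:
    if segment == "stance":
        return cg.points[: cg.stance_boundary + 1]
    if segment == "swing":
        return cg.points[cg.stance_boundary:]
    if segment == "total":
        return cg.points
    raise ValidationError(f"unknown segment {segment!r}; expected one of {SEGMENTS}")


def _polyline_length(pts: np.ndarray, closed: bool) -> float:
    d = np.diff(pts, axis=0)
    length = float(np.sqrt((d ** 2).sum(axis=1)).sum())
    if closed and len(pts) > 1:
        length += float(np.hypot(*(pts[0] - pts[-1])))
    return length


def perimeter(cg: Cyclogram, segment: str = "total") -> float:
    """Sum of straight-line distances between consecutive cyclogram points.

    ``total`` includes the closing segment from the last point back to the
    heel-strike point; stance/swing are open polyline lengths.
    """
    pts = _segment_points(cg, segment)
    return _polyline_length(pts, closed=(segment == "total"))


def perimeter_from_velocity(
    omega_hip: np.ndarray, omega_knee: np.ndarray, dt: float
) -> float:
    """Perimeter from per-interval average angular velocities.

    With omega_i = (theta_{i+1} - theta_i) / dt this is algebraically
    identical to the angle-difference form: each segment contributes
    dt * sqrt(omega_h^2 + omega_k^2).
    """
    wh = np.asarray(omega_hip, dtype=float)
    wk = np.asarray(omega_knee, dtype=float)
    if wh.shape != wk.shape:
        raise ValidationError("angular-velocity series length mismatch")
    return float(dt * np.sqrt(wh ** 2 + wk ** 2).sum())


def _shoelace_signed(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * yn - xn * y))


def area(cg: Cyclogram, segment: str = "total") -> float:
    """Absolute shoelace area of the (closed) segment sub-polygon.

    Open stance/swing sub-curves are closed by the chord from their last
    point to their first before the shoelace sum is taken.
    """
    pts = _segment_points(cg, segment)
    if len(pts) < 3:
        raise ValidationError(f"segment {segment!r} has fewer than 3 points")
    return abs(_shoelace_signed(pts))


def centroid_and_means(cg: Cyclogram) -> tuple[float, float, float, float, bool]:
    """(com_hip, com_knee, mean_hip, mean_knee, degenerate_flag).

    CoM is the area-weighted centroid of the closed polygon; the means are
    plain time-averages of the angle samples. For (near-)zero-area curves
    the centroid falls back to the vertex mean and the flag is set.
    """
    pts = cg.points
    mean_hip = float(pts[:, 0].mean())
    mean_knee = float(pts[:, 1].mean())
    a = _shoelace_signed(pts)
    if abs(a) < _DEGENERATE_AREA:
        return mean_hip, mean_knee, mean_hip, mean_knee, True
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    cx = float(np.sum((x + xn) * cross) / (6.0 * a))
    cy = float(np.sum((y + yn) * cross) / (6.0 * a))
    return cx, cy, mean_hip, mean_knee, False


def range_of_motion(cg: Cyclogram) -> tuple[float, float]:
    """(rom_hip, rom_knee): max minus min joint angle, degrees."""
    return (
        float(cg.hip.max() - cg.hip.min()),
        float(cg.knee.max() - cg.knee.min()),
    )


def cyclogram_features(cg: Cyclogram) -> dict[str, float]:
    """The 12 per-plane features for a single cyclogram, in PLANE_FEATURES order."""
    rom_h, rom_k = range_of_motion(cg)
    com_h, com_k, mean_h, mean_k, _ = centroid_and_means(cg)
    vals = {
        "rom_hip": rom_h,
        "rom_knee": rom_k,
        "com_hip": com_h,
        "com_knee": com_k,
        "mean_hip": mean_h,
        "mean_knee": mean_k,
    }
    for seg in SEGMENTS:
        vals[f"perimeter_{seg}"] = perimeter(cg, seg)
        vals[f"area_{seg}"] = area(cg, seg)
    return vals


def subject_feature_vector(
    cyclograms_by_plane: dict[str, list[Cyclogram]]
) -> np.ndarray:
    """Average the 12 per-cycle features over a subject's cycles, per plane.

    Returns the 36-vector in FEATURE_NAMES order. Raises if any plane has
    no valid cycles.
    """
    out = []
    for plane in PLANES:
        cgs = cyclograms_by_plane.get(plane, [])
        if not cgs:
            raise ValidationError(f"no valid cycles for plane {plane!r}")
        per_cycle = np.array(
            [[cyclogram_features(cg)[f] for f in PLANE_FEATURES] for cg in cgs]
        )
        out.append(per_cycle.mean(axis=0))
    return np.concatenate(out)


def cycle_feature_vector(cycle: GaitCycle) -> np.ndarray:
    """The 36-vector for a single gait cycle (FEATURE_NAMES order)."""
    out = []
    for plane in PLANES:
        cg = build_cyclogram(cycle, plane)
        feats = cyclogram_features(cg)
        out.extend(feats[f] for f in PLANE_FEATURES)
    return np.asarray(out)
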