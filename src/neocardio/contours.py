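"""Parametric 4-chamber ventricular contours.

The silhouette family is a superellipse truncated at the annulus chord: the
endocardial border runs from one annulus corner, around the apex, to the
other corner; the epicardial border is the outward normal offset of the
endocardium by the wall thickness.  A single "globularity" parameter in
[-1, 1] interpolates between a short, round ("globular", +1) and an
elongated, tapered ("conical", -1) ventricle by moving both the
length/width ratio and the superellipse exponent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString

__all__ = [
    "ContourSet",
    "generate_contour",
    "globularity_to_ratio",
    "globularity_to_exponent",
    "write_contours_csv",
    "read_contours_csv",
]

_DENSE = 1200  # dense parametric samples before arc-length resampling


def globularity_to_ratio(g: float) -> float:
    """Length/width ratio: +1 -> 1.2 (globular), -1 -> 1.9 (conical)."""
    return 1.55 - 0.35 * float(g)


def globularity_to_exponent(g: float) -> float:
    """Superellipse exponent: +1 -> 2.4 (boxy/round), -1 -> 1.6 (tapered)."""
    return 2.0 + 0.4 * float(g)


@dataclass
class ContourSet:
    """An open 2D border from one annulus corner, over the apex, to the other.

    points: (n, 2) array in cm; border: 'endocardial' or 'epicardial';
    landmarks: indices of annulus corner A (0), the apex, and corner B (n-1).
    """

    points: np.ndarray
    border: str
    landmarks: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if len(self.points) < 20:
            raise ValueError("a contour needs at least 20 points")
        if not self.landmarks:
            self.landmarks = {
                "corner_a": 0,
                "apex": int(self._apex_index()),
                "corner_b": len(self.points) - 1,
            }

    def _apex_index(self) -> int:
        mid = 0.5 * (self.points[0] + self.points[-1])
        return int(np.argmax(np.linalg.norm(self.points - mid, axis=1)))

    # -- geometric summaries -------------------------------------------
    @property
    def annulus_midpoint(self) -> np.ndarray:
        return 0.5 * (self.points[0] + self.points[-1])

    def annulus_width(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    def max_width(self) -> float:
        """Maximal extent perpendicular to the long axis (annulus direction)."""
        chord = self.points[-1] - self.points[0]
        n = np.linalg.norm(chord)
        if n == 0:
            raise ValueError("degenerate contour: coincident annulus corners")
        u = chord / n
        proj = self.points @ u
        return float(proj.max() - proj.min())

    def length(self) -> float:
        """Extent along the long axis: maximal perpendicular distance of any
        border point from the annulus chord line."""
        chord = self.points[-1] - self.points[0]
        u = chord / np.linalg.norm(chord)
        normal = np.array([-u[1], u[0]])
        d = (self.points - self.points[0]) @ normal
        return float(np.max(np.abs(d)))

    def length_width_ratio(self) -> float:
        return self.length() / self.max_width()

    def arc_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    def is_simple(self) -> bool:
        return bool(LineString(self.points).is_simple)


def _superellipse_dense(half_width: float, semi_len: float, m: float,
                        annulus_ratio: float) -> tuple[np.ndarray, np.ndarray]:
    """Dense endocardial arc and outward unit normals.

    Full superellipse |x/half_width|^m + |y/semi_len|^m = 1 kept above the
    annulus chord (the chord of width annulus_ratio * 2*half_width lying
    below the equator), traversed corner A -> apex -> corner B.
    """
    a = annulus_ratio
    # corner parameter: |cos t|^(2/m) = a  =>  |cos t| = a^(m/2)
    alpha = np.arcsin(np.sqrt(max(0.0, 1.0 - a ** m)))
    t = np.linspace(np.pi + alpha, -alpha, _DENSE)
    c, s = np.cos(t), np.sin(t)
    x = half_width * np.sign(c) * np.abs(c) ** (2.0 / m)
    y = semi_len * np.sign(s) * np.abs(s) ** (2.0 / m)
    pts = np.column_stack([x, y])
    # outward normal from the gradient of the implicit function
    gx = np.sign(x) * np.abs(x / half_width) ** (m - 1) / half_width
    gy = np.sign(y) * np.abs(y / semi_len) ** (m - 1) / semi_len
    grad = np.column_stack([gx, gy])
    grad /= np.linalg.norm(grad, axis=1, keepdims=True)
    return pts, grad


def _snap_extremes(pts: np.ndarray, half_width: float, apex_y: float) -> None:
    """Move the nearest samples onto the exact apex and equator points."""
    pts[np.argmax(pts[:, 1])] = (0.0, apex_y)
    left = np.where(pts[:, 0] < 0)[0]
    right = np.where(pts[:, 0] > 0)[0]
    if len(left):
        pts[left[np.argmin(pts[left, 0])]] = (-half_width, 0.0)
    if len(right):
        pts[right[np.argmax(pts[right, 0])]] = (half_width, 0.0)


def resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline to n points equally spaced in arc length."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise ValueError("degenerate (zero-length) contour")
    target = np.linspace(0.0, s[-1], n)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(target, s, points[:, 0])
    out[:, 1] = np.interp(target, s, points[:, 1])
    return out


def generate_contour(
    globularity: float,
    size_scale: float,
    annulus_ratio: float = 0.85,
    wall_thickness: float = 0.3,
    n_points: int = 50,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    length_width_ratio: float | None = None,
) -> tuple[ContourSet, ContourSet]:
    """Generate an (endocardial, epicardial) border pair.

    size_scale is the maximal endocardial width in cm; the apex-to-annulus
    length is length/width ratio times that.  Gaussian point noise of
    noise_sd cm is added i.i.d.; if the noisy curve self-intersects the draw
    is retried (up to 10 attempts) with fresh noise.
    """
    if n_points < 20:
        raise ValueError("n_points must be >= 20")
    if size_scale <= 0 or wall_thickness <= 0:
        raise ValueError("size_scale and wall_thickness must be > 0")
    if not -1.0 <= globularity <= 1.0:
        raise ValueError("globularity must lie in [-1, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rho = (length_width_ratio if length_width_ratio is not None
           else globularity_to_ratio(globularity))
    m = globularity_to_exponent(globularity)
    a = annulus_ratio
    half_width = size_scale / 2.0
    c = (1.0 - a ** m) ** (1.0 / m)  # chord depth fraction of the semi-length
    semi_len = rho * size_scale / (1.0 + c)

    endo_dense, normals = _superellipse_dense(half_width, semi_len, m, a)
    epi_dense = endo_dense + wall_thickness * normals

    endo_pts = resample_polyline(endo_dense, n_points)
    epi_pts = resample_polyline(epi_dense, n_points)
    # snap the nearest samples onto the analytic extremes (apex and the
    # equator, where the width is maximal) so the constructed length/width
    # ratio holds exactly on the discrete contour
    _snap_extremes(endo_pts, half_width, semi_len)
    _snap_extremes(epi_pts, half_width + wall_thickness,
                   semi_len + wall_thickness)

    for attempt in range(10):
        e = endo_pts + rng.normal(0.0, noise_sd, endo_pts.shape)
        p = epi_pts + rng.normal(0.0, noise_sd, epi_pts.shape)
        endo = ContourSet(e, "endocardial")
        epi = ContourSet(p, "epicardial")
        if noise_sd == 0.0 or (endo.is_simple() and epi.is_simple()):
            return endo, epi
    raise RuntimeError(
        "could not generate a simple (non-self-intersecting) contour in 10 attempts"
    )


# ---------------------------------------------------------------------------
# plain-text IO: CSV with columns point_index, x_cm, y_cm, border, landmark
# ---------------------------------------------------------------------------

def write_contours_csv(path, contour_pairs: dict) -> None:
    """Write {key: (endo, epi)} pairs to one CSV, key split into id columns."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "stage", "border", "point_index",
                    "x_cm", "y_cm", "landmark"])
        for (sid, stage), pair in contour_pairs.items():
            for cs in pair:
                marks = {v: k for k, v in cs.landmarks.items()}
                for i, (x, y) in enumerate(cs.points):
                    w.writerow([sid, stage, cs.border, i,
                                f"{x:.6f}", f"{y:.6f}", marks.get(i, "")])


def read_contours_csv(path) -> dict:
    import csv
    from collections import defaultdict

    rows = defaultdict(list)
    with open(path, newline="", encoding="utf-8") as fh:
        for r in csv.DictReader(fh):
            rows[(r["subject_id"], r["stage"], r["border"])].append(r)
    pairs: dict = {}
    for (sid, stage, border), rs in rows.items():
        rs.sort(key=lambda r: int(r["point_index"]))
        pts = np.array([[float(r["x_cm"]), float(r["y_cm"])] for r in rs])
        marks = {r["landmark"]: int(r["point_index"]) for r in rs if r["landmark"]}
        cs = ContourSet(pts, border, marks)
        key = (sid, stage)
        pairs.setdefault(key, [None, None])
        pairs[key][0 if border == "endocardial" else 1] = cs
    return {k: tuple(v) for k, v in pairs.items()}
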