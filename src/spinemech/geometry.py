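"""Planar spine-profile geometry: sharpness and curvature metrics.

A spine is represented by its outline in the *local sagittal plane* — the
plane that bisects the spine perpendicular to the surface it sits on, which
is also the plane in which puncture-test rotations happen.  By convention
the tip points toward −y at a test angle of 0°.

Three tool properties are computed from a profile:

``tip angle``
    the opening angle of the tapering flanks near the apex, in degrees.
    Scale-independent sharpness measure.
``tip radius of curvature``
    the radius of the circle best fitting the rounded apex.  Reported both
    in profile units (mm) and normalised by the longest-axis length, since
    only the normalised value is comparable across spines printed or scanned
    at a common length.
``structural curvature``
    the arc angle, in degrees, subtended by a circle fitted to the spine's
    centerline, followed from the tip toward the base for as long as the
    circle keeps bisecting the spine.  0° is a straight spine; a basal hook
    can exceed 100°.

Meshes (for volumes) are handled through :mod:`trimesh`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely.geometry as sgeom
import trimesh
from scipy import optimize
from scipy.spatial import ConvexHull

from .errors import DegenerateGeometryError, MeshError, ParameterError

__all__ = [
    "SpineProfile",
    "CircleFit",
    "Centerline",
    "ToolMetrics",
    "Morphotype",
    "MorphotypeThresholds",
    "fit_circle",
    "extract_centerline",
    "measure_tip_angle",
    "measure_tip_roc",
    "measure_structural_curvature",
    "measure_volume",
    "classify_morphotype",
    "measure_profile",
    "read_profile_csv",
    "write_profile_csv",
    "read_mesh",
    "metrics_table",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpineProfile:
    """Closed, simple 2D outline of a spine in its local sagittal plane.

    Parameters
    ----------
    vertices
        ``(n, 2)`` array of outline vertices, ordered around the boundary,
        without a repeated closing vertex.  Units are mm unless stated.
    tip_index
        Index of the apex vertex.
    spine_id
        Optional identifier carried into metric tables.
    validate
        When true (default), reject non-simple or degenerate polygons.
    """

    vertices: np.ndarray
    tip_index: int
    spine_id: str | None = None
    units: str = "mm"
    validate: bool = True

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise DegenerateGeometryError(
                "profile needs an (n, 2) vertex array with n >= 3"
            )
        object.__setattr__(self, "vertices", verts)
        if not 0 <= self.tip_index < verts.shape[0]:
            raise ParameterError(f"tip_index {self.tip_index} out of range")
        if self.validate:
            poly = sgeom.Polygon(verts)
            if (not poly.is_valid) or (not poly.is_simple) or poly.area <= 0:
                raise DegenerateGeometryError(
                    "profile polygon is not a simple closed polygon"
                )

    # -- derived quantities -------------------------------------------------

    @cached_property
    def polygon(self) -> sgeom.Polygon:
        return sgeom.Polygon(self.vertices)

    @cached_property
    def longest_axis(self) -> float:
        """Maximum distance between any two outline vertices (caliper length)."""
        pts = self.vertices
        if len(pts) > 16:
            try:
                pts = pts[ConvexHull(pts).vertices]
            except Exception:  # nearly degenerate hull; fall back to all points
                pass
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        return float(np.sqrt(d2.max()))

    @cached_property
    def boundary_lengths(self) -> np.ndarray:
        """Cumulative arclength over the closed boundary starting at vertex 0."""
        closed = np.vstack([self.vertices, self.vertices[:1]])
        seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def perimeter(self) -> float:
        return float(self.boundary_lengths[-1])

    def tip_sides(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Split the boundary at the apex into two equal-arclength chains.

        Returns ``(pts_a, s_a, pts_b, s_b)`` where each chain starts at the
        apex, ``s`` is arclength from the apex, and both chains end at the
        boundary point half the perimeter away from the apex (the *base
        point*).  The chains include that shared endpoint.
        """
        n = len(self.vertices)
        order = np.roll(np.arange(n), -self.tip_index)
        closed = np.vstack([self.vertices[order], self.vertices[order[:1]]])
        seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        half = s[-1] / 2.0
        base_pt = _point_at_arclength(closed, s, half)

        ia = np.searchsorted(s, half)  # first index with s >= half
        pts_a = np.vstack([closed[:ia], base_pt])
        s_a = np.concatenate([s[:ia], [half]])
        # chain B walks the boundary backwards from the apex
        rev = closed[::-1]
        s_rev = s[-1] - s[::-1]
        ib = np.searchsorted(s_rev, half)
        pts_b = np.vstack([rev[:ib], base_pt])
        s_b = np.concatenate([s_rev[:ib], [half]])
        return pts_a, s_a, pts_b, s_b


def _point_at_arclength(closed: np.ndarray, s: np.ndarray, target: float) -> np.ndarray:
    x = np.interp(target, s, closed[:, 0])
    y = np.interp(target, s, closed[:, 1])
    return np.array([x, y])


@dataclass(frozen=True)
class CircleFit:
    """Least-squares circle: algebraic seed + geometric (radial) refinement."""

    center: np.ndarray
    radius: float
    rmse: float
    n_points: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if not (self.radius > 0):
            raise DegenerateGeometryError("circle fit produced non-positive radius")


@dataclass(frozen=True)
class Centerline:
    """Midline of a profile with per-station half-widths, ordered base → tip
    (station 0 at the base midpoint, last station at the apex)."""

    points: np.ndarray      # (m, 2)
    halfwidth: np.ndarray   # (m,)

    @property
    def arclength(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def from_tip(self) -> tuple[np.ndarray, np.ndarray]:
        """Points and half-widths reordered tip → base."""
        return self.points[::-1], self.halfwidth[::-1]


@dataclass(frozen=True)
class ToolMetrics:
    """The per-spine tool-property record."""

    tip_angle_deg: float
    tip_roc_mm: float
    tip_roc_norm: float
    structural_curvature_deg: float
    aspect_ratio: float
    length_mm: float
    volume_mm3: float | None = None
    spine_id: str | None = None


@dataclass(frozen=True)
class Morphotype:
    """Binary shape categories used to decide whether a spine is 'markedly
    different' from its neighbours: elongate/short, hooked/straight-tipped,
    wavy/straight, conical/laterally compressed."""

    elongate: bool
    hooked: bool
    wavy: bool
    conical: bool


@dataclass(frozen=True)
class MorphotypeThresholds:
    """Configurable cut-offs for :func:`classify_morphotype`.

    ``elongate_aspect``: spines with max-width/length below this are elongate
    (short spines have aspect ratio roughly over 50%).
    ``hooked_deg``: structural curvature at/above this is a hook.
    ``wavy_sign_changes``: minimum number of centerline-curvature sign flips.
    ``wavy_turn_floor_deg``: per-station turning below this is noise.
    ``conical_ratio``: out-of-plane/in-plane width ratio at/above this is
    conical rather than laterally compressed.
    """

    elongate_aspect: float = 0.5
    hooked_deg: float = 60.0
    wavy_sign_changes: int = 2
    wavy_turn_floor_deg: float = 0.75
    conical_ratio: float = 0.8


# ---------------------------------------------------------------------------
# circle fitting
# ---------------------------------------------------------------------------


def fit_circle(points: Sequence[Sequence[float]] | np.ndarray) -> CircleFit:
    """Least-squares circle through 2D points.

    An algebraic (Kåsa) fit provides the seed, refined by minimising the
    true radial residuals with Levenberg–Marquardt.  ``rmse`` is the root
    mean square radial residual of the refined circle.

    Raises
    ------
    DegenerateGeometryError
        For fewer than three points or (near-)collinear input.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n < 3:
        raise DegenerateGeometryError("circle fit needs at least 3 points")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[0] <= 0 or sv[-1] <= 1e-9 * sv[0]:
        raise DegenerateGeometryError("cannot fit a circle to collinear points")

    # Kåsa: solve 2*cx*x + 2*cy*y + c = x^2 + y^2
    A = np.column_stack([2.0 * pts, np.ones(n)])
    b = (pts**2).sum(axis=1)
    (cx, cy, c), *_ = np.linalg.lstsq(A, b, rcond=None)
    r0 = float(np.sqrt(max(c + cx**2 + cy**2, np.finfo(float).tiny)))

    def radial(p: np.ndarray) -> np.ndarray:
        return np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1]) - p[2]

    sol = optimize.least_squares(radial, x0=[cx, cy, r0], method="lm")
    cx, cy, r = sol.x
    if r <= 0:
        raise DegenerateGeometryError("circle fit collapsed to non-positive radius")
    res = radial(sol.x)
    return CircleFit(
        center=np.array([cx, cy]),
        radius=float(r),
        rmse=float(np.sqrt(np.mean(res**2))),
        n_points=n,
    )


# ---------------------------------------------------------------------------
# centerline
# ---------------------------------------------------------------------------


def extract_centerline(
    profile: SpineProfile,
    n_stations: int = 80,
    refine: int = 25,
) -> Centerline:
    """Midline of the profile between the base midpoint and the apex.

    The midline is traced by tube-following from the apex: each step moves
    a short distance along the current axis tangent and recenters on the
    midpoint of the cross-section chord perpendicular to that tangent; the
    trace terminates where the axis exits through the base.  The polyline
    is then resampled to ``n_stations`` equally spaced stations (``refine``
    extra recentering passes polish them) and returned ordered base -> tip
    together with the local half-widths (half the chord lengths).

    With ``n_stations=2`` only the two endpoints (base midpoint and apex)
    are returned.

    Raises
    ------
    DegenerateGeometryError
        If a cross-section at some interior station is empty or does not
        contain the station (multiply connected cross-section).
    """
    if n_stations < 2:
        raise ParameterError("n_stations must be >= 2")
    poly = profile.polygon
    span = 4.0 * profile.longest_axis
    apex = profile.vertices[profile.tip_index].astype(float)
    frame = _FlankFrame(profile.vertices)

    # seed direction: midpoints of early equal-arclength chain pairs, which
    # are reliable close to the apex where both chains straddle the tip
    pts_a, s_a, pts_b, s_b = profile.tip_sides()
    half = s_a[-1]
    u0 = np.linspace(0.0, 0.04, 9)[1:] * half
    seeds = 0.5 * (
        np.column_stack(
            [np.interp(u0, s_a, pts_a[:, 0]), np.interp(u0, s_a, pts_a[:, 1])]
        )
        + np.column_stack(
            [np.interp(u0, s_b, pts_b[:, 0]), np.interp(u0, s_b, pts_b[:, 1])]
        )
    )
    tangent = seeds[-1] - apex
    nrm = np.linalg.norm(tangent)
    if nrm == 0:
        raise DegenerateGeometryError("cannot determine an axis direction at the apex")
    tangent /= nrm

    step = half / (2.0 * max(n_stations, 32))
    max_steps = 8 * max(n_stations, 32)
    mids = [apex]
    hws = [0.0]
    cur = apex
    hit_base = False
    for _ in range(max_steps):
        cand = cur + step * tangent
        if not poly.contains(sgeom.Point(cand)):
            hit_base = True
            break  # axis exits through the base
        chord = _min_chord(poly, cand, tangent, span)
        if chord is None:
            raise DegenerateGeometryError(
                "cross-section during centerline trace is not simply connected"
            )
        p0, p1 = chord
        new_hw = 0.5 * float(np.linalg.norm(p1 - p0))
        if new_hw < 0.75 * hws[-1]:
            # chord started clipping the base cap: stop recentering here
            hit_base = True
            break
        mid_pt = 0.5 * (p0 + p1)
        mids.append(mid_pt)
        hws.append(new_hw)
        direction = mid_pt - cur
        nd = np.linalg.norm(direction)
        if nd > 0:
            # momentum damps the recentering feedback, which oscillates raw
            blended = 0.75 * tangent + 0.25 * direction / nd
            tangent = blended / np.linalg.norm(blended)
        cur = mid_pt
    else:
        raise DegenerateGeometryError("centerline trace failed to terminate")
    if hit_base:
        # finish with a straight extension of the axis to the base surface
        ray = sgeom.LineString([cur + 1e-9 * span * tangent, cur + span * tangent])
        hit = poly.exterior.intersection(ray)
        if not hit.is_empty:
            pt = min(_points_of(hit), key=lambda p: float(np.linalg.norm(p - cur)))
            if np.linalg.norm(pt - cur) > 1e-9 * span:
                mids.append(pt)
                hws.append(hws[-1])

    mids_arr = np.asarray(mids)
    seg = np.linalg.norm(np.diff(mids_arr, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    grid = np.linspace(0.0, s[-1], n_stations)
    mid = np.column_stack(
        [np.interp(grid, s, mids_arr[:, 0]), np.interp(grid, s, mids_arr[:, 1])]
    )
    hw = np.interp(grid, s, np.asarray(hws))
    if n_stations > 2:
        # polish passes: perpendicular chords to tangents of a smoothed
        # midline, applied with under-relaxation — the raw recentering
        # feedback has gain above 1 in steep tapering regions and diverges
        relax = 0.4
        kernel = np.ones(9) / 9.0
        for _ in range(max(refine, 0)):
            moved = 0.0
            pad = np.vstack([mid[:1].repeat(4, axis=0), mid, mid[-1:].repeat(4, axis=0)])
            sx = np.convolve(pad[:, 0], kernel, mode="valid")
            sy = np.convolve(pad[:, 1], kernel, mode="valid")
            smooth = np.column_stack([sx, sy])
            smooth[:2], smooth[-2:] = mid[:2], mid[-2:]
            tang = np.gradient(smooth, axis=0)
            norms = np.linalg.norm(tang, axis=1)
            norms[norms == 0] = 1.0
            tang /= norms[:, None]
            for k in range(1, n_stations - 1):
                normal_k = np.array([-tang[k, 1], tang[k, 0]])
                chord = _cross_section_chord(poly, mid[k], normal_k, span)
                if chord is None:
                    raise DegenerateGeometryError(
                        f"cross-section at station {k} is not simply connected"
                    )
                p0, p1 = chord
                new_hw = 0.5 * np.linalg.norm(p1 - p0)
                if not 0.75 * hw[k] <= new_hw <= 1.5 * max(hw[k], 1e-12):
                    continue  # oblique or base-clipped chord; keep estimate
                target = 0.5 * (p0 + p1)
                step_vec = relax * (target - mid[k])
                moved = max(moved, float(np.linalg.norm(step_vec)))
                mid[k] = mid[k] + step_vec
                hw[k] = (1 - relax) * hw[k] + relax * new_hw
            if moved < 1e-8 * span:
                break
    hw[0] = 0.0
    return Centerline(points=mid[::-1].copy(), halfwidth=hw[::-1].copy())


def _min_chord(
    poly: sgeom.Polygon,
    point: np.ndarray,
    tangent: np.ndarray,
    span: float,
    max_tilt: float = np.radians(6.0),
) -> tuple[np.ndarray, np.ndarray] | None:
    """Shortest boundary-to-boundary chord through ``point``, searched over
    cutting directions within ``max_tilt`` of the perpendicular to
    ``tangent``.  The minimal chord is the true local cross-section of a
    tube, independent of small errors in the tangent estimate."""
    base = np.arctan2(tangent[1], tangent[0]) + np.pi / 2.0

    def chord_for(phi: float):
        ang = base + phi
        d = np.array([np.cos(ang), np.sin(ang)])
        return _cross_section_chord(poly, point, d, span)

    def length_of(phi: float) -> float:
        ch = chord_for(phi)
        if ch is None:
            return np.inf
        return float(np.linalg.norm(ch[1] - ch[0]))

    l_perp = length_of(0.0)
    res = optimize.minimize_scalar(
        length_of,
        bounds=(-max_tilt, max_tilt),
        method="bounded",
        options={"xatol": 2e-3},
    )
    # tilt only when it shortens the section decisively (a badly wrong
    # tangent); marginal "minima" come from taper corners or base-cap
    # clipping and would bias the midpoint off the true axis
    if np.isfinite(res.fun) and (not np.isfinite(l_perp) or res.fun < 0.98 * l_perp):
        return chord_for(float(res.x))
    return chord_for(0.0)


class _FlankFrame:
    """Nearest-boundary-edge lookup for a profile, used to place each
    centerline station at the point of the cross-section chord equidistant
    from the two flank tangent lines (the true bisecting locus; the plain
    chord midpoint is biased where taper and curvature interact)."""

    def __init__(self, vertices: np.ndarray):
        closed = np.vstack([vertices, vertices[:1]])
        self.a = closed[:-1]
        self.b = closed[1:]
        self.ab = self.b - self.a
        self.len2 = np.maximum((self.ab**2).sum(axis=1), 1e-300)

    def edge_dir(self, p: np.ndarray) -> np.ndarray:
        t = np.clip(((p - self.a) * self.ab).sum(axis=1) / self.len2, 0.0, 1.0)
        proj = self.a + t[:, None] * self.ab
        i = int(np.argmin(((proj - p) ** 2).sum(axis=1)))
        d = self.ab[i]
        return d / np.linalg.norm(d)

    def bisect_chord(
        self, p0: np.ndarray, p1: np.ndarray
    ) -> tuple[np.ndarray, float]:
        """Equidistant point between the flank tangent lines at the chord
        endpoints; returns the point and its distance to either line."""
        c = p1 - p0
        u0 = self.edge_dir(p0)
        u1 = self.edge_dir(p1)
        w0 = abs(u0[0] * c[1] - u0[1] * c[0])
        w1 = abs(u1[0] * c[1] - u1[1] * c[0])
        if w0 + w1 <= 1e-12 * np.linalg.norm(c):
            return 0.5 * (p0 + p1), 0.5 * float(np.linalg.norm(c))
        t = w1 / (w0 + w1)
        return p0 + t * c, float(t * w0)


def _points_of(geom) -> list[np.ndarray]:
    """All coordinates of a (multi)geometry as a flat point list."""
    if hasattr(geom, "geoms"):
        out = []
        for g in geom.geoms:
            out.extend(_points_of(g))
        return out
    return [np.asarray(c, dtype=float) for c in geom.coords]


def _cross_section_chord(
    poly: sgeom.Polygon,
    point: np.ndarray,
    direction: np.ndarray,
    span: float,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray] | None:
    """The boundary-to-boundary chord through ``point`` along ``direction``.

    Returns the endpoints of the intersection component that contains the
    point, or ``None`` when no component does.
    """
    line = sgeom.LineString(
        [point - span * direction, point + span * direction]
    )
    inter = poly.intersection(line)
    if inter.is_empty:
        return None
    if isinstance(inter, sgeom.LineString):
        parts = [inter]
    elif hasattr(inter, "geoms"):
        parts = [g for g in inter.geoms if isinstance(g, sgeom.LineString)]
    else:
        return None
    pt = sgeom.Point(point)
    best = None
    best_d = np.inf
    for g in parts:
        d = g.distance(pt)
        if d < best_d:
            best_d = d
            best = g
    if best is None or best_d > max(tol, 1e-9 * span):
        return None
    coords = np.asarray(best.coords)
    return coords[0], coords[-1]


# ---------------------------------------------------------------------------
# tip metrics
# ---------------------------------------------------------------------------


def _adaptive_tip_cap(
    profile: SpineProfile,
    cap_window: float = 0.35,
    rel_tol: float = 0.02,
    min_points: int = 7,
) -> tuple[CircleFit, float]:
    """Fit a circle to the rounded apex by growing outward from the tip.

    Boundary vertices are ordered by arclength distance from the apex
    (both sides interleaved).  The innermost ``min_points`` seed the fit;
    further vertices are admitted while they stay within ``rel_tol`` of the
    fitted radius, refitting as the set grows, out to at most
    ``cap_window`` × longest-axis arclength.

    Returns the fit and the largest admitted arclength distance from the
    apex (the detected cap extent).
    """
    L = profile.longest_axis
    pts_a, s_a, pts_b, s_b = profile.tip_sides()
    lim = cap_window * L
    cand_pts = np.vstack([pts_a[s_a <= lim], pts_b[1:][s_b[1:] <= lim]])
    cand_s = np.concatenate([s_a[s_a <= lim], s_b[1:][s_b[1:] <= lim]])
    order = np.argsort(cand_s, kind="stable")
    cand_pts, cand_s = cand_pts[order], cand_s[order]
    if len(cand_pts) < max(min_points, 3):
        raise DegenerateGeometryError("too few boundary points near the apex")

    k = min(max(min_points, 3), len(cand_pts))
    fit = None
    while fit is None and k <= len(cand_pts):
        try:
            fit = fit_circle(cand_pts[:k])
        except DegenerateGeometryError:
            k += 2
    if fit is None:
        raise DegenerateGeometryError("apex region is degenerate (collinear)")

    floor = 1e-7 * L
    while k < len(cand_pts):
        p = cand_pts[k]
        dev = abs(np.linalg.norm(p - fit.center) - fit.radius)
        if dev > max(rel_tol * fit.radius, floor):
            break
        k += 1
        if k % 4 == 0:
            fit = fit_circle(cand_pts[:k])
    fit = fit_circle(cand_pts[:k])
    return fit, float(cand_s[k - 1])


def measure_tip_roc(
    profile: SpineProfile,
    cap_window: float = 0.05,
    adaptive: bool = True,
    rel_tol: float = 0.02,
    full: bool = False,
):
    """Tip radius of curvature: circle fit to the rounded apex.

    Parameters
    ----------
    cap_window
        Maximum boundary arclength from the apex considered, as a fraction
        of the longest-axis length.
    adaptive
        Default: grow the fitted point set outward from the apex while the
        points keep lying on the fitted circle (robust to caps much smaller
        or larger than the window).  With ``adaptive=False`` all points in
        the window are fitted, reproducing a fixed measurement window.
    full
        Also return the underlying :class:`CircleFit`.

    Returns
    -------
    (tip_roc, tip_roc_norm) or (tip_roc, tip_roc_norm, CircleFit)
        Radius in profile units, and divided by the longest-axis length.

    A fit whose radial rmse exceeds 5% of the radius is flagged unreliable
    with a :class:`UserWarning` (e.g. a sharp wedge with no real cap).
    """
    L = profile.longest_axis
    if not 0 < cap_window < 1:
        raise ParameterError("cap_window must be in (0, 1)")
    if adaptive:
        fit, _ = _adaptive_tip_cap(profile, cap_window=cap_window, rel_tol=rel_tol)
    else:
        pts_a, s_a, pts_b, s_b = profile.tip_sides()
        lim = cap_window * L
        pts = np.vstack([pts_a[s_a <= lim], pts_b[1:][s_b[1:] <= lim]])
        if len(pts) < 3:
            raise DegenerateGeometryError("cap window contains too few points")
        fit = fit_circle(pts)
    if fit.rmse > 0.05 * fit.radius:
        warnings.warn(
            "tip circle fit unreliable (rmse > 5% of radius); "
            "the apex may not be a circular cap",
            stacklevel=2,
        )
    if full:
        return float(fit.radius), float(fit.radius / L), fit
    return float(fit.radius), float(fit.radius / L)


def measure_tip_angle(
    profile: SpineProfile,
    flank_window: float = 0.15,
    cap_exclusion: float | str = "auto",
    n_fit: int = 64,
) -> float:
    """Tip angle: the opening angle of the tapering flanks, in degrees.

    Total-least-squares lines are fitted to the two flank point sets near
    the apex and the angle between them returned (in (0, 180)).  Each
    flank's fit window starts just beyond the rounded cap and grows away
    from the apex only while the points keep lying on the fitted line, so
    the fit stops at the end of the tapering region (e.g. where a short
    wedge meets a parallel-sided shank) and never averages in geometry
    that is not flank.

    Parameters
    ----------
    flank_window
        Maximum arclength extent of each flank fit window, as a fraction
        of the longest-axis length.
    cap_exclusion
        Either a fraction of length to exclude around the apex (the fit
        window then starts at ``cap_exclusion × length`` from the apex and
        may not exceed ``flank_window × length``), or ``"auto"``
        (default): the rounded-cap extent found by the adaptive cap fit is
        excluded and the window starts just beyond it.
    """
    L = profile.longest_axis
    if not 0 < flank_window < 1:
        raise ParameterError("flank_window must be in (0, 1)")
    if cap_exclusion == "auto":
        try:
            _, s_cap = _adaptive_tip_cap(profile)
        except DegenerateGeometryError:
            s_cap = 0.0
        lo = 1.15 * s_cap + 0.005 * L
        hi = lo + flank_window * L
    else:
        if not 0 <= float(cap_exclusion) < flank_window:
            raise ParameterError("need 0 <= cap_exclusion < flank_window")
        lo = float(cap_exclusion) * L
        hi = flank_window * L

    pts_a, s_a, pts_b, s_b = profile.tip_sides()
    hi = min(hi, 0.95 * s_a[-1])
    if hi <= lo:
        raise DegenerateGeometryError("flank window collapsed; profile too short")

    apex = profile.vertices[profile.tip_index]
    spacing = max((hi - lo) / n_fit, 1e-4 * L)
    line_tol = 2e-3 * L

    def tls_dir(points: np.ndarray) -> np.ndarray:
        c = points - points.mean(axis=0)
        _, _, vt = np.linalg.svd(c, full_matrices=False)
        return vt[0]

    def line_residual(points: np.ndarray) -> np.ndarray:
        c = points - points.mean(axis=0)
        d = tls_dir(points)
        return np.abs(c[:, 0] * d[1] - c[:, 1] * d[0])

    dirs = []
    for pts, s in ((pts_a, s_a), (pts_b, s_b)):
        if s[-1] <= lo:
            raise DegenerateGeometryError("too few flank points in window")
        grid = np.arange(lo, hi + 0.5 * spacing, spacing)
        if len(grid) < 4:
            raise DegenerateGeometryError("too few flank points in window")
        fx = np.interp(grid, s, pts[:, 0])
        fy = np.interp(grid, s, pts[:, 1])
        flank = np.column_stack([fx, fy])
        k = min(max(6, n_fit // 8), len(flank))
        while k < len(flank):
            if line_residual(flank[: k + 1]).max() > line_tol:
                break
            k += 1
        flank = flank[:k]
        d = tls_dir(flank)
        if np.dot(d, flank.mean(axis=0) - apex) < 0:
            d = -d
        dirs.append(d)
    cosang = float(np.clip(np.dot(dirs[0], dirs[1]), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# structural curvature
# ---------------------------------------------------------------------------


def measure_structural_curvature(
    profile: SpineProfile,
    deviation_tol: float = 0.25,
    n_stations: int = 80,
    straight_radius_factor: float = 1e3,
    min_stations: int = 8,
    centerline: Centerline | None = None,
) -> float:
    """Structural curvature: arc angle of the circle bisecting the spine.

    A circle is fitted to the centerline starting from the tip and extended
    station by station toward the base for as long as every included
    station stays within ``deviation_tol`` of the local half-width of the
    fitted circle ("the circle still bisects the spine").  The returned
    value is the arc angle (degrees) accumulated around the fitted center
    between the tip and the last included station.

    Nearly straight spines (fit radius above ``straight_radius_factor`` ×
    length, or collinear stations) return 0.
    """
    cl = centerline if centerline is not None else extract_centerline(
        profile, n_stations=n_stations
    )
    pts, hw = cl.from_tip()
    n = len(pts)
    if n < min_stations:
        raise ParameterError("too few centerline stations")
    L = profile.longest_axis
    floor_w = 0.02 * L
    tol = deviation_tol * np.maximum(hw, floor_w)

    # largest tip-anchored prefix of stations whose best-fit circle still
    # bisects every included station ("bisects" = stays within deviation_tol
    # of the local half-width at each station)
    fit = None
    k = n
    while k >= min_stations:
        try:
            trial = fit_circle(pts[:k])
        except DegenerateGeometryError:
            return 0.0
        dev = np.abs(np.linalg.norm(pts[:k] - trial.center, axis=1) - trial.radius)
        if np.all(dev <= tol[:k]):
            fit = trial
            break
        k -= 1
    if fit is None:
        return 0.0

    if fit.radius > straight_radius_factor * L:
        return 0.0
    rel = pts[:k] - fit.center
    ang = 0.0
    for i in range(k - 1):
        v1, v2 = rel[i], rel[i + 1]
        ang += np.arctan2(abs(_cross2(v1, v2)), np.dot(v1, v2))
    return float(np.degrees(ang))


def _cross2(a: np.ndarray, b: np.ndarray) -> float:
    return float(a[0] * b[1] - a[1] * b[0])


# ---------------------------------------------------------------------------
# volume & morphotype
# ---------------------------------------------------------------------------


def measure_volume(mesh: trimesh.Trimesh) -> float:
    """Signed volume of a watertight, consistently oriented triangle mesh
    (divergence theorem over the triangles; positive for outward normals).

    Raises
    ------
    MeshError
        For non-watertight meshes, naming the number of boundary edges.
    """
    if not isinstance(mesh, trimesh.Trimesh):
        raise MeshError("measure_volume expects a trimesh.Trimesh")
    if not mesh.is_watertight:
        edges = mesh.edges_sorted
        _, counts = np.unique(edges, axis=0, return_counts=True)
        n_open = int((counts == 1).sum())
        raise MeshError(f"mesh is not watertight: {n_open} boundary (open) edges")
    return float(mesh.volume)


def classify_morphotype(
    metrics: ToolMetrics,
    centerline: Centerline,
    thresholds: MorphotypeThresholds | None = None,
    lateral_compression: float = 1.0,
) -> Morphotype:
    """Binary morphotype flags from measured metrics and the centerline.

    ``elongate`` — aspect ratio below the elongate threshold;
    ``hooked`` — structural curvature at/above the hook threshold;
    ``wavy`` — the centerline's turning direction flips at least twice
    (ignoring turns below the noise floor);
    ``conical`` — out-of-plane / in-plane width ratio at/above the conical
    threshold (pass the mesh-derived ratio as ``lateral_compression``).
    """
    thr = thresholds or MorphotypeThresholds()
    pts = centerline.points
    seg = np.diff(pts, axis=0)
    lens = np.linalg.norm(seg, axis=1)
    keep = lens > 0
    seg = seg[keep]
    turns = np.array(
        [
            np.degrees(
                np.arctan2(_cross2(seg[i], seg[i + 1]), np.dot(seg[i], seg[i + 1]))
            )
            for i in range(len(seg) - 1)
        ]
    )
    sig = turns[np.abs(turns) > thr.wavy_turn_floor_deg]
    sign_changes = int(np.sum(np.diff(np.sign(sig)) != 0)) if len(sig) > 1 else 0
    return Morphotype(
        elongate=bool(metrics.aspect_ratio < thr.elongate_aspect),
        hooked=bool(metrics.structural_curvature_deg >= thr.hooked_deg),
        wavy=bool(sign_changes >= thr.wavy_sign_changes),
        conical=bool(lateral_compression >= thr.conical_ratio),
    )


# ---------------------------------------------------------------------------
# orchestration & IO
# ---------------------------------------------------------------------------


def measure_profile(
    profile: SpineProfile,
    mesh: trimesh.Trimesh | None = None,
    cap_window: float = 0.05,
    flank_window: float = 0.15,
    cap_exclusion: float | str = "auto",
    deviation_tol: float = 0.25,
    n_stations: int = 80,
) -> tuple[ToolMetrics, Centerline]:
    """Compute the full tool-property record for one profile."""
    cl = extract_centerline(profile, n_stations=n_stations)
    L = profile.longest_axis
    roc, roc_norm = measure_tip_roc(profile, cap_window=cap_window)
    metrics = ToolMetrics(
        tip_angle_deg=measure_tip_angle(
            profile, flank_window=flank_window, cap_exclusion=cap_exclusion
        ),
        tip_roc_mm=roc,
        tip_roc_norm=roc_norm,
        structural_curvature_deg=measure_structural_curvature(
            profile, deviation_tol=deviation_tol, centerline=cl
        ),
        aspect_ratio=float(2.0 * cl.halfwidth.max() / L),
        length_mm=L,
        volume_mm3=measure_volume(mesh) if mesh is not None else None,
        spine_id=profile.spine_id,
    )
    return metrics, cl


def read_profile_csv(
    path: str | Path,
    spine_id: str | None = None,
    tip_index: int | None = None,
) -> SpineProfile:
    """Read a profile polygon from CSV with columns ``x_mm,y_mm`` (or ``x,y``).

    An ``is_tip`` marker column (as written by :func:`write_profile_csv`)
    identifies the apex.  Without it or an explicit ``tip_index``, the apex
    is taken as the vertex farthest from the polygon's area centroid (ties
    broken by smallest index) — a heuristic that can fail on strongly
    hooked outlines, so annotate the tip when you can.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    try:
        xc = cols.get("x_mm", cols.get("x"))
        yc = cols.get("y_mm", cols.get("y"))
        verts = df[[xc, yc]].to_numpy(dtype=float)
    except (KeyError, TypeError) as exc:
        raise DegenerateGeometryError(f"no x/y columns in {path}") from exc
    if tip_index is None and "is_tip" in cols:
        flags = df[cols["is_tip"]].astype(bool).to_numpy()
        if flags.sum() == 1:
            tip_index = int(np.argmax(flags))
    if tip_index is None:
        centroid = np.asarray(sgeom.Polygon(verts).centroid.coords[0])
        tip_index = int(np.argmax(np.linalg.norm(verts - centroid, axis=1)))
    return SpineProfile(vertices=verts, tip_index=tip_index, spine_id=spine_id)


def write_profile_csv(profile: SpineProfile, path: str | Path) -> None:
    df = pd.DataFrame(profile.vertices, columns=["x_mm", "y_mm"])
    df["is_tip"] = False
    df.loc[profile.tip_index, "is_tip"] = True
    df.to_csv(path, index=False)


def read_mesh(path: str | Path) -> trimesh.Trimesh:
    """Load an OBJ/PLY/STL mesh."""
    mesh = trimesh.load(str(path), force="mesh")
    if not isinstance(mesh, trimesh.Trimesh):
        raise MeshError(f"{path} did not contain a single triangle mesh")
    return mesh


def metrics_table(records: Sequence[tuple[ToolMetrics, Morphotype | None]]) -> pd.DataFrame:
    """Tidy one-row-per-spine table of metrics (+ optional morphotype flags)."""
    rows = []
    for metrics, morpho in records:
        row = {
            "spine_id": metrics.spine_id,
            "length_mm": metrics.length_mm,
            "tip_angle_deg": metrics.tip_angle_deg,
            "tip_roc_mm": metrics.tip_roc_mm,
            "tip_roc_norm": metrics.tip_roc_norm,
            "structural_curvature_deg": metrics.structural_curvature_deg,
            "volume_mm3": metrics.volume_mm3,
            "aspect_ratio": metrics.aspect_ratio,
        }
        if morpho is not None:
            row.update(
                elongate=morpho.elongate,
                hooked=morpho.hooked,
                wavy=morpho.wavy,
                conical=morpho.conical,
            )
        rows.append(row)
    return pd.DataFrame(rows)
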