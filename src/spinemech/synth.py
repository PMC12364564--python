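"""Synthetic spines and compression traces with exact ground truth.

The generator stands in for μCT-derived meshes and universal-testing-machine
raw data so that every downstream stage — shape metrics, puncture-event
detection, performance summaries, shape–performance regressions — can be
exercised and validated without any external download.

A generated spine is a tapering outline swept along a circular-arc
centerline:

* the centerline is an arc whose total arc angle *is* the structural
  curvature (0° = straight cone);
* near the apex the outline is a wedge of opening angle = tip angle, closed
  by an *exactly circular* cap of radius = the tip radius of curvature;
* the base carries a constant-width shank and a flat base cap;
* the centerline arclength is solved so that the emitted profile's
  longest-axis length equals the requested length exactly.

Simulated force–displacement traces rise as a convex power-law indentation
ramp; a puncture event is a configurable sharp force drop completed within
two samples, after which loading resumes.  Gaussian noise is seeded.
A full experiment replays the serial-angle protocol: every spine × angle
combination on a 10°-increment grid, three replicates, success determined
by whether the test angle is within the spine's ground-truth puncture
envelope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import json

import numpy as np
import pandas as pd
import shapely.geometry as sgeom
import trimesh
from scipy import optimize

from . import geometry
from .errors import DegenerateGeometryError, ParameterError
from .geometry import Centerline, SpineProfile
from .puncture import ForceTrace, TraceMeta

__all__ = [
    "SpineGenParams",
    "TraceGenParams",
    "ExperimentGenParams",
    "GroundTruthMetrics",
    "GroundTruthEvent",
    "TrialTable",
    "generate_spine_profile",
    "generate_spine_mesh",
    "simulate_force_trace",
    "simulate_experiment",
    "export_experiment",
]


# ---------------------------------------------------------------------------
# parameter records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpineGenParams:
    """Generative description of one spine profile.

    Lengths are mm.  ``tip_angle`` (degrees, 5–120) is the wedge opening
    angle, ``tip_roc`` the apex cap radius, ``structural_curvature``
    (degrees, 0–150) the centerline arc angle, ``base_width`` the shank
    width.  ``waviness`` adds a small sinusoidal lateral centerline
    perturbation (amplitude as a fraction of length).  ``lateral_compression``
    in (0, 1] is the out-of-plane/in-plane width ratio used when a mesh is
    built.  ``n_points`` is the outline vertex budget.
    """

    length: float = 3.22
    tip_angle: float = 30.0
    tip_roc: float = 0.10
    structural_curvature: float = 0.0
    base_width: float = 1.0
    waviness: float = 0.0
    lateral_compression: float = 1.0
    n_points: int = 512
    seed: int = 0

    def validate(self) -> None:
        p = self
        if not p.length > 0:
            raise ParameterError("length must be > 0")
        if not 5.0 <= p.tip_angle <= 120.0:
            raise ParameterError("tip_angle must be in [5, 120] degrees")
        if not p.tip_roc > 0:
            raise ParameterError("tip_roc must be > 0")
        if not 0.0 <= p.structural_curvature < 150.0:
            raise ParameterError("structural_curvature must be in [0, 150)")
        if not p.base_width > 0:
            raise ParameterError("base_width must be > 0")
        beta = np.radians(p.tip_angle) / 2.0
        # the cap must fit inside the tapering body: its tangency width may
        # not reach the shank width (blunt domes can still have
        # tip_roc approaching base_width when the tip angle is wide)
        if p.tip_roc * np.cos(beta) >= p.base_width / 2.0:
            raise ParameterError(
                "tip cap wider than the local profile width "
                "(tip_roc·cos(tip_angle/2) >= base_width/2)"
            )
        if p.waviness < 0:
            raise ParameterError("waviness must be >= 0")
        if not 0 < p.lateral_compression <= 1:
            raise ParameterError("lateral_compression must be in (0, 1]")
        if p.n_points < 64:
            raise ParameterError("n_points must be >= 64")


@dataclass(frozen=True)
class TraceGenParams:
    """Generative description of one force–displacement trace.

    The ramp is ``F(d) = puncture_force · (d / puncture_displacement) ^
    pre_stiffness_exponent`` (Hertz-like for the default 1.5).  A puncture
    event — force falling by ``drop_fraction`` of the peak within one
    sample step — is embedded iff ``drop_fraction > 0``; loading then
    resumes along the same ramp shape.  ``noise_sd`` is the s.d. of
    additive Gaussian noise (N).  The compression ``rate`` (mm·min⁻¹,
    default 10) is metadata; ``travel_limit`` must lie in [5, 15] mm.
    """

    puncture_force: float = 20.0
    puncture_displacement: float = 2.0
    pre_stiffness_exponent: float = 1.5
    drop_fraction: float = 0.4
    noise_sd: float = 0.0
    rate: float = 10.0
    travel_limit: float = 10.0
    sample_spacing: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        p = self
        if not p.puncture_force > 0:
            raise ParameterError("puncture_force must be > 0")
        if not 0 < p.puncture_displacement < p.travel_limit:
            raise ParameterError("puncture_displacement must be in (0, travel_limit)")
        if not p.pre_stiffness_exponent >= 1:
            raise ParameterError("pre_stiffness_exponent must be >= 1")
        if not 0 <= p.drop_fraction <= 1:
            raise ParameterError("drop_fraction must be in [0, 1]")
        if p.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not 5.0 <= p.travel_limit <= 15.0:
            raise ParameterError("travel_limit must be in [5, 15] mm")
        if not 0 < p.sample_spacing < p.travel_limit / 10:
            raise ParameterError("sample_spacing too large for travel limit")


@dataclass(frozen=True)
class ExperimentGenParams:
    """Design of a serial-angle compression experiment.

    ``angle_grid`` is a symmetric grid of test angles in 10° increments.
    A trial at angle a succeeds iff |a| <= the spine's maximum puncture
    angle, which grows with structural curvature:
    ``max_angle = base_max_angle + curvature_to_angle · structural_curvature``.
    The force required at 0° grows with tip angle (blunter = harder):
    ``F0 = base_force + tip_angle_to_force · tip_angle``, and with the test
    angle: ``F(a) = F0 + force_angle_slope · |a|``.
    """

    angle_grid: tuple[int, ...] = (-30, -20, -10, 0, 10, 20, 30)
    replicates: int = 3
    base_max_angle: float = 5.0
    curvature_to_angle: float = 0.25
    base_force: float = 5.0
    tip_angle_to_force: float = 0.4
    force_angle_slope: float = 0.1
    drop_fraction: float = 0.4
    noise_sd: float = 0.2
    puncture_displacement: float = 2.0
    pre_stiffness_exponent: float = 1.5
    travel_limit: float = 5.0
    sample_spacing: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        grid = np.asarray(self.angle_grid)
        if len(grid) == 0:
            raise ParameterError("angle_grid must not be empty")
        if np.any(grid % 10 != 0):
            raise ParameterError("angle_grid must contain multiples of 10 degrees")
        if sorted(self.angle_grid) != sorted(-a for a in self.angle_grid):
            raise ParameterError("angle_grid must be symmetric about 0")
        if self.replicates < 1:
            raise ParameterError("replicates must be >= 1")


# ---------------------------------------------------------------------------
# ground truth records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroundTruthMetrics:
    """Exact generative values for one emitted profile."""

    tip_angle_deg: float
    tip_roc_mm: float
    tip_roc_norm: float
    structural_curvature_deg: float
    length_mm: float
    base_width_mm: float
    lateral_compression: float
    centerline: np.ndarray          # (m, 2) exact centerline samples, tip → base
    arc_radius: float               # inf for a straight centerline
    arc_center: np.ndarray | None   # None for a straight centerline


@dataclass(frozen=True)
class GroundTruthEvent:
    """Embedded puncture event of a simulated trace."""

    force: float
    displacement: float
    drop_fraction: float


@dataclass
class TrialTable:
    """Simulated experiment: traces, per-trial metadata and ground truth."""

    traces: list[ForceTrace]
    meta: pd.DataFrame         # spine_id, angle_deg, replicate, success_truth, force_truth
    spine_truth: pd.DataFrame  # per-spine ground truth incl. true_range_deg


# ---------------------------------------------------------------------------
# profile generation
# ---------------------------------------------------------------------------


def _centerline_frame(
    t: np.ndarray, S: float, params: SpineGenParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Points, unit tangents and unit normals of the centerline at
    arclengths ``t`` (0 = apex end).  Tip points toward −y: the centerline
    leaves the apex along +y and bends by the structural-curvature arc."""
    theta = np.radians(params.structural_curvature)
    if theta < 1e-12:
        pts = np.column_stack([np.zeros_like(t), t])
    else:
        R = S / theta
        phi = t / R
        pts = np.column_stack([R * (1.0 - np.cos(phi)), R * np.sin(phi)])
    if params.waviness > 0:
        # lateral sinusoid, ~2.5 periods along the body, zero at the apex
        amp = params.waviness * S
        off = amp * np.sin(2.0 * np.pi * 2.5 * t / S) * (t / S)
        if theta < 1e-12:
            normal0 = np.array([1.0, 0.0])
            pts = pts + off[:, None] * normal0
        else:
            phi = t / (S / theta)
            normal0 = np.column_stack([np.cos(phi), -np.sin(phi)])
            pts = pts + off[:, None] * normal0
    # numeric tangents/normals (exact enough on a dense grid)
    tang = np.gradient(pts, t, axis=0)
    tang /= np.linalg.norm(tang, axis=1)[:, None]
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    return pts, tang, normal


def _build_outline(S: float, p: SpineGenParams) -> tuple[np.ndarray, np.ndarray]:
    """Outline vertices (apex at index 0) and exact centerline samples for a
    centerline of arclength ``S``.  Raises ParameterError when the tapering
    geometry cannot fit into ``S``."""
    beta = np.radians(p.tip_angle) / 2.0
    r = p.tip_roc
    wb2 = p.base_width / 2.0
    t_tan = r * (1.0 - np.sin(beta))
    h_tan = r * np.cos(beta)
    t_w = t_tan + (wb2 - h_tan) / np.tan(beta)
    if not t_w < 0.9 * S:
        raise ParameterError(
            "tapering wedge does not fit: profile too short for base_width/tip dims"
        )
    theta = np.radians(p.structural_curvature)
    if theta > 1e-12 and wb2 >= 0.8 * S / theta:
        raise ParameterError("base half-width too large for the centerline arc radius")

    dense_t = np.linspace(0.0, S, 2048)
    cpts, ctan, cnorm = _centerline_frame(dense_t, S, p)

    def frame_at(tq: np.ndarray):
        x = np.interp(tq, dense_t, cpts[:, 0])
        y = np.interp(tq, dense_t, cpts[:, 1])
        tx = np.interp(tq, dense_t, ctan[:, 0])
        ty = np.interp(tq, dense_t, ctan[:, 1])
        tv = np.column_stack([tx, ty])
        tv /= np.linalg.norm(tv, axis=1)[:, None]
        nv = np.column_stack([-tv[:, 1], tv[:, 0]])
        return np.column_stack([x, y]), tv, nv

    def halfwidth(tq: np.ndarray) -> np.ndarray:
        h = np.where(
            tq <= t_w, h_tan + (tq - t_tan) * np.tan(beta), wb2
        )
        return np.minimum(h, wb2)

    n = p.n_points
    n_cap_side = max(12, int(round(0.08 * n)))
    n_base = max(5, int(round(0.04 * n)))
    n_flank = max(8, (n - 2 * n_cap_side - n_base - 1) // 2)

    # exact circular cap centered on the centerline point at arclength r
    (cap_center,), (cap_T,), (cap_N,) = frame_at(np.array([r]))
    psi_max = np.pi / 2.0 - beta

    def cap_arc(psis: np.ndarray) -> np.ndarray:
        return (
            cap_center[None, :]
            - r * np.cos(psis)[:, None] * cap_T[None, :]
            + r * np.sin(psis)[:, None] * cap_N[None, :]
        )

    psis_plus = np.linspace(0.0, psi_max, n_cap_side + 1)
    cap_plus = cap_arc(psis_plus)                      # apex .. +N tangency
    psis_minus = np.linspace(-psi_max, 0.0, n_cap_side + 1)[:-1]
    cap_minus = cap_arc(psis_minus)                    # -N tangency .. just before apex

    t_flank = np.linspace(t_tan, S, n_flank + 1)
    fpts, _, fnorm = frame_at(t_flank)
    hw = halfwidth(t_flank)
    flank_plus = fpts + hw[:, None] * fnorm
    flank_minus = fpts - hw[:, None] * fnorm

    base_a = flank_plus[-1]
    base_b = flank_minus[-1]
    u = np.linspace(0.0, 1.0, n_base + 2)[1:-1]
    base_pts = base_a[None, :] + u[:, None] * (base_b - base_a)[None, :]

    outline = np.vstack(
        [
            cap_plus,               # apex first (tip_index = 0)
            flank_plus[1:],         # skip near-duplicate of cap tangency
            base_pts,
            flank_minus[::-1][:-1],
            cap_minus,
        ]
    )
    # collapse numerically coincident consecutive vertices (seam points)
    keep = np.ones(len(outline), dtype=bool)
    d = np.linalg.norm(np.diff(outline, axis=0), axis=1)
    keep[1:] = d > 1e-9 * S
    outline = outline[keep]
    return outline, cpts


def _longest_axis(verts: np.ndarray) -> float:
    try:
        from scipy.spatial import ConvexHull

        hull = verts[ConvexHull(verts).vertices]
    except Exception:
        hull = verts
    d2 = ((hull[:, None, :] - hull[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def generate_spine_profile(
    params: SpineGenParams,
) -> tuple[SpineProfile, GroundTruthMetrics]:
    """Generate a spine profile whose longest axis equals ``params.length``.

    The centerline arclength is solved (Brent's method) so that the caliper
    length of the emitted outline matches the requested length; tip radius,
    tip angle, base width and structural curvature are then exact by
    construction and recorded in the returned ground truth.
    """
    params.validate()

    def caliper(S: float) -> float:
        verts, _ = _build_outline(S, params)
        return _longest_axis(verts)

    beta = np.radians(params.tip_angle) / 2.0
    t_w = params.tip_roc * (1 - np.sin(beta)) + (
        params.base_width / 2 - params.tip_roc * np.cos(beta)
    ) / np.tan(beta)
    theta = np.radians(params.structural_curvature)
    s_arc_min = params.base_width / 2.0 * theta / 0.8 if theta > 1e-12 else 0.0
    s_lo = max(t_w / 0.9, s_arc_min, 0.02 * params.length) * 1.0001
    s_hi = 3.0 * params.length
    f_lo = caliper(s_lo) - params.length
    if f_lo > 0:
        raise ParameterError(
            "requested length is unreachable: base/tip dimensions already "
            "exceed it at the shortest feasible body"
        )
    f_hi = caliper(s_hi) - params.length
    if f_hi < 0:
        raise ParameterError("requested length unreachable within solver bracket")
    S = optimize.brentq(
        lambda s: caliper(s) - params.length, s_lo, s_hi, xtol=1e-10 * params.length
    )
    verts, cpts = _build_outline(S, params)

    poly = sgeom.Polygon(verts)
    if not (poly.is_valid and poly.is_simple):
        raise DegenerateGeometryError(
            "generated outline self-intersects; reduce waviness/curvature "
            "or base width"
        )
    # normalise to counter-clockwise orientation, keeping the apex at index 0
    if sgeom.LinearRing(verts).is_ccw is False:
        verts = np.vstack([verts[:1], verts[1:][::-1]])

    profile = SpineProfile(vertices=verts, tip_index=0)
    theta = np.radians(params.structural_curvature)
    if theta < 1e-12:
        arc_radius, arc_center = np.inf, None
    else:
        arc_radius = S / theta
        arc_center = np.array([arc_radius, 0.0])
    truth = GroundTruthMetrics(
        tip_angle_deg=params.tip_angle,
        tip_roc_mm=params.tip_roc,
        tip_roc_norm=params.tip_roc / params.length,
        structural_curvature_deg=params.structural_curvature,
        length_mm=params.length,
        base_width_mm=params.base_width,
        lateral_compression=params.lateral_compression,
        centerline=cpts,
        arc_radius=arc_radius,
        arc_center=arc_center,
    )
    return profile, truth


# ---------------------------------------------------------------------------
# mesh generation
# ---------------------------------------------------------------------------


def generate_spine_mesh(
    profile: SpineProfile,
    lateral_compression: float = 1.0,
    n_stations: int = 80,
    n_ring: int = 48,
) -> trimesh.Trimesh:
    """Watertight triangle mesh by sweeping elliptical cross-sections along
    the profile's centerline.

    In-plane semi-axis = the local half-width; out-of-plane semi-axis =
    half-width × ``lateral_compression`` (1 = circular sections).
    """
    if not 0 < lateral_compression <= 1:
        raise ParameterError("lateral_compression must be in (0, 1]")
    poly = sgeom.Polygon(profile.vertices)
    if not (poly.is_valid and poly.is_simple):
        raise DegenerateGeometryError("profile polygon is not simple; cannot sweep")

    cl = geometry.extract_centerline(profile, n_stations=n_stations)
    pts, hw = cl.from_tip()
    tang = np.gradient(pts, axis=0)
    tang /= np.linalg.norm(tang, axis=1)[:, None]
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])

    phis = np.linspace(0.0, 2.0 * np.pi, n_ring, endpoint=False)
    cphi, sphi = np.cos(phis), np.sin(phis)

    vertices: list[np.ndarray] = []
    apex3 = np.array([pts[0, 0], pts[0, 1], 0.0])
    vertices.append(apex3)
    ring_start = {}
    m = len(pts)
    for i in range(1, m):
        c3 = np.array([pts[i, 0], pts[i, 1], 0.0])
        n3 = np.array([normal[i, 0], normal[i, 1], 0.0])
        z3 = np.array([0.0, 0.0, 1.0])
        ring = (
            c3[None, :]
            + hw[i] * cphi[:, None] * n3[None, :]
            + hw[i] * lateral_compression * sphi[:, None] * z3[None, :]
        )
        ring_start[i] = len(vertices)
        vertices.extend(ring)
    base_center = np.array([pts[-1, 0], pts[-1, 1], 0.0])
    base_idx = len(vertices)
    vertices.append(base_center)
    V = np.asarray(vertices)

    faces: list[tuple[int, int, int]] = []
    r1 = ring_start[1]
    for j in range(n_ring):
        faces.append((0, r1 + j, r1 + (j + 1) % n_ring))
    for i in range(1, m - 1):
        ra, rb = ring_start[i], ring_start[i + 1]
        for j in range(n_ring):
            jn = (j + 1) % n_ring
            faces.append((ra + j, rb + j, rb + jn))
            faces.append((ra + j, rb + jn, ra + jn))
    rl = ring_start[m - 1]
    for j in range(n_ring):
        faces.append((base_idx, rl + (j + 1) % n_ring, rl + j))

    mesh = trimesh.Trimesh(vertices=V, faces=np.asarray(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        raise DegenerateGeometryError("swept mesh is not watertight")
    return mesh


# ---------------------------------------------------------------------------
# trace simulation
# ---------------------------------------------------------------------------


def simulate_force_trace(
    params: TraceGenParams,
    meta: TraceMeta | None = None,
) -> tuple[ForceTrace, list[GroundTruthEvent]]:
    """Simulate one compression trace, returning it with its embedded events.

    With ``drop_fraction == 0`` the noiseless trace is a monotone
    nondecreasing ramp and the event list is empty.
    """
    params.validate()
    p = params
    d = np.arange(0.0, p.travel_limit + 0.5 * p.sample_spacing, p.sample_spacing)
    ramp = lambda x: np.maximum(x, 0.0) ** p.pre_stiffness_exponent  # noqa: E731

    events: list[GroundTruthEvent] = []
    if p.drop_fraction > 0:
        i_drop = int(np.searchsorted(d, p.puncture_displacement))
        i_drop = min(max(i_drop, 1), len(d) - 2)
        d_peak = d[i_drop]
        scale = p.puncture_force / ramp(np.array([d_peak / p.puncture_displacement]))[0]
        force = scale * ramp(d / p.puncture_displacement)
        f_peak = force[i_drop]
        f_after = f_peak * (1.0 - p.drop_fraction)
        resume = f_after + scale * ramp((d - d[i_drop + 1]) / p.puncture_displacement)
        force = np.where(d > d_peak, resume, force)
        events.append(
            GroundTruthEvent(
                force=float(f_peak),
                displacement=float(d_peak),
                drop_fraction=p.drop_fraction,
            )
        )
    else:
        force = p.puncture_force * ramp(d / p.puncture_displacement)

    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        force = force + rng.normal(0.0, p.noise_sd, size=len(force))

    trace_meta = meta if meta is not None else TraceMeta(
        rate=p.rate, travel_limit=p.travel_limit
    )
    return ForceTrace(displacement=d, force=force, meta=trace_meta), events


# ---------------------------------------------------------------------------
# experiment simulation
# ---------------------------------------------------------------------------


def _spine_links(
    spine: SpineGenParams, xp: ExperimentGenParams
) -> tuple[float, float]:
    max_angle = xp.base_max_angle + xp.curvature_to_angle * spine.structural_curvature
    force_at_zero = xp.base_force + xp.tip_angle_to_force * spine.tip_angle
    return max_angle, force_at_zero


def true_range(angle_grid: Sequence[int], max_angle: float) -> float:
    """Ground-truth puncture range on a grid: span of successful angles,
    0 when at most one angle succeeds."""
    ok = sorted(a for a in angle_grid if abs(a) <= max_angle)
    if len(ok) <= 1:
        return 0.0
    return float(ok[-1] - ok[0])


def simulate_experiment(
    spines: Sequence[SpineGenParams],
    params: ExperimentGenParams | None = None,
) -> TrialTable:
    """Simulate the full serial-angle protocol over a set of spines.

    One trace per spine × angle × replicate.  Successful trials embed a
    drop at the angle-dependent required force; failed trials embed none.
    """
    xp = params or ExperimentGenParams()
    xp.validate()
    if len(spines) == 0:
        raise ParameterError("spine list must not be empty")

    ss = np.random.SeedSequence(xp.seed)
    traces: list[ForceTrace] = []
    meta_rows = []
    truth_rows = []
    angles = sorted(xp.angle_grid)
    for i, spine in enumerate(spines):
        spine_id = f"SYN_{i:02d}"
        max_angle, f0 = _spine_links(spine, xp)
        truth_rows.append(
            {
                "spine_id": spine_id,
                "tip_angle_deg": spine.tip_angle,
                "structural_curvature_deg": spine.structural_curvature,
                "max_puncture_angle_deg": max_angle,
                "force_at_zero_N": f0,
                "true_range_deg": true_range(angles, max_angle),
            }
        )
        for a in angles:
            success = abs(a) <= max_angle
            f_req = f0 + xp.force_angle_slope * abs(a)
            for rep in range(1, xp.replicates + 1):
                child = ss.spawn(1)[0]
                tp = TraceGenParams(
                    puncture_force=f_req,
                    puncture_displacement=xp.puncture_displacement,
                    pre_stiffness_exponent=xp.pre_stiffness_exponent,
                    drop_fraction=xp.drop_fraction if success else 0.0,
                    noise_sd=xp.noise_sd,
                    travel_limit=xp.travel_limit,
                    sample_spacing=xp.sample_spacing,
                    seed=int(child.generate_state(1)[0] % (2**31)),
                )
                tm = TraceMeta(
                    spine_id=spine_id,
                    angle_deg=a,
                    replicate=rep,
                    rate=10.0,
                    travel_limit=xp.travel_limit,
                )
                trace, events = simulate_force_trace(tp, meta=tm)
                traces.append(trace)
                meta_rows.append(
                    {
                        "spine_id": spine_id,
                        "angle_deg": a,
                        "replicate": rep,
                        "success_truth": success,
                        "force_truth": events[0].force if events else np.nan,
                    }
                )
    return TrialTable(
        traces=traces,
        meta=pd.DataFrame(meta_rows),
        spine_truth=pd.DataFrame(truth_rows),
    )


def generate_landmark_set(
    n_specimens: int = 15,
    k: int = 8,
    effect_size: float = 0.3,
    noise_sd: float = 0.02,
    seed: int = 0,
):
    """Landmark configurations with a known one-dimensional shape signal.

    Each specimen is a common template deformed along a single latent shape
    direction by a specimen-specific score, plus isotropic landmark noise,
    then arbitrarily rotated (proper rotation), scaled and translated — so
    alignment must undo a full similarity transform.  Returns the
    :class:`~spinemech.morpho.LandmarkSet` and the latent scores (the
    ground truth that PC1 should recover up to sign and scale).
    """
    from .morpho import LandmarkSet

    if k < 4:
        raise ParameterError("need at least 4 landmarks")
    rng = np.random.default_rng(seed)
    template = rng.normal(size=(k, 3))
    direction = rng.normal(size=(k, 3))
    direction /= np.linalg.norm(direction)
    scores = rng.normal(size=n_specimens)
    coords = []
    for i in range(n_specimens):
        c = template + effect_size * scores[i] * direction
        c = c + noise_sd * rng.normal(size=(k, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        c = (c @ q) * rng.uniform(0.5, 2.0) + rng.normal(size=3) * 5.0
        coords.append(c)
    lms = LandmarkSet(
        ids=tuple(f"spec{i:02d}" for i in range(n_specimens)),
        coords=np.stack(coords),
    )
    return lms, scores


def export_experiment(table: TrialTable, outdir: str | Path) -> Path:
    """Write an experiment to disk: one trace CSV per trial, a trial-metadata
    CSV and a JSON sidecar with the ground truth, for provenance."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, trace in enumerate(table.traces):
        name = (
            f"{trace.meta.spine_id}_a{trace.meta.angle_deg:+d}"
            f"_r{trace.meta.replicate}.csv"
        )
        pd.DataFrame(
            {"displacement_mm": trace.displacement, "force_N": trace.force}
        ).to_csv(out / name, index=False)
        rows.append(
            {
                "spine_id": trace.meta.spine_id,
                "angle_deg": trace.meta.angle_deg,
                "replicate": trace.meta.replicate,
                "trace_path": name,
            }
        )
    pd.DataFrame(rows).to_csv(out / "trials.csv", index=False)
    (out / "ground_truth.json").write_text(
        json.dumps(table.spine_truth.to_dict(orient="records"), indent=2)
    )
    return out
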