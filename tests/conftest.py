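"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from spinemech import synth


@pytest.fixture(scope="session")
def straight_cone():
    """Straight conical spine (zero structural curvature) with ground truth."""
    params = synth.SpineGenParams(
        length=3.22, tip_angle=60.0, structural_curvature=0.0,
        tip_roc=0.08, base_width=0.8,
    )
    return synth.generate_spine_profile(params)


@pytest.fixture(scope="session")
def arc_spine():
    """Hook-shaped spine on a 90-degree circular-arc centerline."""
    params = synth.SpineGenParams(
        length=3.22, tip_angle=30.0, structural_curvature=90.0,
        tip_roc=0.08, base_width=0.8,
    )
    return synth.generate_spine_profile(params)


def column_parity_volume(mesh, pitch: float) -> float:
    """Independent voxelization volume oracle.

    Rasterises the mesh over an (x, y) grid of column centers: for every
    column the surface z-crossings are found by barycentric interpolation
    over the triangles, sorted, and paired by parity; the enclosed volume
    is the summed inside-span length times the column footprint.  Exact in
    z, O(pitch) in the footprint — no dependency on the mesh library's own
    volume code.
    """
    tri = np.asarray(mesh.triangles, dtype=float)  # (m, 3, 3)
    lo, hi = np.asarray(mesh.bounds, dtype=float)
    # offset avoids grid lines hitting shared triangle edges exactly
    xs = np.arange(lo[0] + 0.377 * pitch, hi[0], pitch)
    ys = np.arange(lo[1] + 0.377 * pitch, hi[1], pitch)
    crossings: dict[tuple[int, int], list[float]] = {}
    for v0, v1, v2 in tri:
        det = (v1[0] - v0[0]) * (v2[1] - v0[1]) - (v2[0] - v0[0]) * (v1[1] - v0[1])
        if abs(det) < 1e-14:
            continue  # vertical triangle: zero-measure footprint
        t_lo_x = min(v0[0], v1[0], v2[0])
        t_hi_x = max(v0[0], v1[0], v2[0])
        t_lo_y = min(v0[1], v1[1], v2[1])
        t_hi_y = max(v0[1], v1[1], v2[1])
        i0 = np.searchsorted(xs, t_lo_x)
        i1 = np.searchsorted(xs, t_hi_x)
        j0 = np.searchsorted(ys, t_lo_y)
        j1 = np.searchsorted(ys, t_hi_y)
        if i0 >= i1 and j0 >= j1:
            pass
        gx, gy = np.meshgrid(xs[i0:i1], ys[j0:j1], indexing="ij")
        if gx.size == 0:
            continue
        px = gx.ravel() - v0[0]
        py = gy.ravel() - v0[1]
        a = ((v2[1] - v0[1]) * px - (v2[0] - v0[0]) * py) / det
        b = (-(v1[1] - v0[1]) * px + (v1[0] - v0[0]) * py) / det
        inside = (a >= 0) & (b >= 0) & (a + b <= 1)
        if not inside.any():
            continue
        z = v0[2] + a * (v1[2] - v0[2]) + b * (v2[2] - v0[2])
        ii = (np.repeat(np.arange(i0, i1), j1 - j0))[inside]
        jj = (np.tile(np.arange(j0, j1), i1 - i0))[inside]
        for iidx, jidx, zval in zip(ii, jj, z[inside]):
            crossings.setdefault((int(iidx), int(jidx)), []).append(float(zval))
    total = 0.0
    for zs in crossings.values():
        if len(zs) < 2:
            continue
        zs = sorted(zs)
        for k in range(0, len(zs) - 1, 2):
            total += zs[k + 1] - zs[k]
    return total * pitch * pitch
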