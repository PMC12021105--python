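"""Point-in-polygon tests for phasor-space gating and scene rasterization.

Even-odd (ray crossing) rule with boundary points counted as inside, so
gate definitions are portable across implementations.
"""

from __future__ import annotations

import numpy as np

__all__ = ["points_in_polygon"]


def points_in_polygon(points, vertices, atol: float = 1e-12) -> np.ndarray:
    """Vectorized even-odd containment of ``points`` in a closed polygon.

    Parameters
    ----------
    points : (N, 2) array
        Query points.
    vertices : (M, 2) array
        Polygon vertices in order; the closing edge back to the first
        vertex is implied.  Self-intersecting polygons are resolved by
        the even-odd rule.
    atol : float
        Distance tolerance for the boundary-inclusive test.
    """
    pts = np.asarray(points, dtype=float)
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise ValueError("polygon needs at least 3 (x, y) vertices")
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (N, 2) array")

    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    on_edge = np.zeros(len(pts), dtype=bool)
    v1 = verts
    v2 = np.roll(verts, -1, axis=0)
    for (x1, y1), (x2, y2) in zip(v1, v2):
        # boundary test: point within segment bounding box and collinear
        dx, dy = x2 - x1, y2 - y1
        seg_len2 = dx * dx + dy * dy
        if seg_len2 == 0.0:
            on_edge |= (np.abs(x - x1) <= atol) & (np.abs(y - y1) <= atol)
            continue
        t = ((x - x1) * dx + (y - y1) * dy) / seg_len2
        t = np.clip(t, 0.0, 1.0)
        d2 = (x - (x1 + t * dx)) ** 2 + (y - (y1 + t * dy)) ** 2
        on_edge |= d2 <= atol * atol
        # even-odd ray crossing (horizontal ray toward +x)
        cond = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_cross = x1 + (y - y1) * dx / dy if dy != 0 else np.inf
        inside ^= cond & (x < x_cross)
    return inside | on_edge
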