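"""Deterministic software rasterizer for surface snapshots.

Orthographic projection, per-triangle z-buffer, Gouraud (barycentric)
interpolation of per-vertex RGBA.  No GPU, no hidden state: identical
inputs produce byte-identical images, which is what the PNG export
contract requires.  Background pixels keep alpha 0.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rasterize", "VIEW_ROTATIONS", "view_rotation"]

# world axes: +x right, +y anterior, +z superior; lh occupies x<0, rh x>0.
VIEW_ROTATIONS: dict[tuple[str, str], np.ndarray] = {}


def _rot(sx, sy, depth) -> np.ndarray:
    """Rows: screen-x, screen-y, depth (larger depth = closer to viewer)."""
    return np.array([sx, sy, depth], dtype=float)


VIEW_ROTATIONS[("superior", "lh")] = VIEW_ROTATIONS[("superior", "rh")] = _rot(
    [1, 0, 0], [0, 1, 0], [0, 0, 1]
)
VIEW_ROTATIONS[("inferior", "lh")] = VIEW_ROTATIONS[("inferior", "rh")] = _rot(
    [-1, 0, 0], [0, 1, 0], [0, 0, -1]
)
# lateral = viewed from outside the hemisphere; medial = from midline
VIEW_ROTATIONS[("lateral", "lh")] = _rot([0, -1, 0], [0, 0, 1], [-1, 0, 0])
VIEW_ROTATIONS[("medial", "lh")] = _rot([0, 1, 0], [0, 0, 1], [1, 0, 0])
VIEW_ROTATIONS[("lateral", "rh")] = _rot([0, 1, 0], [0, 0, 1], [1, 0, 0])
VIEW_ROTATIONS[("medial", "rh")] = _rot([0, -1, 0], [0, 0, 1], [-1, 0, 0])


def view_rotation(view: str, hemisphere: str) -> np.ndarray:
    key = (view, hemisphere)
    if key not in VIEW_ROTATIONS:
        raise ValueError(
            f"unknown view {view!r} for hemisphere {hemisphere!r}; "
            "expected superior, inferior, lateral or medial"
        )
    return VIEW_ROTATIONS[key]


def rasterize(
    vertices: np.ndarray,
    faces: np.ndarray,
    rgba: np.ndarray,
    rotation: np.ndarray,
    size: int = 400,
    pad: float = 0.05,
) -> np.ndarray:
    """Render to an RGBA uint8 image of shape (size, size, 4)."""
    v = np.asarray(vertices, float) @ np.asarray(rotation, float).T
    xy, depth = v[:, :2], v[:, 2]
    lo = xy.min(axis=0)
    hi = xy.max(axis=0)
    span = float(max((hi - lo).max(), 1e-12))
    scale = (1.0 - 2.0 * pad) * (size - 1) / span
    centre = (lo + hi) / 2.0
    px = (xy - centre) * scale + (size - 1) / 2.0
    # image row 0 at top: flip y
    px[:, 1] = (size - 1) - px[:, 1]

    img = np.zeros((size, size, 4), dtype=np.uint8)
    zbuf = np.full((size, size), -np.inf)
    rgba = np.asarray(rgba, float)

    for tri in faces:
        p = px[tri]          # 3x2
        z = depth[tri]
        c = rgba[tri]        # 3x4
        xmin = max(int(np.floor(p[:, 0].min())), 0)
        xmax = min(int(np.ceil(p[:, 0].max())), size - 1)
        ymin = max(int(np.floor(p[:, 1].min())), 0)
        ymax = min(int(np.ceil(p[:, 1].max())), size - 1)
        if xmin > xmax or ymin > ymax:
            continue
        det = (p[1, 0] - p[0, 0]) * (p[2, 1] - p[0, 1]) - (
            p[2, 0] - p[0, 0]
        ) * (p[1, 1] - p[0, 1])
        if abs(det) < 1e-12:
            continue
        gx, gy = np.meshgrid(
            np.arange(xmin, xmax + 1), np.arange(ymin, ymax + 1)
        )
        w1 = ((gx - p[0, 0]) * (p[2, 1] - p[0, 1]) -
              (p[2, 0] - p[0, 0]) * (gy - p[0, 1])) / det
        w2 = ((p[1, 0] - p[0, 0]) * (gy - p[0, 1]) -
              (gx - p[0, 0]) * (p[1, 1] - p[0, 1])) / det
        w0 = 1.0 - w1 - w2
        inside = (w0 >= -1e-9) & (w1 >= -1e-9) & (w2 >= -1e-9)
        if not inside.any():
            continue
        zs = w0 * z[0] + w1 * z[1] + w2 * z[2]
        rows, cols = gy[inside], gx[inside]
        zvals = zs[inside]
        closer = zvals > zbuf[rows, cols]
        if not closer.any():
            continue
        rows, cols, zvals = rows[closer], cols[closer], zvals[closer]
        wi = np.stack([w0[inside][closer], w1[inside][closer], w2[inside][closer]])
        colors = np.clip(np.einsum("kn,kc->nc", wi, c), 0, 255)
        zbuf[rows, cols] = zvals
        img[rows, cols] = colors.astype(np.uint8)
    return img
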