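"""Software rasterizer kernel (numba).

Screen-space barycentric triangle fill with a z-buffer.  Depth is
interpolated affinely in screen space, which is accurate to second order
for the small triangles produced by the mesh generators and keeps the
depth test used for back-projection consistent with rasterization.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["rasterize"]


@njit(cache=True)
def _fill(uv, z, faces, height, width, depth, pix2face, bary):  # pragma: no cover
    for m in range(faces.shape[0]):
        i0, i1, i2 = faces[m, 0], faces[m, 1], faces[m, 2]
        z0, z1, z2 = z[i0], z[i1], z[i2]
        if z0 <= 1e-6 or z1 <= 1e-6 or z2 <= 1e-6:
            continue  # behind the camera
        x0, y0 = uv[i0, 0], uv[i0, 1]
        x1, y1 = uv[i1, 0], uv[i1, 1]
        x2, y2 = uv[i2, 0], uv[i2, 1]
        area = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
        if area == 0.0:
            continue
        xmin = int(max(0.0, np.floor(min(x0, min(x1, x2)))))
        xmax = int(min(width - 1.0, np.ceil(max(x0, max(x1, x2)))))
        ymin = int(max(0.0, np.floor(min(y0, min(y1, y2)))))
        ymax = int(min(height - 1.0, np.ceil(max(y0, max(y1, y2)))))
        if xmin > xmax or ymin > ymax:
            continue
        inv = 1.0 / area
        for py in range(ymin, ymax + 1):
            for px in range(xmin, xmax + 1):
                cx = px + 0.0
                cy = py + 0.0
                w0 = ((x1 - cx) * (y2 - cy) - (x2 - cx) * (y1 - cy)) * inv
                w1 = ((x2 - cx) * (y0 - cy) - (x0 - cx) * (y2 - cy)) * inv
                w2 = 1.0 - w0 - w1
                if w0 < 0.0 or w1 < 0.0 or w2 < 0.0:
                    continue
                d = w0 * z0 + w1 * z1 + w2 * z2
                if d < depth[py, px]:
                    depth[py, px] = d
                    pix2face[py, px] = m
                    bary[py, px, 0] = w0
                    bary[py, px, 1] = w1
                    bary[py, px, 2] = w2


def rasterize(uv: np.ndarray, z: np.ndarray, faces: np.ndarray, height: int, width: int):
    """Rasterize projected triangles.

    Parameters
    ----------
    uv : (N, 2) float64
        Vertex pixel coordinates (x = column, y = row); pixel centers are
        at integer coordinates.
    z : (N,) float64
        Camera-space depth per vertex (positive in front of the camera).
    faces : (M, 3) int64
    height, width : int

    Returns
    -------
    depth : (H, W) float64, ``inf`` on background
    pix2face : (H, W) int64, ``-1`` on background
    bary : (H, W, 3) float64 barycentric weights of the winning face
    """
    depth = np.full((height, width), np.inf)
    pix2face = np.full((height, width), -1, dtype=np.int64)
    bary = np.zeros((height, width, 3))
    _fill(
        np.ascontiguousarray(uv, dtype=np.float64),
        np.ascontiguousarray(z, dtype=np.float64),
        np.ascontiguousarray(faces, dtype=np.int64),
        height, width, depth, pix2face, bary,
    )
    return depth, pix2face, bary
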