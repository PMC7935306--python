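"""Numba-compiled fan-beam projection and backprojection kernels.

Geometry: source on a circle of radius ``sid`` (mm) around the isocenter,
equiangular detector channels with angular pitch ``dgamma`` (rad) centered on
the line from source through isocenter. View angle ``beta`` is the source
azimuth; channel angle ``gamma`` rotates the central ray counter-clockwise.
Images are row-major with row 0 at the top (y decreasing with row index).
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def fan_project(img, pixel_size, sid, n_views, n_channels, dgamma,
                step, r_max):
    """Line integrals (image units x mm) of ``img`` for every view/channel.

    Rays are marched in steps of ``step`` mm between their entry and exit
    points of the circle of radius ``r_max`` around the isocenter, sampling
    the image bilinearly.
    """
    ny, nx = img.shape
    cx = (nx - 1) / 2.0
    cy = (ny - 1) / 2.0
    sino = np.zeros((n_views, n_channels))
    c0 = (n_channels - 1) / 2.0
    for v in range(n_views):
        beta = 2.0 * math.pi * v / n_views
        sxp = sid * math.cos(beta)
        syp = sid * math.sin(beta)
        ux = -math.cos(beta)
        uy = -math.sin(beta)
        for c in range(n_channels):
            gamma = (c - c0) * dgamma
            cg = math.cos(gamma)
            sg = math.sin(gamma)
            dx = ux * cg - uy * sg
            dy = ux * sg + uy * cg
            b = sxp * dx + syp * dy
            disc = b * b - (sid * sid - r_max * r_max)
            if disc <= 0.0:
                continue
            sq = math.sqrt(disc)
            t0 = -b - sq
            t1 = -b + sq
            n_steps = int((t1 - t0) / step) + 1
            acc = 0.0
            for k in range(n_steps):
                t = t0 + (k + 0.5) * step
                x = sxp + t * dx
                y = syp + t * dy
                fx = x / pixel_size + cx
                fy = cy - y / pixel_size
                ix = int(math.floor(fx))
                iy = int(math.floor(fy))
                if ix < 0 or ix >= nx - 1 or iy < 0 or iy >= ny - 1:
                    continue
                wx = fx - ix
                wy = fy - iy
                acc += ((1 - wx) * (1 - wy) * img[iy, ix]
                        + wx * (1 - wy) * img[iy, ix + 1]
                        + (1 - wx) * wy * img[iy + 1, ix]
                        + wx * wy * img[iy + 1, ix + 1])
            sino[v, c] = acc * step
    return sino


@njit(cache=True)
def fan_backproject(q, pixel_size, sid, dgamma, nx, ny, r_max):
    """Weighted backprojection of filtered projections ``q`` onto the grid.

    Implements the equiangular fan-beam inversion: accumulate
    ``dbeta * q(beta, gamma') / L^2`` where ``L`` is the source-to-pixel
    distance and ``gamma'`` the channel angle of the ray through the pixel.
    Pixels outside the circle of radius ``r_max`` are left at zero.
    """
    n_views, n_channels = q.shape
    img = np.zeros((ny, nx))
    cx = (nx - 1) / 2.0
    cy = (ny - 1) / 2.0
    c0 = (n_channels - 1) / 2.0
    dbeta = 2.0 * math.pi / n_views
    r2max = r_max * r_max
    for v in range(n_views):
        beta = 2.0 * math.pi * v / n_views
        sxp = sid * math.cos(beta)
        syp = sid * math.sin(beta)
        ux = -math.cos(beta)
        uy = -math.sin(beta)
        for i in range(ny):
            y = (cy - i) * pixel_size
            for j in range(nx):
                x = (j - cx) * pixel_size
                if x * x + y * y > r2max:
                    continue
                rx = x - sxp
                ry = y - syp
                l2 = rx * rx + ry * ry
                dot = rx * ux + ry * uy
                cross = ux * ry - uy * rx
                gamma = math.atan2(cross, dot)
                fc = gamma / dgamma + c0
                ic = int(math.floor(fc))
                if ic < 0 or ic >= n_channels - 1:
                    continue
                w = fc - ic
                val = (1 - w) * q[v, ic] + w * q[v, ic + 1]
                img[i, j] += dbeta * val / l2
    return img
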