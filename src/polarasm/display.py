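"""Scan conversion and image export for sector images."""

from __future__ import annotations

import numpy as np
from PIL import Image as PILImage
from scipy.ndimage import map_coordinates

from .geometry import cartesian_to_polar
from .migration import PolarImage

__all__ = ["scan_convert", "save_png"]


def scan_convert(image: PolarImage, x_range, z_range, pixel_size: float,
                 sentinel: float = np.nan) -> tuple[np.ndarray, np.ndarray,
                                                    np.ndarray]:
    """Resample the envelope onto a Cartesian raster.

    Bilinear interpolation from ``(theta, r)`` to ``(x, z)``; raster
    pixels outside the polar sector get ``sentinel``.  Returns
    ``(raster, x_axis, z_axis)`` with ``raster`` indexed (z, x).
    """
    grid = image.grid
    x = np.arange(x_range[0], x_range[1] + pixel_size / 2, pixel_size)
    z = np.arange(z_range[0], z_range[1] + pixel_size / 2, pixel_size)
    if x.size == 0 or z.size == 0:
        raise ValueError("empty raster")
    X, Z = np.meshgrid(x, z)
    ok = np.hypot(X, Z) > 0
    theta = np.full(X.shape, np.nan)
    r = np.full(X.shape, np.nan)
    theta[ok], r[ok] = cartesian_to_polar(X[ok], Z[ok])
    ti = (theta - grid.theta_samples[0]) / grid.dtheta
    ri = (r - grid.r_samples[0]) / grid.dr
    inside = (ok & (ti >= 0) & (ti <= grid.n_theta - 1)
              & (ri >= 0) & (ri <= grid.n_r - 1))
    if not np.any(inside):
        raise ValueError("raster does not overlap the polar sector")
    env = image.envelope()
    out = np.full(X.shape, sentinel, dtype=float)
    coords = np.stack([ti[inside], ri[inside]])
    out[inside] = map_coordinates(env, coords, order=1, mode="nearest")
    return out, x, z


def save_png(path, raster: np.ndarray, dynamic_range_db: float = 60.0) -> None:
    """Log-compress an envelope raster and write an 8-bit grayscale PNG."""
    valid = np.isfinite(raster) & (raster > 0)
    if not np.any(valid):
        raise ValueError("nothing to display")
    db = np.full(raster.shape, -dynamic_range_db)
    db[valid] = 20.0 * np.log10(raster[valid] / raster[valid].max())
    db = np.clip(db, -dynamic_range_db, 0.0)
    gray = ((db + dynamic_range_db) / dynamic_range_db * 255).astype(np.uint8)
    PILImage.fromarray(gray, mode="L").save(path)
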