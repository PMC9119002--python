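"""Image- and field-quality metrics: NRMSE, lateral resolution, contrast.

All metrics operate on pre-compression data: envelopes for image metrics
(never log-compressed values), raw pressure traces for NRMSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import PolarGrid, polar_to_cartesian
from .migration import PolarImage

__all__ = ["RegionSpec", "nrmse", "lateral_fwhm", "contrast_db"]


@dataclass(frozen=True)
class RegionSpec:
    """Region of interest on a polar image grid.

    ``kind='disc'``: Cartesian disc, ``params={'x', 'z', 'radius'}`` (m).
    ``kind='sector'``: ``params={'theta_min','theta_max','r_min','r_max'}``.
    ``role`` labels the region (lesion / background / point).
    """

    kind: str
    params: dict
    role: str = ""

    def mask(self, grid: PolarGrid) -> np.ndarray:
        """Boolean pixel mask, shape (n_theta, n_r)."""
        if self.kind == "disc":
            X, Z = polar_to_cartesian(grid.theta_samples[:, None],
                                      grid.r_samples[None, :])
            m = np.hypot(X - self.params["x"],
                         Z - self.params["z"]) <= self.params["radius"]
        elif self.kind == "sector":
            p = self.params
            th = grid.theta_samples[:, None]
            r = grid.r_samples[None, :]
            m = ((th >= p["theta_min"]) & (th <= p["theta_max"])
                 & (r >= p["r_min"]) & (r <= p["r_max"]))
        else:
            raise ValueError("kind must be 'disc' or 'sector'")
        if not np.any(m):
            raise ValueError("region is empty on this grid")
        return m


def nrmse(test, reference) -> float:
    """Normalized RMS error in percent, after global LS scale alignment.

    ``100 * RMS(a*test - reference) / RMS(reference)`` with the single
    real scalar ``a`` minimizing the residual (scale only, no shift); the
    two arrays must share their sample axes exactly.
    """
    t = np.asarray(test, dtype=float).ravel()
    r = np.asarray(reference, dtype=float).ravel()
    if t.shape != r.shape:
        raise ValueError("test/reference shape mismatch")
    r_norm = np.linalg.norm(r)
    if r_norm == 0:
        raise ValueError("reference is identically zero")
    tt = t @ t
    a = (r @ t) / tt if tt > 0 else 0.0
    return float(100.0 * np.linalg.norm(a * t - r) / r_norm)


def _parabolic_peak(y0: float, y1: float, y2: float) -> tuple[float, float]:
    """Sub-sample peak offset (in samples, relative to the middle) and value."""
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return 0.0, y1
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    value = y1 - 0.25 * (y0 - y2) * delta
    return delta, float(value)


def lateral_fwhm(image: PolarImage, point_xz, search_radius: float,
                 threshold_db: float = -6.0) -> float:
    """-6 dB full width (meters of arc) of a point target's lateral profile.

    Locates the envelope maximum within ``search_radius`` of the nominal
    point position, takes the constant-``r`` profile through it, refines
    the peak with a parabola, and interpolates the two threshold
    crossings linearly.  Gain-invariant; measure before log compression.
    """
    grid = image.grid
    env = image.envelope()
    if env.ndim != 2:
        raise ValueError("lateral_fwhm expects a compounded image")
    X, Z = polar_to_cartesian(grid.theta_samples[:, None],
                              grid.r_samples[None, :])
    near = np.hypot(X - point_xz[0], Z - point_xz[1]) <= search_radius
    if not np.any(near):
        raise ValueError("no pixels within the search radius")
    masked = np.where(near, env, -np.inf)
    i_th, i_r = np.unravel_index(np.argmax(masked), env.shape)
    profile = env[:, i_r]
    if i_th in (0, grid.n_theta - 1):
        raise ValueError("peak lies on the image boundary")
    delta, peak = _parabolic_peak(profile[i_th - 1], profile[i_th],
                                  profile[i_th + 1])
    level = peak * 10.0 ** (threshold_db / 20.0)

    def crossing(direction: int) -> float:
        j = i_th
        while 0 <= j + direction < grid.n_theta:
            k = j + direction
            if profile[k] < level:
                # linear interpolation between j and k
                frac = (profile[j] - level) / (profile[j] - profile[k])
                return j + direction * frac
            j = k
        raise ValueError("width not bracketed inside the image")

    left = crossing(-1)
    right = crossing(+1)
    width_samples = right - left
    return float(width_samples * grid.dtheta * grid.r_samples[i_r])


def contrast_db(image: PolarImage, lesion: RegionSpec,
                background: RegionSpec) -> float:
    """Anechoic-lesion contrast, dB: −20 log10(lesion mean / background mean).

    Means are of the pre-compression envelope; higher is better for an
    anechoic (scatterer-free) lesion.  Invariant to global gain.
    """
    lm = lesion.mask(image.grid)
    bm = background.mask(image.grid)
    if np.any(lm & bm):
        raise ValueError("lesion and background regions overlap")
    env = image.envelope()
    mu_l = float(env[lm].mean())
    mu_b = float(env[bm].mean())
    if mu_b == 0:
        raise ValueError("background mean envelope is zero")
    return float(-20.0 * np.log10(mu_l / mu_b + 1e-300))
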