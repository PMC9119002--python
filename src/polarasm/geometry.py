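"""Curvilinear array geometry and the polar imaging coordinate convention.

A curvilinear (convex) probe places its elements on a circular arc of
radius ``r0`` about a center of curvature.  All imaging happens on a polar
grid ``(theta, r)`` anchored at that center: ``theta`` is measured from the
depth axis through the middle of the array (so the aperture is symmetric
about ``theta = 0``) and ``r`` starts at the element arc ``r0``.  The
Cartesian convention is

    x = r * sin(theta),   z = r * cos(theta),

with ``z`` the depth axis.  The log-radius ``rho = ln r`` is the conformal
coordinate in which the two-dimensional wave equation separates; the grid
exposes it but stores uniform steps in ``r`` (the angular-spectrum
propagator is marched shell-to-shell in ``r`` directly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CurvilinearProbe",
    "PolarGrid",
    "PROBE_PRESETS",
    "element_angles",
    "polar_to_cartesian",
    "cartesian_to_polar",
]


@dataclass(frozen=True)
class CurvilinearProbe:
    """Idealized curvilinear array: point-like elements on the arc ``r = r0``.

    Parameters
    ----------
    n_elements:
        Number of transducer elements.
    radius_r0:
        Radius of curvature in meters (distance from the center of
        curvature to the element faces).
    pitch:
        Arc length between adjacent element centers, meters.
    center_frequency:
        Nominal center frequency in Hz; used only for defaults (grid
        steps, pulse construction) never inside the propagator.
    """

    n_elements: int
    radius_r0: float
    pitch: float
    center_frequency: float = 3.5e6

    def __post_init__(self) -> None:
        if self.n_elements < 1:
            raise ValueError("n_elements must be >= 1")
        if self.radius_r0 <= 0:
            raise ValueError("radius_r0 must be positive")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if (self.n_elements - 1) * self.pitch / self.radius_r0 >= np.pi:
            raise ValueError("total angular aperture must be < pi")

    @property
    def angular_pitch(self) -> float:
        """Angle subtended by one element pitch, radians."""
        return self.pitch / self.radius_r0

    @property
    def angular_span(self) -> float:
        """Angle between the first and last element centers, radians."""
        return (self.n_elements - 1) * self.angular_pitch


#: Built-in probe presets.  ``c52v`` is a 128-element, 49.57 mm radius,
#: 0.508 mm pitch array; ``5c1`` is the Siemens 5C1 (180 elements,
#: 46.03 mm radius, 0.3212 mm pitch).
PROBE_PRESETS: dict[str, CurvilinearProbe] = {
    "c52v": CurvilinearProbe(128, 49.57e-3, 0.508e-3, 3.5e6),
    "5c1": CurvilinearProbe(180, 46.03e-3, 0.3212e-3, 3.5e6),
}


def element_angles(probe: CurvilinearProbe) -> np.ndarray:
    """Angles of the element centers, radians, symmetric about 0.

    Element ``e`` sits at ``(e - (n-1)/2) * pitch / r0``.
    """
    n = probe.n_elements
    idx = np.arange(n) - (n - 1) / 2.0
    return idx * probe.angular_pitch


def element_positions(probe: CurvilinearProbe) -> np.ndarray:
    """Cartesian ``(x, z)`` element-center positions, shape (n_elements, 2)."""
    th = element_angles(probe)
    x, z = polar_to_cartesian(th, probe.radius_r0)
    return np.stack([x, z], axis=-1)


def element_normals(probe: CurvilinearProbe) -> np.ndarray:
    """Outward (radial) unit normals of each element, shape (n_elements, 2)."""
    th = element_angles(probe)
    return np.stack([np.sin(th), np.cos(th)], axis=-1)


def polar_to_cartesian(theta, r):
    """Map imaging polar coordinates to Cartesian ``(x, z)``.

    ``theta = 0`` points along the depth axis ``z``; positive ``theta``
    is toward positive ``x``.  ``r`` must be positive.
    """
    theta = np.asarray(theta, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    return r * np.sin(theta), r * np.cos(theta)


def cartesian_to_polar(x, z):
    """Inverse of :func:`polar_to_cartesian`; returns ``(theta, r)``."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    r = np.hypot(x, z)
    if np.any(r == 0):
        raise ValueError("origin has no polar angle")
    return np.arctan2(x, z), r


@dataclass(frozen=True)
class PolarGrid:
    """Uniform polar reconstruction grid.

    ``theta_samples`` must be uniformly spaced (required by the discrete
    angular Fourier transform); ``r_samples`` starts at the probe radius
    ``r0`` with uniform step ``dr``.
    """

    theta_samples: np.ndarray
    r_samples: np.ndarray

    def __post_init__(self) -> None:
        th = np.asarray(self.theta_samples, dtype=float)
        r = np.asarray(self.r_samples, dtype=float)
        object.__setattr__(self, "theta_samples", th)
        object.__setattr__(self, "r_samples", r)
        if th.ndim != 1 or th.size < 2:
            raise ValueError("theta_samples must be a 1-D array, length >= 2")
        dth = np.diff(th)
        if np.any(dth <= 0) or not np.allclose(dth, dth[0], rtol=1e-9, atol=0):
            raise ValueError("theta_samples must be uniform and increasing")
        if r.ndim != 1 or r.size < 1 or r[0] <= 0:
            raise ValueError("r_samples must be 1-D with positive start")
        if r.size > 1:
            drr = np.diff(r)
            if np.any(drr <= 0) or not np.allclose(drr, drr[0], rtol=1e-9, atol=0):
                raise ValueError("r_samples must be uniform and increasing")

    @property
    def n_theta(self) -> int:
        return self.theta_samples.size

    @property
    def n_r(self) -> int:
        return self.r_samples.size

    @property
    def dtheta(self) -> float:
        return float(self.theta_samples[1] - self.theta_samples[0])

    @property
    def dr(self) -> float:
        if self.r_samples.size < 2:
            raise ValueError("grid has a single radial shell")
        return float(self.r_samples[1] - self.r_samples[0])

    @property
    def rho_samples(self) -> np.ndarray:
        """Log-radius ``rho = ln r`` of each shell."""
        return np.log(self.r_samples)

    @classmethod
    def for_probe(
        cls,
        probe: CurvilinearProbe,
        max_depth: float,
        dr: float | None = None,
        n_theta: int = 512,
        theta_span: float | None = None,
    ) -> "PolarGrid":
        """Convenience grid: ``r`` from ``r0`` to ``r0 + max_depth``.

        The default radial step is half a wavelength at the probe's
        nominal center frequency in soft tissue (1540 m/s); the default
        angular span is the element span padded by 10% on each side.
        """
        if dr is None:
            dr = 0.5 * 1540.0 / probe.center_frequency
        if theta_span is None:
            theta_span = 1.2 * probe.angular_span
        n_r = int(np.floor(max_depth / dr)) + 1
        r = probe.radius_r0 + dr * np.arange(n_r)
        th = np.linspace(-theta_span / 2.0, theta_span / 2.0, n_theta)
        return cls(th, r)
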