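"""Angular spectrum method on a polar grid for curvilinear apertures.

The two-dimensional wave equation, written in log-polar coordinates
``(theta, rho = ln r)``, separates under an angular Fourier transform into
independent one-dimensional problems per angular wavenumber ``k_theta``
(cycles/radian) and temporal frequency ``f``.  Each angular-spectrum
component is advanced from the shell ``r = r1`` to ``r = r2`` by the
closed-form, phase-only propagator

    H±(k_theta, r1, r2, f) = exp(±j 2π |k_theta| [Φ(r2) − Φ(r1)]),
    Φ(r) = sqrt((f r / (c k_theta))² − 1) − arctan(sqrt((f r / (c k_theta))² − 1)),

with the ``k_theta = 0`` component handled by its plane-radial-wave limit
``exp(±j 2π f (r2 − r1)/c)``.  A mode is *evanescent* at radius ``r`` when
``f r / (c |k_theta|) <= 1``; there the square root is imaginary and a
policy (zero or decay) applies.  ``|H| = 1`` exactly for propagating
modes: the propagator transports phase only, the angular redistribution
of the spectrum carries the diffraction.

Temporal spectra follow the ``exp(-j 2π f t)`` analysis convention, under
which the ``-`` branch advances an outgoing (transmit) field to larger
radii and the ``+`` branch back-propagates receive data outward while
reversing time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .geometry import PolarGrid

__all__ = [
    "PolarField",
    "PropagatorSpec",
    "propagator",
    "angular_transform",
    "k_theta_axis",
    "asm_step",
    "march",
    "make_window",
]


@dataclass
class PolarField:
    """Complex frequency-domain wavefield on one radial shell.

    ``values`` is indexed ``(..., theta, frequency)``; leading axes (for
    example a batch of transmit events) are propagated together.
    """

    values: np.ndarray
    radius: float
    theta_axis: np.ndarray
    freq_axis: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.theta_axis = np.asarray(self.theta_axis, dtype=float)
        self.freq_axis = np.asarray(self.freq_axis, dtype=float)
        if self.values.shape[-2] != self.theta_axis.size:
            raise ValueError("values/theta_axis size mismatch")
        if self.values.shape[-1] != self.freq_axis.size:
            raise ValueError("values/freq_axis size mismatch")
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    @property
    def n_theta(self) -> int:
        return self.theta_axis.size

    @property
    def dtheta(self) -> float:
        return float(self.theta_axis[1] - self.theta_axis[0])


@dataclass(frozen=True)
class PropagatorSpec:
    """One radial propagation interval.

    ``branch`` is ``'-'`` (outgoing/transmit) or ``'+'`` (time-reversed
    receive back-propagation); ``evanescent_mode`` is ``'zero'`` (drop
    evanescent content) or ``'decay'`` (analytic continuation with the
    decaying branch).
    """

    r1: float
    r2: float
    sound_speed: float
    branch: str = "-"
    evanescent_mode: str = "zero"

    def __post_init__(self) -> None:
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("radii must be positive")
        if self.sound_speed <= 0:
            raise ValueError("sound_speed must be positive")
        if self.branch not in ("+", "-"):
            raise ValueError("branch must be '+' or '-'")
        if self.evanescent_mode not in ("zero", "decay"):
            raise ValueError("evanescent_mode must be 'zero' or 'decay'")


def _phi(u: np.ndarray) -> np.ndarray:
    """Φ(u) = sqrt(u² − 1) − arctan(sqrt(u² − 1)) for real u ≥ 0.

    Returns 0 where u <= 1 (the 'zero' evanescent policy: phase is only
    accumulated over the propagating portion of the path).
    """
    u = np.asarray(u, dtype=float)
    s = np.sqrt(np.maximum(u * u - 1.0, 0.0))
    return s - np.arctan(s)


def _phi_complex(u: np.ndarray) -> np.ndarray:
    """Analytic continuation of Φ for the 'decay' policy."""
    s = np.sqrt(np.asarray(u, dtype=complex) ** 2 - 1.0)
    return s - np.arctan(s)


def propagator(k_theta, spec: PropagatorSpec, f) -> np.ndarray:
    """Evaluate H±(k_theta, r1, r2, f) on a broadcast (k_theta, f) pair.

    ``k_theta`` is in cycles/radian, ``f`` in Hz (non-negative).  The
    ``k_theta = 0`` component is returned by its closed-form limit.  For
    fully propagating modes the modulus is exactly 1.
    """
    k_theta = np.asarray(k_theta, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("f must be non-negative")
    if np.any(~np.isfinite(k_theta)) or np.any(~np.isfinite(f)):
        raise ValueError("non-finite inputs")
    sign = -1.0 if spec.branch == "-" else 1.0
    c = spec.sound_speed
    ak = np.abs(k_theta)
    if spec.r1 == spec.r2:
        # zero-length propagation: exponent vanishes for every mode
        return np.ones(np.broadcast_shapes(ak.shape, f.shape), dtype=complex)
    with np.errstate(divide="ignore", invalid="ignore"):
        u1 = f * spec.r1 / (c * ak)
        u2 = f * spec.r2 / (c * ak)

    zero_bin = ak == 0
    if spec.evanescent_mode == "zero":
        with np.errstate(invalid="ignore"):
            expo = 2j * np.pi * ak * (_phi(u2) - _phi(u1)) * sign
        H = np.exp(np.where(zero_bin, 0.0, expo))
        # hard-zero modes evanescent at the destination radius
        dest_evan = ~zero_bin & ~np.isnan(u2) & (u2 <= 1.0)
        H = np.where(dest_evan, 0.0, H)
    else:
        with np.errstate(invalid="ignore"):
            expo = 2j * np.pi * ak * (_phi_complex(u2) - _phi_complex(u1)) * sign
        expo = np.where(zero_bin, 0.0, expo)
        # keep the phase, force the amplitude onto the decaying branch
        H = np.exp(1j * expo.imag - np.abs(expo.real))
    # k_theta = 0: plane-radial-wave limit
    limit = np.exp(sign * 2j * np.pi * f * (spec.r2 - spec.r1) / c)
    H = np.where(zero_bin, limit * np.ones_like(H), H)
    if np.any(~np.isfinite(H)):
        raise FloatingPointError("propagator produced non-finite values")
    return H


def k_theta_axis(n_theta: int, dtheta: float) -> np.ndarray:
    """Angular wavenumber bins (cycles/radian) in FFT layout."""
    return np.fft.fftfreq(n_theta, d=dtheta)


def angular_transform(field: PolarField, direction: str = "forward") -> PolarField:
    """Discrete version of the angular Fourier-transform pair.

    ``forward`` maps ``theta -> k_theta`` with kernel ``exp(-j 2π k_theta
    theta)`` (scaled by Δθ to approximate the continuous integral);
    ``inverse`` uses the conjugate kernel scaled by Δk_theta so the round
    trip is the identity.  The transformed axis is returned in FFT bin
    order (cycles/radian).
    """
    dth = field.dtheta
    if not np.allclose(np.diff(field.theta_axis), dth, rtol=1e-9, atol=0):
        raise ValueError("theta axis must be uniform")
    if direction == "forward":
        vals = np.fft.fft(field.values, axis=-2) * dth
        axis = k_theta_axis(field.n_theta, dth)
    elif direction == "inverse":
        vals = np.fft.ifft(field.values, axis=-2) / dth
        # values arrive on the k_theta axis; restore theta labelling
        axis = field.theta_axis
        return replace(field, values=vals, theta_axis=axis)
    else:
        raise ValueError("direction must be 'forward' or 'inverse'")
    out = PolarField(vals, field.radius, field.theta_axis, field.freq_axis)
    out.theta_axis = field.theta_axis  # keep grid labels; spectrum axis below
    out.k_theta = axis  # type: ignore[attr-defined]
    return out


def make_window(n_theta: int, taper_fraction: float = 0.25) -> np.ndarray:
    """Tukey (cosine-tapered) angular window suppressing FFT wraparound.

    Flat at 1 in the interior, rolling smoothly to 0 at both edges over
    ``taper_fraction/2`` of the aperture each side.  ``taper_fraction=0``
    is rectangular, ``taper_fraction=1`` is a full Hann window.
    """
    if n_theta < 4:
        raise ValueError("n_theta must be >= 4")
    if not 0.0 <= taper_fraction <= 1.0:
        raise ValueError("taper_fraction must be in [0, 1]")
    if taper_fraction == 0.0:
        return np.ones(n_theta)
    w = np.ones(n_theta)
    edge = taper_fraction * (n_theta - 1) / 2.0
    n = np.arange(n_theta)
    left = n < edge
    w[left] = 0.5 * (1 + np.cos(np.pi * (n[left] / edge - 1)))
    right = n > (n_theta - 1) - edge
    w[right] = 0.5 * (1 + np.cos(np.pi * ((n[right] - (n_theta - 1)) / edge + 1)))
    return w


def _step_values(
    values: np.ndarray,
    k_axis: np.ndarray,
    spec: PropagatorSpec,
    freq_axis: np.ndarray,
    window: np.ndarray | None,
    k_weights: np.ndarray | None = None,
) -> np.ndarray:
    """One propagation step on raw arrays: W * IFFT( H * FFT(p) ).

    ``values`` is (..., n_theta, n_f).  The Δθ/Δk_theta scalings of the
    forward/inverse transforms cancel and are omitted.  ``k_weights`` is
    an optional extra angular-spectrum weighting (e.g. f-number control)
    with shape broadcastable to (n_theta, n_f).
    """
    H = propagator(k_axis[:, None], spec, freq_axis[None, :])
    spec_vals = np.fft.fft(values, axis=-2)
    spec_vals *= H.astype(spec_vals.dtype)
    if k_weights is not None:
        spec_vals *= k_weights.astype(spec_vals.dtype)
    out = np.fft.ifft(spec_vals, axis=-2)
    if window is not None:
        out *= window[:, None].astype(out.dtype)
    return out


def asm_step(
    field: PolarField,
    spec: PropagatorSpec,
    window: np.ndarray | None = None,
) -> PolarField:
    """Advance a field from ``spec.r1`` to ``spec.r2`` in one step."""
    if abs(field.radius - spec.r1) > 1e-9 * max(field.radius, spec.r1):
        raise ValueError("field radius does not match spec.r1")
    if window is not None:
        window = np.asarray(window, dtype=float)
        if window.shape != (field.n_theta,):
            raise ValueError("window length mismatch")
        if np.any(window < 0) or np.any(window > 1):
            raise ValueError("window values must lie in [0, 1]")
    k_axis = k_theta_axis(field.n_theta, field.dtheta)
    vals = _step_values(field.values, k_axis, spec, field.freq_axis, window)
    return PolarField(vals, spec.r2, field.theta_axis, field.freq_axis)


def march(
    initial: PolarField,
    grid: PolarGrid,
    sound_speed,
    branch: str = "-",
    window: np.ndarray | None = None,
    evanescent_mode: str = "zero",
    keep: Sequence[int] | None = None,
    upsample: int = 1,
) -> tuple[np.ndarray, PolarGrid]:
    """Repeated :func:`asm_step` over all shells of ``grid``.

    Parameters
    ----------
    sound_speed:
        Scalar, or a callable ``c(r)`` evaluated at the midpoint of each
        radial interval (piecewise-constant profile per step).
    keep:
        Optional radial shell indices to retain (bounds memory); default
        keeps every shell.
    upsample:
        Optional integer angular up-sampling factor applied once to the
        initial field by zero-padding its angular spectrum (default off).

    Returns
    -------
    cube, grid:
        ``cube`` indexed ``(..., theta, shell, f)`` over the retained
        shells, and the (possibly angularly up-sampled) grid actually
        used.
    """
    if grid.n_r < 1:
        raise ValueError("empty grid")
    if abs(grid.r_samples[0] - initial.radius) > 1e-9 * initial.radius:
        raise ValueError("grid must start at the initial field's radius")
    if upsample > 1:
        initial = _upsample_theta(initial, upsample)
        grid = PolarGrid(initial.theta_axis, grid.r_samples)
        if window is not None:
            raise ValueError("provide the window for the up-sampled grid")
    keep_idx = list(range(grid.n_r)) if keep is None else sorted(keep)
    keep_set = set(keep_idx)
    c_of = sound_speed if callable(sound_speed) else (lambda r: float(sound_speed))

    shells = {}
    cur = initial
    if 0 in keep_set:
        shells[0] = cur.values.copy()
    for m in range(1, grid.n_r):
        r1, r2 = grid.r_samples[m - 1], grid.r_samples[m]
        spec = PropagatorSpec(r1, r2, c_of(0.5 * (r1 + r2)), branch,
                              evanescent_mode)
        cur = asm_step(cur, spec, window)
        if m in keep_set:
            shells[m] = cur.values
    cube = np.stack([shells[m] for m in keep_idx], axis=-2)
    out_grid = PolarGrid(grid.theta_samples, grid.r_samples[keep_idx])
    return cube, out_grid


def _upsample_theta(field: PolarField, factor: int) -> PolarField:
    """Angular up-sampling by zero-padding the angular spectrum."""
    n = field.n_theta
    m = n * factor
    spec = np.fft.fft(field.values, axis=-2)
    padded_shape = list(spec.shape)
    padded_shape[-2] = m
    padded = np.zeros(padded_shape, dtype=spec.dtype)
    half = n // 2
    idx_pos = np.arange(half + (n % 2))
    idx_neg = np.arange(-half, 0)
    padded[..., idx_pos, :] = spec[..., idx_pos, :]
    padded[..., idx_neg + m, :] = spec[..., idx_neg + n, :]
    vals = np.fft.ifft(padded, axis=-2) * factor
    dth = field.dtheta * n / m
    theta = field.theta_axis[0] + dth * np.arange(m)
    return PolarField(vals, field.radius, theta, field.freq_axis)
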