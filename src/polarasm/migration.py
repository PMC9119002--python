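"""Fourier-domain shot-profile migration on the polar grid.

For each transmit event the transmit field is advanced outward shell by
shell with the ``-`` branch propagator and the receive field is
back-propagated outward (time-reversed) with the ``+`` branch; the
per-shot image is the zero-lag cross-correlation (imaging condition)

    I_i(theta, r) = Σ_f w_band(f) * conj(p_tx(theta, r, f)) * p_rx(theta, r, f),

and the final image is the coherent sum over events.  Optional f-number
control is applied as an angular-spectrum weight on the receive field at
each shell (the framework has no per-pixel receive apodization; aperture
acceptance lives in k-space).  Only the current shell of both fields is
held in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .asm import PolarField, PropagatorSpec, k_theta_axis, propagator
from .geometry import PolarGrid
from .wavefield import Pulse

__all__ = [
    "PolarImage",
    "migrate_shot",
    "migrate_shots",
    "compound",
    "fnumber_weights",
    "band_weights",
]


@dataclass
class PolarImage:
    """Complex image on a polar grid, plus reconstruction metadata."""

    values: np.ndarray
    grid: PolarGrid
    per_shot: bool = False
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape[-2:] != (self.grid.n_theta, self.grid.n_r):
            raise ValueError("image shape does not match grid")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("image must be finite")

    def envelope(self) -> np.ndarray:
        return np.abs(self.values)

    def log_compressed(self, dynamic_range_db: float = 60.0) -> np.ndarray:
        """Envelope in dB below its maximum, clipped to the dynamic range."""
        env = self.envelope()
        db = 20.0 * np.log10(env / env.max() + 1e-300)
        return np.clip(db, -dynamic_range_db, 0.0)


def fnumber_weights(k_axis, r: float, f, c: float, f_number: float) -> np.ndarray:
    """Angular-spectrum aperture-acceptance weights in [0, 1].

    Passes ``|k_theta| <= (f r / c) * sin(arctan(1 / (2 F)))`` with a
    cosine taper over the outer 10% of the passband.  ``f_number = 0`` is
    the all-pass sentinel.
    """
    if f_number < 0:
        raise ValueError("f_number must be non-negative")
    k_axis = np.asarray(k_axis, dtype=float)
    f = np.asarray(f, dtype=float)
    if f_number == 0:
        return np.ones(np.broadcast_shapes(k_axis.shape, f.shape))
    kc = (f * r / c) * np.sin(np.arctan(1.0 / (2.0 * f_number)))
    ak = np.abs(k_axis)
    inner = 0.9 * kc
    w = np.zeros(np.broadcast_shapes(ak.shape, np.shape(kc)))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (ak - inner) / (kc - inner)
    w = np.where(ak <= inner, 1.0,
                 np.where(ak <= kc, 0.5 * (1.0 + np.cos(np.pi * np.clip(t, 0, 1))),
                          0.0))
    return w


def band_weights(freq_axis, pulse: Pulse, mode: str = "flat",
                 taper_fraction: float = 0.25,
                 threshold_db: float = -40.0) -> np.ndarray:
    """Frequency weights over the reconstruction band.

    ``flat``: 1 on the pulse's support down to ``threshold_db``, 0
    outside.  ``taper``: cosine roll-off over ``taper_fraction`` of the
    band at each edge (Tukey), trading axial resolution for less ringing.
    """
    f = np.asarray(freq_axis, dtype=float)
    lo, hi = pulse.support(threshold_db)
    inside = (f >= lo) & (f <= hi)
    if not np.any(inside):
        raise ValueError("empty band on this frequency axis")
    w = inside.astype(float)
    if mode == "flat" or taper_fraction == 0.0:
        return w
    if mode != "taper":
        raise ValueError("mode must be 'flat' or 'taper'")
    width = hi - lo
    edge = taper_fraction * width / 2.0
    rise = inside & (f < lo + edge)
    fall = inside & (f > hi - edge)
    w[rise] = 0.5 * (1.0 - np.cos(np.pi * (f[rise] - lo) / edge))
    w[fall] = 0.5 * (1.0 - np.cos(np.pi * (hi - f[fall]) / edge))
    return w


def migrate_shots(
    tx0: PolarField,
    rx0: PolarField,
    grid: PolarGrid,
    sound_speed,
    window: np.ndarray | None = None,
    band: np.ndarray | None = None,
    f_number: float = 0.0,
    evanescent_mode: str = "zero",
) -> np.ndarray:
    """Per-shot migration images for a batch of events.

    ``tx0``/``rx0`` hold the boundary fields at ``r0`` with values shaped
    ``(..., n_theta, n_f)``; any leading axes are treated as independent
    transmit events marched together.  Returns the per-shot complex
    images shaped ``(..., n_theta, n_r)``.
    """
    if tx0.values.shape != rx0.values.shape:
        raise ValueError("tx/rx field shape mismatch")
    if not (np.array_equal(tx0.theta_axis, rx0.theta_axis)
            and np.array_equal(tx0.freq_axis, rx0.freq_axis)):
        raise ValueError("tx/rx fields must share theta and frequency axes")
    if abs(grid.r_samples[0] - tx0.radius) > 1e-9 * tx0.radius:
        raise ValueError("grid must start at the boundary fields' radius")
    if not np.allclose(grid.theta_samples, tx0.theta_axis):
        raise ValueError("grid theta axis must match the boundary fields")
    freq = tx0.freq_axis
    n_theta, n_f = grid.n_theta, freq.size
    if band is None:
        band_w = np.ones(n_f)
    else:
        band_w = np.asarray(band, dtype=float)
        if band_w.shape != (n_f,):
            raise ValueError("band weights length mismatch")
        if not np.any(band_w > 0):
            raise ValueError("empty band")
    if window is not None:
        window = np.asarray(window, dtype=float)
        if window.shape != (n_theta,):
            raise ValueError("window length mismatch")

    k_axis = k_theta_axis(n_theta, grid.dtheta)
    c_of = sound_speed if callable(sound_speed) else (lambda r: float(sound_speed))
    lead = tx0.values.shape[:-2]
    cur_tx = tx0.values.astype(np.complex64)
    cur_rx = rx0.values.astype(np.complex64)
    images = np.zeros(lead + (n_theta, grid.n_r), dtype=np.complex64)
    bw = band_w.astype(np.complex64)

    for m in range(grid.n_r):
        r_m = grid.r_samples[m]
        if f_number > 0:
            spec_rx_now = np.fft.fft(cur_rx, axis=-2)
            wk = fnumber_weights(k_axis[:, None], r_m, freq[None, :],
                                 c_of(r_m), f_number)
            rx_im = np.fft.ifft(spec_rx_now * wk.astype(np.complex64), axis=-2)
        else:
            rx_im = cur_rx
        images[..., m] = ((np.conj(cur_tx) * rx_im) @ bw)
        if m == grid.n_r - 1:
            break
        r1, r2 = r_m, grid.r_samples[m + 1]
        c_step = c_of(0.5 * (r1 + r2))
        spec_tx = np.fft.fft(cur_tx, axis=-2)
        if f_number > 0:
            spec_rx = spec_rx_now
        else:
            spec_rx = np.fft.fft(cur_rx, axis=-2)
        Htx = propagator(k_axis[:, None],
                         PropagatorSpec(r1, r2, c_step, "-", evanescent_mode),
                         freq[None, :]).astype(np.complex64)
        Hrx = propagator(k_axis[:, None],
                         PropagatorSpec(r1, r2, c_step, "+", evanescent_mode),
                         freq[None, :]).astype(np.complex64)
        cur_tx = np.fft.ifft(spec_tx * Htx, axis=-2).astype(np.complex64)
        cur_rx = np.fft.ifft(spec_rx * Hrx, axis=-2).astype(np.complex64)
        if window is not None:
            cur_tx *= window[:, None].astype(np.complex64)
            cur_rx *= window[:, None].astype(np.complex64)
    return images


def migrate_shot(
    tx0: PolarField,
    rx0: PolarField,
    grid: PolarGrid,
    sound_speed,
    window: np.ndarray | None = None,
    band: np.ndarray | None = None,
    f_number: float = 0.0,
    evanescent_mode: str = "zero",
) -> PolarImage:
    """Single-event shot-profile migration image (per-shot ``I_i``)."""
    if tx0.values.ndim != 2:
        raise ValueError("migrate_shot expects single-event fields")
    vals = migrate_shots(tx0, rx0, grid, sound_speed, window, band,
                         f_number, evanescent_mode)
    meta = {"f_number": f_number, "evanescent_mode": evanescent_mode}
    return PolarImage(vals, grid, per_shot=True, metadata=meta)


def compound(images) -> PolarImage:
    """Coherent complex sum of per-shot images (envelope taken after)."""
    if isinstance(images, PolarImage):
        images = [images]
    images = list(images)
    if not images:
        raise ValueError("no images to compound")
    grid = images[0].grid
    for im in images[1:]:
        if not (np.array_equal(im.grid.theta_samples, grid.theta_samples)
                and np.array_equal(im.grid.r_samples, grid.r_samples)):
            raise ValueError("grid mismatch between per-shot images")
    total = np.sum([im.values for im in images], axis=0)
    meta = dict(images[0].metadata)
    meta["n_shots"] = len(images)
    return PolarImage(total, grid, per_shot=False, metadata=meta)
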