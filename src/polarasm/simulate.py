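"""Time-domain reference simulator and synthetic phantoms.

This module is the independent oracle the angular-spectrum march is
validated against.  The polar ASM solves the *two-dimensional* wave
equation, so the reference superposes 2-D line sources rather than 3-D
point sources: each element is subdivided into sub-sources along its arc
width, and each sub-source radiates the Rayleigh–Sommerfeld type-I
(dipole) field

    K(f, d) = -(j k / 2) * H1⁽²⁾(k d) * cos(phi),   k = 2π f / c,

where ``d`` is the source-to-field distance and ``phi`` the angle between
the element's outward normal and the source-to-field direction.  This
kernel is the exact free-space solution of the same boundary-value
problem the ASM marches (pressure prescribed on the r = r0 arc, outgoing
waves selected), so discrepancies between the two measure the propagator,
not a model mismatch.  Temporal spectra use the ``exp(-j 2π f t)``
analysis convention shared with the rest of the package.

For pulse-echo channel data the large-argument (far-field) form of the
kernels is used.  The transmit dipole magnitude grows like sqrt(f) and
the monopole scattering return decays like 1/sqrt(f), so the two-way
frequency profile is flat: every transmit-scatterer-receiver path
contributes a delayed replica of the pulse weighted by
``cos(phi_tx) cos(phi_rx) / sqrt(d_tx d_rx)`` (single scattering, Born).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.special import hankel2

from .geometry import CurvilinearProbe, element_angles, polar_to_cartesian
from .wavefield import ChannelData, Pulse, TransmitEvent

__all__ = [
    "Phantom",
    "make_phantom",
    "resolution_cell_area",
    "simulate_transmit_field",
    "simulate_channel_data",
]


# ---------------------------------------------------------------------------
# phantoms

@dataclass
class Phantom:
    """Scatterer cloud: positions (x, z) in meters and reflectivities."""

    x: np.ndarray
    z: np.ndarray
    amp: np.ndarray
    spec: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.z = np.atleast_1d(np.asarray(self.z, dtype=float))
        self.amp = np.atleast_1d(np.asarray(self.amp, dtype=float))
        if not (self.x.shape == self.z.shape == self.amp.shape):
            raise ValueError("x, z, amp must have identical shapes")
        if np.any(~np.isfinite(self.amp)):
            raise ValueError("amplitudes must be finite")

    @property
    def n_scatterers(self) -> int:
        return self.x.size


def resolution_cell_area(pulse: Pulse, c: float) -> float:
    """Nominal speckle resolution cell, m².

    Axial extent ``c / (2 f0 fbw)`` (pulse-bandwidth limit) times a
    lateral extent of two wavelengths (an f/2-ish system); used only to
    convert "scatterers per resolution cell" into a count.
    """
    axial = c / (2.0 * pulse.center_frequency * pulse.fractional_bandwidth)
    lateral = 2.0 * c / pulse.center_frequency
    return axial * lateral


def make_phantom(
    field_of_view: dict,
    *,
    points: list[tuple[float, float]] | None = None,
    point_amplitude: float = 30.0,
    lesions: list[dict] | None = None,
    diffuse_density: float = 0.0,
    cell_area: float | None = None,
    pulse: Pulse | None = None,
    sound_speed: float = 1540.0,
    seed: int = 0,
) -> Phantom:
    """Build a sector phantom: point grid + diffuse speckle + anechoic discs.

    Parameters
    ----------
    field_of_view:
        ``{"theta_min", "theta_max", "r_min", "r_max"}`` sector (radians /
        meters, polar about the array's center of curvature) containing
        the diffuse scatterers.
    points:
        Bright point targets as ``(theta, r)`` pairs, amplitude
        ``point_amplitude`` (diffuse amplitudes are standard normal).
    lesions:
        Anechoic discs ``{"theta", "r", "radius"}``; diffuse scatterers
        inside are removed (points are left untouched).
    diffuse_density:
        Scatterers per resolution cell; 10 gives fully developed speckle.
    cell_area:
        Resolution cell area, m²; computed from ``pulse`` if omitted.
    """
    rng = np.random.default_rng(seed)
    th0, th1 = field_of_view["theta_min"], field_of_view["theta_max"]
    r0, r1 = field_of_view["r_min"], field_of_view["r_max"]
    if not (th1 > th0 and r1 > r0 > 0):
        raise ValueError("degenerate field of view")
    lesions = lesions or []
    if lesions and diffuse_density <= 0:
        raise ValueError("lesion contrast needs a nonzero diffuse density")

    xs, zs, amps = [], [], []
    if diffuse_density > 0:
        if cell_area is None:
            if pulse is None:
                raise ValueError("need cell_area or pulse for diffuse density")
            cell_area = resolution_cell_area(pulse, sound_speed)
        area = 0.5 * (r1 ** 2 - r0 ** 2) * (th1 - th0)
        n = rng.poisson(diffuse_density * area / cell_area)
        th = rng.uniform(th0, th1, n)
        r = np.sqrt(rng.uniform(r0 ** 2, r1 ** 2, n))  # uniform in area
        x, z = polar_to_cartesian(th, r)
        a = rng.standard_normal(n)
        keep = np.ones(n, dtype=bool)
        for les in lesions:
            lx, lz = polar_to_cartesian(les["theta"], les["r"])
            keep &= np.hypot(x - lx, z - lz) >= les["radius"]
        xs.append(x[keep])
        zs.append(z[keep])
        amps.append(a[keep])
    for (pth, pr) in points or []:
        px, pz = polar_to_cartesian(pth, pr)
        xs.append([px])
        zs.append([pz])
        amps.append([point_amplitude])
    if not xs:
        raise ValueError("empty phantom specification")
    spec = {
        "field_of_view": dict(field_of_view),
        "points": [list(p) for p in (points or [])],
        "point_amplitude": point_amplitude,
        "lesions": [dict(l) for l in lesions],
        "diffuse_density": diffuse_density,
        "seed": int(seed),
    }
    return Phantom(np.concatenate(xs), np.concatenate(zs),
                   np.concatenate(amps), spec)


# ---------------------------------------------------------------------------
# source bookkeeping

def _sub_sources(probe: CurvilinearProbe, event: TransmitEvent,
                 n_sub: int) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                      np.ndarray]:
    """Active sub-source positions, normals, delays and weights.

    Each active element is split into ``n_sub`` sub-sources across its
    arc width; weights carry the apodization and the arc length
    ``pitch / n_sub`` so the discrete sum approximates the aperture
    integral.
    """
    active = np.flatnonzero(event.apodization > 0)
    if active.size == 0:
        raise ValueError("event has no active elements")
    el_th = element_angles(probe)[active]
    offs = (np.arange(n_sub) + 0.5) / n_sub - 0.5
    th = (el_th[:, None] + offs[None, :] * probe.angular_pitch).ravel()
    x, z = polar_to_cartesian(th, probe.radius_r0)
    normals = np.stack([np.sin(th), np.cos(th)], axis=-1)
    tau = np.repeat(event.delays[active], n_sub)
    w = np.repeat(event.apodization[active], n_sub) * (probe.pitch / n_sub)
    return np.stack([x, z], axis=-1), normals, tau, w


def _geometry(src_pos: np.ndarray, src_norm: np.ndarray,
              px: np.ndarray, pz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distances and obliquity cosines, shapes (n_points, n_src)."""
    dx = px[:, None] - src_pos[None, :, 0]
    dz = pz[:, None] - src_pos[None, :, 1]
    d = np.hypot(dx, dz)
    if np.any(d == 0):
        raise ValueError("field point coincides with a source point")
    cosphi = (dx * src_norm[None, :, 0] + dz * src_norm[None, :, 1]) / d
    return d, cosphi


# ---------------------------------------------------------------------------
# one-way transmit field (exact kernel)

def simulate_transmit_field(
    probe: CurvilinearProbe,
    event: TransmitEvent,
    pulse: Pulse,
    field_points: np.ndarray,
    c: float,
    sampling_rate: float,
    n_samples: int,
    t_start: float = 0.0,
    n_sub: int = 4,
    threshold_db: float = -60.0,
) -> np.ndarray:
    """Pressure versus time at arbitrary field points, shape (n_points, n_t).

    Exact 2-D Rayleigh–Sommerfeld dipole superposition evaluated in the
    frequency domain on the pulse's support and inverse-transformed to
    the requested time grid (sample ``n`` is at ``t_start + n / fs``).
    ``field_points`` is (n_points, 2) Cartesian (x, z).
    """
    pts = np.atleast_2d(np.asarray(field_points, dtype=float))
    src_pos, src_norm, tau, w = _sub_sources(probe, event, n_sub)
    d, cosphi = _geometry(src_pos, src_norm, pts[:, 0], pts[:, 1])

    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    lo, hi = pulse.support(threshold_db)
    band = np.flatnonzero((freqs >= lo) & (freqs <= hi) & (freqs > 0))
    if band.size == 0:
        raise ValueError("time axis too short for the pulse band")
    P = pulse.spectrum(freqs[band])

    spectrum = np.zeros((pts.shape[0], freqs.size), dtype=complex)
    for j, b in enumerate(band):
        f = freqs[b]
        k = 2.0 * np.pi * f / c
        kern = -0.5j * k * hankel2(1, k * d) * cosphi
        phase = np.exp(-2j * np.pi * f * tau)
        spectrum[:, b] = P[j] * (kern @ (w * phase))
    # shift onto the requested time origin (synthesis exp(+j 2π f t))
    spectrum *= np.exp(2j * np.pi * freqs * t_start)[None, :]
    return np.fft.irfft(spectrum, n=n_samples, axis=-1)


# ---------------------------------------------------------------------------
# pulse-echo channel data (far-field kernels)

def _band_phase_sum(base: np.ndarray, step: np.ndarray,
                    coeff: np.ndarray | None, n_f: int,
                    out_axis_len: int) -> np.ndarray:
    """Σ over pairs of geometric phase progressions, per frequency bin.

    ``base``/``step`` are (n_left, n_right) complex64; the result is
    (out_axis_len, n_f) where the sum runs over the *left* axis when
    ``coeff`` is given (``coeff`` shape (n_left, n_f), result axis =
    right) or over the right axis otherwise (result axis = left).
    """
    cur = base.copy()
    if coeff is None:
        out = np.empty((base.shape[0], n_f), dtype=np.complex64)
        for j in range(n_f):
            out[:, j] = cur.sum(axis=1)
            if j + 1 < n_f:
                cur *= step
    else:
        out = np.empty((base.shape[1], n_f), dtype=np.complex64)
        for j in range(n_f):
            out[:, j] = coeff[:, j] @ cur
            if j + 1 < n_f:
                cur *= step
    assert out.shape[0] == out_axis_len
    return out


def simulate_channel_data(
    probe: CurvilinearProbe,
    events: list[TransmitEvent],
    pulse: Pulse,
    phantom: Phantom,
    c: float,
    sampling_rate: float,
    n_samples: int,
    t0: float = 0.0,
    n_sub: int = 1,
    noise_db: float | None = None,
    threshold_db: float = -60.0,
    seed: int = 0,
) -> ChannelData:
    """Born single-scattering pulse-echo traces for every event/element.

    Each transmit-scatterer-receiver path deposits a delayed pulse
    weighted by ``cos(phi_tx) cos(phi_rx) / sqrt(d_tx d_rx)`` (far-field
    2-D kernels; the two-way frequency profile is flat).  ``noise_db``
    adds white Gaussian noise at the stated level below the peak trace
    amplitude.
    """
    el_th = element_angles(probe)
    ex, ez = polar_to_cartesian(el_th, probe.radius_r0)
    el_pos = np.stack([ex, ez], axis=-1)
    el_norm = np.stack([np.sin(el_th), np.cos(el_th)], axis=-1)

    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    lo, hi = pulse.support(threshold_db)
    band = np.flatnonzero((freqs >= lo) & (freqs <= hi) & (freqs > 0))
    if band.size == 0:
        raise ValueError("time axis too short for the pulse band")
    if hi >= sampling_rate / 2.0:
        raise ValueError("pulse band exceeds Nyquist")
    fb = freqs[band]
    n_f = band.size
    df = freqs[1] - freqs[0]
    P = pulse.spectrum(fb).astype(np.complex64)

    # receive geometry is event-independent
    d_rx, cos_rx = _geometry(el_pos, el_norm, phantom.x, phantom.z)
    w_rx = (cos_rx / np.sqrt(d_rx)).astype(np.complex64)
    base_rx = (w_rx * np.exp(-2j * np.pi * fb[0] / c * d_rx)).astype(np.complex64)
    step_rx = np.exp(-2j * np.pi * df / c * d_rx).astype(np.complex64)

    n_el = probe.n_elements
    traces = np.empty((len(events), n_el, n_samples), dtype=np.float32)
    for i, ev in enumerate(events):
        src_pos, src_norm, tau, w = _sub_sources(probe, ev, n_sub)
        d_tx, cos_tx = _geometry(src_pos, src_norm, phantom.x, phantom.z)
        t_tx = tau[None, :] + d_tx / c
        w_tx = (w * cos_tx / np.sqrt(d_tx)).astype(np.complex64)
        base_tx = (w_tx * np.exp(-2j * np.pi * fb[0] * t_tx)).astype(np.complex64)
        step_tx = np.exp(-2j * np.pi * df * t_tx).astype(np.complex64)
        # transmit spectrum at each scatterer, (n_scat, n_f)
        A = _band_phase_sum(base_tx, step_tx, None, n_f, phantom.n_scatterers)
        A *= phantom.amp[:, None].astype(np.complex64)
        A *= P[None, :]
        # receive: traces_f(e, f) = Σ_s A(s, f) exp(-j2πf d_rx/c) w_rx
        trf = _band_phase_sum(base_rx, step_rx, A, n_f, n_el)
        spec_full = np.zeros((n_el, freqs.size), dtype=np.complex64)
        spec_full[:, band] = trf
        spec_full *= np.exp(2j * np.pi * freqs * t0)[None, :].astype(np.complex64)
        traces[i] = np.fft.irfft(spec_full, n=n_samples, axis=-1)

    if noise_db is not None:
        rng = np.random.default_rng(seed)
        sigma = np.abs(traces).max() * 10.0 ** (noise_db / 20.0)
        traces = traces + rng.normal(0.0, sigma,
                                     traces.shape).astype(np.float32)

    delays = np.stack([ev.delays for ev in events])
    apod = np.stack([ev.apodization for ev in events])
    foci = None
    if all(ev.focus_theta is not None for ev in events):
        foci = np.array([[ev.focus_theta, ev.focus_r] for ev in events])
    return ChannelData(traces, sampling_rate, t0, delays, apod, foci)
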