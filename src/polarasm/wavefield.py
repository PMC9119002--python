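"""Initial transmit/receive wavefields on the probe arc ``r = r0``.

Shot-profile migration needs both wavefields as frequency-domain boundary
data on the element arc.  The transmit field is synthesized from the
sequence description,

    p_tx(theta, r0, f) = A(theta) * P(f) * exp(-j 2π f τ(theta)),

with ``P(f)`` the pulse spectrum and ``τ``/``A`` the per-element focal
delays and apodization mapped onto the angular grid.  The receive field
is the temporal spectrum of the recorded channel traces placed at the
element angles.  Temporal spectra use the ``exp(-j 2π f t)`` analysis
convention throughout; real traces are represented by their one-sided
(positive-frequency) spectra and images are formed from the analytic
signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .asm import PolarField
from .geometry import CurvilinearProbe, element_angles, element_positions, \
    polar_to_cartesian

__all__ = [
    "Pulse",
    "TransmitEvent",
    "ChannelData",
    "gaussian_pulse_spectrum",
    "focal_delays",
    "make_focused_event",
    "init_transmit_field",
    "init_receive_field",
    "band_freq_axis",
]


@dataclass
class Pulse:
    """Transmit pulse: Gaussian magnitude spectrum, zero phase.

    ``fractional_bandwidth`` is the -6 dB full spectral width divided by
    the center frequency (the conventional transducer definition).  Zero
    phase means the time-domain envelope peaks at t = 0; all timing is
    carried by delays.
    """

    center_frequency: float
    fractional_bandwidth: float

    def __post_init__(self) -> None:
        if self.center_frequency <= 0:
            raise ValueError("center_frequency must be positive")
        if not 0.0 < self.fractional_bandwidth < 2.0:
            raise ValueError("fractional_bandwidth must be in (0, 2)")

    @property
    def sigma_f(self) -> float:
        """Gaussian std-dev of the magnitude spectrum, Hz."""
        # |P| = 1/2 at f0 ± fbw*f0/2  =>  sigma = fbw*f0 / (2 sqrt(2 ln 2))
        return self.fractional_bandwidth * self.center_frequency / (
            2.0 * np.sqrt(2.0 * np.log(2.0)))

    def spectrum(self, freq_axis) -> np.ndarray:
        """Peak-normalized magnitude spectrum |P(f)| on ``freq_axis``."""
        f = np.asarray(freq_axis, dtype=float)
        return np.exp(-((f - self.center_frequency) ** 2)
                      / (2.0 * self.sigma_f ** 2))

    def waveform(self, t) -> np.ndarray:
        """Time-domain pulse: Gaussian-modulated cosine, envelope peak at 0."""
        t = np.asarray(t, dtype=float)
        sigma_t = 1.0 / (2.0 * np.pi * self.sigma_f)
        return np.exp(-(t ** 2) / (2.0 * sigma_t ** 2)) * np.cos(
            2.0 * np.pi * self.center_frequency * t)

    def support(self, threshold_db: float = -40.0) -> tuple[float, float]:
        """Frequency interval where |P| is above ``threshold_db`` of peak."""
        half = self.sigma_f * np.sqrt(2.0 * np.log(10.0 ** (-threshold_db / 20.0)))
        return (max(self.center_frequency - half, 0.0),
                self.center_frequency + half)


def gaussian_pulse_spectrum(center_frequency: float,
                            fractional_bandwidth: float,
                            freq_axis) -> tuple[Pulse, np.ndarray]:
    """Construct a :class:`Pulse` and evaluate its spectrum on an axis."""
    pulse = Pulse(center_frequency, fractional_bandwidth)
    return pulse, pulse.spectrum(freq_axis)


@dataclass
class TransmitEvent:
    """One transmit firing: per-element delays and apodization.

    ``focus_theta``/``focus_r`` record the geometric focus when the event
    was built by :func:`make_focused_event`; the virtual-source DAS
    baseline needs them, migration does not.
    """

    delays: np.ndarray
    apodization: np.ndarray
    index: int = 0
    focus_theta: float | None = None
    focus_r: float | None = None

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.apodization = np.asarray(self.apodization, dtype=float)
        if self.delays.shape != self.apodization.shape:
            raise ValueError("delays/apodization shape mismatch")
        if np.any(~np.isfinite(self.delays)) or np.any(self.delays < 0):
            raise ValueError("delays must be finite and non-negative")
        if np.any(self.apodization < 0) or np.any(self.apodization > 1):
            raise ValueError("apodization weights must lie in [0, 1]")


@dataclass
class ChannelData:
    """Receive traces for a full acquisition.

    ``traces`` is real, indexed (transmit event, element, time sample);
    sample ``n`` of any trace is at absolute time ``t0 + n/sampling_rate``
    where time zero is the firing of the earliest-fired element of each
    event (delay reference).  ``delays``/``apodization`` are per event
    and element, matching the rows of ``traces``.
    """

    traces: np.ndarray
    sampling_rate: float
    t0: float = 0.0
    delays: np.ndarray | None = None
    apodization: np.ndarray | None = None
    foci: np.ndarray | None = None  # (n_tx, 2): (theta, r) per event

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces)
        if self.traces.ndim != 3:
            raise ValueError("traces must be (n_tx, n_rx, n_t)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if np.any(~np.isfinite(self.traces)):
            raise ValueError("traces must be finite")

    @property
    def n_events(self) -> int:
        return self.traces.shape[0]

    @property
    def n_elements(self) -> int:
        return self.traces.shape[1]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[2]

    @property
    def time_axis(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate


def focal_delays(probe: CurvilinearProbe, focus_theta: float, focus_r: float,
                 c: float, active_elements) -> np.ndarray:
    """Geometric focusing delays, seconds, for the active elements.

    The farthest active element fires at t = 0 and every wavefront
    arrives at the focus simultaneously: ``τ_e = (max_e d_e − d_e)/c``.
    Inactive elements get delay 0 (they are silenced by apodization).
    """
    if focus_r <= probe.radius_r0:
        raise ValueError("focus must lie beyond the array (focus_r > r0)")
    active = np.asarray(active_elements, dtype=int)
    pos = element_positions(probe)
    fx, fz = polar_to_cartesian(focus_theta, focus_r)
    d = np.hypot(pos[:, 0] - fx, pos[:, 1] - fz)
    tau = np.zeros(probe.n_elements)
    tau[active] = (d[active].max() - d[active]) / c
    return tau


def make_focused_event(probe: CurvilinearProbe, focus_theta: float,
                       focus_r: float, c: float, n_active: int,
                       index: int = 0) -> TransmitEvent:
    """Focused transmit with a contiguous subaperture centered on the beam.

    The subaperture is the ``n_active`` elements nearest the beam axis
    ``focus_theta`` (clipped at the array ends — walking aperture),
    uniformly apodized.
    """
    th = element_angles(probe)
    center = int(np.argmin(np.abs(th - focus_theta)))
    lo = center - n_active // 2
    lo = max(0, min(lo, probe.n_elements - n_active))
    active = np.arange(lo, min(lo + n_active, probe.n_elements))
    apod = np.zeros(probe.n_elements)
    apod[active] = 1.0
    tau = focal_delays(probe, focus_theta, focus_r, c, active)
    return TransmitEvent(tau, apod, index, focus_theta, focus_r)


def _nearest_element_fill(probe: CurvilinearProbe, theta_axis: np.ndarray,
                          active_mask: np.ndarray) -> np.ndarray:
    """Map each grid sample inside the active aperture to its element.

    Returns an int array (n_theta,) holding the nearest active element
    index, or -1 outside the aperture.  Elements own their full arc
    width (center ± pitch/2), so the fill is a contiguous boxcar.
    """
    theta_axis = np.asarray(theta_axis, dtype=float)
    dth = theta_axis[1] - theta_axis[0]
    if dth > probe.angular_pitch * (1 + 1e-9):
        raise ValueError("theta grid is coarser than the element spacing")
    el_th = element_angles(probe)
    act = np.flatnonzero(active_mask)
    if act.size == 0:
        return np.full(theta_axis.size, -1, dtype=int)
    owner = np.full(theta_axis.size, -1, dtype=int)
    half = probe.angular_pitch / 2.0
    lo = el_th[act[0]] - half
    hi = el_th[act[-1]] + half
    inside = (theta_axis >= lo) & (theta_axis <= hi)
    # nearest active element for each inside sample
    pick = np.argmin(np.abs(theta_axis[inside, None] - el_th[None, act]), axis=1)
    owner[inside] = act[pick]
    return owner


def init_transmit_field(probe: CurvilinearProbe, event: TransmitEvent,
                        pulse: Pulse, theta_axis, freq_axis) -> PolarField:
    """Boundary transmit field ``A(θ) P(f) exp(-j 2π f τ(θ))`` at r0."""
    theta_axis = np.asarray(theta_axis, dtype=float)
    freq_axis = np.asarray(freq_axis, dtype=float)
    owner = _nearest_element_fill(probe, theta_axis, event.apodization > 0)
    vals = np.zeros((theta_axis.size, freq_axis.size), dtype=complex)
    inside = owner >= 0
    P = pulse.spectrum(freq_axis)
    tau = event.delays[owner[inside]]
    amp = event.apodization[owner[inside]]
    vals[inside] = amp[:, None] * P[None, :] * np.exp(
        -2j * np.pi * freq_axis[None, :] * tau[:, None])
    return PolarField(vals, probe.radius_r0, theta_axis, freq_axis)


def band_freq_axis(n_samples: int, sampling_rate: float, pulse: Pulse,
                   threshold_db: float = -40.0) -> tuple[np.ndarray, np.ndarray]:
    """Positive-frequency rfft bins inside the pulse's support.

    Returns ``(freq_axis, bin_indices)`` into the length-``n_samples``
    rfft spectrum.  Raises if the band reaches Nyquist.
    """
    f = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    lo, hi = pulse.support(threshold_db)
    if hi >= sampling_rate / 2.0:
        raise ValueError("pulse band exceeds Nyquist for this sampling rate")
    idx = np.flatnonzero((f >= lo) & (f <= hi) & (f > 0))
    if idx.size == 0:
        raise ValueError("empty band")
    return f[idx], idx


def init_receive_field(channel: ChannelData, event_index: int,
                       probe: CurvilinearProbe, theta_axis,
                       freq_axis, bin_indices,
                       rx_weights: np.ndarray | None = None) -> PolarField:
    """Receive boundary field at r0 from one event's channel traces.

    The temporal analysis spectrum of each element trace (compensated
    for the recording start time ``t0``) is placed on the angular grid
    samples owned by that element.  Only the supplied band bins are
    retained; ``freq_axis``/``bin_indices`` normally come from
    :func:`band_freq_axis`.
    """
    theta_axis = np.asarray(theta_axis, dtype=float)
    freq_axis = np.asarray(freq_axis, dtype=float)
    traces = channel.traces[event_index]
    dt = 1.0 / channel.sampling_rate
    spectra = np.fft.rfft(traces, axis=-1)[:, bin_indices] * dt
    spectra *= np.exp(-2j * np.pi * freq_axis * channel.t0)[None, :]
    if rx_weights is not None:
        spectra = spectra * np.asarray(rx_weights)[:, None]
    owner = _nearest_element_fill(probe, theta_axis,
                                  np.ones(probe.n_elements, dtype=bool))
    vals = np.zeros((theta_axis.size, freq_axis.size), dtype=complex)
    inside = owner >= 0
    vals[inside] = spectra[owner[inside]]
    return PolarField(vals, probe.radius_r0, theta_axis, freq_axis)
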