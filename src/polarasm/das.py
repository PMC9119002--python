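"""Virtual-source synthetic-aperture delay-and-sum baseline.

Each focused transmit beam is modeled as a virtual point source at its
focus: the transmit wavefront is assumed spherical (circular in 2-D)
about the focus, valid inside a cone about the beam axis, diverging
beyond the focus and converging before it (two-sided hyperbolic model).
For a pixel P, virtual source V on beam axis v̂ and receive element E,

    t(P, E) = t_focus ± |P − V| / c + |P − E| / c,

with the + sign beyond the focus, where ``t_focus`` is the (exact)
arrival time of the focused wavefront at V computed from the stored
transmit delays.  Each element's analytic-signal trace is sampled at
``t(P, E)`` (linear interpolation), elements inside a growing receive
aperture (constant f-number) are summed, and per-shot images are
coherently compounded.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import hilbert

from .geometry import CurvilinearProbe, PolarGrid, element_angles, \
    polar_to_cartesian
from .migration import PolarImage
from .wavefield import ChannelData

__all__ = ["VirtualSource", "das_virtual_source"]


class VirtualSource:
    """Virtual transmit source: beam axis angle and focal radius."""

    def __init__(self, theta: float, r: float, r0: float,
                 validity_half_angle: float = np.deg2rad(15.0)):
        if r <= r0:
            raise ValueError("virtual source must lie beyond the array")
        self.theta = float(theta)
        self.r = float(r)
        self.validity_half_angle = float(validity_half_angle)

    @property
    def position(self) -> tuple[float, float]:
        return polar_to_cartesian(self.theta, self.r)

    @property
    def direction(self) -> tuple[float, float]:
        return float(np.sin(self.theta)), float(np.cos(self.theta))


def das_virtual_source(
    channel: ChannelData,
    probe: CurvilinearProbe,
    grid: PolarGrid,
    c: float,
    f_number: float = 2.0,
    validity_half_angle: float = np.deg2rad(15.0),
    rx_apodization: str = "rect",
    near_focus_radius: float = 2e-3,
) -> PolarImage:
    """Beamform all events in ``channel`` and coherently compound.

    ``channel`` must carry per-event delays, apodization and foci (as
    written by the reference simulator / the channel container).
    ``f_number = 0`` disables receive aperture growth (all elements).
    Pixel/element/event combinations whose delay falls outside the
    recorded window contribute zero and are tallied in the metadata.
    """
    if channel.foci is None or channel.delays is None \
            or channel.apodization is None:
        raise ValueError("channel data lacks delays/apodization/foci")
    if rx_apodization not in ("rect", "hann"):
        raise ValueError("rx_apodization must be 'rect' or 'hann'")
    el_th = element_angles(probe)
    ex, ez = polar_to_cartesian(el_th, probe.radius_r0)
    X, Z = polar_to_cartesian(grid.theta_samples[:, None],
                              grid.r_samples[None, :])
    Rpix = grid.r_samples[None, :]  # broadcast over theta
    Tpix = grid.theta_samples[:, None]
    fs = channel.sampling_rate
    nt = channel.n_samples
    cos_cone = np.cos(validity_half_angle)

    image = np.zeros((grid.n_theta, grid.n_r), dtype=np.complex64)
    out_of_window = 0
    for i in range(channel.n_events):
        vs = VirtualSource(channel.foci[i, 0], channel.foci[i, 1],
                           probe.radius_r0, validity_half_angle)
        vx, vz = vs.position
        dx_hat, dz_hat = vs.direction
        active = np.flatnonzero(channel.apodization[i] > 0)
        e_ref = active[np.argmin(np.abs(el_th[active] - vs.theta))]
        t_focus = channel.delays[i, e_ref] + np.hypot(
            ex[e_ref] - vx, ez[e_ref] - vz) / c

        dxv = X - vx
        dzv = Z - vz
        dv = np.hypot(dxv, dzv)
        s = dxv * dx_hat + dzv * dz_hat  # signed distance along beam axis
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.abs(s) / dv
        # the cone test is ill-conditioned right at the virtual source;
        # pixels within a small ball of the focus are always valid
        valid = (dv <= near_focus_radius) | (cosang >= cos_cone)
        t_tx = t_focus + np.sign(s) * dv / c

        analytic = hilbert(channel.traces[i], axis=-1).astype(np.complex64)
        shot = np.zeros((grid.n_theta, grid.n_r), dtype=np.complex64)
        for e in range(probe.n_elements):
            if f_number > 0:
                half_ap = (Rpix - probe.radius_r0) / (2.0 * f_number)
                arc = np.abs(probe.radius_r0 * (el_th[e] - Tpix))
                in_ap = arc <= half_ap
            else:
                in_ap = np.ones_like(valid)
            mask = valid & in_ap
            if not np.any(mask):
                continue
            t = t_tx[mask] + np.hypot(X[mask] - ex[e], Z[mask] - ez[e]) / c
            idx = (t - channel.t0) * fs
            inside = (idx >= 0) & (idx <= nt - 2)
            out_of_window += int(np.count_nonzero(~inside))
            idx = np.clip(idx, 0, nt - 2)
            i0 = idx.astype(np.int64)
            frac = (idx - i0).astype(np.float32)
            tr = analytic[e]
            samp = tr[i0] * (1.0 - frac) + tr[i0 + 1] * frac
            samp[~inside] = 0.0
            if rx_apodization == "hann" and f_number > 0:
                arc_b = np.broadcast_to(arc, mask.shape)[mask]
                half_b = np.broadcast_to(half_ap, mask.shape)[mask]
                samp = samp * np.cos(
                    0.5 * np.pi * arc_b / half_b).astype(np.float32) ** 2
            vals = np.zeros(mask.shape, dtype=np.complex64)
            vals[mask] = samp
            shot += vals
        image += shot
    meta = {
        "beamformer": "das_virtual_source",
        "f_number": f_number,
        "validity_half_angle_deg": float(np.rad2deg(validity_half_angle)),
        "rx_apodization": rx_apodization,
        "out_of_window_samples": out_of_window,
        "n_events": channel.n_events,
    }
    return PolarImage(image, grid, per_shot=False, metadata=meta)
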