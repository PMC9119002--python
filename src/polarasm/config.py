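"""Configuration parsing and transmit-sequence generation.

One YAML file describes a whole experiment: probe (preset name or
explicit geometry), transmit sequence, medium, reconstruction grid and
beamforming options.  Keys carry explicit units (``radius_mm``,
``center_frequency_mhz``, ``span_deg`` ...); everything is converted to
SI on load.  CLI flags override file values.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import yaml

from .geometry import PROBE_PRESETS, CurvilinearProbe, PolarGrid
from .wavefield import Pulse, TransmitEvent, make_focused_event

__all__ = ["ReconConfig", "load_config", "walking_aperture_sequence"]


@dataclass
class ReconConfig:
    """Resolved experiment configuration (all SI units)."""

    probe: CurvilinearProbe
    pulse: Pulse
    sound_speed: float = 1540.0
    # sequence
    n_beams: int = 1
    span: float = 0.0              # angular span of beam axes, radians
    focal_depth: float = 20e-3     # depth of the transmit focus below r0
    subaperture: int = 20          # elements per transmit event
    # grid
    n_theta: int = 512
    dr: float | None = None        # defaults to half a wavelength
    max_depth: float = 80e-3
    theta_span: float | None = None
    # beamforming
    band_mode: str = "flat"
    band_taper: float = 0.25
    f_number: float = 0.0
    das_f_number: float = 2.0
    window_taper: float = 0.25
    seed: int = 0
    extras: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        half_span = self.span / 2.0
        limit = self.probe.angular_span / 2.0 + self.probe.angular_pitch
        if half_span > limit:
            raise ValueError("beam angles fall outside the probe aperture")
        for name in ("sound_speed", "focal_depth", "max_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def grid(self) -> PolarGrid:
        return PolarGrid.for_probe(self.probe, self.max_depth, self.dr,
                                   self.n_theta, self.theta_span)

    def events(self) -> list[TransmitEvent]:
        return walking_aperture_sequence(
            self.probe, self.n_beams, self.span, self.focal_depth,
            self.subaperture, self.sound_speed)

    def to_dict(self) -> dict:
        return {
            "probe": {"n_elements": self.probe.n_elements,
                      "radius_mm": self.probe.radius_r0 * 1e3,
                      "pitch_mm": self.probe.pitch * 1e3,
                      "center_frequency_mhz":
                          self.probe.center_frequency / 1e6},
            "pulse": {"center_frequency_mhz":
                          self.pulse.center_frequency / 1e6,
                      "fractional_bandwidth":
                          self.pulse.fractional_bandwidth},
            "medium": {"sound_speed_m_s": self.sound_speed},
            "sequence": {"n_beams": self.n_beams,
                         "span_deg": float(np.rad2deg(self.span)),
                         "focal_depth_mm": self.focal_depth * 1e3,
                         "subaperture": self.subaperture},
            "grid": {"n_theta": self.n_theta,
                     "dr_mm": None if self.dr is None else self.dr * 1e3,
                     "max_depth_mm": self.max_depth * 1e3,
                     "theta_span_deg":
                         None if self.theta_span is None
                         else float(np.rad2deg(self.theta_span))},
            "beamforming": {"band_mode": self.band_mode,
                            "band_taper": self.band_taper,
                            "f_number": self.f_number,
                            "das_f_number": self.das_f_number,
                            "window_taper": self.window_taper},
            "seed": self.seed,
        }


def _probe_from_dict(d) -> CurvilinearProbe:
    if isinstance(d, str):
        try:
            return PROBE_PRESETS[d.lower()]
        except KeyError:
            raise ValueError(f"unknown probe preset {d!r}; "
                             f"available: {sorted(PROBE_PRESETS)}") from None
    return CurvilinearProbe(
        n_elements=int(d["n_elements"]),
        radius_r0=float(d["radius_mm"]) * 1e-3,
        pitch=float(d["pitch_mm"]) * 1e-3,
        center_frequency=float(d.get("center_frequency_mhz", 3.5)) * 1e6,
    )


def load_config(path_or_dict, **overrides) -> ReconConfig:
    """Load a YAML config file (or an already-parsed dict)."""
    if isinstance(path_or_dict, dict):
        raw = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    probe = _probe_from_dict(raw.get("probe", "c52v"))
    pd = raw.get("pulse", {})
    pulse = Pulse(float(pd.get("center_frequency_mhz",
                               probe.center_frequency / 1e6)) * 1e6,
                  float(pd.get("fractional_bandwidth", 0.5)))
    seq = raw.get("sequence", {})
    grid = raw.get("grid", {})
    bf = raw.get("beamforming", {})
    med = raw.get("medium", {})
    return ReconConfig(
        probe=probe,
        pulse=pulse,
        sound_speed=float(med.get("sound_speed_m_s", 1540.0)),
        n_beams=int(seq.get("n_beams", 1)),
        span=np.deg2rad(float(seq.get("span_deg", 0.0))),
        focal_depth=float(seq.get("focal_depth_mm", 20.0)) * 1e-3,
        subaperture=int(seq.get("subaperture", 20)),
        n_theta=int(grid.get("n_theta", 512)),
        dr=None if grid.get("dr_mm") is None else float(grid["dr_mm"]) * 1e-3,
        max_depth=float(grid.get("max_depth_mm", 80.0)) * 1e-3,
        theta_span=None if grid.get("theta_span_deg") is None
        else np.deg2rad(float(grid["theta_span_deg"])),
        band_mode=str(bf.get("band_mode", "flat")),
        band_taper=float(bf.get("band_taper", 0.25)),
        f_number=float(bf.get("f_number", 0.0)),
        das_f_number=float(bf.get("das_f_number", 2.0)),
        window_taper=float(bf.get("window_taper", 0.25)),
        seed=int(raw.get("seed", 0)),
        extras=raw.get("extras", {}),
    )


def walking_aperture_sequence(probe: CurvilinearProbe, n_beams: int,
                              span: float, focal_depth: float,
                              subaperture: int,
                              sound_speed: float) -> list[TransmitEvent]:
    """Focused beams with axes uniformly spanning ``[-span/2, +span/2]``.

    Each beam's subaperture walks with the beam axis and clips at the
    array ends; the focus sits at ``r0 + focal_depth`` on the beam axis.
    """
    if n_beams < 1:
        raise ValueError("n_beams must be >= 1")
    if n_beams == 1:
        axes = np.array([0.0])
    else:
        axes = np.linspace(-span / 2.0, span / 2.0, n_beams)
    focus_r = probe.radius_r0 + focal_depth
    return [make_focused_event(probe, th, focus_r, sound_speed,
                               subaperture, index=i)
            for i, th in enumerate(axes)]
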