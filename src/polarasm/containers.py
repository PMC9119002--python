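"""HDF5 interchange containers for channel data, images and field cubes.

The channel container is the contract between the reference simulator and
both beamformers; layouts use SI units throughout.  Every writer stamps a
format version and the package version plus a JSON dump of the resolved
configuration so any container is self-describing.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from . import __version__
from .geometry import CurvilinearProbe, PolarGrid
from .migration import PolarImage
from .wavefield import ChannelData, Pulse

__all__ = [
    "write_channel_container",
    "read_channel_container",
    "write_image_container",
    "read_image_container",
    "write_field_cube",
    "read_field_cube",
]

FORMAT_VERSION = "1"

_CHANNEL_REQUIRED = ["channel_data", "sampling_rate", "t0", "delays",
                     "apodization", "probe/n_elements", "probe/radius",
                     "probe/pitch", "pulse/center_frequency",
                     "pulse/fractional_bandwidth"]


class FormatError(ValueError):
    """A container is missing mandatory content or has the wrong version."""


def _stamp(h: h5py.File, config: dict | None) -> None:
    h.attrs["format_version"] = FORMAT_VERSION
    h.attrs["package_version"] = __version__
    h.attrs["config_json"] = json.dumps(config or {}, default=float)


def _check_version(h: h5py.File, path: str) -> None:
    ver = h.attrs.get("format_version")
    if ver is None:
        raise FormatError(f"{path}: missing format_version attribute")
    if str(ver) != FORMAT_VERSION:
        raise FormatError(f"{path}: format_version {ver!r} unsupported "
                          f"(expected {FORMAT_VERSION!r})")


def write_channel_container(path, channel: ChannelData,
                            probe: CurvilinearProbe, pulse: Pulse,
                            config: dict | None = None) -> None:
    """Write the full acquisition (traces + sequence + probe + pulse)."""
    if channel.delays is None or channel.apodization is None:
        raise ValueError("channel data must carry delays and apodization")
    with h5py.File(path, "w") as h:
        h.create_dataset("channel_data",
                         data=channel.traces.astype(np.float32))
        h["sampling_rate"] = float(channel.sampling_rate)
        h["t0"] = float(channel.t0)
        h.create_dataset("delays", data=channel.delays)
        h.create_dataset("apodization", data=channel.apodization)
        if channel.foci is not None:
            h.create_dataset("foci", data=channel.foci)
        g = h.create_group("probe")
        g["n_elements"] = probe.n_elements
        g["radius"] = probe.radius_r0
        g["pitch"] = probe.pitch
        g["center_frequency"] = probe.center_frequency
        g = h.create_group("pulse")
        g["center_frequency"] = pulse.center_frequency
        g["fractional_bandwidth"] = pulse.fractional_bandwidth
        _stamp(h, config)


def read_channel_container(path) -> tuple[ChannelData, CurvilinearProbe, Pulse]:
    with h5py.File(path, "r") as h:
        _check_version(h, str(path))
        for name in _CHANNEL_REQUIRED:
            if name not in h:
                raise FormatError(f"{path}: missing dataset /{name}")
        probe = CurvilinearProbe(
            int(h["probe/n_elements"][()]),
            float(h["probe/radius"][()]),
            float(h["probe/pitch"][()]),
            float(h["probe/center_frequency"][()])
            if "probe/center_frequency" in h else 3.5e6,
        )
        pulse = Pulse(float(h["pulse/center_frequency"][()]),
                      float(h["pulse/fractional_bandwidth"][()]))
        channel = ChannelData(
            h["channel_data"][...],
            float(h["sampling_rate"][()]),
            float(h["t0"][()]),
            h["delays"][...],
            h["apodization"][...],
            h["foci"][...] if "foci" in h else None,
        )
    return channel, probe, pulse


def write_image_container(path, image: PolarImage,
                          config: dict | None = None) -> None:
    with h5py.File(path, "w") as h:
        g = h.create_group("image")
        g.create_dataset("real", data=image.values.real.astype(np.float32))
        g.create_dataset("imag", data=image.values.imag.astype(np.float32))
        h.create_dataset("theta", data=image.grid.theta_samples)
        h.create_dataset("r", data=image.grid.r_samples)
        h.attrs["per_shot"] = bool(image.per_shot)
        h.attrs["image_metadata"] = json.dumps(image.metadata, default=float)
        _stamp(h, config)


def read_image_container(path) -> PolarImage:
    with h5py.File(path, "r") as h:
        _check_version(h, str(path))
        for name in ["image/real", "image/imag", "theta", "r"]:
            if name not in h:
                raise FormatError(f"{path}: missing dataset /{name}")
        grid = PolarGrid(h["theta"][...], h["r"][...])
        vals = h["image/real"][...].astype(np.complex64)
        vals += 1j * h["image/imag"][...].astype(np.complex64)
        meta = json.loads(h.attrs.get("image_metadata", "{}"))
        per_shot = bool(h.attrs.get("per_shot", False))
    return PolarImage(vals, grid, per_shot=per_shot, metadata=meta)


def write_field_cube(path, cube: np.ndarray, theta: np.ndarray,
                     r: np.ndarray, f: np.ndarray,
                     config: dict | None = None) -> None:
    """Field cube indexed (theta, r_shell, f), complex."""
    with h5py.File(path, "w") as h:
        g = h.create_group("field")
        g.create_dataset("real", data=np.real(cube).astype(np.float32))
        g.create_dataset("imag", data=np.imag(cube).astype(np.float32))
        h.create_dataset("theta", data=np.asarray(theta, dtype=float))
        h.create_dataset("r", data=np.asarray(r, dtype=float))
        h.create_dataset("f", data=np.asarray(f, dtype=float))
        _stamp(h, config)


def read_field_cube(path) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    with h5py.File(path, "r") as h:
        _check_version(h, str(path))
        for name in ["field/real", "field/imag", "theta", "r", "f"]:
            if name not in h:
                raise FormatError(f"{path}: missing dataset /{name}")
        cube = h["field/real"][...] + 1j * h["field/imag"][...]
        return cube, h["theta"][...], h["r"][...], h["f"][...]
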