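"""Configuration files, run archives and tabular exports.

Configurations are plain YAML mirroring :class:`~orisel.params.RunConfig`
(missing keys take the Table-of-parameters defaults; unknown keys are
rejected). Run artefacts go into one HDF5 container per run plus
human-readable CSV/JSON summaries.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .params import ModelParams, MosaicSpec, DevSchedule, RunConfig
from .mosaic import ChannelArray
from .mapping import OrientationMap, MapSummary

_SECTIONS = {"mosaic": MosaicSpec, "params": ModelParams,
             "schedule": DevSchedule}


def _build_section(cls, data: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: "
                         f"{sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data or {})
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = data.pop(name, {}) or {}
        if not isinstance(section, dict):
            raise ValueError(f"section '{name}' must be a mapping")
        kwargs[name] = _build_section(cls, section)
    scale = data.pop("scale", "full")
    if data:
        raise ValueError(f"unknown config sections: {sorted(data)}")
    return RunConfig(scale=scale, **kwargs)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; an empty file yields all defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def channels_to_frame(channels: ChannelArray) -> pd.DataFrame:
    return pd.DataFrame({
        "j": np.arange(len(channels)),
        "x_deg": channels.x,
        "y_deg": channels.y,
        "sign": channels.sign,
    })


def save_channels_csv(channels: ChannelArray, path) -> None:
    channels_to_frame(channels).to_csv(path, index=False)


def save_map_csv(omap: OrientationMap, path) -> None:
    ny, nx = omap.shape
    half_y = (ny - 1) / 2 * omap.spacing
    half_x = (nx - 1) / 2 * omap.spacing
    ys = np.linspace(-half_y, half_y, ny)
    xs = np.linspace(-half_x, half_x, nx)
    gx, gy = np.meshgrid(xs, ys)
    pd.DataFrame({
        "x_deg": gx.ravel(), "y_deg": gy.ravel(),
        "orientation_deg": omap.orientation_deg.ravel(),
    }).to_csv(path, index=False)


def save_summary_json(summary: MapSummary | dict, path) -> None:
    data = summary.to_dict() if hasattr(summary, "to_dict") else summary
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)


class RunArchive:
    """One HDF5 container per run, with seeds and units as attributes."""

    def __init__(self, path, mode: str = "a"):
        self.path = Path(path)
        self.file = h5py.File(self.path, mode)

    def close(self) -> None:
        self.file.close()

    def __enter__(self) -> "RunArchive":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def save_config(self, config: RunConfig) -> None:
        self.file.attrs["config_yaml"] = yaml.safe_dump(config.to_dict())

    def load_config(self) -> RunConfig:
        return config_from_dict(
            yaml.safe_load(self.file.attrs["config_yaml"]))

    def save_channels(self, channels: ChannelArray) -> None:
        g = self.file.require_group("mosaic")
        for name, data in (("x", channels.x), ("y", channels.y),
                           ("sign", channels.sign)):
            if name in g:
                del g[name]
            g.create_dataset(name, data=data)
        g.attrs["units"] = "deg"
        g.attrs["seed"] = channels.spec.seed

    def load_channels(self, spec: MosaicSpec) -> ChannelArray:
        g = self.file["mosaic"]
        return ChannelArray(g["x"][...], g["y"][...], g["sign"][...], spec)

    def save_array(self, name: str, data: np.ndarray,
                   units: str = "") -> None:
        if name in self.file:
            del self.file[name]
        ds = self.file.create_dataset(name, data=data)
        if units:
            ds.attrs["units"] = units

    def load_array(self, name: str) -> np.ndarray:
        return self.file[name][...]

    def __contains__(self, name: str) -> bool:
        return name in self.file
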