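"""TOML configuration loading.

A config file can carry any subset of the sections below; omitted keys keep
the reference defaults::

    [calibration]
    dx = 0.1
    dy = 0.1
    dz = 0.7
    dt = 15.0

    [segmentation]
    slic_labels = 3
    blur_sigma = 5.0
    min_region_voxels = 200

    [vesselness]
    alpha = 0.5
    beta = 0.5
    scales = [1.0, 1.5, 2.0]

    [tracking]
    lookback_frames = 5
    cutoff_radius_px = 25.0

    [filter]
    min_max_length_um = 3.0
    min_lifetime_frames = 2

    [simulate]
    frames = 60
    n_filopodia = 8
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path
from typing import Any

from .core import VoxelCalibration
from .pipeline import PipelineConfig
from .quantify import FilterConfig
from .segmentation import SegmentationConfig, VesselnessParams
from .simulate import SimConfig
from .tracking import TrackingConfig

__all__ = ["load_toml", "pipeline_config_from_dict", "calibration_from_dict"]

_SECTIONS = {
    "segmentation": SegmentationConfig,
    "vesselness": VesselnessParams,
    "tracking": TrackingConfig,
    "filter": FilterConfig,
    "simulate": SimConfig,
}


def _build(cls, data: dict[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list) and f.type.startswith("tuple"):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


def calibration_from_dict(data: dict[str, Any]) -> VoxelCalibration:
    return _build(VoxelCalibration, data)


def pipeline_config_from_dict(doc: dict[str, Any]) -> PipelineConfig:
    cfg = PipelineConfig()
    if "segmentation" in doc:
        cfg.segmentation = _build(SegmentationConfig, doc["segmentation"])
    if "vesselness" in doc:
        cfg.vesselness = _build(VesselnessParams, doc["vesselness"])
    if "tracking" in doc:
        cfg.tracking = _build(TrackingConfig, doc["tracking"])
    if "filter" in doc:
        cfg.filters = _build(FilterConfig, doc["filter"])
    if "merge_gap" in doc:
        cfg.merge_gap = float(doc["merge_gap"])
    return cfg


def load_toml(path: str | Path) -> dict[str, Any]:
    """Parse a TOML file into typed config objects.

    Returns a dict with any of the keys ``calibration``, ``pipeline`` (a
    :class:`PipelineConfig` assembled from the segmentation / vesselness /
    tracking / filter sections) and ``simulate``.
    """
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    unknown = set(doc) - set(_SECTIONS) - {"calibration", "merge_gap"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    out: dict[str, Any] = {"pipeline": pipeline_config_from_dict(doc)}
    if "calibration" in doc:
        out["calibration"] = calibration_from_dict(doc["calibration"])
    if "simulate" in doc:
        out["simulate"] = _build(SimConfig, doc["simulate"])
    return out
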