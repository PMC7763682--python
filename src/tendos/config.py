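"""Plain-text (YAML) configuration files mapped onto the config dataclasses.

Recognised blocks and keys::

    preprocess: {loff, butter_order, notch_freqs, notch_q, internal_fs}
    quality:    {gamma_ms, q, window_before, window_after}
    shrinkage:  {xi, metric}
    delineator: {search_window, zhang_w_ms, carlos_ref_offset_ms,
                 wavelet_scales, wavelet_threshold_frac, twave_polarity}
    base_detector, tsqi_pair, channel

Unknown keys raise, so typos never silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .delineate import DelineatorConfig
from .pipeline import PipelineConfig
from .preprocess import PreprocessConfig
from .quality import QualityConfig
from .shrinkage import ShrinkageConfig

__all__ = ["load_config"]

_BLOCKS = {
    "preprocess": PreprocessConfig,
    "quality": QualityConfig,
    "shrinkage": ShrinkageConfig,
    "delineator": DelineatorConfig,
}
_TUPLE_KEYS = {"notch_freqs", "search_window", "wavelet_scales", "tsqi_pair"}


def _build(cls, block: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kw = {k: tuple(v) if k in _TUPLE_KEYS and isinstance(v, list) else v
          for k, v in block.items()}
    return cls(**kw)


def load_config(path) -> PipelineConfig:
    """Read a YAML config file into a :class:`PipelineConfig`."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must hold a mapping")
    kw = {}
    for name, cls in _BLOCKS.items():
        if name in raw:
            kw[name] = _build(cls, raw.pop(name) or {})
    for key in ("base_detector", "channel"):
        if key in raw:
            kw[key] = raw.pop(key)
    if "tsqi_pair" in raw:
        kw["tsqi_pair"] = tuple(raw.pop("tsqi_pair"))
    if raw:
        raise ValueError(f"unknown config keys: {sorted(raw)}")
    return PipelineConfig(**kw)
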