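"""YAML run configuration.

One file configures every stage; all blocks are optional and fall back to
the documented defaults.  Layout::

    kinetics:            # SI units: rates 1/M/s and 1/s, concentrations M
      kon1: 1.0e5
      koff1: 1.0e-4
      ...
    synth:               # trace generator (see SyntheticSpec)
      duration: 60.0
      sample_rate: 1000.0
      ...
    signal_models:       # analyte -> amplitude anchors (a.u.)
      insulin:  {blank_amplitude: 6.5, ref_conc_pM: 1000.0, ref_amplitude: 45.0}
      glucagon: {blank_amplitude: 15.0, ref_conc_pM: 100.0, ref_amplitude: 60.0}
    channel_map:         # channel -> [qdot_nm, analyte]
      ch605: [605, glucagon]
      ch655: [655, insulin]
    analysis:            # AnalysisConfig fields
      scan_duration_s: 60.0
      rel_threshold: 0.10
      ...
    experiment:          # optional sample sequence for `simulate`
      samples:
        - {}
        - {insulin: 1000.0, glucagon: 10.0}
"""

from __future__ import annotations

import dataclasses
from typing import Any, Mapping

import yaml

from .kinetics import KineticsParams
from .pipeline import AnalysisConfig, ChannelMap
from .synth import AnalyteSignalModel, SyntheticSpec, default_signal_models

__all__ = [
    "load_config",
    "kinetics_from_config",
    "synth_from_config",
    "analysis_from_config",
    "channel_map_from_config",
    "signal_models_from_config",
]


def load_config(path: str | None) -> dict[str, Any]:
    """Load a YAML config file; None or an empty file yields {}."""
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def _build(cls, block: Mapping[str, Any] | None, **overrides):
    field_types = {f.name: f.type for f in dataclasses.fields(cls)}
    block = dict(block or {})
    unknown = set(block) - set(field_types)
    if unknown:
        raise ValueError(f"unknown {cls.__name__} option(s): {sorted(unknown)}")
    # YAML 1.1 reads "2.0e5" (no sign in the exponent) as a string; coerce
    # numeric-looking strings for numeric fields.
    for key, value in list(block.items()):
        if isinstance(value, str) and str(field_types[key]) in ("float", "int"):
            block[key] = float(value) if "float" in str(field_types[key]) else int(value)
    block.update(overrides)
    return cls(**block)


def kinetics_from_config(cfg: Mapping[str, Any]) -> KineticsParams:
    return _build(KineticsParams, cfg.get("kinetics"))


def synth_from_config(cfg: Mapping[str, Any], **overrides) -> SyntheticSpec:
    block = dict(cfg.get("synth") or {})
    if "amplitude_mean" in block:
        block["amplitude_mean"] = {k: float(v) for k, v in block["amplitude_mean"].items()}
    if "crosstalk" in block:
        block["crosstalk"] = tuple(tuple(float(v) for v in row) for row in block["crosstalk"])
    if "baseline_coeffs" in block:
        block["baseline_coeffs"] = tuple(float(v) for v in block["baseline_coeffs"])
    return _build(SyntheticSpec, block, **overrides)


def analysis_from_config(cfg: Mapping[str, Any], **overrides) -> AnalysisConfig:
    block = dict(cfg.get("analysis") or {})
    if "f0_scan_indices" in block:
        block["f0_scan_indices"] = tuple(int(i) for i in block["f0_scan_indices"])
    if "f0_values" in block:
        block["f0_values"] = tuple((str(k), float(v)) for k, v in dict(block["f0_values"]).items())
    return _build(AnalysisConfig, block, **overrides)


def channel_map_from_config(cfg: Mapping[str, Any]) -> ChannelMap:
    block = cfg.get("channel_map")
    if not block:
        return ChannelMap()
    mapping = tuple(
        (str(ch), int(qdot), str(analyte)) for ch, (qdot, analyte) in block.items()
    )
    return ChannelMap(mapping=mapping)


def signal_models_from_config(cfg: Mapping[str, Any]) -> dict[str, AnalyteSignalModel]:
    block = cfg.get("signal_models")
    if not block:
        models = default_signal_models()
    else:
        kinetics = kinetics_from_config(cfg)
        models = {}
        for analyte, opts in block.items():
            models[analyte] = AnalyteSignalModel(
                analyte=str(analyte),
                blank_amplitude=float(opts["blank_amplitude"]),
                ref_conc_pM=float(opts["ref_conc_pM"]),
                ref_amplitude=float(opts["ref_amplitude"]),
                kinetics=kinetics,
                incubation_s=float(opts.get("incubation_s", 30.0)),
            )
    if "kinetics" in cfg and not block:
        kinetics = kinetics_from_config(cfg)
        models = {
            a: dataclasses.replace(m, kinetics=kinetics, _cache={}) for a, m in models.items()
        }
    return models
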