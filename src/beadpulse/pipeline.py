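"""End-to-end orchestration of the two-channel continuous measurement.

A run is a continuous dual-channel trace segmented into fixed-duration
scans (60 s by default).  For every channel and scan the peak pipeline is
applied (baseline -> peaks -> areas -> validity/F1), F1 is normalised by a
reference F0 (mean F1 of designated blank scans, or of the scans preceding
an in vivo event, or a fixed value), and the ratio is inverted through the
analyte's 4PL calibration into a time-stamped concentration estimate.
Channels are analysed independently; spectral crosstalk is *not* unmixed
(the physical channels are engineered to be spectrally clean), and
out-of-range ratios are flagged rather than clipped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .calibration import CalibrationData, CalibrationModel, fit_4pl
from .peaks import ScanSummary, Trace, detect_peaks, estimate_baseline, summarize_scan
from .synth import (
    CHANNELS,
    AnalyteSignalModel,
    SyntheticSpec,
    default_signal_models,
    generate_experiment,
)

__all__ = [
    "ChannelMap",
    "AnalysisConfig",
    "RunResult",
    "read_traces",
    "scan_summaries",
    "analyze_run",
    "recovery_experiment",
]

logger = logging.getLogger("beadpulse")

#: Insulin and glucagon spiked-sample pairs (pM) used in the continuous
#: multiplexed validation runs.
SAMPLE_PAIRS = {
    "A": {"insulin": 1000.0, "glucagon": 10.0},
    "B": {"insulin": 400.0, "glucagon": 40.0},
    "C": {"insulin": 100.0, "glucagon": 100.0},
    "D": {"insulin": 200.0, "glucagon": 80.0},
}


@dataclass(frozen=True)
class ChannelMap:
    """Bijective channel <-> QDot emission <-> analyte assignment.

    Default is the instrument's assignment: the 655 nm QDot reports insulin
    and the 605 nm QDot reports glucagon.
    """

    mapping: tuple[tuple[str, int, str], ...] = (
        ("ch605", 605, "glucagon"),
        ("ch655", 655, "insulin"),
    )

    def __post_init__(self) -> None:
        channels = [m[0] for m in self.mapping]
        analytes = [m[2] for m in self.mapping]
        if len(set(channels)) != len(channels) or len(set(analytes)) != len(analytes):
            raise ValueError("channel map must be bijective")

    @property
    def channel_to_analyte(self) -> dict[str, str]:
        return {c: a for c, _, a in self.mapping}

    @property
    def analyte_to_channel(self) -> dict[str, str]:
        return {a: c for c, _, a in self.mapping}


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the per-scan analysis and of the F0 normalisation mode."""

    scan_duration_s: float = 60.0
    baseline_degree: int = 3
    baseline_max_iter: int = 100
    rel_threshold: float = 0.10
    min_distance_s: float = 0.05
    min_peaks_per_30s: int = 10
    validity_window_s: float = 30.0
    f0_mode: str = "blank_scans"  # "blank_scans" | "first_scans" | "fixed"
    f0_scan_indices: tuple[int, ...] = ()
    f0_values: tuple[tuple[str, float], ...] = ()
    n_first_scans: int = 1

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunResult:
    """Per-scan summaries, concentration estimates and reproducibility metadata."""

    summaries: dict[str, list[ScanSummary]]
    records: list[dict]
    f0: dict[str, float]
    metadata: dict

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: scan_index, scan_start_s, channel, analyte, n_peaks,
        valid, F1, F_ratio, conc_pM, flag."""
        return pd.DataFrame(self.records)

    def report_hash(self) -> str:
        """Stable digest of the tidy report plus config snapshot."""
        frame = self.to_frame()
        payload = frame.to_csv(index=False) + json.dumps(self.metadata, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def read_traces(
    path,
    delimiter: str = ",",
    time_col: str = "time_s",
    channel_cols: Mapping[str, str] | None = None,
    comment: str | None = "#",
    decimal: str = ".",
    uniform_rel_tol: float = 1e-6,
) -> dict[str, Trace]:
    """Read delimited-text traces (oscilloscope export or synthetic).

    ``channel_cols`` maps channel label -> column name; by default every
    column except the time column is taken as a channel named after the
    column with a trailing ``_au`` stripped.  Rejects NaNs (with row
    numbers), non-increasing or non-uniform time stamps.
    """
    frame = pd.read_csv(path, sep=delimiter, comment=comment, decimal=decimal,
                        float_precision="round_trip")
    if time_col not in frame.columns:
        raise ValueError(f"missing time column {time_col!r} in {path}")
    if frame.isna().any().any():
        bad = frame.index[frame.isna().any(axis=1)].tolist()
        raise ValueError(f"malformed/NaN rows in {path} at data rows {bad[:10]}")
    t = frame[time_col].to_numpy(float)
    if len(t) >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError(f"time column in {path} is not strictly increasing")
        if np.max(np.abs(dt - dt[0])) > uniform_rel_tol * dt[0]:
            raise ValueError(f"time column in {path} is not uniformly sampled")

    if channel_cols is None:
        channel_cols = {
            (c[:-3] if c.endswith("_au") else c): c for c in frame.columns if c != time_col
        }
    traces = {}
    for channel, col in channel_cols.items():
        if col not in frame.columns:
            raise ValueError(f"missing channel column {col!r} in {path}")
        traces[channel] = Trace(t=t, y=frame[col].to_numpy(float), channel=channel)
    return traces


def _analyze_scan(trace: Trace, window: tuple[float, float], config: AnalysisConfig) -> ScanSummary:
    sub = trace.slice(*window)
    baseline = estimate_baseline(sub, degree=config.baseline_degree,
                                 max_iter=config.baseline_max_iter)
    peaks = detect_peaks(sub, baseline, rel_threshold=config.rel_threshold,
                         min_distance_s=config.min_distance_s)
    return summarize_scan(peaks, window, min_peaks_per_30s=config.min_peaks_per_30s,
                          validity_window_s=config.validity_window_s)


def scan_summaries(
    traces: Mapping[str, Trace], config: AnalysisConfig
) -> dict[str, list[ScanSummary]]:
    """Segment each channel into scan windows and run the peak pipeline."""
    out: dict[str, list[ScanSummary]] = {}
    for channel, trace in traces.items():
        if len(trace.t) == 0:
            out[channel] = []
            continue
        start, end = trace.t[0], trace.t[-1]
        n_scans = int(math.floor((end - start + 1.0 / trace.sample_rate + 1e-9)
                                 / config.scan_duration_s))
        if n_scans < 1:
            raise ValueError(
                f"trace for {channel!r} shorter than one scan window "
                f"({config.scan_duration_s} s)"
            )
        windows = [
            (start + k * config.scan_duration_s, start + (k + 1) * config.scan_duration_s)
            for k in range(n_scans)
        ]
        out[channel] = [_analyze_scan(trace, w, config) for w in windows]
        logger.info("channel %s: %d scans, %d valid", channel, n_scans,
                    sum(s.valid for s in out[channel]))
    return out


def _reference_f0(
    summaries: Mapping[str, list[ScanSummary]], config: AnalysisConfig
) -> dict[str, float]:
    f0: dict[str, float] = {}
    fixed = dict(config.f0_values)
    for channel, scans in summaries.items():
        if config.f0_mode == "fixed":
            if channel not in fixed:
                raise ValueError(f"no fixed F0 supplied for channel {channel!r}")
            f0[channel] = float(fixed[channel])
            continue
        if config.f0_mode == "blank_scans":
            indices = config.f0_scan_indices
        elif config.f0_mode == "first_scans":
            indices = tuple(range(config.n_first_scans))
        else:
            raise ValueError(f"unknown f0_mode {config.f0_mode!r}")
        vals = [
            scans[i].F1
            for i in indices
            if i < len(scans) and scans[i].valid and not math.isnan(scans[i].F1)
        ]
        if not vals:
            raise ValueError(
                f"no valid reference scans for channel {channel!r} (indices {indices})"
            )
        f0[channel] = float(np.mean(vals))
    return f0


def analyze_run(
    traces: Mapping[str, Trace],
    channel_map: ChannelMap,
    models: Mapping[str, CalibrationModel],
    config: AnalysisConfig | None = None,
    seed: int | None = None,
) -> RunResult:
    """Traces -> scans -> F1/F0 -> concentrations for every mapped channel.

    Raises if a mapped analyte has no fitted calibration model.  Invalid
    scans (too few beads) carry no concentration estimate; out-of-range
    ratios are flagged, never clipped.
    """
    config = config or AnalysisConfig()
    c2a = channel_map.channel_to_analyte
    missing = [a for c, a in c2a.items() if c in traces and a not in models]
    if missing:
        raise ValueError(f"missing calibration model(s) for analyte(s) {missing}")

    summaries = scan_summaries(traces, config)
    f0 = _reference_f0(summaries, config)

    records: list[dict] = []
    n_valid = 0
    for channel, scans in summaries.items():
        analyte = c2a.get(channel)
        for k, scan in enumerate(scans):
            rec = {
                "scan_index": k,
                "scan_start_s": scan.window[0],
                "channel": channel,
                "analyte": analyte,
                "n_peaks": scan.n_peaks,
                "valid": scan.valid,
                "F1": scan.F1,
                "F_ratio": math.nan,
                "conc_pM": math.nan,
                "flag": "invalid_scan",
            }
            if scan.valid and not math.isnan(scan.F1) and analyte is not None:
                n_valid += 1
                ratio = scan.F1 / f0[channel]
                scan.F_ratio = ratio
                conc, flag = models[analyte].invert(ratio)
                rec.update(F_ratio=ratio, conc_pM=conc, flag=flag)
            records.append(rec)

    if n_valid == 0:
        logger.warning("all scans invalid; run produced no concentration estimates")

    config_dict = config.as_dict()
    metadata = {
        "config": config_dict,
        "config_hash": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "channel_map": list(channel_map.mapping),
        "seed": seed,
        "version": _version,
    }
    return RunResult(summaries=summaries, records=records, f0=f0, metadata=metadata)


def _derived_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def _build_samples(
    pairs: Sequence[Mapping[str, float]], scans_per_level: int, n_blanks: int
) -> tuple[list[dict[str, float]], list[int], dict[int, int]]:
    """Sample sequence with wash blanks interleaved between concentration levels.

    Mirrors the continuous protocol: a blank (whole blood without spiked
    analyte) is run before and after every concentration level.  Returns the
    ordered samples, the indices of all blank scans (used for F0 and blank
    SD), and a map scan index -> level number for the non-blank scans.
    """
    samples: list[dict[str, float]] = []
    blank_indices: list[int] = []
    level_of: dict[int, int] = {}
    for level, pair in enumerate(pairs):
        for _ in range(n_blanks):
            blank_indices.append(len(samples))
            samples.append({})
        for _ in range(scans_per_level):
            level_of[len(samples)] = level
            samples.append(dict(pair))
    for _ in range(n_blanks):
        blank_indices.append(len(samples))
        samples.append({})
    return samples, blank_indices, level_of


def calibrate_from_experiment(
    pairs: Sequence[Mapping[str, float]],
    template: SyntheticSpec,
    channel_map: ChannelMap,
    signal_models: Mapping[str, AnalyteSignalModel],
    config: AnalysisConfig,
    seed: int,
    scans_per_level: int = 3,
    n_blanks: int = 3,
) -> dict[str, CalibrationModel]:
    """Simulate a calibration run and fit one 4PL model per analyte.

    Blank scans define F0; blank ratios (scattering around 1) provide the
    blank SD that enters the LOD.
    """
    samples, blank_indices, _ = _build_samples(pairs, scans_per_level, n_blanks)
    exp = generate_experiment(samples, template, channel_map.channel_to_analyte,
                              signal_models, seed=seed)
    cfg = dataclasses.replace(config, f0_mode="blank_scans",
                              f0_scan_indices=tuple(blank_indices))
    summaries = scan_summaries(exp.traces, cfg)
    f0 = _reference_f0(summaries, cfg)

    models: dict[str, CalibrationModel] = {}
    for channel, analyte in channel_map.channel_to_analyte.items():
        conc, ratio = [], []
        for i, scan in enumerate(summaries[channel]):
            if not scan.valid or math.isnan(scan.F1):
                continue
            conc.append(float(samples[i].get(analyte, 0.0)))
            ratio.append(scan.F1 / f0[channel])
        models[analyte] = fit_4pl(CalibrationData(analyte, np.array(conc), np.array(ratio)))
    return models


def recovery_experiment(
    seed: int,
    template: SyntheticSpec | None = None,
    channel_map: ChannelMap | None = None,
    signal_models: Mapping[str, AnalyteSignalModel] | None = None,
    config: AnalysisConfig | None = None,
    calib_pairs: Sequence[Mapping[str, float]] | None = None,
    holdout_pairs: Sequence[Mapping[str, float]] | None = None,
    scans_per_level: int = 3,
    n_replicates: int = 3,
    n_blanks: int = 3,
) -> dict:
    """simulate -> calibrate -> analyze on held-out seeds; recovery report.

    A calibration run (a concentration ladder with wash blanks interleaved
    between levels) is simulated and fitted, then a held-out run with fresh
    seeds covering ``holdout_pairs`` is analysed with those models.  Each
    concentration level is measured ``scans_per_level`` scans at a time in
    ``n_replicates`` replicates (the protocol's mean-of-three-scans with
    three replicates), i.e. ``scans_per_level * n_replicates`` scans per
    level in total.  Per (analyte, true concentration) the
    report carries the per-scan estimates, the level estimate (inversion of
    the level's mean ratio, as when plotting the mean of replicate scans on
    the calibration curve), bias, and relative RMSE of the per-scan
    estimates, plus rank-order correctness per analyte and the
    calibration-derived (empirical) LODs.
    """
    template = template or SyntheticSpec()
    channel_map = channel_map or ChannelMap()
    signal_models = signal_models or default_signal_models()
    config = config or AnalysisConfig(scan_duration_s=template.duration)
    if calib_pairs is None:
        calib_pairs = [
            {"insulin": 100.0, "glucagon": 10.0},
            {"insulin": 200.0, "glucagon": 40.0},
            {"insulin": 400.0, "glucagon": 80.0},
            {"insulin": 1000.0, "glucagon": 100.0},
        ]
    if holdout_pairs is None:
        holdout_pairs = [SAMPLE_PAIRS[k] for k in "ABCD"]

    per_level = scans_per_level * n_replicates
    models = calibrate_from_experiment(
        calib_pairs, template, channel_map, signal_models, config,
        seed=_derived_seed(seed, 0), scans_per_level=per_level, n_blanks=n_blanks,
    )

    samples, blank_indices, level_of = _build_samples(holdout_pairs, per_level, n_blanks)
    exp = generate_experiment(samples, template, channel_map.channel_to_analyte,
                              signal_models, seed=_derived_seed(seed, 1))
    cfg = dataclasses.replace(config, f0_mode="blank_scans",
                              f0_scan_indices=tuple(blank_indices))
    result = analyze_run(exp.traces, channel_map, models, cfg, seed=seed)

    frame = result.to_frame()
    levels: list[dict] = []
    rank_ok: dict[str, bool] = {}
    for analyte, channel in channel_map.analyte_to_channel.items():
        level_ests: list[tuple[float, float]] = []
        for j, pair in enumerate(holdout_pairs):
            true_conc = float(pair.get(analyte, 0.0))
            idx = [i for i, lv in level_of.items() if lv == j]
            sub = frame[(frame.channel == channel) & frame.scan_index.isin(idx)
                        & frame.valid]
            est = sub[sub.flag == "ok"].conc_pM.to_numpy(float)
            ratios = sub.F_ratio.to_numpy(float)
            if len(ratios):
                level_est, level_flag = models[analyte].invert(float(np.mean(ratios)))
            else:
                level_est, level_flag = math.nan, "no_valid_scans"
            rel_rmse = (
                float(np.sqrt(np.mean((est - true_conc) ** 2)) / true_conc)
                if len(est) and true_conc > 0
                else math.nan
            )
            levels.append({
                "analyte": analyte,
                "true_conc_pM": true_conc,
                "n_scans": int(len(ratios)),
                "estimates_pM": est.tolist(),
                "mean_ratio": float(np.mean(ratios)) if len(ratios) else math.nan,
                "level_est_pM": level_est,
                "level_flag": level_flag,
                "bias_pM": level_est - true_conc,
                "rel_rmse": rel_rmse,
            })
            level_ests.append((true_conc, level_est))
        order_true = [c for c, _ in sorted(level_ests)]
        order_est = [c for c, _ in sorted(level_ests, key=lambda p: p[1])]
        rank_ok[analyte] = order_true == order_est

    return {
        "seed": seed,
        "levels": levels,
        "rank_order_correct": rank_ok,
        "empirical_lod_pM": {a: models[a].lod_pM for a in models},
        "calibration": {
            a: {"d0": m.d0, "dmax": m.dmax, "c50": m.c50, "b": m.b,
                "blank_sd": m.blank_sd, "lin_slope": m.lin_slope}
            for a, m in models.items()
        },
        "run_hash": result.report_hash(),
    }
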