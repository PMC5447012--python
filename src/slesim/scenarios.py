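"""Reproducible experiment driver: single runs, sweeps, test fixtures.

``run_scenario`` executes the full pipeline for one configuration -
build topology, calibrate the transmission ratio, simulate, analyze the
group LFPs, classify the suppression extent - and writes every artifact
(trace, raster, structured report) to a run directory as plain text.

``run_sweep`` maps that pipeline over a ratio x noise (x stimulation
site) grid with several replicate seeds per cell and aggregates a
majority suppression label per cell, the in-silico analogue of scanning
noise level against propagation mechanism.

``generate_fixture`` writes synthetic multichannel signals with known
ground truth (lags, phases, band contents) for exercising the analysis
suite without running the simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import analyze_channels
from .engine import (SimulationConfig, StimConfig, TriggerConfig,
                     classify_suppression, run_simulation)
from .exceptions import ConfigurationError, SlesimError
from .io import write_multichannel, write_raster, write_report
from .network import build_small_world, calibrate_ratio

__all__ = [
    "ScenarioConfig",
    "SweepSpec",
    "load_scenario_config",
    "run_scenario",
    "run_sweep",
    "aggregate_sweep",
    "generate_fixture",
]

_KNOWN_TOP_KEYS = {
    "seed", "duration", "dt", "noise_variance", "ratio", "network",
    "trigger", "stim", "gabaa_block", "calibration", "background_drive",
    "stable_window", "heterogeneity", "w_scale", "alpha", "w_inh_scale",
}
_KNOWN_NETWORK_KEYS = {"n_exc", "n_inh", "p_long", "window", "layout", "groups"}
_KNOWN_TRIGGER_KEYS = {"enabled", "t_on", "duration", "n_targets", "mean",
                       "std", "focus_bias"}
_KNOWN_STIM_KEYS = {"enabled", "group", "t_on", "duration"}
_KNOWN_CALIB_KEYS = {"enabled", "tol_pp", "max_iter", "calib_duration"}


@dataclass
class ScenarioConfig:
    """Validated scenario configuration (network + simulation + calibration)."""

    seed: int = 0
    network: dict = dc_field(default_factory=dict)
    sim: SimulationConfig = dc_field(default_factory=SimulationConfig)
    calibrate: bool = True
    calib_kwargs: dict = dc_field(default_factory=dict)


def parse_ratio(value):
    """Accept 'S:F' strings or (S, F) pairs summing to 100."""
    if isinstance(value, str):
        parts = value.split(":")
        if len(parts) != 2:
            raise ConfigurationError(f"ratio: expected 'SYN:FIELD', got {value!r}")
        value = [float(p) for p in parts]
    syn, fld = (float(x) for x in value)
    if abs(syn + fld - 100.0) > 1e-6:
        raise ConfigurationError(f"ratio: shares must sum to 100, got {syn}:{fld}")
    return (syn, fld)


def _check_keys(section, data, known):
    unknown = set(data) - known
    if unknown:
        key = sorted(unknown)[0]
        prefix = f"{section}." if section else ""
        raise ConfigurationError(f"unknown configuration key {prefix}{key}")


def load_scenario_config(source) -> ScenarioConfig:
    """Build a ScenarioConfig from a YAML file path or a plain dict.

    Schema violations raise :class:`ConfigurationError` naming the
    offending key (e.g. a stimulation section without ``stim.group``).
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source or {})
    _check_keys("", data, _KNOWN_TOP_KEYS)

    net = dict(data.get("network") or {})
    _check_keys("network", net, _KNOWN_NETWORK_KEYS)

    sim_kwargs = {}
    for key in ("dt", "duration", "noise_variance", "gabaa_block",
                "background_drive", "heterogeneity", "w_scale", "alpha",
                "w_inh_scale"):
        if key in data:
            sim_kwargs[key] = data[key]
    if "stable_window" in data:
        sim_kwargs["stable_window"] = tuple(data["stable_window"])
    if "ratio" in data:
        sim_kwargs["ratio"] = parse_ratio(data["ratio"])
    if "seed" in data:
        sim_kwargs["seed"] = int(data["seed"])

    trig = dict(data.get("trigger") or {})
    _check_keys("trigger", trig, _KNOWN_TRIGGER_KEYS)
    sim_kwargs["trigger"] = TriggerConfig(**trig)

    stim = dict(data.get("stim") or {})
    _check_keys("stim", stim, _KNOWN_STIM_KEYS)
    if stim.get("enabled", bool(stim)):
        if "group" not in stim:
            raise ConfigurationError("missing configuration key stim.group")
        stim.setdefault("enabled", True)
    sim_kwargs["stim"] = StimConfig(**stim) if stim else StimConfig()

    calib = dict(data.get("calibration") or {})
    _check_keys("calibration", calib, _KNOWN_CALIB_KEYS)
    calibrate = calib.pop("enabled", "alpha" not in data)

    return ScenarioConfig(seed=int(data.get("seed", 0)), network=net,
                          sim=SimulationConfig(**sim_kwargs),
                          calibrate=calibrate, calib_kwargs=calib)


def _build_topology(cfg: ScenarioConfig):
    # unspecified keys fall through to build_small_world's own defaults
    kwargs = {name: cfg.network[key] for key, name in
              (("n_exc", "n_exc"), ("n_inh", "n_inh"), ("p_long", "p_long"),
               ("window", "window"), ("layout", "layout"),
               ("groups", "n_groups")) if key in cfg.network}
    return build_small_world(
        rng=np.random.default_rng(cfg.seed + 7_654_321), **kwargs)


def run_scenario(config, out_dir=None, topology=None, calibration=None):
    """Execute calibrate -> simulate -> analyze -> classify for one config.

    ``config`` may be a YAML path, a dict, or a ScenarioConfig.  Returns
    a dict with the trace, the analysis report and the suppression
    result; if ``out_dir`` is given, writes ``trace.txt`` (time + group
    LFPs), ``raster.txt``, ``report.yaml`` and ``analysis.tsv`` there.
    Reruns of the same configuration produce identical artifacts.
    """
    cfg = config if isinstance(config, ScenarioConfig) \
        else load_scenario_config(config)
    if topology is None:
        topology = _build_topology(cfg)
    sim_cfg = cfg.sim

    calib_report = None
    if calibration is not None:
        sim_cfg = replace(sim_cfg, w_scale=calibration.w_scale,
                          alpha=calibration.alpha)
        calib_report = calibration
    elif cfg.calibrate:
        calib_report = calibrate_ratio(
            topology, sim_cfg.ratio, sim_cfg.noise_variance,
            rng=np.random.default_rng(cfg.seed + 1_234_567),
            base_config=sim_cfg, **cfg.calib_kwargs)
        sim_cfg = replace(sim_cfg, w_scale=calib_report.w_scale,
                          alpha=calib_report.alpha)

    trace = run_simulation(sim_cfg, topology)
    window = sim_cfg.stable_window
    report = analyze_channels(trace.lfp, trace.fs, window=window)
    suppression = None
    if sim_cfg.stim.enabled:
        suppression = classify_suppression(trace)

    summary = {
        "slesim_version": __version__,
        "seed": sim_cfg.seed,
        "ratio_target": list(sim_cfg.ratio),
        "ratio_achieved": [round(trace.shares["syn_share"], 3),
                           round(trace.shares["field_share"], 3)],
        "noise_variance": sim_cfg.noise_variance,
        "w_scale": sim_cfg.w_scale,
        "alpha": sim_cfg.alpha,
        "dominant_frequency_hz": round(report.dominant_frequency_hz, 4),
        "mean_delay_ms": round(report.mean_delay_ms, 4),
        "band_fractions": {k: round(v, 6)
                           for k, v in report.band_fractions.items()},
        "plv": {k: round(v, 6) for k, v in report.plv_per_band.items()},
        "suppression": None if suppression is None else {
            "label": suppression.label,
            "per_group": {int(g): s for g, s in suppression.per_group.items()},
        },
        "calibration": None if calib_report is None else {
            "converged": calib_report.converged,
            "achieved_ratio": [round(x, 3) for x in calib_report.achieved_ratio],
            "iterations": calib_report.iterations,
        },
        "event_log": {
            "trigger": {k: v for k, v in trace.event_log["trigger"].items()
                        if k != "targets"},
            "stim": {k: v for k, v in trace.event_log["stim"].items()
                     if k != "neurons"},
        },
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        names = [f"lfp_g{g}" for g in range(1, trace.n_groups + 1)]
        write_multichannel(out / "trace.txt", trace.t, trace.lfp, names)
        write_raster(out / "raster.txt", trace)
        write_report(out / "report.yaml", summary)
        with open(out / "analysis.tsv", "w") as fh:
            fh.write("measure\tkey\tvalue\n")
            for row in report.as_flat_table():
                fh.write(f"{row[0]}\t{row[1]}\t{row[2]:.6g}\n")

    return {"trace": trace, "report": report, "suppression": suppression,
            "summary": summary, "calibration": calib_report,
            "topology": topology}


@dataclass
class SweepSpec:
    """Grid specification for the suppression-extent sweep.

    Ratios default to the studied span (synaptic share 90 down to 70);
    the noise grid brackets the printed variance of 1 with a low and a
    high environment.
    """

    ratios: tuple = ((85.0, 15.0), (75.0, 25.0))
    noise_variances: tuple = (0.25, 1.0, 4.0)
    seeds: tuple = (0, 1, 2, 3, 4)
    stim_groups: tuple = (1,)
    base: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.ratios = tuple(parse_ratio(r) for r in self.ratios)
        if len(self.seeds) < 1:
            raise ConfigurationError("need at least one seed per sweep cell")


def run_sweep(spec: SweepSpec, out_dir=None, progress=False):
    """Run the ratio x noise (x stim site) grid and tabulate the results.

    One row per (ratio, noise, stim_group, seed): achieved ratio,
    dominant frequency, mean delay, per-band PLVs and the suppression
    label.  Each (ratio, noise) cell is calibrated once and the
    calibrated (weight scale, alpha) reused across its replicate seeds.
    Failed cells are recorded with their error and skipped.
    """
    rows = []
    base = dict(spec.base)
    for ratio in spec.ratios:
        for noise in spec.noise_variances:
            cal = None
            cal_error = None
            cfg0 = load_scenario_config({**base, "ratio": list(ratio),
                                         "noise_variance": noise,
                                         "seed": int(spec.seeds[0]),
                                         "stim": {"enabled": True, "group": 1}})
            topology = _build_topology(cfg0)
            try:
                cal = calibrate_ratio(
                    topology, ratio, noise,
                    rng=np.random.default_rng(int(spec.seeds[0]) + 1_234_567),
                    base_config=cfg0.sim, **cfg0.calib_kwargs)
            except SlesimError as exc:
                cal_error = str(exc)
            for stim_group in spec.stim_groups:
                for seed in spec.seeds:
                    row = {"ratio": f"{ratio[0]:g}:{ratio[1]:g}",
                           "noise_variance": noise,
                           "stim_group": stim_group, "seed": int(seed)}
                    if cal_error is not None:
                        row.update(status="calibration_failed",
                                   error=cal_error, label=None)
                        rows.append(row)
                        continue
                    cfg = load_scenario_config(
                        {**base, "ratio": list(ratio), "noise_variance": noise,
                         "seed": int(seed),
                         "stim": {"enabled": True, "group": int(stim_group)}})
                    try:
                        res = run_scenario(cfg, topology=topology,
                                           calibration=cal)
                    except SlesimError as exc:
                        row.update(status="failed", error=str(exc), label=None)
                        rows.append(row)
                        continue
                    s = res["summary"]
                    row.update(
                        status="ok", error="",
                        label=s["suppression"]["label"],
                        achieved_syn=s["ratio_achieved"][0],
                        achieved_field=s["ratio_achieved"][1],
                        dominant_frequency_hz=s["dominant_frequency_hz"],
                        mean_delay_ms=s["mean_delay_ms"],
                        **{f"plv_{k}": v for k, v in s["plv"].items()})
                    rows.append(row)
                    if progress:
                        print(f"  {row['ratio']} noise={noise} "
                              f"stim=g{stim_group} seed={seed}: "
                              f"{row['label']}")
    table = pd.DataFrame(rows)
    grid = aggregate_sweep(table)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "sweep.tsv", sep="\t", index=False)
        write_report(out / "sweep_grid.yaml", grid)
    return table, grid


def aggregate_sweep(table: pd.DataFrame):
    """Majority suppression label per (ratio, noise, stim site) cell.

    A pure function of the row table: re-aggregating a stored table
    reproduces the grid.  Ties and failed runs are recorded in the split.
    """
    grid = {}
    if len(table) == 0:
        return grid
    for (ratio, noise, sg), cell in table.groupby(
            ["ratio", "noise_variance", "stim_group"]):
        labels = cell["label"].dropna().tolist()
        counts = {lab: labels.count(lab) for lab in sorted(set(labels))}
        majority = max(counts, key=lambda k: (counts[k], k)) if counts else None
        grid[f"{ratio}|noise={noise:g}|stim=g{sg}"] = {
            "majority": majority, "split": counts,
            "n_ok": len(labels), "n_total": len(cell)}
    return grid


# ---------------------------------------------------------------------------
# synthetic fixtures for the analysis suite

_FIXTURE_KINDS = ("lagged-oscillation", "phase-offset-set", "band-mixture",
                  "iid-noise")


def generate_fixture(kind, params=None, seed=0, out_path=None):
    """Synthesize a multichannel signal with known ground truth.

    Kinds: 'lagged-oscillation' (peaked 8-Hz-like waveform, channel k
    delayed by k*lag_ms), 'phase-offset-set' (common sinusoid with fixed
    per-channel phase offsets), 'band-mixture' (sum of tones with given
    band amplitudes), 'iid-noise'.  If ``out_path`` is given, writes the
    columnar signal file plus a ``<out_path>.meta.yaml`` sidecar holding
    the true generating parameters.

    Returns (t_ms, channels, metadata).
    """
    if kind not in _FIXTURE_KINDS:
        raise ConfigurationError(
            f"unknown fixture kind {kind!r}; expected one of {_FIXTURE_KINDS}")
    p = dict(params or {})
    fs = float(p.pop("fs", 1000.0))
    duration_ms = float(p.pop("duration_ms", 4000.0))
    n_channels = int(p.pop("n_channels", 4))
    noise_std = float(p.pop("noise_std", 0.0))
    rng = np.random.default_rng(seed)
    n = int(round(duration_ms * fs / 1000.0))
    t = np.arange(n) / fs  # seconds
    meta = {"kind": kind, "fs": fs, "duration_ms": duration_ms,
            "n_channels": n_channels, "noise_std": noise_std, "seed": seed}

    if kind == "lagged-oscillation":
        freq = float(p.pop("freq", 8.0))
        lag_ms = float(p.pop("lag_ms", 8.5))
        if abs(lag_ms) * (n_channels - 1) >= duration_ms:
            raise ConfigurationError("lag exceeds the signal length")
        _reject_unknown(kind, p)
        # sharpened oscillation: distinct positive peaks once per cycle
        def wave(tt):
            return np.maximum(0.0, np.cos(2 * np.pi * freq * tt)) ** 3
        channels = np.array([wave(t - k * lag_ms / 1000.0)
                             for k in range(n_channels)])
        meta.update(freq=freq, lag_ms=lag_ms)
    elif kind == "phase-offset-set":
        freq = float(p.pop("freq", 8.0))
        phases_deg = p.pop("phases_deg", [10.0 * k for k in range(n_channels)])
        _reject_unknown(kind, p)
        if len(phases_deg) != n_channels:
            raise ConfigurationError("phases_deg length must equal n_channels")
        channels = np.array([np.sin(2 * np.pi * freq * t + math.radians(ph))
                             for ph in phases_deg])
        meta.update(freq=freq, phases_deg=list(map(float, phases_deg)))
    elif kind == "band-mixture":
        tones = p.pop("tones", {6.0: 1.0, 20.0: 1.0})
        _reject_unknown(kind, p)
        base = sum(amp * np.sin(2 * np.pi * float(freq) * t + 0.1 * k)
                   for k, (freq, amp) in enumerate(tones.items()))
        channels = np.tile(base, (n_channels, 1))
        meta.update(tones={float(f): float(a) for f, a in tones.items()})
    else:  # iid-noise
        _reject_unknown(kind, p)
        channels = rng.standard_normal((n_channels, n))

    if noise_std > 0:
        channels = channels + noise_std * rng.standard_normal(channels.shape)

    t_ms = t * 1000.0
    if out_path is not None:
        write_multichannel(out_path, t_ms, channels)
        with open(str(out_path) + ".meta.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)
    return t_ms, channels, meta


def _reject_unknown(kind, leftover):
    if leftover:
        raise ConfigurationError(
            f"unknown parameter {sorted(leftover)[0]!r} for fixture kind {kind}")
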