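"""Plain-text readers/writers for traces, rasters and reports.

Multichannel time series travel as columnar text with a header row
(``time_ms`` + one column per channel); the sampling rate is recovered
from the time column.  Structured reports are YAML.
"""

from __future__ import annotations

import numpy as np
import yaml

from .exceptions import AnalysisError

__all__ = [
    "write_multichannel",
    "read_multichannel",
    "write_raster",
    "read_raster",
    "write_report",
    "read_report",
]


def write_multichannel(path, t_ms, channels, names=None):
    """Write (time_ms, ch1..chK) columns; channels shaped (K, T)."""
    channels = np.atleast_2d(np.asarray(channels, dtype=float))
    t_ms = np.asarray(t_ms, dtype=float)
    if names is None:
        names = [f"ch{k + 1}" for k in range(channels.shape[0])]
    header = "time_ms\t" + "\t".join(names)
    data = np.column_stack([t_ms, channels.T])
    np.savetxt(path, data, fmt="%.6g", delimiter="\t", header=header,
               comments="")


def read_multichannel(path):
    """Read a columnar multichannel file.

    Returns (t_ms, channels (K, T), names, fs_hz).
    """
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
    if not header or header[0] != "time_ms":
        raise AnalysisError(f"{path}: expected a 'time_ms' header column")
    data = np.loadtxt(path, skiprows=1, delimiter="\t", ndmin=2)
    t_ms = data[:, 0]
    if len(t_ms) < 2:
        raise AnalysisError(f"{path}: need at least 2 samples")
    dt = np.diff(t_ms)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise AnalysisError(f"{path}: non-uniform sampling")
    return t_ms, data[:, 1:].T, header[1:], 1000.0 / dt[0]


def write_raster(path, trace):
    """Write the spike raster as (neuron_id, t_ms) rows."""
    steps, neurons = np.nonzero(trace.spikes)
    with open(path, "w") as fh:
        fh.write("neuron_id\tt_ms\n")
        for s, nid in zip(steps, neurons):
            fh.write(f"{nid}\t{trace.t[s]:.6g}\n")


def read_raster(path):
    data = np.loadtxt(path, skiprows=1, delimiter="\t", ndmin=2)
    if data.size == 0:
        return np.empty(0, int), np.empty(0)
    return data[:, 0].astype(int), data[:, 1]


def write_report(path, report: dict):
    with open(path, "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=False, default_flow_style=False)


def read_report(path):
    with open(path) as fh:
        return yaml.safe_load(fh)
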