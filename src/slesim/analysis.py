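"""SLE characterization: propagation delay, spectrogram/band power, PLV.

These measures apply equally to simulated group LFPs and to recorded
multichannel field potentials:

* propagation delay - positive LFP peaks are detected per channel in a
  stable-state window and matched across adjacent channels; the delay is
  the mean peak-time difference,
* frequency content - short-time Fourier transform with a 256-sample
  Kaiser window, 85% overlap and 8192-point transforms, summarized as
  mean power per EEG band (delta..gamma) and a dominant frequency,
* phase synchrony - the phase-locking value: channels are band-passed,
  instantaneous phases extracted with the analytic signal (Hilbert
  transform), and the magnitude of the mean unit phasor of pairwise
  phase differences computed over the six channel pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import signal as sps

from .exceptions import AnalysisError, ConfigurationError, InsufficientDataError

__all__ = [
    "BandSpec",
    "DEFAULT_BANDS",
    "AnalysisReport",
    "propagation_delay",
    "DelayResult",
    "spectrogram",
    "band_power_fractions",
    "plv",
    "PLVResult",
    "dominant_frequency",
    "analyze_channels",
]


@dataclass(frozen=True)
class BandSpec:
    """Named frequency bands with (low, high) edges in Hz.

    Defaults are the conventional EEG bands truncated at the 50-Hz LFP
    cutoff: delta 1-4, theta 4-8, alpha 8-13, beta 13-30, gamma 30-50.
    """

    bands: tuple = (
        ("delta", (1.0, 4.0)),
        ("theta", (4.0, 8.0)),
        ("alpha", (8.0, 13.0)),
        ("beta", (13.0, 30.0)),
        ("gamma", (30.0, 50.0)),
    )

    def __post_init__(self):
        prev_hi = 0.0
        for name, (lo, hi) in self.bands:
            if not lo < hi:
                raise ConfigurationError(f"band {name}: edges must increase")
            if lo < prev_hi:
                raise ConfigurationError(f"band {name}: bands must not overlap")
            prev_hi = hi

    @property
    def names(self):
        return [name for name, _ in self.bands]

    def edges(self, name):
        for n, e in self.bands:
            if n == name:
                return e
        raise ConfigurationError(f"unknown band {name!r}")

    @property
    def max_edge(self):
        return max(hi for _, (_, hi) in self.bands)


DEFAULT_BANDS = BandSpec()


@dataclass
class AnalysisReport:
    """Summary measures of one multichannel recording or simulation."""

    mean_delay_ms: float
    pair_delays_ms: dict
    band_fractions: dict           # fractions of the five-band total, sum 1
    plv_per_band: dict             # headline PLV per band, in [0, 1]
    dominant_frequency_hz: float
    dominant_frequency_confident: bool

    def as_flat_table(self):
        """Rows of (measure, band_or_pair, value) for the text report."""
        rows = [("mean_delay_ms", "", self.mean_delay_ms),
                ("dominant_frequency_hz", "", self.dominant_frequency_hz)]
        rows += [("pair_delay_ms", k, v) for k, v in self.pair_delays_ms.items()]
        rows += [("band_fraction", k, v) for k, v in self.band_fractions.items()]
        rows += [("plv", k, v) for k, v in self.plv_per_band.items()]
        return rows


# ---------------------------------------------------------------------------
# propagation delay


@dataclass
class DelayResult:
    mean_delay_ms: float
    pair_delays_ms: dict           # {(i, j): mean signed delay}
    matched_peaks: int


def _detect_peaks(x, fs, min_interval_ms=50.0, prominence=None):
    if prominence is None:
        prominence = 0.5 * float(np.std(x))
    idx, _ = sps.find_peaks(x, prominence=prominence,
                            distance=max(1, int(min_interval_ms * fs / 1000.0)))
    return idx / fs * 1000.0


def propagation_delay(channels, fs, window=None, *, max_lag_ms=25.0,
                      min_interval_ms=50.0, prominence=None, min_matched=3):
    """Mean positive-peak propagation delay between adjacent channels.

    Channels must be ordered along the propagation axis.  Positive peaks
    are detected per channel inside ``window`` (seconds are ms here:
    (t0_ms, t1_ms); None = whole signal) and matched across adjacent
    pairs to the nearest peak within ``max_lag_ms``.  Returns the
    per-pair mean signed peak-time differences (later channel minus
    earlier) and their overall mean.

    Raises :class:`InsufficientDataError` if fewer than ``min_matched``
    peak pairs were matched in total.
    """
    channels = np.atleast_2d(np.asarray(channels, dtype=float))
    if channels.shape[0] < 2:
        raise AnalysisError("propagation delay needs at least 2 channels")
    t_ms = np.arange(channels.shape[1]) / fs * 1000.0
    if window is not None:
        t0, t1 = window
        if t0 < t_ms[0] - 1e-9 or t1 > t_ms[-1] + 1000.0 / fs + 1e-9:
            raise AnalysisError("analysis window outside the signal span")
        sel = (t_ms >= t0) & (t_ms < t1)
    else:
        t0 = 0.0
        sel = slice(None)
    peak_times = [_detect_peaks(ch[sel], fs, min_interval_ms, prominence) + t0
                  for ch in channels]

    pair_delays = {}
    total_matched = 0
    for k in range(len(peak_times) - 1):
        early, late = peak_times[k], peak_times[k + 1]
        diffs = []
        for tp in early:
            if len(late) == 0:
                break
            j = int(np.argmin(np.abs(late - tp)))
            if abs(late[j] - tp) <= max_lag_ms:
                diffs.append(late[j] - tp)
        if diffs:
            pair_delays[(k, k + 1)] = float(np.mean(diffs))
            total_matched += len(diffs)
    if total_matched < min_matched or not pair_delays:
        raise InsufficientDataError(
            f"only {total_matched} matched peaks (< {min_matched}); "
            "cannot estimate the propagation delay")
    mean_delay = float(np.mean(list(pair_delays.values())))
    return DelayResult(mean_delay_ms=mean_delay, pair_delays_ms=pair_delays,
                       matched_peaks=total_matched)


# ---------------------------------------------------------------------------
# spectral measures


def spectrogram(x, fs, *, nperseg=256, overlap=0.85, nfft=8192,
                kaiser_beta=0.5):
    """Short-time Fourier power with a 256-sample Kaiser window.

    85% overlap (hop of ~38 samples) and zero-padding to 8192-point
    transforms give the high frequency resolution (fs/8192) used for the
    SLE spectra.  Returns (frequencies Hz, segment times s, power).
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < nperseg:
        raise AnalysisError(
            f"signal length {x.shape[-1]} shorter than the {nperseg}-sample window")
    noverlap = int(round(overlap * nperseg))
    f, t, sxx = sps.spectrogram(
        x, fs=fs, window=("kaiser", kaiser_beta), nperseg=nperseg,
        noverlap=noverlap, nfft=nfft, detrend=False, scaling="density",
        mode="psd")
    return f, t, sxx


def band_power_fractions(x, fs, bands: BandSpec = DEFAULT_BANDS, window=None,
                         **spec_kwargs):
    """Mean power per band over the window, as fractions of the band total.

    ``x`` may be a 1-D signal or the (f, t, sxx) triple returned by
    :func:`spectrogram`.  Fractions are normalization-invariant and sum
    to 1.
    """
    if isinstance(x, tuple) and len(x) == 3:
        f, t, sxx = x
    else:
        if fs <= 2 * bands.max_edge:
            raise ConfigurationError(
                f"sampling rate {fs} Hz cannot resolve bands up to "
                f"{bands.max_edge} Hz")
        f, t, sxx = spectrogram(x, fs, **spec_kwargs)
    if window is not None:
        t0, t1 = window
        sel = (t * 1000.0 >= t0) & (t * 1000.0 < t1)
        if not sel.any():
            raise AnalysisError("no spectrogram frames inside the window")
        sxx = sxx[..., sel]
    mean_spec = sxx.mean(axis=-1)
    powers = {}
    for name, (lo, hi) in bands.bands:
        m = (f >= lo) & (f < hi)
        powers[name] = float(mean_spec[m].mean()) if m.any() else 0.0
    total = sum(powers.values())
    if total <= 0:
        return {name: 0.0 for name in powers}
    return {name: p / total for name, p in powers.items()}


def dominant_frequency(x, fs, window=None, *, fmin=1.0, fmax=50.0,
                       confidence_ratio=5.0, **spec_kwargs):
    """Frequency of maximal mean spectral power in [fmin, fmax] Hz.

    Returns (frequency_hz, confident): the confidence flag is lowered
    when the spectral peak is not prominent (peak power below
    ``confidence_ratio`` times the median in-range power), as for
    featureless/white-noise input.
    """
    f, t, sxx = spectrogram(x, fs, **spec_kwargs)
    if window is not None:
        t0, t1 = window
        sel = (t * 1000.0 >= t0) & (t * 1000.0 < t1)
        if not sel.any():
            raise AnalysisError("no spectrogram frames inside the window")
        sxx = sxx[..., sel]
    mean_spec = sxx.mean(axis=-1)
    m = (f >= fmin) & (f <= fmax)
    spec = mean_spec[m]
    freqs = f[m]
    peak = int(np.argmax(spec))
    confident = bool(spec[peak] >= confidence_ratio * max(np.median(spec), 1e-300))
    return float(freqs[peak]), confident


# ---------------------------------------------------------------------------
# phase-locking value


@dataclass
class PLVResult:
    """Phase-locking values of a channel set within one band.

    ``plv`` is the headline value: the average over channel pairs of the
    per-pair time-locked PLVs |<e^{i dphi}>_t|.  ``plv_instantaneous``
    is the literal instantaneous form - the magnitude of the pair-mean
    unit phasor at each sample, averaged over time.
    """

    plv: float
    per_pair: dict
    plv_instantaneous: float


def _bandpass_phase(x, fs, lo, hi, order=4):
    nyq = fs / 2.0
    if hi >= nyq:
        raise ConfigurationError(
            f"band edge {hi} Hz at or above the Nyquist frequency {nyq} Hz")
    sos = sps.butter(order, [lo, hi], btype="band", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, x)
    return np.angle(sps.hilbert(filtered))


def plv(channels, band, fs, window=None, *, bands: BandSpec = DEFAULT_BANDS,
        order=4):
    """Phase-locking value of a channel set in one frequency band.

    Each channel is zero-phase band-passed, its instantaneous phase
    extracted by the Hilbert analytic signal, and the pairwise phase
    differences formed over all channel pairs (6 pairs for 4 channels).
    ``band`` is a band name from ``bands`` or an explicit (lo, hi) pair;
    ``window`` is (t0_ms, t1_ms).
    """
    channels = np.atleast_2d(np.asarray(channels, dtype=float))
    if channels.shape[0] < 2:
        raise AnalysisError("PLV needs at least 2 channels")
    lo, hi = bands.edges(band) if isinstance(band, str) else band
    phases = np.array([_bandpass_phase(ch, fs, lo, hi, order)
                       for ch in channels])
    if window is not None:
        t_ms = np.arange(channels.shape[1]) / fs * 1000.0
        sel = (t_ms >= window[0]) & (t_ms < window[1])
        if not sel.any():
            raise AnalysisError("no samples inside the PLV window")
        phases = phases[:, sel]
    pairs = list(combinations(range(channels.shape[0]), 2))
    per_pair = {}
    phasor_sum = np.zeros(phases.shape[1], dtype=complex)
    for (j, k) in pairs:
        dphi = phases[j] - phases[k]
        phasors = np.exp(1j * dphi)
        per_pair[(j, k)] = float(np.abs(phasors.mean()))
        phasor_sum += phasors
    instantaneous = float(np.abs(phasor_sum / len(pairs)).mean())
    headline = float(np.mean(list(per_pair.values())))
    return PLVResult(plv=headline, per_pair=per_pair,
                     plv_instantaneous=instantaneous)


# ---------------------------------------------------------------------------
# one-call report


def analyze_channels(channels, fs, window=None, *,
                     bands: BandSpec = DEFAULT_BANDS, **delay_kwargs):
    """Full AnalysisReport (delay, band power, PLVs, dominant frequency)."""
    channels = np.atleast_2d(np.asarray(channels, dtype=float))
    delay = propagation_delay(channels, fs, window, **delay_kwargs)
    reference = channels[0]
    fractions = band_power_fractions(reference, fs, bands, window=window)
    dom, confident = dominant_frequency(reference, fs, window=window)
    plvs = {name: plv(channels, name, fs, window, bands=bands).plv
            for name in bands.names}
    return AnalysisReport(
        mean_delay_ms=delay.mean_delay_ms,
        pair_delays_ms={f"{i}-{j}": v for (i, j), v in delay.pair_delays_ms.items()},
        band_fractions=fractions,
        plv_per_band=plvs,
        dominant_frequency_hz=dom,
        dominant_frequency_confident=confident,
    )
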