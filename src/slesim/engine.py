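"""Network simulation engine: SLE induction, stimulation, LFP, classification.

The engine advances the whole network on a 1-ms grid (membrane potential
via two 0.5-ms forward-Euler half-steps, the model family's standard
practice).  Each step combines

* conductance-based synaptic currents (AMPA/NMDA/GABA_A/GABA_B with
  short-term depression; GABA_A blocked by default to model the
  bicuculline bath),
* instantaneous electric-field coupling from the previous step's
  membrane currents (explicit coupling at the native resolution),
* per-neuron i.i.d. Gaussian noise and a constant subthreshold
  background drive to excitatory cells,
* a ~1-s abrupt random trigger to 25 "focus" neurons of group 1 that
  ignites the seizure-like event (the focus keeps a small sustained
  bias so every stable-state wave initiates there and propagates
  1 -> G), and
* the stimulation effect: a logarithmic rise of the potassium-reversal
  proxy v_Ek in the stimulated group, gating the synaptic + field input
  through v_c (depolarization blockade).

Group LFPs are the 50-Hz low-passed averages of each group's 50 shifted
excitatory membrane potentials, sampled at 1 kHz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy import signal as sps

from .dynamics import (
    SPIKE_CUTOFF,
    BlockadeParams,
    make_population,
    population_arrays,
)
from .exceptions import AnalysisError, ConfigurationError, NumericalError
from .field import FieldParams, field_kernel
from .synapses import SynapseParams, SynapseState, decay_and_accumulate, \
    synaptic_current
from .network import NetworkTopology

__all__ = [
    "TriggerConfig",
    "StimConfig",
    "SimulationConfig",
    "Trace",
    "run_simulation",
    "compute_lfp",
    "classify_suppression",
    "SuppressionResult",
    "single_neuron_blockade_demo",
]


@dataclass(frozen=True)
class TriggerConfig:
    """Abrupt random input that ignites the SLE.

    ``n_targets`` excitatory neurons at the start of group 1 (the focus)
    receive i.i.d. Gaussian current pulses of positive mean for
    ``duration`` ms.  ``focus_bias`` is a small sustained extra drive to
    the same neurons for the whole run; it is subthreshold at rest (no
    trigger, no noise => no activity) but makes the focus the pacemaker
    of the established rhythm.
    """

    enabled: bool = True
    t_on: float = 200.0
    duration: float = 1000.0
    n_targets: int = 25
    mean: float = 10.0
    std: float = 5.0
    focus_bias: float = 8.0


@dataclass(frozen=True)
class StimConfig:
    """Stimulation-effect protocol (potassium blockade of one group)."""

    enabled: bool = False
    group: int = 1
    t_on: float = 4000.0
    duration: float = 4000.0
    blockade: BlockadeParams = dc_field(default_factory=BlockadeParams)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one run (besides the topology).

    ``w_scale`` and ``alpha`` are normally set by
    :func:`slesim.network.calibrate_ratio` so that the achieved
    |I_syn| : |I_field| split matches ``ratio``.  ``noise_variance`` is
    in squared current units (the printed value 1 mapped 1:1 onto the
    model's dimensionless current).
    """

    dt: float = 1.0
    duration: float = 8000.0
    noise_variance: float = 1.0
    ratio: tuple = (85.0, 15.0)
    w_scale: float = 0.33
    w_inh_scale: float = 1.0       # inhibitory weights relative to w_scale
    alpha: float = 0.0
    background_drive: float = 2.25  # mean constant drive to excitatory cells
    background_jitter: float = 0.0  # s.d. of per-neuron static drive spread
    trigger: TriggerConfig = dc_field(default_factory=TriggerConfig)
    stim: StimConfig = dc_field(default_factory=StimConfig)
    gabaa_block: bool = True
    synapses: SynapseParams = dc_field(default_factory=SynapseParams)
    min_distance: float = 1.0
    field_radius: float | None = 60.0
    lfp_cutoff: float = 50.0
    stable_window: tuple = (2500.0, 4000.0)
    heterogeneity: float = 1.0
    seed: int = 0


@dataclass
class Trace:
    """Full output of one simulation run."""

    t: np.ndarray                  # (T,) ms
    spikes: np.ndarray             # (T, N) bool
    v: np.ndarray                  # (T, N) float32, spike steps clipped to 30 mV
    lfp: np.ndarray                # (G, T) mV
    fs: float                      # LFP sampling rate, Hz
    groups: np.ndarray             # (N,) group label per neuron
    is_inhibitory: np.ndarray      # (N,) bool
    shares: dict                   # achieved current shares and diagnostics
    event_log: dict                # trigger / stimulation windows and targets
    v_ek_final: np.ndarray         # (N,) potassium-reversal proxy at end
    v_c_final: np.ndarray          # (N,) gating factor at end
    config: SimulationConfig

    @property
    def n_groups(self) -> int:
        return self.lfp.shape[0]

    def group_rate(self, g, t0, t1):
        """Mean excitatory firing rate (Hz) of group g in [t0, t1) ms."""
        members = np.flatnonzero((self.groups == g) & ~self.is_inhibitory)
        sel = (self.t >= t0) & (self.t < t1)
        dur_s = sel.sum() * (self.t[1] - self.t[0]) / 1000.0
        if dur_s <= 0 or len(members) == 0:
            return 0.0
        return self.spikes[np.ix_(sel, members)].sum() / (len(members) * dur_s)


def _validate_config(config: SimulationConfig, topology: NetworkTopology):
    if config.dt <= 0:
        raise ConfigurationError("dt must be positive")
    if config.duration <= 0:
        raise ConfigurationError("duration must be positive")
    if topology.n_groups < 1:
        raise ConfigurationError("topology has no group assignment")
    if config.stim.enabled:
        if not (0 <= config.stim.t_on < config.duration):
            raise ConfigurationError("stim.t_on must lie within the duration")
        if not (1 <= config.stim.group <= topology.n_groups):
            raise ConfigurationError(
                f"stim.group {config.stim.group} outside 1..{topology.n_groups}")
    if config.trigger.enabled and not (0 <= config.trigger.t_on < config.duration):
        raise ConfigurationError("trigger.t_on must lie within the duration")


def run_simulation(config: SimulationConfig, topology: NetworkTopology) -> Trace:
    """Run the full network simulation and return its Trace.

    Identical (config, topology) including the seed give bit-identical
    output.  Raises :class:`NumericalError` naming the neuron and time
    if the integration produces non-finite state.
    """
    _validate_config(config, topology)
    rng = np.random.default_rng(config.seed)
    n = topology.n_neurons
    dt = config.dt
    n_steps = int(round(config.duration / dt))

    # --- populations ------------------------------------------------------
    exc_idx = topology.exc_indices
    inh_idx = topology.inh_indices
    pop_exc = make_population(topology.n_exc, "excitatory-spiking",
                              config.heterogeneity, rng)
    pop_inh = make_population(topology.n_inh, "inhibitory-fast-spiking",
                              config.heterogeneity, rng)
    pe, pi = population_arrays(pop_exc), population_arrays(pop_inh)
    a = np.empty(n); b = np.empty(n); c = np.empty(n); d = np.empty(n)
    for key, arr in (("a", a), ("b", b), ("c", c), ("d", d)):
        arr[exc_idx] = pe[key]
        arr[inh_idx] = pi[key]

    # start every neuron at its own subthreshold fixed point (I = 0) so the
    # settling transient cannot cross threshold
    disc = np.maximum((5.0 - b) ** 2 - 4.0 * 0.04 * 140.0, 0.0)
    v = (-(5.0 - b) - np.sqrt(disc)) / (2.0 * 0.04)
    u = b * v
    syn = SynapseState.zeros(topology, w_scale=config.w_scale,
                             w_inh_scale=config.w_inh_scale * config.w_scale)
    sparams = config.synapses
    if config.gabaa_block:
        sparams = replace(sparams, gabaa_blocked=True)

    kernel = field_kernel(topology.distances, FieldParams(
        alpha=config.alpha, min_distance=config.min_distance,
        radius=config.field_radius)) if config.alpha > 0 else None
    i_m = np.zeros(n)

    blockade = config.stim.blockade
    v_ek = np.full(n, blockade.e_k0)
    v_c = np.ones(n)
    stim_mask = np.zeros(n, dtype=bool)
    if config.stim.enabled:
        stim_mask[topology.groups == config.stim.group] = True

    # focus = first n_targets excitatory neurons of group 1 (by position)
    g1 = topology.group_members(1)
    n_targets = min(config.trigger.n_targets, len(g1))
    targets = g1[:n_targets]

    noise_std = math.sqrt(config.noise_variance)
    # static per-neuron background drive: a fixed mean plus a frozen
    # Gaussian spread (cellular excitability heterogeneity)
    bg_static = np.full(topology.n_exc, float(config.background_drive))
    if config.background_jitter > 0:
        bg_static = bg_static + config.background_jitter * rng.standard_normal(
            topology.n_exc)
    trig = config.trigger
    stim = config.stim

    spikes = np.zeros((n_steps, n), dtype=bool)
    vrec = np.empty((n_steps, n), dtype=np.float32)
    sum_abs_syn = np.zeros(n)
    sum_abs_field = np.zeros(n)
    n_stable = 0
    lo, hi = config.stable_window

    for step in range(n_steps):
        t = step * dt
        i_syn = synaptic_current(syn, v, sparams)
        i_field = kernel @ i_m if kernel is not None else 0.0
        # background tone and the focus bias stand in for ambient network
        # drive, so they pass through the v_c gate like I_syn + I_field;
        # membrane noise and the externally injected trigger do not
        i_drive = i_syn + i_field
        i_drive[exc_idx] += bg_static
        if trig.enabled and t >= trig.t_on:
            i_drive[targets] += trig.focus_bias
        i_total = v_c * i_drive
        if noise_std > 0:
            i_total = i_total + noise_std * rng.standard_normal(n)
        if trig.enabled and trig.t_on <= t < trig.t_on + trig.duration:
            i_total[targets] += rng.normal(trig.mean, trig.std, n_targets)

        v_prev = v
        # two half-steps with the cutoff clamp: a neuron crossing 30 mV is
        # held there until the end-of-step reset, so strong input cannot
        # blow up the quadratic nonlinearity within a step
        v = v + 0.5 * dt * (0.04 * v * v + 5.0 * v + 140.0 - u + i_total)
        spk = v >= SPIKE_CUTOFF
        v = np.minimum(v, SPIKE_CUTOFF)
        v = np.where(spk, SPIKE_CUTOFF,
                     v + 0.5 * dt * (0.04 * v * v + 5.0 * v + 140.0 - u
                                     + i_total))
        spk |= v >= SPIKE_CUTOFF
        v = np.minimum(v, SPIKE_CUTOFF)
        u = u + dt * a * (b * v - u)
        if not np.isfinite(v).all():
            bad = int(np.flatnonzero(~np.isfinite(v))[0])
            raise NumericalError(
                f"membrane potential diverged at t={t:.1f} ms (neuron {bad})",
                neuron=bad, time_ms=t)

        # reset jumps excluded: the field carries the pre-reset upstroke
        i_m = (v - v_prev) / dt
        vrec[step] = v
        spikes[step] = spk
        v = np.where(spk, c, v)
        u = np.where(spk, u + d, u)

        if lo <= t < hi:
            sum_abs_syn += np.abs(i_syn)
            sum_abs_field += np.abs(np.broadcast_to(i_field, (n,)))
            n_stable += 1

        syn = decay_and_accumulate(syn, spk, topology, dt, sparams)

        if stim.enabled:
            stim_active = stim.t_on <= t < stim.t_on + stim.duration
            if stim_active:
                rate = (blockade.rise_gain / blockade.rise_tau) * np.exp(
                    -(v_ek[stim_mask] - blockade.e_k0) / blockade.rise_gain)
                v_ek[stim_mask] = np.minimum(
                    v_ek[stim_mask] + dt * rate, blockade.v_ek_max)
                v_c[stim_mask] = blockade.vc_of_vek(v_ek[stim_mask])
            elif blockade.recovery_rate > 0 and t >= stim.t_on:
                v_ek[stim_mask] += dt * blockade.recovery_rate * (
                    blockade.e_k0 - v_ek[stim_mask])
                v_c[stim_mask] = blockade.vc_of_vek(v_ek[stim_mask])

    # --- LFP channels -----------------------------------------------------
    fs = 1000.0 / dt
    t_axis = np.arange(n_steps) * dt
    baseline_end = int(round(max(trig.t_on, 100.0) / dt)) if trig.enabled \
        else int(round(200.0 / dt))
    baseline_end = max(1, min(baseline_end, n_steps))
    shift = np.median(vrec[:baseline_end], axis=0)
    lfp = np.empty((topology.n_groups, n_steps))
    for g in range(1, topology.n_groups + 1):
        members = topology.group_members(g)
        lfp[g - 1] = compute_lfp(vrec[:, members].T.astype(float), fs,
                                 cutoff=config.lfp_cutoff,
                                 shift=shift[members])

    # --- achieved current shares over active neurons ----------------------
    shares = {"mean_abs_syn": 0.0, "mean_abs_field": 0.0,
              "syn_share": 100.0, "field_share": 0.0, "n_active": 0}
    if n_stable > 0:
        sel = (t_axis >= lo) & (t_axis < hi)
        rates = spikes[sel][:, exc_idx].sum(axis=0) / ((hi - lo) / 1000.0)
        active = exc_idx[rates >= 1.0]
        shares["n_active"] = int(len(active))
        if len(active):
            s = float(sum_abs_syn[active].mean() / n_stable)
            f = float(sum_abs_field[active].mean() / n_stable)
            shares["mean_abs_syn"] = s
            shares["mean_abs_field"] = f
            if s + f > 0:
                shares["field_share"] = 100.0 * f / (s + f)
                shares["syn_share"] = 100.0 - shares["field_share"]

    event_log = {
        "trigger": {"enabled": trig.enabled, "t_on": trig.t_on,
                    "t_off": trig.t_on + trig.duration,
                    "targets": targets.tolist()},
        "stim": {"enabled": stim.enabled, "group": stim.group,
                 "t_on": stim.t_on, "t_off": stim.t_on + stim.duration,
                 "neurons": np.flatnonzero(stim_mask).tolist()},
    }
    return Trace(t=t_axis, spikes=spikes, v=vrec, lfp=lfp, fs=fs,
                 groups=topology.groups.copy(),
                 is_inhibitory=topology.is_inhibitory.copy(),
                 shares=shares, event_log=event_log,
                 v_ek_final=v_ek, v_c_final=v_c, config=config)


def compute_lfp(voltages, fs, cutoff=50.0, shift=None, baseline_samples=200):
    """Group LFP: mean of shifted membrane potentials, low-passed at 50 Hz.

    ``voltages`` has shape (n_neurons, n_samples).  Each neuron's
    ``shift`` (default: its median over the first ``baseline_samples``)
    is subtracted so the resting mean sits near 0 mV, then the
    population mean is filtered with a zero-phase 4th-order Butterworth
    low-pass at ``cutoff`` Hz.
    """
    voltages = np.atleast_2d(np.asarray(voltages, dtype=float))
    if voltages.shape[0] < 2:
        raise ConfigurationError("LFP requires a group of at least 2 neurons")
    if shift is None:
        nb = max(1, min(baseline_samples, voltages.shape[1]))
        shift = np.median(voltages[:, :nb], axis=1)
    mean = (voltages - np.asarray(shift)[:, None]).mean(axis=0)
    sos = sps.butter(4, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, mean)


@dataclass
class SuppressionResult:
    """Per-group suppression verdicts and the overall extent label."""

    per_group: dict              # {group: "suppressed" | "persisting"}
    label: str                   # "local" | "whole" | "downstream" | "none"
    metrics: dict                # pre/post amplitudes and rates per group

    @property
    def suppressed_groups(self):
        return sorted(g for g, s in self.per_group.items() if s == "suppressed")


def classify_suppression(trace: Trace, stim_group=None, t_stim=None, *,
                         amp_fraction=0.25, rate_fraction=0.2,
                         latency=2000.0, min_pre_amplitude=1.0):
    """Classify the extent of stimulation-induced suppression.

    A group counts as suppressed when, after the latency window
    following stimulation onset, both its LFP oscillation amplitude
    (standard deviation of the detrended channel) and its mean
    excitatory firing rate fall below the configured fractions of their
    pre-stimulation stable-state values.  The overall label is
    "local" (only the stimulated group), "whole" (all groups),
    "downstream" (the stimulated group plus exactly the groups activated
    after it - with the focus in group 1, the higher-numbered groups),
    or "none".  The amplitude measure is invariant to LFP sign and to
    any uniform voltage offset.
    """
    if stim_group is None:
        stim_group = trace.config.stim.group
    if t_stim is None:
        t_stim = trace.config.stim.t_on
    t_end = trace.t[-1] + (trace.t[1] - trace.t[0])
    if t_end - t_stim < latency + 500.0:
        raise AnalysisError("need at least ~1 s of post-stimulation trace "
                            "after the latency window")
    pre0, pre1 = t_stim - 1500.0, t_stim - 100.0
    if pre0 < 0:
        raise AnalysisError("missing stable pre-stimulation window")
    post0, post1 = t_stim + latency, t_end

    def window_amp(ch, t0, t1):
        sel = (trace.t >= t0) & (trace.t < t1)
        x = ch[sel]
        return float(np.std(x - x.mean()))

    per_group, metrics = {}, {}
    for g in range(1, trace.n_groups + 1):
        ch = trace.lfp[g - 1]
        pre_amp = window_amp(ch, pre0, pre1)
        post_amp = window_amp(ch, post0, post1)
        pre_rate = trace.group_rate(g, pre0, pre1)
        post_rate = trace.group_rate(g, post0, post1)
        if pre_amp < min_pre_amplitude:
            raise AnalysisError(
                f"group {g} shows no stable pre-stimulation oscillation "
                f"(amplitude {pre_amp:.3f} mV)")
        suppressed = (post_amp < amp_fraction * pre_amp
                      and post_rate < rate_fraction * max(pre_rate, 1e-9))
        per_group[g] = "suppressed" if suppressed else "persisting"
        metrics[g] = {"pre_amp": pre_amp, "post_amp": post_amp,
                      "pre_rate": pre_rate, "post_rate": post_rate}

    supp = {g for g, s in per_group.items() if s == "suppressed"}
    all_groups = set(range(1, trace.n_groups + 1))
    if supp == all_groups:
        label = "whole"
    elif supp == {stim_group}:
        label = "local"
    elif stim_group in supp and supp == set(range(stim_group,
                                                  trace.n_groups + 1)):
        label = "downstream"
    else:
        label = "none"
    return SuppressionResult(per_group=per_group, label=label, metrics=metrics)


# ---------------------------------------------------------------------------
# single-neuron blockade demonstration


@dataclass
class SingleNeuronDemo:
    """Output of the single-neuron depolarization-blockade demonstration."""

    t: np.ndarray
    v: np.ndarray
    spike_times: np.ndarray
    burst_times: np.ndarray
    burst_rate_pre: float        # bursts/s over the pre-stimulation window
    last_spike_ms: float
    stim_onset: float
    v_ek: np.ndarray
    v_c: np.ndarray


def single_neuron_blockade_demo(seed=0, *, duration=8000.0, dt=1.0,
                                stim_onset=4000.0,
                                drive_frequency=8.0, drive_amplitude=18.0,
                                pulse_width=30.0, noise_std=0.5,
                                trigger_duration=1000.0, trigger_mean=10.0,
                                trigger_std=5.0,
                                blockade=BlockadeParams(),
                                burst_gap=40.0,
                                rate_window=(2000.0, 4000.0)):
    """Silencing of a single driven neuron by the potassium blockade.

    A bursting-parameterized excitatory neuron receives an abrupt random
    trigger for the first second plus a sustained neighbor-like drive:
    periodic current pulses at the SLE rhythm (default 8 Hz, the rate the
    surrounding synchronized network would impose).  The drive passes
    through the v_c gate; at ``stim_onset`` the stimulation effect starts
    raising v_Ek, v_c collapses, and the neuron stops spiking although
    the drive never changes.  Deterministic at fixed seed.
    """
    rng = np.random.default_rng(seed)
    a_, b_, c_, d_ = 0.02, 0.2, -55.0, 4.0  # bursting endpoint parameters
    n_steps = int(round(duration / dt))
    t_axis = np.arange(n_steps) * dt
    v, u = -70.0, -14.0
    v_ek, v_c = blockade.e_k0, 1.0
    vs = np.empty(n_steps)
    veks = np.empty(n_steps)
    vcs = np.empty(n_steps)
    spike_times = []
    period = 1000.0 / drive_frequency
    for step in range(n_steps):
        t = step * dt
        phase = t % period
        pulse = drive_amplitude * math.sin(math.pi * phase / pulse_width) ** 2 \
            if phase < pulse_width else 0.0
        i_net = v_c * pulse
        i_ext = noise_std * rng.standard_normal()
        if t < trigger_duration:
            i_ext += rng.normal(trigger_mean, trigger_std)
        current = i_net + i_ext
        v = v + 0.5 * dt * (0.04 * v * v + 5.0 * v + 140.0 - u + current)
        v = v + 0.5 * dt * (0.04 * v * v + 5.0 * v + 140.0 - u + current)
        u = u + dt * a_ * (b_ * v - u)
        if v >= SPIKE_CUTOFF:
            spike_times.append(t)
            vs[step] = SPIKE_CUTOFF
            v, u = c_, u + d_
        else:
            vs[step] = v
        if stim_onset <= t:
            rate = (blockade.rise_gain / blockade.rise_tau) * math.exp(
                -(v_ek - blockade.e_k0) / blockade.rise_gain)
            v_ek = min(v_ek + dt * rate, blockade.v_ek_max)
            v_c = float(blockade.vc_of_vek(v_ek))
        veks[step] = v_ek
        vcs[step] = v_c

    spike_times = np.asarray(spike_times)
    # bursts = spike clusters separated by gaps exceeding burst_gap
    if len(spike_times):
        starts = np.concatenate([[True], np.diff(spike_times) > burst_gap])
        burst_times = spike_times[starts]
    else:
        burst_times = np.array([])
    w0, w1 = rate_window
    n_bursts = int(((burst_times >= w0) & (burst_times < w1)).sum())
    rate = n_bursts / ((w1 - w0) / 1000.0)
    return SingleNeuronDemo(
        t=t_axis, v=vs, spike_times=spike_times, burst_times=burst_times,
        burst_rate_pre=rate,
        last_spike_ms=float(spike_times[-1]) if len(spike_times) else float("nan"),
        stim_onset=stim_onset, v_ek=veks, v_c=vcs)
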