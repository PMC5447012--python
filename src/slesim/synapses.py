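"""Conductance-based synaptic transmission with short-term depression.

The synaptic current onto each neuron is the sum of AMPA, NMDA, GABA_A
and GABA_B receptor currents.  Each receptor conductance decays
exponentially with its own time constant and is incremented on every
presynaptic spike by (edge weight x short-term resource); resources
deplete per spike and recover between spikes (Tsodyks-Markram
depression).  Long-term plasticity (additive STDP on excitatory-to-
excitatory weights) is available but off by default: the headline
simulations span seconds, over which short-term dynamics dominate.

The bicuculline switch (``apply_gabaa_block``) zeroes all GABA_A
conductance increments, reproducing disinhibition by a GABA_A
antagonist while leaving GABA_B untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ConfigurationError, TopologyError

__all__ = [
    "SynapseParams",
    "SynapseState",
    "decay_and_accumulate",
    "synaptic_current",
    "nmda_gate",
    "apply_gabaa_block",
]


@dataclass(frozen=True)
class SynapseParams:
    """Receptor kinetics, reversal potentials and plasticity settings.

    Time constants (ms) default to canonical cortical-model values.
    ``nmda_fraction`` and ``gabab_fraction`` scale the NMDA / GABA_B
    conductance increment relative to the AMPA / GABA_A one on the same
    edge.  ``gabaa_blocked`` is the bicuculline switch.
    """

    tau_ampa: float = 5.0
    tau_nmda: float = 150.0
    tau_gabaa: float = 6.0
    tau_gabab: float = 150.0
    e_ampa: float = 0.0
    e_nmda: float = 0.0
    e_gabaa: float = -70.0
    e_gabab: float = -90.0
    nmda_fraction: float = 0.1
    gabab_fraction: float = 0.1
    # Tsodyks-Markram depression (per excitatory connection)
    depression: bool = True
    depression_U: float = 0.85
    tau_rec: float = 60.0
    gabaa_blocked: bool = False
    # optional long-term plasticity (additive STDP), off by default
    stdp: bool = False
    stdp_rate: float = 0.0
    w_max: float = 10.0


@dataclass
class SynapseState:
    """Per-target conductances plus per-connection resources and weights.

    Conductances are arrays of length n_neurons; ``exc_resources`` and
    the weight arrays are aligned with the topology's edge lists
    (shape (n_neurons, in-degree)).
    """

    g_ampa: np.ndarray
    g_nmda: np.ndarray
    g_gabaa: np.ndarray
    g_gabab: np.ndarray
    exc_resources: np.ndarray
    exc_weights: np.ndarray
    inh_weights: np.ndarray

    @classmethod
    def zeros(cls, topology, w_scale=1.0, w_inh_scale=1.0):
        n = topology.n_neurons
        return cls(
            g_ampa=np.zeros(n),
            g_nmda=np.zeros(n),
            g_gabaa=np.zeros(n),
            g_gabab=np.zeros(n),
            exc_resources=np.ones_like(topology.exc_weights),
            exc_weights=topology.exc_weights * w_scale,
            inh_weights=topology.inh_weights * w_inh_scale,
        )


def nmda_gate(v):
    """Voltage-dependent magnesium-block factor of the NMDA receptor."""
    x = ((np.asarray(v, dtype=float) + 80.0) / 60.0) ** 2
    return x / (1.0 + x)


def decay_and_accumulate(syn: SynapseState, presyn_spikes, topology, dt,
                         params: SynapseParams = SynapseParams()):
    """Advance conductances and depression resources by one step.

    Conductances decay exponentially; every presynaptic spike increments
    the target's conductances by weight x resource (exactly the weight at
    full resource), after which the spiking connection's resource is
    depleted by the release fraction U.  Resources recover toward 1 with
    time constant ``tau_rec``.  Operates in place and returns ``syn``.
    """
    presyn_spikes = np.asarray(presyn_spikes, dtype=bool)
    if presyn_spikes.shape[0] != topology.n_neurons:
        raise TopologyError(
            f"spike vector length {presyn_spikes.shape[0]} does not match "
            f"topology size {topology.n_neurons}"
        )
    if np.any(syn.exc_weights < 0) or np.any(syn.inh_weights < 0):
        raise ConfigurationError("synaptic weights must be non-negative")
    if np.any(syn.exc_resources < 0) or np.any(syn.exc_resources > 1):
        raise ConfigurationError("depression resources must lie in [0, 1]")

    syn.g_ampa *= np.exp(-dt / params.tau_ampa)
    syn.g_nmda *= np.exp(-dt / params.tau_nmda)
    syn.g_gabaa *= np.exp(-dt / params.tau_gabaa)
    syn.g_gabab *= np.exp(-dt / params.tau_gabab)

    if params.depression:
        # exact exponential recovery toward full resource
        syn.exc_resources = 1.0 - (1.0 - syn.exc_resources) * np.exp(
            -dt / params.tau_rec
        )

    spk_exc = presyn_spikes[topology.exc_sources]  # (n, k_exc) bool
    if spk_exc.any():
        release = np.where(spk_exc, syn.exc_weights * syn.exc_resources, 0.0)
        inc = release.sum(axis=1)
        syn.g_ampa += inc
        syn.g_nmda += params.nmda_fraction * inc
        if params.depression:
            syn.exc_resources = np.where(
                spk_exc,
                syn.exc_resources * (1.0 - params.depression_U),
                syn.exc_resources,
            )
    spk_inh = presyn_spikes[topology.inh_sources]
    if spk_inh.any():
        inc = np.where(spk_inh, syn.inh_weights, 0.0).sum(axis=1)
        if not params.gabaa_blocked:
            syn.g_gabaa += inc
        syn.g_gabab += params.gabab_fraction * inc
    return syn


def synaptic_current(syn: SynapseState, v, params: SynapseParams = SynapseParams()):
    """Total synaptic driving-force current per neuron.

    I_syn = I_AMPA + I_NMDA + I_GABAA + I_GABAB with excitatory reversal
    at 0 mV, GABA_A at -70 mV, GABA_B at -90 mV, and the NMDA term
    scaled by the voltage-dependent magnesium gate.
    """
    v = np.asarray(v, dtype=float)
    i = syn.g_ampa * (params.e_ampa - v)
    i = i + syn.g_nmda * nmda_gate(v) * (params.e_nmda - v)
    i = i + syn.g_gabaa * (params.e_gabaa - v)
    i = i + syn.g_gabab * (params.e_gabab - v)
    return i


def apply_gabaa_block(params: SynapseParams) -> SynapseParams:
    """Return a copy of ``params`` with GABA_A transmission disabled.

    Models bicuculline bath application: GABA_A conductance increments
    are forced to zero for all neurons at all times; every other
    receptor is untouched.
    """
    return replace(params, gabaa_blocked=True)
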