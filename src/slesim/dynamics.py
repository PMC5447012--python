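"""Single-neuron dynamics and the stimulation-induced blockade mechanism.

This module implements

* the Izhikevich quadratic integrate-and-fire model used for every neuron
  in the network (``izhikevich_step``, ``make_population``),
* the phenomenological depolarization-blockade mechanism by which
  high-frequency stimulation silences neurons: extracellular potassium
  accumulation is represented by a potassium-reversal proxy ``v_Ek`` that
  rises logarithmically in time while stimulation is on, and an input
  gating factor ``v_c`` in [0, 1] that decays with ``v_Ek`` and multiplies
  the neuron's synaptic + field input (``update_suppression``,
  ``effective_input``), and
* the classical electrophysiology calculators (Nernst and
  Goldman-Hodgkin-Katz resting potentials) used to motivate the blockade
  mechanism.

All voltages are in mV, times in ms, currents in the Izhikevich model's
conventional dimensionless units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, NumericalError

__all__ = [
    "SPIKE_CUTOFF",
    "NeuronParams",
    "NeuronState",
    "IonSpec",
    "BlockadeParams",
    "izhikevich_step",
    "make_population",
    "population_arrays",
    "update_suppression",
    "effective_input",
    "nernst_potential",
    "ghk_resting_potential",
]

#: Spike detection / reset threshold of the Izhikevich model (mV).
SPIKE_CUTOFF = 30.0

# Gas constant (J mol^-1 K^-1) and Faraday constant (C mol^-1).
_R = 8.314462618
_F = 96485.33212

#: Canonical Izhikevich parameter endpoints, keyed by cell kind.
_KIND_BASE = {
    "excitatory-spiking": dict(a=0.02, b=0.2, c=-65.0, d=8.0),
    "excitatory-bursting": dict(a=0.02, b=0.2, c=-55.0, d=4.0),
    "inhibitory-fast-spiking": dict(a=0.1, b=0.2, c=-65.0, d=2.0),
}


@dataclass(frozen=True)
class NeuronParams:
    """Izhikevich model parameters for one neuron.

    a : recovery time scale (1/ms); b : recovery sensitivity;
    c : post-spike reset voltage (mV); d : post-spike recovery increment.
    """

    a: float
    b: float
    c: float
    d: float
    kind: str = "excitatory-spiking"
    group_id: int = 1

    def __post_init__(self):
        if self.a <= 0:
            raise ConfigurationError(f"NeuronParams.a must be > 0, got {self.a}")
        if self.c >= SPIKE_CUTOFF:
            raise ConfigurationError(
                f"reset voltage c={self.c} must lie below the spike cutoff "
                f"({SPIKE_CUTOFF} mV)"
            )


@dataclass
class NeuronState:
    """Dynamical variables of one neuron (or an array of neurons).

    v, u are the Izhikevich membrane potential and recovery variable;
    v_Ek is the potassium-reversal proxy driven by stimulation and v_c
    the input gating factor derived from it.
    """

    v: float | np.ndarray
    u: float | np.ndarray
    v_Ek: float | np.ndarray = -95.0
    v_c: float | np.ndarray = 1.0


@dataclass(frozen=True)
class IonSpec:
    """One ionic species for the Nernst / GHK calculators.

    Concentrations in mM; permeability is relative (dimensionless).
    """

    z: int
    conc_in: float
    conc_out: float
    permeability: float = 0.0

    def __post_init__(self):
        if self.conc_in <= 0 or self.conc_out <= 0:
            raise ConfigurationError("ion concentrations must be positive")
        if self.permeability < 0:
            raise ConfigurationError("permeability must be >= 0")


@dataclass(frozen=True)
class BlockadeParams:
    """Parameters of the potassium-blockade suppression mechanism.

    While stimulation is active the potassium-reversal proxy follows
    ``v_Ek(t) = e_k0 + rise_gain * ln(1 + t/rise_tau)`` (clipped at
    ``v_ek_max``); the gating factor is a logistic decay
    ``v_c = sigma((vc_center - v_Ek)/vc_slope)`` normalized so that
    ``v_c(e_k0) = 1``.  The defaults silence a continuously driven
    neuron within ~1-2 s of stimulation onset.
    """

    e_k0: float = -95.0          # resting potassium reversal proxy (mV)
    rise_gain: float = 12.0      # k of the logarithmic rise (mV)
    rise_tau: float = 250.0      # tau of the logarithmic rise (ms)
    v_ek_max: float = -60.0      # saturation of v_Ek (mV)
    vc_center: float = -80.0     # v_Ek at which v_c has fallen to 1/2 (mV)
    vc_slope: float = 3.0        # logistic width (mV)
    recovery_rate: float = 0.0   # 1/ms relaxation of v_Ek toward e_k0 off-stim

    def vc_of_vek(self, v_ek):
        """Gating factor as a monotone non-increasing function of v_Ek."""
        raw = 1.0 / (1.0 + np.exp((np.asarray(v_ek, dtype=float) - self.vc_center)
                                  / self.vc_slope))
        base = 1.0 / (1.0 + math.exp((self.e_k0 - self.vc_center) / self.vc_slope))
        return np.clip(raw / base, 0.0, 1.0)


def _izh_substep_v(v, u, current, h):
    """One forward-Euler substep of the membrane equation (step h, ms)."""
    return v + h * (0.04 * v * v + 5.0 * v + 140.0 - u + current)


def izhikevich_step(state, params, input_current, dt, *, neuron_index=None,
                    time_ms=None):
    """Advance one Izhikevich neuron by ``dt`` milliseconds.

    The membrane potential is integrated with forward-Euler substeps of at
    most 0.5 ms (two half-steps at the network's native dt = 1 ms); the
    recovery variable u takes a single step of ``dt`` using the updated v.
    When v reaches the 30 mV cutoff the spike flag is set and (v, u) are
    reset to (c, u + d).

    Parameters
    ----------
    state : NeuronState
    params : NeuronParams
    input_current : float
        Total input current I (already gated, noise included).
    dt : float
        Step in ms; must be positive.

    Returns
    -------
    (NeuronState, bool)
        The updated state and whether a spike occurred during this step.
    """
    if dt <= 0:
        raise ConfigurationError(f"dt must be > 0, got {dt}")
    v, u = float(state.v), float(state.u)
    if not (math.isfinite(v) and math.isfinite(u) and math.isfinite(input_current)):
        raise NumericalError(
            f"non-finite neuron state or input at t={time_ms} ms "
            f"(neuron {neuron_index}): v={v}, u={u}, I={input_current}",
            neuron=neuron_index, time_ms=time_ms,
        )
    spiked = v >= SPIKE_CUTOFF
    if spiked:
        # Entered above cutoff: apply the reset rule before integrating.
        v, u = params.c, u + params.d
    n_sub = max(1, int(math.ceil(dt / 0.5)))
    h = dt / n_sub
    crossed = False
    for _ in range(n_sub):
        if crossed:
            break
        v = _izh_substep_v(v, u, input_current, h)
        if v >= SPIKE_CUTOFF:
            # clamp at the cutoff for the remainder of the step; the reset
            # is applied once at the end of the step
            crossed = True
            v = SPIKE_CUTOFF
    u = u + dt * params.a * (params.b * v - u)
    if crossed:
        spiked = True
        v, u = params.c, u + params.d
    if not (math.isfinite(v) and math.isfinite(u)):
        raise NumericalError(
            f"integration diverged at t={time_ms} ms (neuron {neuron_index})",
            neuron=neuron_index, time_ms=time_ms,
        )
    return NeuronState(v=v, u=u, v_Ek=state.v_Ek, v_c=state.v_c), bool(spiked)


def resting_state(params: NeuronParams) -> NeuronState:
    """Stable fixed point of the subthreshold dynamics at I = 0.

    Solves 0.04 v^2 + 5 v + 140 - u = 0 with u = b v and returns the
    lower (stable) root.
    """
    b = params.b
    disc = (5.0 - b) ** 2 - 4.0 * 0.04 * 140.0
    if disc < 0:
        raise ConfigurationError("no subthreshold fixed point for these parameters")
    v = (-(5.0 - b) - math.sqrt(disc)) / (2.0 * 0.04)
    return NeuronState(v=v, u=b * v)


def make_population(n, kind, heterogeneity_scale=1.0, rng=None, group_id=1):
    """Draw ``n`` Izhikevich parameter sets of the requested kind.

    Heterogeneity follows the model's canonical recipe: excitatory cells
    perturb (c, d) by a squared-uniform deviate (biasing the population
    toward the regular-spiking endpoint with a tail of intrinsically
    bursting cells), inhibitory cells perturb (a, b) linearly.
    ``heterogeneity_scale`` in [0, 1] scales the perturbation;
    0 yields ``n`` identical parameter sets.

    ``kind`` is one of 'excitatory-spiking', 'excitatory-bursting',
    'inhibitory-fast-spiking' (the alias 'excitatory' maps to
    'excitatory-spiking', the mixed spiking/bursting population).
    """
    if n <= 0:
        raise ConfigurationError(f"population size must be > 0, got {n}")
    if kind == "excitatory":
        kind = "excitatory-spiking"
    if kind not in _KIND_BASE:
        raise ConfigurationError(
            f"unknown neuron kind {kind!r}; expected one of {sorted(_KIND_BASE)}"
        )
    rng = np.random.default_rng(rng)
    base = _KIND_BASE[kind]
    h = float(heterogeneity_scale)
    r = rng.random(n)
    pop = []
    for i in range(n):
        a, b, c, d = base["a"], base["b"], base["c"], base["d"]
        if kind == "excitatory-spiking":
            # RS -> IB interpolation via r^2
            c = c + 10.0 * h * r[i] ** 2
            d = d - 4.0 * h * r[i] ** 2
        elif kind == "excitatory-bursting":
            # IB endpoint with a squared-uniform pull back toward RS
            c = c - 10.0 * h * r[i] ** 2
            d = d + 4.0 * h * r[i] ** 2
        else:  # inhibitory-fast-spiking
            a = a - 0.08 * h * r[i]
            b = b + 0.05 * h * r[i]
        pop.append(NeuronParams(a=a, b=b, c=c, d=d, kind=kind, group_id=group_id))
    return pop


def population_arrays(pop):
    """Pack a list of NeuronParams into a dict of contiguous arrays."""
    return {
        key: np.array([getattr(p, key) for p in pop], dtype=float)
        for key in ("a", "b", "c", "d")
    }


def update_suppression(state, stim_active, dt, mech: BlockadeParams):
    """Advance the blockade variables (v_Ek, v_c) by ``dt`` milliseconds.

    While stimulation is active, v_Ek follows the logarithmic-in-time
    rise ``e_k0 + k ln(1 + t/tau)``; this trajectory is integrated in
    time-local form as dv_Ek/dt = (k/tau) exp(-(v_Ek - e_k0)/k), which
    reproduces the logarithm exactly in the continuous limit without
    tracking time-since-onset, and is clipped at ``v_ek_max``.  Off
    stimulation, v_Ek relaxes toward e_k0 at ``recovery_rate`` (default
    zero: no recovery within a simulated window).  v_c is recomputed
    from v_Ek after every update.
    """
    v_ek = np.asarray(state.v_Ek, dtype=float)
    if stim_active:
        rate = (mech.rise_gain / mech.rise_tau) * np.exp(
            -(v_ek - mech.e_k0) / mech.rise_gain
        )
        v_ek = np.minimum(v_ek + dt * rate, mech.v_ek_max)
    elif mech.recovery_rate > 0:
        v_ek = v_ek + dt * mech.recovery_rate * (mech.e_k0 - v_ek)
    v_c = mech.vc_of_vek(v_ek)
    if np.isscalar(state.v_Ek) or np.ndim(state.v_Ek) == 0:
        v_ek, v_c = float(v_ek), float(v_c)
    return replace_state(state, v_Ek=v_ek, v_c=v_c)


def replace_state(state: NeuronState, **kwargs) -> NeuronState:
    out = NeuronState(v=state.v, u=state.u, v_Ek=state.v_Ek, v_c=state.v_c)
    for k, v in kwargs.items():
        setattr(out, k, v)
    return out


def effective_input(v_c, i_syn, i_field):
    """Gated neuronal input current ``v_c * (I_syn + I_field)``.

    With v_c = 1 this reduces to the ungated sum of synaptic and
    electric-field currents; v_c = 0 shuts the neuron's network input
    off entirely.
    """
    v_c = np.asarray(v_c, dtype=float)
    if np.any(v_c < 0) or np.any(v_c > 1):
        raise ConfigurationError("gating factor v_c must lie in [0, 1]")
    out = v_c * (np.asarray(i_syn, dtype=float) + np.asarray(i_field, dtype=float))
    return float(out) if out.ndim == 0 else out


def nernst_potential(ion: IonSpec, temperature=310.15):
    """Nernst reversal potential of a single ion, in mV.

    E = (R T / z F) ln([out]/[in]).
    """
    if ion.z == 0:
        raise ConfigurationError("Nernst potential undefined for valence z = 0")
    if temperature <= 0:
        raise ConfigurationError("temperature must be positive (K)")
    return (_R * temperature / (ion.z * _F)) * math.log(
        ion.conc_out / ion.conc_in
    ) * 1000.0


def ghk_resting_potential(ions, temperature=310.15):
    """Goldman-Hodgkin-Katz resting potential over monovalent ions, in mV.

    Cations (z = +1) enter with their outside concentration in the
    numerator; anions (z = -1) with inside/outside swapped, the standard
    GHK form.  At a single permeant ion the result equals that ion's
    Nernst potential.
    """
    num = 0.0
    den = 0.0
    any_permeant = False
    for ion in ions:
        if abs(ion.z) != 1:
            raise ConfigurationError(
                f"GHK form implemented for monovalent ions only (z={ion.z})"
            )
        if ion.permeability == 0:
            continue
        any_permeant = True
        if ion.z > 0:
            num += ion.permeability * ion.conc_out
            den += ion.permeability * ion.conc_in
        else:
            num += ion.permeability * ion.conc_in
            den += ion.permeability * ion.conc_out
    if not any_permeant:
        raise ConfigurationError("GHK potential requires at least one permeant ion")
    return (_R * temperature / _F) * math.log(num / den) * 1000.0
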