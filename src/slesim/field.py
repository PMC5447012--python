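"""Instantaneous electric-field (ephaptic) coupling between neurons.

Each neuron's membrane current I_m is taken as the unit-capacitance
voltage derivative of the previous network step; the field current a
neuron receives is the distance-weighted sum of every other neuron's
membrane current,

    I_field(i) = alpha * sum_{j != i} I_m(j) / max(r_ij, min_distance),

i.e. field transmission is proportional to neighbors' membrane currents
and falls off as 1/r.  Spike-reset discontinuities are excluded from
I_m (the engine caps the pre-reset voltage at the spike cutoff), so the
field carries the action-potential upstroke, not the reset jump.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, TopologyError

__all__ = ["FieldParams", "membrane_current", "field_current", "field_kernel"]


@dataclass(frozen=True)
class FieldParams:
    """Electric-field coupling parameters.

    alpha : dimensionless field-strength scale (calibrated against the
        synaptic weight scale to realize a target transmission ratio).
    min_distance : distance floor preventing 1/r blow-up; defaults to
        the lattice's nearest-neighbor spacing.
    radius : optional cutoff beyond which contributions are ignored
        (None: no cutoff).
    capacitance : membrane capacitance used in I_m = C dv/dt.
    """

    alpha: float = 0.0
    min_distance: float = 1.0
    radius: float | None = None
    capacitance: float = 1.0

    def __post_init__(self):
        if self.alpha < 0:
            raise ConfigurationError("field alpha must be >= 0")
        if self.min_distance <= 0:
            raise ConfigurationError("min_distance must be > 0")


def membrane_current(prev_v, curr_v, dt, capacitance=1.0):
    """Membrane current I_m = C (v_t - v_{t-1}) / dt.

    Callers are responsible for passing the pre-reset (cutoff-capped)
    voltage on spike steps so the reset jump never enters the field.
    """
    if dt <= 0:
        raise ConfigurationError(f"dt must be > 0, got {dt}")
    out = capacitance * (np.asarray(curr_v, dtype=float)
                         - np.asarray(prev_v, dtype=float)) / dt
    return float(out) if out.ndim == 0 else out


def field_kernel(distances, params: FieldParams):
    """Precompute the (n, n) weight matrix alpha / max(r, min_distance).

    The diagonal (self-contribution) is zero; entries beyond the cutoff
    radius, if one is set, are zeroed.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise TopologyError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise TopologyError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise TopologyError("distance matrix diagonal must be zero")
    off = d[~np.eye(d.shape[0], dtype=bool)]
    if np.any(off <= 0):
        raise TopologyError("off-diagonal distances must be positive")
    kernel = params.alpha / np.maximum(d, params.min_distance)
    np.fill_diagonal(kernel, 0.0)
    if params.radius is not None:
        kernel[d > params.radius] = 0.0
    return kernel


def field_current(all_i_m, distances, params: FieldParams):
    """Per-neuron field current from every other neuron's I_m.

    Vectorized as a matrix-vector product with the precomputed 1/r
    kernel; equals the naive double loop over (i, j) pairs.
    """
    i_m = np.asarray(all_i_m, dtype=float)
    kernel = field_kernel(distances, params)
    if i_m.shape[0] != kernel.shape[0]:
        raise TopologyError("I_m length does not match distance matrix")
    return kernel @ i_m
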