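"""Small-world network construction and transmission-ratio calibration.

The modeled tissue is a quasi-1-D strip of entorhinal cortex: 200
excitatory (principal) neurons and 40 interleaved inhibitory neurons on
a line with unit nearest-neighbor spacing (one inhibitory cell per five
excitatory).  Every neuron receives exactly five excitatory in-edges -
drawn from a local window with a fraction rewired to long-range sources
(Watts-Strogatz-style small world) - and two local inhibitory in-edges.
The excitatory population is partitioned into G contiguous groups
(default four groups of fifty), each of which contributes one LFP
channel.

``calibrate_ratio`` runs short simulations to fix the synaptic weight
scale and the field strength alpha so that the time-averaged mean
|I_syn| : |I_field| over active neurons during the stable seizure-like
event matches a target percentage split while the total input current
stays near a synapse-only reference run.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import CalibrationError, ConfigurationError, TopologyError

__all__ = [
    "NetworkTopology",
    "build_small_world",
    "assign_groups",
    "calibrate_ratio",
    "CalibrationResult",
    "write_edge_list",
]


@dataclass
class NetworkTopology:
    """Spatial layout, adjacency and group structure of the network.

    ``exc_sources`` / ``inh_sources`` give, for every neuron (row), the
    global indices of its excitatory / inhibitory presynaptic partners;
    the aligned weight arrays hold per-edge base weights (scaled by the
    engine's calibrated weight scale at run time).
    """

    n_exc: int
    n_inh: int
    positions: np.ndarray          # (n,) 1-D coordinate, unit spacing
    is_inhibitory: np.ndarray      # (n,) bool
    exc_sources: np.ndarray        # (n, 5) int
    inh_sources: np.ndarray        # (n, 2) int
    exc_weights: np.ndarray        # (n, 5)
    inh_weights: np.ndarray        # (n, 2)
    distances: np.ndarray          # (n, n) symmetric
    groups: np.ndarray             # (n,) int labels 1..G (0 = unassigned)
    n_groups: int = 0
    layout: str = "line"

    @property
    def n_neurons(self) -> int:
        return self.n_exc + self.n_inh

    @property
    def exc_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_inhibitory)

    @property
    def inh_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_inhibitory)

    def group_members(self, g, excitatory_only=True):
        mask = self.groups == g
        if excitatory_only:
            mask &= ~self.is_inhibitory
        return np.flatnonzero(mask)

    def validate(self):
        n = self.n_neurons
        if self.exc_sources.shape != (n, 5) or self.inh_sources.shape != (n, 2):
            raise TopologyError("every neuron must have exactly 5 excitatory "
                                "and 2 inhibitory in-edges")
        if self.is_inhibitory[self.exc_sources].any():
            raise TopologyError("excitatory in-edge drawn from an inhibitory cell")
        if not self.is_inhibitory[self.inh_sources].all():
            raise TopologyError("inhibitory in-edge drawn from an excitatory cell")
        if (self.exc_sources == np.arange(n)[:, None]).any() or (
                self.inh_sources == np.arange(n)[:, None]).any():
            raise TopologyError("self-edges are not allowed")
        for row in self.exc_sources:
            if len(set(row.tolist())) != 5:
                raise TopologyError("duplicate excitatory in-edges")
        if not np.allclose(self.distances, self.distances.T):
            raise TopologyError("distance matrix must be symmetric")
        return self


def _interleave(n_exc, n_inh):
    """Neuron type sequence along the line: one inhibitory per block."""
    if n_inh <= 0 or n_exc <= 0:
        raise ConfigurationError("need positive excitatory and inhibitory counts")
    if n_exc % n_inh:
        raise ConfigurationError(
            f"n_exc ({n_exc}) must be divisible by n_inh ({n_inh}) for the "
            "interleaved layout"
        )
    per = n_exc // n_inh
    is_inh = np.zeros(n_exc + n_inh, dtype=bool)
    is_inh[per::per + 1] = True
    return is_inh


def build_small_world(n_exc=200, n_inh=40, p_long=0.12, rng=None, *,
                      window=6, long_range_max=50, layout="line", n_groups=4):
    """Construct the interleaved small-world topology.

    Excitatory in-edges are drawn from the ±``window`` nearest excitatory
    cells (in excitatory rank order), each independently rewired with
    probability ``p_long`` to a uniformly random distant excitatory cell
    up to ``long_range_max`` ranks away (None: unbounded; the default
    caps shortcuts at about one group-width so activity cannot skip
    intermediate groups); inhibitory in-edges come from the nearest
    inhibitory cells.  The default layout is an open line (the slice
    strip); ``layout='ring'`` closes it.  Deterministic under a fixed
    rng seed.
    """
    if layout not in ("line", "ring"):
        raise ConfigurationError(f"unknown layout {layout!r}")
    if n_exc < 2 * window + 1 or n_inh < 4:
        raise ConfigurationError("network too small for the requested degrees")
    rng = np.random.default_rng(rng)
    is_inh = _interleave(n_exc, n_inh)
    n = n_exc + n_inh
    positions = np.arange(n, dtype=float)
    exc_idx = np.flatnonzero(~is_inh)          # global index per exc rank
    inh_idx = np.flatnonzero(is_inh)
    rank_of = -np.ones(n, dtype=int)
    rank_of[exc_idx] = np.arange(n_exc)

    exc_sources = np.empty((n, 5), dtype=int)
    inh_sources = np.empty((n, 2), dtype=int)
    for i in range(n):
        # local excitatory candidates by excitatory rank
        if is_inh[i]:
            center = int(np.searchsorted(exc_idx, i))
        else:
            center = rank_of[i]
        lo, hi = center - window, center + window + 1
        if layout == "ring":
            cand = [(r % n_exc) for r in range(lo, hi)]
        else:
            # at the cut ends of the strip the missing outward neighbors are
            # replaced by a doubly-stretched inward span, which keeps the
            # candidate pool size without creating a dense reciprocal clique
            # of boundary cells
            if lo < 0:
                lo, hi = 0, min(n_exc, hi - 2 * lo)
            if hi > n_exc:
                lo, hi = max(0, lo - 2 * (hi - n_exc)), n_exc
            cand = list(range(lo, hi))
        cand = [r for r in cand if exc_idx[r] != i]
        chosen = rng.choice(len(cand), size=5, replace=False)
        picked = {int(cand[j]) for j in chosen}
        # rewire to long-range sources (bounded rank distance)
        if long_range_max is None:
            far_pool = [r for r in range(n_exc) if exc_idx[r] != i]
        else:
            far_pool = []
            for r in range(n_exc):
                dr = abs(r - center)
                if layout == "ring":
                    dr = min(dr, n_exc - dr)
                if window < dr <= long_range_max and exc_idx[r] != i:
                    far_pool.append(r)
        final = set()
        for r in picked:
            if rng.random() < p_long and far_pool:
                for _ in range(100):
                    far = far_pool[int(rng.integers(len(far_pool)))]
                    if far not in final and far not in picked:
                        r = far
                        break
            final.add(r)
        exc_sources[i] = exc_idx[sorted(final)]

        # two inhibitory sources sampled from the four nearest
        d_inh = np.abs(positions[inh_idx] - positions[i])
        if layout == "ring":
            d_inh = np.minimum(d_inh, n - d_inh)
        order = np.argsort(d_inh, kind="stable")
        near = [j for j in order[:5] if inh_idx[j] != i][:4]
        pick = rng.choice(len(near), size=2, replace=False)
        inh_sources[i] = inh_idx[[near[j] for j in pick]]

    delta = np.abs(positions[:, None] - positions[None, :])
    if layout == "ring":
        delta = np.minimum(delta, n - delta)
    topo = NetworkTopology(
        n_exc=n_exc, n_inh=n_inh, positions=positions, is_inhibitory=is_inh,
        exc_sources=exc_sources, inh_sources=inh_sources,
        exc_weights=np.ones((n, 5)), inh_weights=np.ones((n, 2)),
        distances=delta, groups=np.zeros(n, dtype=int), layout=layout,
    )
    topo.validate()
    if n_groups:
        topo = assign_groups(topo, n_groups)
    return topo


def assign_groups(topology: NetworkTopology, n_groups: int) -> NetworkTopology:
    """Label G contiguous, equal-size excitatory groups (1..G) by position.

    Inhibitory neurons inherit the group of their position block.
    """
    if n_groups < 1:
        raise ConfigurationError("need at least one group")
    if topology.n_exc % n_groups:
        raise ConfigurationError(
            f"n_exc ({topology.n_exc}) is not divisible by G ({n_groups})"
        )
    per = topology.n_exc // n_groups
    groups = np.zeros(topology.n_neurons, dtype=int)
    exc_idx = topology.exc_indices
    for g in range(n_groups):
        members = exc_idx[g * per:(g + 1) * per]
        groups[members] = g + 1
    # inhibitory cells take the group spanning their position
    for i in topology.inh_indices:
        exc_groups = groups[exc_idx]
        nearest = exc_idx[np.argmin(np.abs(topology.positions[exc_idx]
                                           - topology.positions[i]))]
        groups[i] = groups[nearest]
    topology.groups = groups
    topology.n_groups = n_groups
    return topology


@dataclass
class CalibrationResult:
    """Outcome of the synaptic:field transmission-ratio calibration."""

    w_scale: float
    alpha: float
    achieved_ratio: tuple        # (syn %, field %)
    total_input: float           # mean |I_syn| + |I_field| over active neurons
    reference_total: float       # same quantity in the synapse-only reference
    iterations: int
    converged: bool


def calibrate_ratio(topology, target_ratio, noise_variance=1.0, rng=None, *,
                    base_config=None, tol_pp=2.0, total_band=0.25,
                    max_iter=8, calib_duration=4000.0):
    """Scale (synaptic weights, alpha) to a target syn:field current split.

    ``target_ratio`` is a (syn_share, field_share) pair summing to 100.
    Short trigger-to-stable simulations are run and the achieved shares -
    time-averaged population-mean |I_syn| and |I_field| over active
    neurons in the stable window - drive a multiplicative fixed-point
    update of the weight scale and alpha.  Convergence requires the
    field share within ``tol_pp`` percentage points of the target and
    the total input within ``total_band`` (fractional) of a synapse-only
    reference run at the default weight scale.
    """
    from . import engine  # local import: engine depends on this module's types

    syn_share, field_share = (float(x) for x in target_ratio)
    if abs(syn_share + field_share - 100.0) > 1e-9:
        raise ConfigurationError("ratio shares must sum to 100")
    if field_share < 0 or syn_share < 0:
        raise ConfigurationError("ratio shares must be non-negative")
    rng = np.random.default_rng(rng)
    seed = int(rng.integers(2 ** 31 - 1))

    cfg = base_config if base_config is not None else engine.SimulationConfig()
    cfg = replace(cfg, duration=calib_duration, noise_variance=noise_variance,
                  seed=seed, ratio=(syn_share, field_share),
                  stim=replace(cfg.stim, enabled=False),
                  stable_window=(min(cfg.stable_window[0], calib_duration - 1000.0),
                                 min(cfg.stable_window[1], calib_duration)))
    w0 = cfg.w_scale

    def measure(w, alpha):
        trace = engine.run_simulation(
            replace(cfg, w_scale=w, alpha=alpha), topology)
        s = trace.shares
        return s["mean_abs_syn"], s["mean_abs_field"], s["n_active"]

    ref_syn, _, n_active = measure(w0, 0.0)
    if n_active == 0 or ref_syn <= 0:
        raise CalibrationError("reference run produced no active neurons; "
                               "cannot calibrate")
    total_target = ref_syn

    if field_share == 0:
        return CalibrationResult(w_scale=w0, alpha=0.0,
                                 achieved_ratio=(100.0, 0.0),
                                 total_input=ref_syn, reference_total=ref_syn,
                                 iterations=0, converged=True)

    s_target = total_target * syn_share / 100.0
    f_target = total_target * field_share / 100.0
    w = w0 * syn_share / 100.0
    alpha = 1e-3
    best = None
    for it in range(1, max_iter + 1):
        s_meas, f_meas, n_active = measure(w, alpha)
        if n_active == 0 or (s_meas + f_meas) <= 0:
            w *= 1.5  # seizure failed to ignite; restore drive and retry
            continue
        total = s_meas + f_meas
        achieved_field = 100.0 * f_meas / total
        achieved = (100.0 - achieved_field, achieved_field)
        err_ratio = abs(achieved_field - field_share)
        err_total = abs(total - total_target) / total_target
        if best is None or err_ratio < best[0]:
            best = (err_ratio, achieved, w, alpha, total)
        if err_ratio <= tol_pp and err_total <= total_band:
            return CalibrationResult(
                w_scale=w, alpha=alpha, achieved_ratio=achieved,
                total_input=total, reference_total=total_target,
                iterations=it, converged=True)
        w *= float(np.clip(s_target / s_meas, 0.3, 3.0))
        alpha *= float(np.clip(f_target / max(f_meas, 1e-12), 0.3, 3.0))
    raise CalibrationError(
        f"calibration did not converge in {max_iter} iterations "
        f"(best achieved ratio {best[1] if best else None})",
        achieved_ratio=best[1] if best else None,
        params={"w_scale": best[2], "alpha": best[3]} if best else None)


def write_edge_list(topology: NetworkTopology, path):
    """Export the topology as a plain edge-list text file.

    Columns: source, target, weight, receptor_class (exc edges drive
    AMPA+NMDA, inh edges GABA_A+GABA_B).
    """
    with open(path, "w") as fh:
        fh.write("# source\ttarget\tweight\treceptor_class\n")
        for i in range(topology.n_neurons):
            for k in range(5):
                fh.write(f"{topology.exc_sources[i, k]}\t{i}\t"
                         f"{topology.exc_weights[i, k]:.6g}\texc\n")
            for k in range(2):
                fh.write(f"{topology.inh_sources[i, k]}\t{i}\t"
                         f"{topology.inh_weights[i, k]:.6g}\tinh\n")
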