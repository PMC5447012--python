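"""Single-neuron dynamics, blockade variables and electrochemistry."""

import math

import numpy as np
import pytest

from slesim.dynamics import (
    BlockadeParams,
    IonSpec,
    NeuronParams,
    NeuronState,
    SPIKE_CUTOFF,
    effective_input,
    ghk_resting_potential,
    izhikevich_step,
    make_population,
    nernst_potential,
    resting_state,
    update_suppression,
)
from slesim.exceptions import ConfigurationError, NumericalError

RS = NeuronParams(a=0.02, b=0.2, c=-65.0, d=8.0)


class TestIzhikevichStep:
    def test_reset_rule_above_cutoff(self):
        state = NeuronState(v=31.0, u=0.0)
        out, spiked = izhikevich_step(state, RS, 0.0, 1.0)
        assert spiked
        # reset applied: u incremented at least once by d
        assert out.u >= RS.d - 1.0

    def test_spike_resets_v_to_c_exactly(self):
        state = NeuronState(v=-60.0, u=-14.0)
        for _ in range(2000):
            state, spiked = izhikevich_step(state, RS, 10.0, 1.0)
            if spiked:
                break
        assert spiked
        assert state.v == RS.c

    def test_tonic_spiking_matches_fine_step_reference(self):
        # independent plain forward-Euler reference at dt = 0.1 ms gives
        # 23 spikes over 1 s for RS parameters at constant I = 10
        state = NeuronState(v=-70.0, u=-14.0)
        count = 0
        for _ in range(10000):
            state, spiked = izhikevich_step(state, RS, 10.0, 0.1)
            count += spiked
        assert abs(count - 23) <= 1

    def test_rest_stays_at_fixed_point(self):
        # fixed point: 0.04 v^2 + 5 v + 140 - u = 0 with u = b v -> v = -70
        state = resting_state(RS)
        assert state.v == pytest.approx(-70.0, abs=1e-9)
        v0 = state.v
        for _ in range(1000):
            state, spiked = izhikevich_step(state, RS, 0.0, 1.0)
            assert not spiked
        assert abs(state.v - v0) < 1.0

    def test_fine_step_convergence_of_spike_count(self):
        counts = {}
        for dt in (0.25, 0.125):
            state = NeuronState(v=-70.0, u=-14.0)
            n = 0
            for _ in range(int(1000 / dt)):
                state, spiked = izhikevich_step(state, RS, 10.0, dt)
                n += spiked
            counts[dt] = n
        assert abs(counts[0.25] - counts[0.125]) <= 1

    def test_non_finite_input_raises_named_error(self):
        state = NeuronState(v=float("nan"), u=0.0)
        with pytest.raises(NumericalError) as err:
            izhikevich_step(state, RS, 0.0, 1.0, neuron_index=17, time_ms=42.0)
        assert err.value.neuron == 17

    def test_invalid_dt_rejected(self):
        with pytest.raises(ConfigurationError):
            izhikevich_step(NeuronState(v=-70, u=-14), RS, 0.0, 0.0)


class TestMakePopulation:
    def test_zero_heterogeneity_gives_identical_sets(self):
        pop = make_population(10, "excitatory-spiking", 0.0,
                              np.random.default_rng(0))
        assert all(p == pop[0] for p in pop)

    def test_seeded_determinism(self):
        p1 = make_population(50, "excitatory", 1.0, np.random.default_rng(3))
        p2 = make_population(50, "excitatory", 1.0, np.random.default_rng(3))
        assert p1 == p2

    @pytest.mark.parametrize("kind,n", [("excitatory", 200),
                                        ("inhibitory-fast-spiking", 40)])
    def test_population_sizes_as_configured(self, kind, n):
        pop = make_population(n, kind, 1.0, np.random.default_rng(1))
        assert len(pop) == n
        assert all(p.c < SPIKE_CUTOFF and p.a > 0 for p in pop)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            make_population(5, "pyramidal", 1.0, np.random.default_rng(0))


class TestSuppression:
    def test_inactive_with_zero_recovery_leaves_state_unchanged(self):
        mech = BlockadeParams(recovery_rate=0.0)
        state = NeuronState(v=-70, u=-14, v_Ek=-80.0, v_c=0.5)
        out = update_suppression(state, False, 1.0, mech)
        assert out.v_Ek == -80.0

    def test_vek_rise_is_monotone_and_concave(self):
        mech = BlockadeParams()
        state = NeuronState(v=-70, u=-14, v_Ek=mech.e_k0, v_c=1.0)
        seq = []
        for _ in range(3000):
            state = update_suppression(state, True, 1.0, mech)
            seq.append(state.v_Ek)
        seq = np.array(seq)
        diffs = np.diff(seq)
        assert np.all(diffs >= -1e-12)           # non-decreasing
        grow = diffs[diffs > 1e-9]
        assert np.all(np.diff(grow) <= 1e-9)     # concave (log-shaped)
        assert seq[-1] <= mech.v_ek_max + 1e-9

    def test_vek_follows_logarithmic_law(self):
        mech = BlockadeParams(v_ek_max=0.0)  # no clipping in this range
        state = NeuronState(v=-70, u=-14, v_Ek=mech.e_k0, v_c=1.0)
        dt = 0.05
        for _ in range(int(1000 / dt)):
            state = update_suppression(state, True, dt, mech)
        expected = mech.e_k0 + mech.rise_gain * math.log(1 + 1000 / mech.rise_tau)
        assert state.v_Ek == pytest.approx(expected, rel=1e-3)

    def test_vc_monotone_non_increasing_and_bounded(self):
        mech = BlockadeParams()
        state = NeuronState(v=-70, u=-14, v_Ek=mech.e_k0, v_c=1.0)
        prev = 1.0
        for _ in range(4000):
            state = update_suppression(state, True, 1.0, mech)
            assert 0.0 <= state.v_c <= prev + 1e-12
            prev = state.v_c
        assert prev < 0.05  # blockade engaged after sustained stimulation


class TestEffectiveInput:
    def test_unity_gate_recovers_plain_sum(self):
        assert effective_input(1.0, 3.5, 1.5) == pytest.approx(5.0)

    def test_zero_gate_blocks_everything(self):
        assert effective_input(0.0, 1e6, -1e6) == 0.0

    def test_half_gate_arithmetic(self):
        assert effective_input(0.5, 6.0, 2.0) == pytest.approx(4.0)

    def test_gate_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            effective_input(1.5, 1.0, 0.0)


class TestElectrochemistry:
    R, F = 8.314462618, 96485.33212

    def test_equal_concentrations_give_zero(self):
        ion = IonSpec(z=1, conc_in=10.0, conc_out=10.0)
        assert nernst_potential(ion) == pytest.approx(0.0, abs=1e-12)

    def test_potassium_reversal_closed_form(self):
        ion = IonSpec(z=1, conc_in=140.0, conc_out=4.0)
        expected = (self.R * 310.15 / self.F) * math.log(4.0 / 140.0) * 1000.0
        got = nernst_potential(ion, 310.15)
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(-95.0, abs=0.2)

    def test_doubling_valence_halves_magnitude(self):
        i1 = IonSpec(z=1, conc_in=10.0, conc_out=100.0)
        i2 = IonSpec(z=2, conc_in=10.0, conc_out=100.0)
        assert nernst_potential(i1) == pytest.approx(2 * nernst_potential(i2))

    def test_zero_valence_rejected(self):
        with pytest.raises(ConfigurationError):
            nernst_potential(IonSpec(z=0, conc_in=1.0, conc_out=2.0))

    def test_single_permeant_ion_equals_nernst(self):
        ion = IonSpec(z=1, conc_in=140.0, conc_out=4.0, permeability=1.0)
        assert ghk_resting_potential([ion]) == pytest.approx(
            nernst_potential(ion), abs=1e-9)

    def test_potassium_dominant_mixture_closed_form(self):
        ions = [IonSpec(1, 140.0, 4.0, 1.0),      # K+
                IonSpec(1, 10.0, 145.0, 0.04),    # Na+
                IonSpec(-1, 10.0, 110.0, 0.45)]   # Cl-
        num = 1.0 * 4.0 + 0.04 * 145.0 + 0.45 * 10.0
        den = 1.0 * 140.0 + 0.04 * 10.0 + 0.45 * 110.0
        expected = (self.R * 310.15 / self.F) * math.log(num / den) * 1000.0
        got = ghk_resting_potential(ions, 310.15)
        assert got == pytest.approx(expected, abs=1e-9)
        e_k = nernst_potential(ions[0])
        e_na = nernst_potential(ions[1])
        assert e_k < got < e_na
        assert abs(got - e_k) < abs(got - e_na)

    def test_raising_external_potassium_raises_resting_potential(self):
        def em(k_out):
            ions = [IonSpec(1, 140.0, k_out, 1.0),
                    IonSpec(1, 10.0, 145.0, 0.04),
                    IonSpec(-1, 10.0, 110.0, 0.45)]
            return ghk_resting_potential(ions)
        values = [em(k) for k in (4.0, 8.0, 16.0, 32.0)]
        assert np.all(np.diff(values) > 0)

    def test_all_zero_permeabilities_rejected(self):
        with pytest.raises(ConfigurationError):
            ghk_resting_potential([IonSpec(1, 1.0, 1.0, 0.0)])
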