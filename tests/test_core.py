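"""Unit and property tests for the membrane/conductance simulator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sifneuron import (
    MembraneParams,
    NeuronSpec,
    SpikeTrainSet,
    SynapseGroupParams,
    default_sif_spec,
    make_lif,
    run_simulation,
    step_voltage,
    update_conductances,
)
from sifneuron.errors import (
    DomainError,
    EmptyHorizonError,
    MappingError,
    ResolutionError,
    StateCorruptionError,
)
from sifneuron.protocol import generate_poisson_trains, generate_single_spike_trains

from conftest import trains_from


def forward_euler_reference(v0, g_ps, duration_ms, membrane, e_s_mv=0.0, dt=1e-3):
    """Independent dense forward-Euler integration of the membrane ODE
    with constant conductance; oracle for the exponential-Euler step."""
    rg = membrane.r_mohm * g_ps * 1e-6
    v = v0
    for _ in range(int(duration_ms / dt)):
        v = v + dt * (-(v - membrane.v_rest_mv) + rg * (e_s_mv - v)) / membrane.tau_ms
    return v


class TestUpdateConductances:
    def test_exponential_decay_closed_form(self, sif_spec):
        state = update_conductances([100.0, 0.0], dt_ms=1.0, arrivals=[], spec=sif_spec)
        assert state[0] == pytest.approx(100.0 * math.exp(-1.0))
        assert state[1] == 0.0

    def test_saturating_jump_sets_ceiling_not_sum(self, sif_spec):
        # a decayed group hit by a spike returns to exactly its bound
        state = update_conductances(
            [100.0 * math.exp(-1.0), 0.0], dt_ms=1.0, arrivals=[(1, 1)], spec=sif_spec
        )
        assert state[0] == 100.0

    def test_additive_unbounded_accumulates(self, lif_spec):
        state = update_conductances([100.0], dt_ms=1e-9, arrivals=[(1, 1), (3, 1)], spec=lif_spec)
        assert state[0] == pytest.approx(100.0 + 200.0)

    def test_unknown_source_rejected(self, sif_spec):
        with pytest.raises(MappingError):
            update_conductances([0.0, 0.0], dt_ms=0.1, arrivals=[(9, 1)], spec=sif_spec)

    def test_negative_state_rejected(self, sif_spec):
        with pytest.raises(StateCorruptionError):
            update_conductances([-1.0, 0.0], dt_ms=0.1, arrivals=[], spec=sif_spec)


class TestStepVoltage:
    membrane = MembraneParams()

    def test_rest_is_fixed_point(self):
        for dt in (0.1, 5.0, 1e4):
            assert step_voltage(-65.0, 0.0, dt, self.membrane, 0.0) == pytest.approx(-65.0)

    def test_passive_relaxation_closed_form(self):
        v = step_voltage(-60.0, 0.0, 20.0, self.membrane, 0.0)
        assert v == pytest.approx(-65.0 + 5.0 * math.exp(-1.0), abs=1e-12)

    def test_constant_conductance_fixed_point_matches_dense_euler(self):
        # R*g = 20 MOhm * 100 pS = 2e-3; v* = v_rest / (1 + R g) for E_s = 0
        oracle = forward_euler_reference(-65.0, 100.0, 2000.0, self.membrane)
        v = step_voltage(-65.0, 100.0, 1e6, self.membrane, 0.0)
        assert v == pytest.approx(oracle, abs=1e-6)
        assert v == pytest.approx(-64.87, abs=5e-3)

    def test_drives_toward_reversal_potential(self):
        v = step_voltage(-65.0, 5e4, 1e6, self.membrane, 0.0)
        assert -65.0 < v < 0.0
        assert v == pytest.approx(-65.0 / (1.0 + 20.0 * 5e4 * 1e-6))


class TestRunSimulation:
    def test_no_input_stays_at_rest(self, sif_spec):
        res = run_simulation(sif_spec, trains_from({}, horizon_ms=100.0))
        assert np.all(res.voltage_mv == -65.0)
        assert res.n_somatic_spikes == 0
        assert res.n_steps == 1000

    def test_clustered_vs_scattered_peak_conductance(self, sif_spec):
        # two spikes into one saturating group give 100 pS total; one spike
        # into each of two groups gives 200 pS
        same = run_simulation(sif_spec, trains_from({1: [10.0], 2: [10.0]}))
        split = run_simulation(sif_spec, trains_from({1: [10.0], 3: [10.0]}))
        assert same.total_conductance_ps.max() == 100.0
        assert split.total_conductance_ps.max() == 200.0
        assert split.conductances_ps[0].max() == 100.0
        assert split.conductances_ps[1].max() == 100.0

    @pytest.mark.parametrize("drive_scale", [1.0, 100.0])
    def test_dense_dt_oracle_agreement(self, drive_scale):
        spec = default_sif_spec(drive_scale=drive_scale)
        trains = trains_from({1: [5.0, 12.0], 2: [30.0], 3: [5.0, 20.0]})
        coarse = run_simulation(spec, trains, dt_ms=0.1, spiking=False)
        dense = run_simulation(spec, trains, dt_ms=0.001, spiking=False)
        assert abs(coarse.peak_voltage_mv - dense.peak_voltage_mv) < 1e-3  # 1 uV

    def test_resolution_guard(self, sif_spec):
        with pytest.raises(ResolutionError):
            run_simulation(sif_spec, trains_from({}, horizon_ms=10.0), dt_ms=0.5)

    def test_empty_horizon_rejected(self):
        with pytest.raises(EmptyHorizonError):
            SpikeTrainSet(trains={}, horizon_ms=0.0)

    def test_spiking_records_reset_and_threshold_alignment(self):
        spec = default_sif_spec(drive_scale=100.0).with_threshold(-64.5)
        res = run_simulation(spec, trains_from({1: [10.0], 3: [10.0]}))
        assert res.n_somatic_spikes >= 1
        mem = spec.membrane
        assert res.voltage_mv.min() >= mem.v_reset_mv
        assert res.voltage_mv.max() <= mem.v_threshold_mv
        # each recorded spike time is a step boundary with a reset sample
        for t in res.spike_times_ms:
            k = int(round(t / res.dt_ms)) - 1
            assert res.voltage_mv[k] == mem.v_reset_mv

    def test_conductances_persist_through_somatic_reset(self):
        spec = default_sif_spec(drive_scale=100.0).with_threshold(-64.9)
        res = run_simulation(spec, trains_from({1: [10.0], 3: [10.0]}))
        nospike = run_simulation(spec, trains_from({1: [10.0], 3: [10.0]}), spiking=False)
        assert res.n_somatic_spikes >= 1
        np.testing.assert_array_equal(res.conductances_ps[0], nospike.conductances_ps[0])


class TestMakeLif:
    def test_pools_all_sources_into_one_unbounded_group(self, sif_spec, lif_spec):
        assert lif_spec.kind == "lif"
        assert lif_spec.n_groups == 1
        assert set(lif_spec.mapping) == {1, 2, 3, 4}
        assert lif_spec.groups[0].g_max_ps == sif_spec.groups[0].g_max_ps

    def test_idempotent(self, lif_spec):
        assert make_lif(lif_spec) == lif_spec

    def test_pattern_invariance_for_two_active_inputs(self, lif_spec):
        # any two simultaneously active inputs produce bitwise identical traces
        results = [
            run_simulation(lif_spec, generate_single_spike_trains(p, 10.0, 100.0))
            for p in ([0, 0, 1, 1], [1, 1, 0, 0], [0, 1, 0, 1], [1, 0, 1, 0])
        ]
        for other in results[1:]:
            np.testing.assert_array_equal(results[0].voltage_mv, other.voltage_mv)
            np.testing.assert_array_equal(
                results[0].total_conductance_ps, other.total_conductance_ps
            )


class TestInvariants:
    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**20), scale=st.sampled_from([1.0, 10.0, 100.0]))
    def test_saturating_bound_conserved_under_random_drive(self, seed, scale):
        spec = default_sif_spec(drive_scale=scale)
        trains = generate_poisson_trains([1, 1, 1, 1], 200.0, 100.0, seed=seed)
        res = run_simulation(spec, trains, spiking=False)
        for gi, group in enumerate(spec.groups):
            trace = res.conductances_ps[gi]
            assert trace.min() >= 0.0
            assert trace.max() <= scale * group.g_max_ps

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 2**20),
        extra_source=st.sampled_from([1, 2, 3, 4]),
        extra_frac=st.floats(0.01, 0.99),
    )
    def test_extra_spike_never_reduces_output(self, seed, extra_source, extra_frac):
        # excitatory-only model: more input can only help
        spec = default_sif_spec(drive_scale=100.0).with_threshold(-64.17)
        base = generate_poisson_trains([1, 0, 1, 0], 50.0, 200.0, seed=seed)
        n0 = run_simulation(spec, base).n_somatic_spikes
        t_extra = extra_frac * 200.0
        old = base.trains.get(extra_source, np.empty(0))
        augmented = SpikeTrainSet(
            trains={**base.trains, extra_source: np.unique(np.append(old, t_extra))},
            horizon_ms=200.0,
        )
        n1 = run_simulation(spec, augmented).n_somatic_spikes
        assert n1 >= n0


class TestSpecValidation:
    def test_membrane_ordering_enforced(self):
        with pytest.raises(DomainError):
            MembraneParams(v_threshold_mv=-70.0)

    def test_train_times_must_be_sorted_and_in_range(self):
        with pytest.raises(DomainError):
            SpikeTrainSet(trains={1: np.asarray([5.0, 2.0])}, horizon_ms=10.0)
        with pytest.raises(DomainError):
            SpikeTrainSet(trains={1: np.asarray([12.0])}, horizon_ms=10.0)

    def test_lif_cannot_have_two_groups(self):
        g = SynapseGroupParams(jump_mode="additive_unbounded")
        with pytest.raises(DomainError):
            NeuronSpec(membrane=MembraneParams(), groups=(g, g), mapping={1: 0})

    def test_mapping_must_reference_existing_groups(self):
        with pytest.raises(MappingError):
            NeuronSpec(
                membrane=MembraneParams(),
                groups=(SynapseGroupParams(),),
                mapping={1: 3},
            )
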