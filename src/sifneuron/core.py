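"""Single-compartment integrate-and-fire neuron with saturating synaptic groups.

The model is a leaky integrate-and-fire (LIF) membrane

    tau * dv/dt = -(v - v_rest) + R * I_s(t),
    I_s(t) = sum_i g_i(t) * (E_s - v(t)),

whose synaptic input sources are pooled into conductance *groups*.  Each
group carries one conductance variable g_i.  In the saturating variant
(SIF) an incoming spike sets the group conductance to its ceiling
``g_max`` — nearby synapses interact and cannot drive the group past its
maximal conductance per unit of membrane surface — and g_i then decays
exponentially with time constant ``tau_s``.  The classical LIF is the
special case of a single group whose conductance increments without
bound, so that total drive depends only on the number of input spikes.

Units are fixed throughout: time in ms, voltage in mV, conductance in pS,
resistance in MOhm.  The product R*g is dimensionless after a 1e-6
conversion (MOhm * pS = 1e-6).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    DomainError,
    EmptyHorizonError,
    MappingError,
    ResolutionError,
    StateCorruptionError,
)

__all__ = [
    "MembraneParams",
    "SynapseGroupParams",
    "NeuronSpec",
    "SpikeTrainSet",
    "SimResult",
    "update_conductances",
    "step_voltage",
    "run_simulation",
    "make_lif",
    "default_sif_spec",
    "RG_UNIT",
]

#: MOhm * pS expressed as a dimensionless number (1e6 Ohm * 1e-12 S).
RG_UNIT = 1e-6

SET_TO_MAX = "set_to_max"
ADDITIVE_UNBOUNDED = "additive_unbounded"
_JUMP_MODES = (SET_TO_MAX, ADDITIVE_UNBOUNDED)


@dataclass(frozen=True)
class MembraneParams:
    """Passive membrane and spike-generation parameters.

    Defaults follow the compact-neuron regime: tau = 20 ms, rest/reset at
    -65 mV, input resistance 20 MOhm.  ``v_threshold_mv`` is the somatic
    spike threshold; it is typically overwritten by protocol calibration.
    """

    tau_ms: float = 20.0
    v_rest_mv: float = -65.0
    r_mohm: float = 20.0
    v_threshold_mv: float = -62.0
    v_reset_mv: float = -65.0

    def __post_init__(self) -> None:
        if self.tau_ms <= 0:
            raise DomainError(f"tau_ms must be positive, got {self.tau_ms}")
        if self.r_mohm <= 0:
            raise DomainError(f"r_mohm must be positive, got {self.r_mohm}")
        if not (self.v_reset_mv <= self.v_rest_mv < self.v_threshold_mv):
            raise DomainError(
                "membrane ordering violated: need v_reset <= v_rest < v_threshold, "
                f"got {self.v_reset_mv}, {self.v_rest_mv}, {self.v_threshold_mv}"
            )


@dataclass(frozen=True)
class SynapseGroupParams:
    """One conductance group: reversal potential, kinetics and ceiling.

    ``jump_mode`` selects the response to an incoming spike:

    - ``"set_to_max"``: the conductance jumps to ``g_max_ps`` (scaled by the
      neuron's drive_scale) and never exceeds it — the saturating synapse.
    - ``"additive_unbounded"``: each spike adds ``g_max_ps`` with no ceiling —
      the linear pooling of the classical LIF.
    """

    e_s_mv: float = 0.0
    tau_s_ms: float = 1.0
    g_max_ps: float = 100.0
    jump_mode: str = SET_TO_MAX

    def __post_init__(self) -> None:
        if self.tau_s_ms <= 0:
            raise DomainError(f"tau_s_ms must be positive, got {self.tau_s_ms}")
        if self.g_max_ps <= 0:
            raise DomainError(f"g_max_ps must be positive, got {self.g_max_ps}")
        if self.jump_mode not in _JUMP_MODES:
            raise DomainError(f"unknown jump_mode {self.jump_mode!r}")


@dataclass(frozen=True)
class NeuronSpec:
    """A complete neuron definition: membrane, groups and input routing.

    ``mapping`` sends each input-source id (1-based by convention) to an
    index into ``groups``; every source belongs to exactly one group.
    ``drive_scale`` multiplies every group's conductance ceiling/increment
    uniformly; it preserves the ratio of drives between stimulation
    patterns while moving the absolute response into the spiking regime.
    """

    membrane: MembraneParams
    groups: tuple[SynapseGroupParams, ...]
    mapping: Mapping[int, int]
    drive_scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.groups:
            raise DomainError("spec needs at least one conductance group")
        if self.drive_scale < 1.0:
            raise DomainError(f"drive_scale must be >= 1, got {self.drive_scale}")
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "mapping", dict(self.mapping))
        for src, gi in self.mapping.items():
            if not 0 <= gi < len(self.groups):
                raise MappingError(f"source {src} maps to unknown group {gi}")
        modes = {g.jump_mode for g in self.groups}
        if len(modes) > 1:
            raise DomainError("groups must share a jump_mode (pure LIF or pure SIF)")
        if modes == {ADDITIVE_UNBOUNDED} and len(self.groups) != 1:
            raise DomainError("a LIF pools all inputs into exactly one group")

    @property
    def kind(self) -> str:
        """``"lif"`` for the single unbounded group, ``"sif"`` otherwise."""
        return "lif" if self.groups[0].jump_mode == ADDITIVE_UNBOUNDED else "sif"

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_of(self, source: int) -> int:
        try:
            return self.mapping[source]
        except KeyError:
            raise MappingError(f"unknown input source {source}") from None

    def with_drive_scale(self, scale: float) -> "NeuronSpec":
        return replace(self, drive_scale=scale)

    def with_threshold(self, v_threshold_mv: float) -> "NeuronSpec":
        return replace(self, membrane=replace(self.membrane, v_threshold_mv=v_threshold_mv))


@dataclass(frozen=True)
class SpikeTrainSet:
    """Per-source input spike times over a finite horizon.

    ``trains`` maps a source id to a strictly increasing array of spike
    times in ms; all times lie in [0, horizon_ms).  Sources absent from the
    dict are silent.
    """

    trains: Mapping[int, np.ndarray]
    horizon_ms: float

    def __post_init__(self) -> None:
        if self.horizon_ms <= 0:
            raise EmptyHorizonError(f"horizon_ms must be positive, got {self.horizon_ms}")
        clean: dict[int, np.ndarray] = {}
        for src, times in dict(self.trains).items():
            arr = np.asarray(times, dtype=float)
            if arr.ndim != 1:
                raise DomainError(f"source {src}: spike times must be 1-D")
            if arr.size and (arr.min() < 0 or arr.max() >= self.horizon_ms):
                raise DomainError(
                    f"source {src}: spike times must lie in [0, {self.horizon_ms})"
                )
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise DomainError(f"source {src}: spike times must be strictly increasing")
            arr.flags.writeable = False
            clean[src] = arr
        object.__setattr__(self, "trains", clean)

    @property
    def n_spikes(self) -> int:
        return sum(a.size for a in self.trains.values())

    def sources(self) -> list[int]:
        return sorted(self.trains)


@dataclass(frozen=True)
class SimResult:
    """Traces and somatic spike times from one simulation run.

    Voltage sample ``k`` is the membrane state at the end of step ``k``
    (time ``(k + 1) * dt``).  Conductance sample ``k`` is the value just
    after the step's spike arrivals — the within-step maximum — so an
    isolated input spike registers its full jump in the trace.
    """

    dt_ms: float
    voltage_mv: np.ndarray
    conductances_ps: tuple[np.ndarray, ...]
    spike_times_ms: np.ndarray

    @property
    def n_steps(self) -> int:
        return self.voltage_mv.size

    @property
    def total_conductance_ps(self) -> np.ndarray:
        return np.sum(self.conductances_ps, axis=0)

    @property
    def times_ms(self) -> np.ndarray:
        return (np.arange(self.n_steps) + 1) * self.dt_ms

    @property
    def peak_voltage_mv(self) -> float:
        return float(self.voltage_mv.max())

    @property
    def n_somatic_spikes(self) -> int:
        return int(self.spike_times_ms.size)


def default_sif_spec(
    n_pairs: int = 2,
    sources_per_group: int = 2,
    membrane: MembraneParams | None = None,
    group: SynapseGroupParams | None = None,
    drive_scale: float = 1.0,
) -> NeuronSpec:
    """Canonical SIF: ``n_pairs`` saturating groups, consecutive sources pooled.

    The default (2 groups x 2 sources) is the four-input neuron whose
    sources 1,2 share group 1 and sources 3,4 share group 2.
    """
    membrane = membrane or MembraneParams()
    group = group or SynapseGroupParams()
    mapping = {
        g * sources_per_group + s + 1: g
        for g in range(n_pairs)
        for s in range(sources_per_group)
    }
    return NeuronSpec(
        membrane=membrane,
        groups=tuple(group for _ in range(n_pairs)),
        mapping=mapping,
        drive_scale=drive_scale,
    )


def make_lif(spec: NeuronSpec) -> NeuronSpec:
    """Collapse a spec into its LIF null model.

    All sources are pooled into one unbounded group with the same membrane,
    kinetics and per-spike increment (``drive_scale * g_max``), so the total
    drive depends only on how many inputs fired — the linear integration the
    saturating model is contrasted against.  Idempotent on a LIF.
    """
    if spec.kind == "lif":
        return spec
    g0 = spec.groups[0]
    pooled = replace(g0, jump_mode=ADDITIVE_UNBOUNDED)
    return NeuronSpec(
        membrane=spec.membrane,
        groups=(pooled,),
        mapping={src: 0 for src in spec.mapping},
        drive_scale=spec.drive_scale,
    )


def update_conductances(
    state: Sequence[float],
    dt_ms: float,
    arrivals: Iterable[tuple[int, int]],
    spec: NeuronSpec,
) -> list[float]:
    """Advance all group conductances by one step.

    Each group first decays exactly, by ``exp(-dt/tau_s)``, then the step's
    spike arrivals are applied: a saturating group is set to its ceiling
    ``drive_scale * g_max`` regardless of how many spikes arrived; an
    unbounded group gains ``drive_scale * g_max`` per spike.  Arrivals are
    applied in ascending source order (only observable for unbounded
    groups, where order is irrelevant anyway; fixed for reproducibility).
    """
    if dt_ms <= 0:
        raise DomainError(f"dt_ms must be positive, got {dt_ms}")
    if len(state) != spec.n_groups:
        raise StateCorruptionError(
            f"state has {len(state)} groups, spec has {spec.n_groups}"
        )
    new = []
    for g, params in zip(state, spec.groups):
        if g < 0:
            raise StateCorruptionError(f"negative conductance {g}")
        new.append(g * math.exp(-dt_ms / params.tau_s_ms))
    for source, count in sorted(arrivals):
        gi = spec.group_of(source)
        params = spec.groups[gi]
        ceiling = spec.drive_scale * params.g_max_ps
        if params.jump_mode == SET_TO_MAX:
            new[gi] = ceiling
        else:
            new[gi] += count * ceiling
    return new


def step_voltage(
    v_mv: float,
    g_total_ps: float,
    dt_ms: float,
    membrane: MembraneParams,
    e_s_mv: float,
) -> float:
    """One exponential-Euler step of the membrane equation.

    With the total conductance frozen over the step the membrane ODE is
    affine, ``tau dv/dt = -(v - v_rest) + R g (E_s - v)``, with fixed point
    ``v* = (v_rest + R g E_s) / (1 + R g)`` and effective time constant
    ``tau / (1 + R g)``; the update is its exact solution.
    """
    if dt_ms <= 0:
        raise DomainError(f"dt_ms must be positive, got {dt_ms}")
    rg = membrane.r_mohm * g_total_ps * RG_UNIT
    v_inf = (membrane.v_rest_mv + rg * e_s_mv) / (1.0 + rg)
    return v_inf + (v_mv - v_inf) * math.exp(-dt_ms * (1.0 + rg) / membrane.tau_ms)


def _bin_arrivals(
    trains: SpikeTrainSet, spec: NeuronSpec, dt_ms: float, n_steps: int
) -> dict[int, list[tuple[int, int]]]:
    """Bucket input spikes into integration steps as (source, count) lists."""
    bins: dict[int, dict[int, int]] = {}
    for src, times in trains.trains.items():
        spec.group_of(src)  # raises MappingError early for unknown sources
        for t in times:
            k = min(int(t / dt_ms), n_steps - 1)
            bins.setdefault(k, {}).setdefault(src, 0)
            bins[k][src] += 1
    return {k: sorted(d.items()) for k, d in bins.items()}


def run_simulation(
    spec: NeuronSpec,
    trains: SpikeTrainSet,
    dt_ms: float = 0.1,
    spiking: bool = True,
) -> SimResult:
    """Time-stepped simulation of a neuron driven by input spike trains.

    Per step: conductances decay over the previous step and absorb the
    current step's arrivals at the step start (`update_conductances`),
    then the voltage advances one exponential-Euler step with each group
    frozen at its exact within-step average, ``g * (tau_s/dt) *
    (1 - exp(-dt/tau_s))`` — the mean of the decaying exponential over the
    step — generalised to per-group reversal potentials.  Averaging the
    (fast) conductance rather than sampling it at one end removes the
    first-order bias of plain freezing while leaving the scheme a
    frozen-coefficient affine update.  When ``spiking`` and the
    end-of-step voltage reaches threshold, the step time is recorded as a
    somatic spike and the voltage is reset; conductances persist through
    the reset.  With ``spiking=False`` the subthreshold trajectory is
    returned unclipped (used by protocol calibration).

    ``dt_ms`` must not exceed a fifth of the fastest synaptic time constant.
    """
    if dt_ms <= 0:
        raise DomainError(f"dt_ms must be positive, got {dt_ms}")
    min_tau_s = min(g.tau_s_ms for g in spec.groups)
    if dt_ms > min_tau_s / 5.0:
        raise ResolutionError(
            f"dt_ms={dt_ms} too coarse for tau_s={min_tau_s} ms (need dt <= tau_s/5)"
        )
    n_steps = math.ceil(trains.horizon_ms / dt_ms)
    if n_steps == 0:
        raise EmptyHorizonError("simulation horizon shorter than one step")

    arrivals = _bin_arrivals(trains, spec, dt_ms, n_steps)
    mem = spec.membrane
    tau = mem.tau_ms
    r = mem.r_mohm
    v_rest = mem.v_rest_mv
    v_thr = mem.v_threshold_mv
    v_reset = mem.v_reset_mv
    e_s = [g.e_s_mv for g in spec.groups]
    decay = [math.exp(-dt_ms / g.tau_s_ms) for g in spec.groups]
    # exact mean of exp(-t/tau_s) over one step, used to freeze each group
    # at its within-step average for the voltage update
    avg = [
        (g.tau_s_ms / dt_ms) * (1.0 - math.exp(-dt_ms / g.tau_s_ms))
        for g in spec.groups
    ]
    ceiling = [spec.drive_scale * g.g_max_ps for g in spec.groups]
    set_max = [g.jump_mode == SET_TO_MAX for g in spec.groups]
    n_groups = spec.n_groups
    group_of = spec.mapping

    voltage = np.empty(n_steps)
    g_traces = np.empty((n_groups, n_steps))
    spikes: list[float] = []

    v = v_rest
    g = [0.0] * n_groups
    exp = math.exp
    for k in range(n_steps):
        g = [gi * di for gi, di in zip(g, decay)]
        ev = arrivals.get(k)
        if ev is not None:
            for source, count in ev:
                gi = group_of[source]
                if set_max[gi]:
                    g[gi] = ceiling[gi]
                else:
                    g[gi] += count * ceiling[gi]
        # exponential-Euler voltage update with per-group reversal potentials
        rg = 0.0
        re = 0.0
        for gi in range(n_groups):
            w = r * g[gi] * avg[gi] * RG_UNIT
            rg += w
            re += w * e_s[gi]
        v_inf = (v_rest + re) / (1.0 + rg)
        v = v_inf + (v - v_inf) * exp(-dt_ms * (1.0 + rg) / tau)
        if spiking and v >= v_thr:
            spikes.append((k + 1) * dt_ms)
            v = v_reset
        voltage[k] = v
        for gi in range(n_groups):
            g_traces[gi, k] = g[gi]

    return SimResult(
        dt_ms=dt_ms,
        voltage_mv=voltage,
        conductances_ps=tuple(g_traces),
        spike_times_ms=np.asarray(spikes),
    )
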