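"""Stimulation protocols deciding whether a neuron implements a truth table.

Each row of a partial Boolean table becomes one stimulation *episode*: the
row's active inputs are driven and the neuron's somatic response is read
out as the row's Boolean output (1 iff at least one somatic spike).  Two
readings of "active" are supported:

- ``spike`` mode: one simultaneous input spike per active source — a
  single coincident volley, fully deterministic;
- ``rate`` mode: independent homogeneous Poisson trains (default 50 Hz)
  on the active sources for the whole episode.

Episodes are simulated independently (fresh state), so their order is
irrelevant.  Because the nominal parameter set leaves single-volley
responses microvolts from rest, a calibration pass first scales the
synaptic drive (powers of ten) and places the spike threshold between the
subthreshold peak responses of the 0-class and 1-class episodes; for a
saturating two-group neuron the scattered patterns recruit twice the peak
conductance of the clustered ones, so such a gap exists, while the
linearly integrating LIF responds identically to every pattern and is
reported not calibratable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import NeuronSpec, SpikeTrainSet, run_simulation
from .errors import DomainError
from .separability import PartialBooleanTable

__all__ = [
    "ProtocolConfig",
    "EpisodeReadout",
    "CalibrationResult",
    "ProtocolReport",
    "generate_poisson_trains",
    "generate_single_spike_trains",
    "calibrate",
    "run_protocol",
    "implements_table",
]

#: Minimum depolarisation of the calibrated threshold above rest (mV).
MIN_THRESHOLD_GAP_MV = 0.5
#: Largest drive multiplier calibration will try before giving up.
MAX_DRIVE_SCALE = 1e8
#: Number of fixed-seed episode draws averaged over during rate-mode
#: calibration; the verdict itself is re-checked across independent seeds.
RATE_CALIBRATION_DRAWS = 5


@dataclass(frozen=True)
class ProtocolConfig:
    """Protocol settings: the target table, stimulation mode and timing."""

    table: PartialBooleanTable
    mode: str = "spike"
    active_rate_hz: float = 50.0
    episode_ms: float = 500.0
    t0_ms: float = 10.0
    inter_episode_reset: bool = True
    seed: int = 0
    dt_ms: float = 0.1
    n_verdict_seeds: int = 20

    def __post_init__(self) -> None:
        if self.mode not in ("spike", "rate"):
            raise DomainError(f"mode must be 'spike' or 'rate', got {self.mode!r}")
        if self.mode == "rate" and self.active_rate_hz <= 0:
            raise DomainError("rate mode requires active_rate_hz > 0")
        if self.episode_ms <= 0:
            raise DomainError("episode_ms must be positive")
        if not 0 <= self.t0_ms < self.episode_ms:
            raise DomainError("t0_ms must lie within the episode")


@dataclass(frozen=True)
class EpisodeReadout:
    """Somatic response summary for one stimulation episode."""

    pattern: tuple[int, ...]
    somatic_spike_count: int
    peak_voltage_mv: float
    episode_ms: float

    @property
    def mean_rate_hz(self) -> float:
        return self.somatic_spike_count / (self.episode_ms * 1e-3)

    @property
    def output(self) -> int:
        return 1 if self.somatic_spike_count >= 1 else 0


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the drive/threshold calibration pass.

    ``calibratable`` is False when the two output classes produce
    indistinguishable peak responses (the LIF case) or the table lacks one
    of the classes; that is a scientific verdict, not an error.  When
    calibratable, ``v_threshold_mv`` sits midway between the largest
    0-class peak and the smallest 1-class peak, ``margin_mv`` is the
    half-gap, and ``drive_scale`` is the multiplier that lifted the
    midpoint at least 0.5 mV above rest.
    """

    calibratable: bool
    drive_scale: float = 1.0
    v_threshold_mv: float = math.nan
    margin_mv: float = math.nan
    reason: str = ""

    def apply(self, spec: NeuronSpec) -> NeuronSpec:
        if not self.calibratable:
            raise DomainError(f"not calibratable: {self.reason}")
        return spec.with_drive_scale(self.drive_scale).with_threshold(
            self.v_threshold_mv
        )


@dataclass(frozen=True)
class ProtocolReport:
    """Per-episode readouts plus the implements-the-table verdict."""

    readouts: tuple[EpisodeReadout, ...]
    expected: tuple[int, ...]
    implements: bool
    calibration: CalibrationResult
    agreement_fraction: float = 1.0
    reason: str = ""

    @property
    def outputs(self) -> tuple[int, ...]:
        return tuple(r.output for r in self.readouts)


def generate_poisson_trains(
    pattern: Sequence[int],
    rate_hz: float,
    duration_ms: float,
    seed: int,
) -> SpikeTrainSet:
    """Independent homogeneous Poisson trains on the active sources.

    Source i (1-based, pattern bit i) receives a Poisson train at
    ``rate_hz`` iff its bit is 1; inactive sources are silent.  Streams are
    drawn from per-source children of one seed sequence, so they are
    independent, reproducible, and a source's train does not depend on
    which other sources are active.
    """
    if rate_hz < 0:
        raise DomainError("rate_hz must be non-negative")
    if duration_ms <= 0:
        raise DomainError("duration_ms must be positive")
    children = np.random.SeedSequence(seed).spawn(len(pattern))
    trains: dict[int, np.ndarray] = {}
    for i, bit in enumerate(pattern):
        if not bit:
            continue
        rng = np.random.default_rng(children[i])
        n = rng.poisson(rate_hz * duration_ms * 1e-3)
        times = np.unique(rng.uniform(0.0, duration_ms, size=n))
        trains[i + 1] = times
    return SpikeTrainSet(trains=trains, horizon_ms=duration_ms)


def generate_single_spike_trains(
    pattern: Sequence[int],
    t0_ms: float,
    duration_ms: float,
) -> SpikeTrainSet:
    """One simultaneous spike at ``t0_ms`` on every active source."""
    if not 0 <= t0_ms < duration_ms:
        raise DomainError("t0_ms must lie within the episode")
    trains = {
        i + 1: np.asarray([t0_ms]) for i, bit in enumerate(pattern) if bit
    }
    return SpikeTrainSet(trains=trains, horizon_ms=duration_ms)


def _episode_trains(
    pattern: Sequence[int], config: ProtocolConfig, seed: int
) -> SpikeTrainSet:
    if config.mode == "spike":
        return generate_single_spike_trains(pattern, config.t0_ms, config.episode_ms)
    return generate_poisson_trains(
        pattern, config.active_rate_hz, config.episode_ms, seed
    )


def _subthreshold_peaks(
    spec: NeuronSpec, config: ProtocolConfig, seeds: Sequence[int]
) -> dict[int, list[float]]:
    """Peak depolarisation per output class, spiking disabled.

    In rate mode each episode's peak is averaged over the given seeds so a
    single unlucky draw does not set the threshold.
    """
    peaks: dict[int, list[float]] = {0: [], 1: []}
    for row_idx, (pattern, output) in enumerate(config.table.rows):
        vals = []
        for seed in seeds:
            trains = _episode_trains(pattern, config, seed + 1000003 * row_idx)
            result = run_simulation(spec, trains, dt_ms=config.dt_ms, spiking=False)
            vals.append(result.peak_voltage_mv)
        peaks[output].append(float(np.mean(vals)))
    return peaks


def calibrate(spec: NeuronSpec, config: ProtocolConfig) -> CalibrationResult:
    """Find a drive scale and threshold separating the two output classes.

    With spiking disabled, measures each episode's peak subthreshold
    voltage, then places the threshold midway between the largest 0-class
    peak and the smallest 1-class peak.  The drive scale is multiplied by
    ten (starting from the spec's own value) until that midpoint exceeds
    the resting potential by at least 0.5 mV, so the calibrated neuron
    spikes robustly rather than at numerical noise level.  Deterministic
    in spike mode; rate mode uses a fixed block of seeds derived from the
    protocol seed.
    """
    outputs = {o for _, o in config.table.rows}
    if outputs != {0, 1}:
        return CalibrationResult(
            calibratable=False,
            reason="table must contain both output classes to define a boundary",
        )
    if config.mode == "spike":
        cal_seeds: Sequence[int] = (config.seed,)
    else:
        cal_seeds = tuple(config.seed + i for i in range(RATE_CALIBRATION_DRAWS))

    scale = spec.drive_scale
    v_rest = spec.membrane.v_rest_mv
    while scale <= MAX_DRIVE_SCALE:
        candidate = spec.with_drive_scale(scale)
        peaks = _subthreshold_peaks(candidate, config, cal_seeds)
        max0 = max(peaks[0])
        min1 = min(peaks[1])
        if min1 - max0 <= 0:
            return CalibrationResult(
                calibratable=False,
                drive_scale=scale,
                reason=(
                    "no gap between output classes: largest 0-class peak "
                    f"{max0:.6f} mV >= smallest 1-class peak {min1:.6f} mV"
                ),
            )
        midpoint = 0.5 * (max0 + min1)
        if midpoint >= v_rest + MIN_THRESHOLD_GAP_MV:
            return CalibrationResult(
                calibratable=True,
                drive_scale=scale,
                v_threshold_mv=midpoint,
                margin_mv=0.5 * (min1 - max0),
            )
        scale *= 10.0
    return CalibrationResult(
        calibratable=False,
        drive_scale=scale,
        reason="drive scale limit reached without a usable threshold gap",
    )


def run_protocol(
    spec: NeuronSpec,
    config: ProtocolConfig,
    calibration: CalibrationResult,
    seed: int | None = None,
) -> tuple[EpisodeReadout, ...]:
    """Run one calibrated episode per table row, in table-row order.

    Each episode starts from rest (independent simulations); the episode's
    Boolean output is 1 iff the soma fired at least once.
    """
    calibrated = calibration.apply(spec)
    base_seed = config.seed if seed is None else seed
    readouts = []
    for row_idx, (pattern, _) in enumerate(config.table.rows):
        trains = _episode_trains(pattern, config, base_seed + 1000003 * row_idx)
        result = run_simulation(calibrated, trains, dt_ms=config.dt_ms, spiking=True)
        readouts.append(
            EpisodeReadout(
                pattern=pattern,
                somatic_spike_count=result.n_somatic_spikes,
                peak_voltage_mv=result.peak_voltage_mv,
                episode_ms=config.episode_ms,
            )
        )
    return tuple(readouts)


def implements_table(spec: NeuronSpec, config: ProtocolConfig) -> ProtocolReport:
    """Decide whether the neuron realises the table under the protocol.

    Calibrates, then runs the episodes and compares each decided output
    with the table.  Spike mode is deterministic and uses a single run.
    Rate mode repeats the whole protocol over ``n_verdict_seeds``
    independent seeds and requires every repetition to match on every
    episode (a unanimity criterion — the claim under test is categorical);
    the agreement fraction across repetitions is reported either way.
    """
    expected = tuple(o for _, o in config.table.rows)
    calibration = calibrate(spec, config)
    if not calibration.calibratable:
        return ProtocolReport(
            readouts=(),
            expected=expected,
            implements=False,
            calibration=calibration,
            agreement_fraction=0.0,
            reason=calibration.reason,
        )
    if config.mode == "spike":
        readouts = run_protocol(spec, config, calibration)
        ok = tuple(r.output for r in readouts) == expected
        return ProtocolReport(
            readouts=readouts,
            expected=expected,
            implements=ok,
            calibration=calibration,
            agreement_fraction=1.0 if ok else 0.0,
            reason="" if ok else "episode outputs differ from the table",
        )
    n_ok = 0
    first: tuple[EpisodeReadout, ...] | None = None
    for rep in range(config.n_verdict_seeds):
        seed = config.seed + 7919 * (rep + 1)
        readouts = run_protocol(spec, config, calibration, seed=seed)
        if first is None:
            first = readouts
        if tuple(r.output for r in readouts) == expected:
            n_ok += 1
    frac = n_ok / config.n_verdict_seeds
    ok = n_ok == config.n_verdict_seeds
    return ProtocolReport(
        readouts=first or (),
        expected=expected,
        implements=ok,
        calibration=calibration,
        agreement_fraction=frac,
        reason="" if ok else f"only {n_ok}/{config.n_verdict_seeds} repetitions matched",
    )
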