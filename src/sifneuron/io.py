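"""Readers, writers and configuration for the package's text formats.

All formats are plain text.  Spike trains and truth tables are delimited
CSV with a mandatory header; simulation results, separability certificates
and protocol reports are JSON.  JSON floats are serialised with Python's
shortest round-trip repr, so write-then-read is bit-exact.  Configuration
is a single YAML document with unit-suffixed keys (``tau_ms``,
``g_max_ps``, ...) to keep units explicit in every file.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .core import (
    MembraneParams,
    NeuronSpec,
    SimResult,
    SpikeTrainSet,
    SynapseGroupParams,
    default_sif_spec,
    make_lif,
)
from .errors import TableParseError
from .protocol import ProtocolConfig, ProtocolReport
from .separability import (
    PairingCertificate,
    PartialBooleanTable,
    SeparabilityCertificate,
    make_cfbp,
)

TRAIN_HEADER = "source_id,time_ms"
TABLE_HEADER = "pattern,output"


# ---------------------------------------------------------------------------
# spike trains

def write_spike_trains(trains: SpikeTrainSet, path: str | Path) -> None:
    lines = [TRAIN_HEADER]
    for src in trains.sources():
        for t in trains.trains[src]:
            lines.append(f"{src},{float(t)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_spike_trains(path: str | Path, horizon_ms: float) -> SpikeTrainSet:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != TRAIN_HEADER:
        raise TableParseError(f"expected header {TRAIN_HEADER!r}", line=1)
    per_source: dict[int, list[float]] = {}
    for ln, raw in enumerate(lines[1:], start=2):
        raw = raw.strip()
        if not raw:
            continue
        parts = raw.split(",")
        if len(parts) != 2:
            raise TableParseError(f"expected 2 comma-separated fields, got {raw!r}", line=ln)
        try:
            src = int(parts[0])
            t = float(parts[1])
        except ValueError as exc:
            raise TableParseError(str(exc), line=ln) from None
        per_source.setdefault(src, []).append(t)
    return SpikeTrainSet(
        trains={s: np.sort(np.asarray(ts)) for s, ts in per_source.items()},
        horizon_ms=horizon_ms,
    )


# ---------------------------------------------------------------------------
# truth tables

def write_table(table: PartialBooleanTable, path: str | Path) -> None:
    lines = [TABLE_HEADER]
    for pattern, output in table.rows:
        lines.append(f"{''.join(map(str, pattern))},{output}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_table(path: str | Path) -> PartialBooleanTable:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != TABLE_HEADER:
        raise TableParseError(f"expected header {TABLE_HEADER!r}", line=1)
    rows: list[tuple[str, int]] = []
    n_bits: int | None = None
    for ln, raw in enumerate(lines[1:], start=2):
        raw = raw.strip()
        if not raw:
            continue
        parts = raw.split(",")
        if len(parts) != 2:
            raise TableParseError(f"expected 2 comma-separated fields, got {raw!r}", line=ln)
        pattern, out_s = parts[0].strip(), parts[1].strip()
        if not pattern or set(pattern) - {"0", "1"}:
            raise TableParseError(f"pattern must be a non-empty bit-string, got {pattern!r}", line=ln)
        if n_bits is None:
            n_bits = len(pattern)
        elif len(pattern) != n_bits:
            raise TableParseError(
                f"pattern length {len(pattern)} differs from first row ({n_bits})", line=ln
            )
        if out_s not in ("0", "1"):
            raise TableParseError(f"output must be 0 or 1, got {out_s!r}", line=ln)
        rows.append((pattern, int(out_s)))
    if not rows:
        raise TableParseError("table has no rows")
    try:
        return PartialBooleanTable.from_strings(rows)
    except Exception as exc:
        raise TableParseError(str(exc)) from None


# ---------------------------------------------------------------------------
# simulation results

def write_sim_result(result: SimResult, path: str | Path) -> None:
    payload = {
        "dt_ms": result.dt_ms,
        "voltage_mv": result.voltage_mv.tolist(),
        "conductances_ps": [g.tolist() for g in result.conductances_ps],
        "spike_times_ms": result.spike_times_ms.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_sim_result(path: str | Path) -> SimResult:
    payload = json.loads(Path(path).read_text())
    return SimResult(
        dt_ms=payload["dt_ms"],
        voltage_mv=np.asarray(payload["voltage_mv"]),
        conductances_ps=tuple(np.asarray(g) for g in payload["conductances_ps"]),
        spike_times_ms=np.asarray(payload["spike_times_ms"]),
    )


# ---------------------------------------------------------------------------
# certificates and reports

def certificate_payload(
    cert: SeparabilityCertificate,
    pairing: PairingCertificate | None = None,
) -> dict[str, Any]:
    payload: dict[str, Any] = {
        "separable": cert.separable,
        "method": cert.method,
        "weights": list(cert.weights) if cert.weights is not None else None,
        "theta": cert.theta,
        "pairing_certificate": None,
    }
    if pairing is not None:
        payload["pairing_certificate"] = {
            "zero_rows": ["".join(map(str, p)) for p in pairing.zero_rows],
            "one_rows": ["".join(map(str, p)) for p in pairing.one_rows],
        }
    return payload


def write_certificate(
    cert: SeparabilityCertificate,
    path: str | Path,
    pairing: PairingCertificate | None = None,
) -> None:
    Path(path).write_text(json.dumps(certificate_payload(cert, pairing), indent=2) + "\n")


def read_certificate(path: str | Path) -> SeparabilityCertificate:
    payload = json.loads(Path(path).read_text())
    return SeparabilityCertificate(
        separable=payload["separable"],
        method=payload["method"],
        weights=tuple(payload["weights"]) if payload["weights"] is not None else None,
        theta=payload["theta"],
    )


def report_payload(report: ProtocolReport) -> dict[str, Any]:
    cal = report.calibration
    return {
        "implements": report.implements,
        "reason": report.reason,
        "agreement_fraction": report.agreement_fraction,
        "calibration": {
            "calibratable": cal.calibratable,
            "drive_scale": cal.drive_scale,
            "v_threshold_mv": None if cal.v_threshold_mv != cal.v_threshold_mv else cal.v_threshold_mv,
            "margin_mv": None if cal.margin_mv != cal.margin_mv else cal.margin_mv,
            "reason": cal.reason,
        },
        "episodes": [
            {
                "pattern": "".join(map(str, r.pattern)),
                "somatic_spike_count": r.somatic_spike_count,
                "peak_voltage_mv": r.peak_voltage_mv,
                "mean_rate_hz": r.mean_rate_hz,
                "decided_output": r.output,
                "expected_output": e,
            }
            for r, e in zip(report.readouts, report.expected)
        ],
    }


def write_report(report: ProtocolReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report_payload(report), indent=2) + "\n")


# ---------------------------------------------------------------------------
# configuration

def spec_to_config(spec: NeuronSpec) -> dict[str, Any]:
    m = spec.membrane
    return {
        "membrane": {
            "tau_ms": m.tau_ms,
            "v_rest_mv": m.v_rest_mv,
            "r_mohm": m.r_mohm,
            "v_threshold_mv": m.v_threshold_mv,
            "v_reset_mv": m.v_reset_mv,
        },
        "groups": [
            {
                "e_s_mv": g.e_s_mv,
                "tau_s_ms": g.tau_s_ms,
                "g_max_ps": g.g_max_ps,
                "jump_mode": g.jump_mode,
            }
            for g in spec.groups
        ],
        "mapping": {int(k): int(v) for k, v in spec.mapping.items()},
        "drive_scale": spec.drive_scale,
    }


def spec_from_config(doc: dict[str, Any]) -> NeuronSpec:
    membrane = MembraneParams(**doc.get("membrane", {}))
    groups = tuple(SynapseGroupParams(**g) for g in doc.get("groups", [{}]))
    mapping = {int(k): int(v) for k, v in doc["mapping"].items()}
    return NeuronSpec(
        membrane=membrane,
        groups=groups,
        mapping=mapping,
        drive_scale=float(doc.get("drive_scale", 1.0)),
    )


def protocol_from_config(
    doc: dict[str, Any], base_dir: str | Path = "."
) -> ProtocolConfig:
    doc = dict(doc)
    table_field = doc.pop("table")
    if isinstance(table_field, str):
        table = read_table(Path(base_dir) / table_field)
    else:
        table = PartialBooleanTable.from_strings(
            [(str(p), int(o)) for p, o in table_field]
        )
    return ProtocolConfig(table=table, **doc)


def load_config(path: str | Path) -> dict[str, Any]:
    """Parse a YAML run configuration into live objects.

    Returns a dict with keys ``spec`` (NeuronSpec), ``dt_ms``,
    ``horizon_ms`` and, when a ``protocol`` section is present,
    ``protocol`` (ProtocolConfig, table resolved relative to the config
    file's directory).
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict) or "neuron" not in doc:
        raise TableParseError(f"config {path} must contain a 'neuron' section")
    out: dict[str, Any] = {"spec": spec_from_config(doc["neuron"])}
    sim = doc.get("simulation", {})
    out["dt_ms"] = float(sim.get("dt_ms", 0.1))
    out["horizon_ms"] = float(sim.get("horizon_ms", 500.0))
    if "protocol" in doc:
        out["protocol"] = protocol_from_config(doc["protocol"], base_dir=path.parent)
    return out


def write_config(
    spec: NeuronSpec,
    path: str | Path,
    dt_ms: float = 0.1,
    horizon_ms: float = 500.0,
    protocol: dict[str, Any] | None = None,
) -> None:
    doc: dict[str, Any] = {
        "neuron": spec_to_config(spec),
        "simulation": {"dt_ms": dt_ms, "horizon_ms": horizon_ms},
    }
    if protocol is not None:
        doc["protocol"] = protocol
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# run manifests

def write_manifest(
    path: str | Path,
    config_snapshot: dict[str, Any],
    seeds: list[int],
    outputs: list[str],
    elapsed_s: float,
    timestamped: bool = True,
) -> None:
    """Record everything needed to reproduce a run bit-identically.

    ``timestamped=False`` omits the wall-clock field so regenerated
    manifests are byte-identical (used for fixture sets).
    """
    payload = {
        "version": __version__,
        "created_utc": (
            datetime.datetime.now(datetime.timezone.utc).isoformat()
            if timestamped
            else None
        ),
        "config": config_snapshot,
        "seeds": seeds,
        "outputs": outputs,
        "elapsed_s": elapsed_s,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_manifest(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# fixtures

def generate_fixtures(out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write the standard fixture set used by tests and examples.

    Emits the four-input feature-binding table and its six-input family
    member, default SIF and LIF configs (protocol section included), one
    single-volley spike-train file per table pattern, and a rate-mode
    manifest recording the seed block.  Regeneration with the same seed is
    byte-identical (the written content is deterministic).
    """
    from .protocol import generate_single_spike_trains  # local to avoid cycle noise

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    cfbp = make_cfbp(2)
    write_table(cfbp, out / "cfbp_table.csv")
    written.append(out / "cfbp_table.csv")
    write_table(make_cfbp(3), out / "cfbp_m3_table.csv")
    written.append(out / "cfbp_m3_table.csv")

    sif = default_sif_spec()
    protocol_doc = {
        "table": "cfbp_table.csv",
        "mode": "spike",
        "active_rate_hz": 50.0,
        "episode_ms": 500.0,
        "t0_ms": 10.0,
        "seed": seed,
        "dt_ms": 0.1,
    }
    write_config(sif, out / "sif_config.yaml", protocol=protocol_doc)
    written.append(out / "sif_config.yaml")
    write_config(make_lif(sif), out / "lif_config.yaml", protocol=dict(protocol_doc))
    written.append(out / "lif_config.yaml")

    for pattern in cfbp.pattern_strings():
        trains = generate_single_spike_trains(
            [int(c) for c in pattern], t0_ms=10.0, duration_ms=500.0
        )
        p = out / f"pattern_{pattern}_spikes.csv"
        write_spike_trains(trains, p)
        written.append(p)

    write_manifest(
        out / "rate_mode_manifest.json",
        config_snapshot={
            "config": "sif_config.yaml",
            "mode": "rate",
            "table": "cfbp_table.csv",
        },
        seeds=[seed + 7919 * (i + 1) for i in range(20)],
        outputs=[],
        elapsed_s=0.0,
        timestamped=False,
    )
    written.append(out / "rate_mode_manifest.json")
    return written
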