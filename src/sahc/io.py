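"""Readers, writers and pipeline configuration.

Run data travel as a long CSV (``time_s, channel, value``) plus a JSON
sidecar holding the metadata (participant, position, foot g, phase
boundaries, events, termination flag).  Reports are delimited text and
JSON.  CSV dialect: comma-separated, UTF-8, '.' decimal, mandatory
header row, times in seconds as floats.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import SchemaError
from .records import Event, PhaseBoundaries, RunRecord
from .synthetic import RunTruth, TrialData

RUN_CSV_COLUMNS = ("time_s", "channel", "value")


def write_run_csv(run: RunRecord, path, sidecar_path) -> None:
    frames = [
        pd.DataFrame({"time_s": t, "channel": name, "value": v})
        for name, (t, v) in run.channels.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")
    meta = {
        "run_id": run.run_id,
        "participant": run.participant,
        "position": run.position,
        "g_foot": run.g_foot,
        "phases": run.phases.to_dict(),
        "events": [{"time": e.time, "label": e.label} for e in run.events],
        "terminated": run.terminated,
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_run_csv(path, sidecar_path) -> RunRecord:
    """Read a run CSV plus sidecar; rows are time-sorted per channel.

    Unknown channels are preserved.  Missing required columns raise a
    schema error naming the column.
    """
    try:
        table = pd.read_csv(path)
    except Exception as exc:  # malformed / truncated file
        raise SchemaError(f"cannot parse run CSV {path}: {exc}") from exc
    for col in RUN_CSV_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"run CSV {path} missing required column {col!r}")
    try:
        meta = json.loads(Path(sidecar_path).read_text())
    except Exception as exc:
        raise SchemaError(f"cannot parse sidecar {sidecar_path}: {exc}") from exc
    for key in ("run_id", "participant", "position", "g_foot", "phases"):
        if key not in meta:
            raise SchemaError(f"sidecar {sidecar_path} missing required key {key!r}")
    channels = {}
    for name, grp in table.groupby("channel", sort=False):
        grp = grp.sort_values("time_s")
        t = grp["time_s"].to_numpy(dtype=float)
        v = grp["value"].to_numpy(dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            t, idx = np.unique(t, return_index=True)
            v = v[idx]
        channels[str(name)] = (t, v)
    return RunRecord(
        run_id=str(meta["run_id"]),
        participant=str(meta["participant"]),
        position=str(meta["position"]),
        g_foot=float(meta["g_foot"]),
        channels=channels,
        phases=PhaseBoundaries.from_dict(meta["phases"]),
        events=[Event(float(e["time"]), str(e["label"])) for e in meta.get("events", [])],
        terminated=bool(meta.get("terminated", False)),
    )


def write_trial(trial: TrialData, out_dir) -> None:
    """Write run CSVs, metadata sidecars and the ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for run in trial.runs:
        write_run_csv(run, out / f"{run.run_id}.csv", out / f"{run.run_id}.json")
    truth = {
        "seed": trial.config.seed,
        "participants": [
            {"pid": p.pid, "stature": p.stature, "intercepts": p.intercepts}
            for p in trial.participants
        ],
        "runs": [dataclasses.asdict(t) for t in trial.truths],
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def write_epoch_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.6f")


def read_epoch_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    for col in ("run", "participant", "position", "g_foot", "channel", "epoch", "delta"):
        if col not in table.columns:
            raise SchemaError(f"epoch table {path} missing required column {col!r}")
    return table


def write_pss_table(results, path) -> None:
    pd.DataFrame(
        [
            {
                "run": r.run_id,
                "label": r.label,
                "criterion": r.criterion,
                "time": "" if r.trigger_time is None else r.trigger_time,
            }
            for r in results
        ]
    ).to_csv(path, index=False)


def read_pss_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    for col in ("run", "label", "criterion"):
        if col not in table.columns:
            raise SchemaError(f"PSS table {path} missing required column {col!r}")
    return table


def write_report(tables: dict[str, pd.DataFrame], out_dir, summary: dict | None = None) -> None:
    """Write named tables as TSV plus a JSON summary.

    Deterministic: byte-identical output for identical input.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        table.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")
    payload = {"tables": sorted(tables)}
    if summary:
        payload.update(summary)
    (out / "summary.json").write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclasses.dataclass
class PipelineConfig:
    """Flat pipeline configuration; round-trips losslessly through YAML."""

    seed: int = 0
    rate_hz: float = 4.0
    max_sd_multiple: float = 3.0
    min_drop_duration_s: float = 15.0
    n_participants: int = 15
    out_dir: str = "sahc_out"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
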