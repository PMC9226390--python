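"""File formats for study bundles: CSV for tabular artifacts, JSON for nested ones.

All CSVs are UTF-8, comma-separated with a header row and '.' decimals;
orders and indices are 1-based.  A bundle directory carries a manifest
recording the seed, the full simulation config and a hash of each file, so
re-running with the manifest seed reproduces every derived file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .design import CONDITION_BY_CODE, StimulusTimeline, TrialSequence
from .simulate import SimulationConfig, StudyBundle

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# sequences (JSON: full structure including gaps)


def sequences_to_json(sequences: list[TrialSequence]) -> str:
    payload = [
        {"id": s.id, "targets": list(s.targets), "gaps": [list(g) for g in s.gaps]}
        for s in sequences
    ]
    return json.dumps({"schema_version": SCHEMA_VERSION, "sequences": payload}, indent=1)


def sequences_from_json(text: str) -> list[TrialSequence]:
    data = json.loads(text)
    return [
        TrialSequence(
            id=s["id"],
            targets=tuple(s["targets"]),
            gaps=tuple(tuple(g) for g in s["gaps"]),
        )
        for s in data["sequences"]
    ]


# ---------------------------------------------------------------------------
# tabular artifacts

_SCHEMAS = {
    "schedule": ["participant", "order", "condition", "sequence_id"],
    "answers": ["participant", "order", "condition", "sequence_id", "answer"],
    "pretest": ["participant", "index", "modality", "object", "rt_ms", "correct"],
    "scores": ["participant", "order", "condition", "sequence_id",
               "per_digit", "levenshtein", "distraction"],
}


def validate_table(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    cols = _SCHEMAS[kind]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} table is missing columns {missing}")
    if "condition" in cols:
        bad = ~df["condition"].isin(CONDITION_BY_CODE)
        if bad.any():
            row = int(df.index[bad][0])
            raise SchemaError(
                f"{kind} table row {row}: unknown condition code "
                f"{df.loc[df.index[bad][0], 'condition']!r}"
            )
    if "modality" in cols:
        bad = ~df["modality"].isin(["Au", "Vi", "AV"])
        if bad.any():
            row = int(df.index[bad][0])
            raise SchemaError(f"{kind} table row {row}: unknown modality")
    return df


def write_table(df: pd.DataFrame, path: Path | str, kind: str | None = None) -> None:
    if kind:
        validate_table(df, kind)
    pd.DataFrame(df).to_csv(path, index=False)


def read_table(path: Path | str, kind: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "answer" in df.columns:
        df["answer"] = df["answer"].fillna("").astype(str).str.replace(
            r"\.0$", "", regex=True)
    if kind:
        validate_table(df, kind)
    return df


def timeline_to_frame(timeline: StimulusTimeline) -> pd.DataFrame:
    """Long-format event table for one trial timeline."""
    return pd.DataFrame(
        [
            {
                "order": timeline.slot.order,
                "condition": timeline.slot.condition.code,
                "sequence_id": timeline.slot.sequence_id,
                "onset_ms": e.onset_ms,
                "duration_ms": e.duration_ms,
                "kind": e.kind,
                "digit": e.digit if e.digit is not None else "",
                "has_tone": e.has_tone,
            }
            for e in timeline.events
        ]
    )


# ---------------------------------------------------------------------------
# configuration


def load_config(path: Path | str) -> SimulationConfig:
    """Read a simulation config from YAML or JSON."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    return SimulationConfig(**data)


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _config_hash(config: SimulationConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# bundle directory


def write_bundle(bundle: StudyBundle, out_dir: Path | str) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "sequences.json").write_text(sequences_to_json(bundle.sequences))
    write_table(bundle.schedule, out / "schedule.csv", "schedule")
    write_table(bundle.answers, out / "answers.csv", "answers")
    write_table(bundle.pretest, out / "pretest.csv", "pretest")
    write_table(bundle.covariates, out / "covariates.csv")
    files = ["sequences.json", "schedule.csv", "answers.csv", "pretest.csv",
             "covariates.csv"]
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "seed": bundle.seed,
        "config": dataclasses.asdict(bundle.config),
        "config_hash": _config_hash(bundle.config),
        "files": {f: _file_hash(out / f) for f in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_bundle(in_dir: Path | str) -> StudyBundle:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    config = SimulationConfig(**manifest["config"])
    if manifest.get("config_hash") != _config_hash(config):
        raise SchemaError("manifest config hash mismatch")
    return StudyBundle(
        config=config,
        sequences=sequences_from_json((src / "sequences.json").read_text()),
        schedule=read_table(src / "schedule.csv", "schedule"),
        answers=read_table(src / "answers.csv", "answers"),
        pretest=read_table(src / "pretest.csv", "pretest"),
        covariates=read_table(src / "covariates.csv"),
        profiles=[],
    )
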