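"""Cohort file I/O, run configuration and run manifests.

All interchange is plain text: the three cohort tables as CSV, the feature
schema and run configuration as YAML, manifests as JSON.  Every artefact a
command writes is listed in a manifest together with the hash of the
configuration that produced it, so downstream commands can refuse inputs
built under a different configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cohort import SimConfig
from .exceptions import ConfigurationError, ValidationError
from .pipeline import FeatureSchema

STATIC_FILE = "static.csv"
FOLLOWUP_FILE = "followups.csv"
EVENTS_FILE = "events.csv"
SCHEMA_FILE = "schema.yaml"
MODEL_FILE = "model.npz"
FLOAT_FORMAT = "%.12g"


def write_cohort(tables, directory, float_format: str = FLOAT_FORMAT):
    """Write the three cohort tables as CSV under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    static_table, followup_table, events_table = tables
    static_table.to_csv(directory / STATIC_FILE, index=False, float_format=float_format)
    followup_table.to_csv(directory / FOLLOWUP_FILE, index=False, float_format=float_format)
    events_table.to_csv(directory / EVENTS_FILE, index=False, float_format=float_format)
    return [directory / STATIC_FILE, directory / FOLLOWUP_FILE, directory / EVENTS_FILE]


def read_cohort(static_path, followup_path, events_path, schema: FeatureSchema | None = None):
    """Read and validate the three cohort tables.

    With a schema, unknown columns and non-coercible cells are reported in a
    :class:`ValidationError` listing the offending cells.  An empty
    follow-up table is always an error.
    """
    static = pd.read_csv(static_path)
    followups = pd.read_csv(followup_path)
    events = pd.read_csv(events_path)
    problems = []
    for name, df, required in (
        ("static", static, ["subject_id"]),
        ("followups", followups, ["subject_id", "t"]),
        ("events", events, ["subject_id", "event", "t_event"]),
    ):
        for col in required:
            if col not in df.columns:
                problems.append(f"{name}: missing required column '{col}'")
    if len(followups) == 0:
        raise ValidationError("no follow-ups: the follow-up table is empty")
    if schema is not None:
        known_static = {"subject_id", *schema.static_names}
        unknown = [c for c in static.columns if c not in known_static]
        if unknown:
            problems.append(f"static: unknown columns {unknown}")
        known_dyn = {"subject_id", "t", *schema.dynamic_names}
        unknown = [c for c in followups.columns if c not in known_dyn]
        if unknown:
            problems.append(f"followups: unknown columns {unknown}")
        for spec in schema:
            df, tname = (static, "static") if spec.role == "static" else (followups, "followups")
            if spec.name not in df.columns:
                problems.append(f"{tname}: missing schema column '{spec.name}'")
                continue
            if spec.numeric:
                vals = pd.to_numeric(df[spec.name], errors="coerce")
                bad = df[spec.name].notna() & vals.isna()
                for idx in df.index[bad][:20]:
                    problems.append(
                        f"{tname}[{idx}].{spec.name}: cannot coerce {df[spec.name].loc[idx]!r}"
                    )
    if problems:
        raise ValidationError("cohort validation failed:\n  " + "\n  ".join(problems))
    return static, followups, events


def read_cohort_dir(directory, schema: FeatureSchema | None = None):
    directory = Path(directory)
    if schema is None and (directory / SCHEMA_FILE).exists():
        schema = load_schema(directory / SCHEMA_FILE)
    tables = read_cohort(
        directory / STATIC_FILE, directory / FOLLOWUP_FILE, directory / EVENTS_FILE, schema
    )
    return tables, schema


def save_schema(schema: FeatureSchema, path):
    with open(path, "w") as fh:
        yaml.safe_dump({"features": schema.to_dicts()}, fh, sort_keys=False)


def load_schema(path) -> FeatureSchema:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "features" not in data:
        raise ValidationError(f"schema file {path} lacks a 'features' list")
    return FeatureSchema.from_dicts(data["features"])


@dataclass
class RunConfig:
    """One structured configuration for the whole pipeline.

    Seeds are explicit everywhere — no wall-clock seeding — so identical
    configurations yield identical outputs.
    """

    output_dir: str = "out"
    seed: int = 0
    simulate: dict = field(default_factory=dict)
    split: dict = field(default_factory=lambda: {"fraction": 0.75})
    embedding: dict = field(default_factory=dict)
    monitoring: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)

    _KNOWN = {"output_dir", "seed", "simulate", "split", "embedding", "monitoring", "evaluation"}

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("config", f"{path} is not a mapping")
        unknown = set(data) - cls._KNOWN
        if unknown:
            raise ConfigurationError(sorted(unknown)[0], "unknown configuration section")
        if "seed" not in data:
            raise ConfigurationError("seed", "an explicit seed is required")
        cfg = cls(**data)
        for section in ("simulate", "split", "embedding", "monitoring", "evaluation"):
            if not isinstance(getattr(cfg, section), dict):
                raise ConfigurationError(section, "must be a mapping")
        return cfg

    def sim_config(self) -> SimConfig:
        kwargs = dict(self.simulate)
        kwargs.setdefault("seed", self.seed)
        return SimConfig(**kwargs)

    def to_dict(self) -> dict:
        return {
            "output_dir": self.output_dir, "seed": self.seed, "simulate": self.simulate,
            "split": self.split, "embedding": self.embedding,
            "monitoring": self.monitoring, "evaluation": self.evaluation,
        }

    def hash(self) -> str:
        """Hash of the computational parameters (the output location is not one)."""
        payload = {k: v for k, v in self.to_dict().items() if k != "output_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(output_dir, command: str, config: RunConfig, inputs, outputs):
    """Machine-readable run record: config hash, seeds, versions, file hashes."""
    import numpy, pandas, scipy, sklearn

    from . import __version__

    manifest = {
        "command": command,
        "config_hash": config.hash(),
        "seed": config.seed,
        "versions": {
            "mklabour": __version__, "numpy": numpy.__version__, "scipy": scipy.__version__,
            "pandas": pandas.__version__, "scikit-learn": sklearn.__version__,
        },
        "inputs": {str(Path(p).name): file_sha256(p) for p in inputs},
        "outputs": {str(Path(p).name): file_sha256(p) for p in outputs},
    }
    path = Path(output_dir) / f"manifest_{command}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def check_manifest(output_dir, command: str, config: RunConfig):
    """Refuse downstream work if an upstream artefact was built under a
    different configuration."""
    path = Path(output_dir) / f"manifest_{command}.json"
    if not path.exists():
        raise ValidationError(f"missing upstream manifest: run '{command}' first")
    with open(path) as fh:
        manifest = json.load(fh)
    if manifest.get("config_hash") != config.hash():
        raise ValidationError(
            f"configuration hash mismatch with upstream '{command}' outputs; re-run the chain"
        )
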