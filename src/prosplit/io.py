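"""Tabular I/O, configuration files, and the registered-model bundle.

A registered model is the package's deposition artifact: a JSON bundle
holding everything needed to reproduce predictions on new data without
refitting (coefficients, intercept, chosen regularization, preprocessing
constants, class labels) together with the stopping decision that froze
it, a creation timestamp, and a SHA-256 checksum over the canonical
serialization of the payload.  The checksum lets a reviewer verify that
the model validated externally is byte-for-byte the model that was
deposited.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import Dataset
from .harness import AcquisitionSchedule
from .models import FittedModel, ModelSpec
from .stopping import RuleParams, StopDecision

__all__ = [
    "read_table",
    "write_table",
    "RegisteredModelBundle",
    "freeze_model",
    "load_bundle",
    "verify_bundle",
    "load_config",
]

FORMAT_VERSION = 1


def read_table(
    path: str | Path,
    target_column: str,
    delimiter: str = ",",
    task: str | None = None,
) -> Dataset:
    """Load a delimited text table into a :class:`Dataset`.

    All feature columns are parsed as numeric; a target with exactly two
    distinct values is treated as classification unless ``task`` overrides
    the detection.
    """
    df = pd.read_csv(path, delimiter=delimiter, float_precision="round_trip")
    if target_column not in df.columns:
        raise ValueError("target not found")
    if df.isna().any().any():
        raise ValueError("missing data not supported")
    y = df[target_column].to_numpy(dtype=float)
    X = df.drop(columns=[target_column]).to_numpy(dtype=float)
    if task is None:
        task = "classification" if np.unique(y).size == 2 else "regression"
    names = tuple(c for c in df.columns if c != target_column)
    return Dataset(X, y, task, feature_names=names)


def write_table(dataset: Dataset, path: str | Path, delimiter: str = ",",
                target_column: str = "target") -> None:
    """Write a dataset as a delimited text table with a header row."""
    names = dataset.feature_names or tuple(
        f"f{i + 1}" for i in range(dataset.p)
    )
    df = pd.DataFrame(dataset.features, columns=list(names))
    df[target_column] = dataset.target
    # %.17g keeps the round-trip through text lossless for float64
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# registered-model bundle


def _canonical_json(payload: dict) -> str:
    return json.dumps(payload, sort_keys=True, separators=(",", ":"))


def _checksum(payload: dict) -> str:
    return hashlib.sha256(_canonical_json(payload).encode()).hexdigest()


@dataclass(frozen=True)
class RegisteredModelBundle:
    """A frozen model plus provenance, protected by a content checksum."""

    payload: dict
    checksum: str

    def verify(self) -> bool:
        return _checksum(self.payload) == self.checksum

    def to_model(self) -> FittedModel:
        m = self.payload["model"]
        classes = m["classes"]
        return FittedModel(
            coefficients=np.asarray(m["coefficients"], dtype=float),
            intercept=float(m["intercept"]),
            chosen_regularization=float(m["chosen_regularization"]),
            center=np.asarray(m["center"], dtype=float),
            scale=np.asarray(m["scale"], dtype=float),
            task=m["task"],
            n_train=int(m["n_train"]),
            classes=None if classes is None else np.asarray(classes, dtype=float),
        )


def freeze_model(
    model: FittedModel,
    decision: StopDecision | None,
    path: str | Path,
    scorer_id: str | None = None,
) -> RegisteredModelBundle:
    """Serialize a finalized model (and the stopping decision that froze
    it) to a checksummed JSON bundle on disk."""
    payload = {
        "format_version": FORMAT_VERSION,
        "created": datetime.now(timezone.utc).isoformat(),
        "scorer_id": scorer_id,
        "model": {
            "coefficients": [float(c) for c in model.coefficients],
            "intercept": float(model.intercept),
            "chosen_regularization": float(model.chosen_regularization),
            "center": [float(c) for c in model.center],
            "scale": [float(s) for s in model.scale],
            "task": model.task,
            "n_train": int(model.n_train),
            "classes": None
            if model.classes is None
            else [float(c) for c in model.classes],
        },
        "stopping_decision": None if decision is None else decision.to_dict(),
    }
    bundle = RegisteredModelBundle(payload=payload, checksum=_checksum(payload))
    Path(path).write_text(
        json.dumps({"payload": payload, "checksum": bundle.checksum}, indent=2)
    )
    return bundle


def load_bundle(path: str | Path) -> RegisteredModelBundle:
    raw = json.loads(Path(path).read_text())
    return RegisteredModelBundle(payload=raw["payload"], checksum=raw["checksum"])


def verify_bundle(path: str | Path) -> bool:
    """Recompute the checksum of a stored bundle; False signals tampering
    or corruption."""
    return load_bundle(path).verify()


# ---------------------------------------------------------------------------
# configuration


def load_config(path: str | Path) -> dict:
    """Read a flat key-value YAML config and split it into RuleParams,
    ModelSpec and AcquisitionSchedule keyword groups."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat key-value mapping")
    groups = {"params": {}, "spec": {}, "schedule": {}}
    fields = {
        "params": set(RuleParams.__dataclass_fields__),
        # task comes from the data (or the --task flag), never the config
        "spec": set(ModelSpec.__dataclass_fields__) - {"task"},
        "schedule": set(AcquisitionSchedule.__dataclass_fields__),
    }
    for key, value in raw.items():
        for group, names in fields.items():
            if key in names:
                if key == "regularization_grid":
                    value = tuple(value)
                groups[group][key] = value
                break
        else:
            raise ValueError(f"unknown config key {key!r}")
    return groups
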