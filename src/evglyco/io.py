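"""CSV / JSON / YAML input-output and model serialization.

One tabular dialect everywhere: UTF-8 comma-separated text with a header
row. Signature models round-trip through JSON (weights, scaling, priors,
thresholds, version tag); simulation configs load from YAML.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .signature import (LECTINS, DiscriminantModel, ScalingParams,
                        SignatureModel)

__all__ = [
    "read_lectin_table",
    "write_table",
    "save_model",
    "load_model",
    "load_sim_config",
    "file_sha256",
    "SchemaError",
]

MODEL_FORMAT_VERSION = "1"

log = logging.getLogger("evglyco")


class SchemaError(ValueError):
    pass


def read_lectin_table(path, required=("sample_id",) + LECTINS) -> pd.DataFrame:
    """Read a lectin intensity table, validating the documented schema.

    Required columns: ``sample_id`` and the lectin intensities (ConA, WGA,
    RCA_I); any extra columns (group, patient_id, timepoint, response,
    time, event, ca15_3, ki67_high, age, ...) are preserved verbatim.
    Violations are reported with row numbers.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file, expected a CSV header")
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    for col in LECTINS:
        if col not in table.columns:
            continue
        numeric = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[numeric.isna() & table[col].notna()].tolist()
        if bad:
            rows = ", ".join(str(b + 2) for b in bad[:5])  # +2: header + 1-based
            raise SchemaError(f"{path}: non-numeric {col} at file row(s) {rows}")
        if (numeric.dropna() < 0).any():
            bad = table.index[numeric < 0].tolist()
            raise SchemaError(
                f"{path}: negative {col} intensity at file row "
                f"{bad[0] + 2}")
        table[col] = numeric
    return table


def write_table(table: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def _scaling_to_dict(s: ScalingParams | None):
    if s is None:
        return None
    return {"minima": s.minima, "maxima": s.maxima}


def _lda_to_dict(m: DiscriminantModel):
    return {
        "classes": list(m.classes),
        "means": m.means.tolist(),
        "pooled_cov": m.pooled_cov.tolist(),
        "weights": m.weights.tolist(),
        "priors": m.priors.tolist(),
        "threshold": m.threshold,
    }


def _lda_from_dict(d) -> DiscriminantModel:
    return DiscriminantModel(
        classes=tuple(d["classes"]),
        means=np.array(d["means"]),
        pooled_cov=np.array(d["pooled_cov"]),
        weights=np.array(d["weights"]),
        priors=np.array(d["priors"]),
        threshold=float(d["threshold"]),
    )


def save_model(model: SignatureModel, path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "kind": model.kind,
        "lectins": list(model.lectins),
        "baseline_normalized": model.baseline_normalized,
        "scaling": _scaling_to_dict(model.scaling),
        "models": {name: _lda_to_dict(m) for name, m in model.models.items()},
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path) -> SignatureModel:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise ValueError(f"{path}: not a valid model file ({err})") from err
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: model format version {version!r} unsupported "
            f"(expected {MODEL_FORMAT_VERSION!r})")
    scaling = payload["scaling"]
    return SignatureModel(
        kind=payload["kind"],
        scaling=None if scaling is None else ScalingParams(**scaling),
        baseline_normalized=payload["baseline_normalized"],
        models={k: _lda_from_dict(v) for k, v in payload["models"].items()},
        lectins=tuple(payload["lectins"]),
    )


def load_sim_config(path):
    """Build (geometry, laser, numerics dict) from a YAML config with
    optional ``geometry``, ``laser`` and ``numerics`` blocks; absent keys
    keep the documented defaults."""
    import yaml

    from .thermosim import ChamberGeometry, LaserSource

    raw = yaml.safe_load(Path(path).read_text()) or {}
    geom = ChamberGeometry(**raw.get("geometry", {}))
    laser = LaserSource(**raw.get("laser", {}))
    numerics = {"duration": 600.0, "ambient": 298.15, "gravity": 9.81,
                "record_every": 5.0}
    numerics.update(raw.get("numerics", {}))
    return geom, laser, numerics


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
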