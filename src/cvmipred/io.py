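"""CSV/JSON serialization and run provenance.

Data CSVs carry one header row; missing cells are the empty string, ``NA``
or ``NaN`` on read and the empty string on write.  Floats are written with 17
significant digits so write/read round trips are bit-exact.  Every CLI run
emits a manifest (config echo, package version, seed, timestamps, output
digests) sufficient to reproduce the outputs bit-identically.
"""
from __future__ import annotations

import datetime
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = [
    "NA_TOKENS",
    "read_cohort",
    "write_cohort",
    "write_predictions",
    "read_predictions",
    "write_summary",
    "write_manifest",
]

NA_TOKENS = ["", "NA", "NaN"]
FLOAT_FORMAT = "%.17g"


def read_cohort(path, outcome, column_spec=None) -> Cohort:
    """Parse a cohort CSV.

    The outcome column must be present, fully observed and binary.  An
    optional ``row_id`` column becomes the row index (duplicates rejected).
    """
    df = pd.read_csv(path, keep_default_na=False, na_values=NA_TOKENS,
                     float_precision="round_trip")
    if "row_id" in df.columns and outcome != "row_id":
        if df["row_id"].duplicated().any():
            raise ValueError("duplicate row_id values in input")
        df = df.set_index("row_id")
    if outcome not in df.columns:
        raise ValueError(f"outcome column {outcome!r} not present in {path}")
    if df[outcome].isna().any():
        raise ValueError(
            "outcome column contains missing values; calibration data must "
            "have a fully observed outcome"
        )
    return Cohort(df, outcome, column_spec=column_spec)


def write_cohort(cohort: Cohort, path) -> None:
    frame = cohort.to_frame()
    frame.index.name = "row_id"
    frame.to_csv(path, float_format=FLOAT_FORMAT, na_rep="")


def write_predictions(prediction_matrices, path, include_imputations=False) -> None:
    """Write replicate prediction sets as a long CSV: one row per
    (subject, replicate) with record status and the pooled prediction."""
    pms = list(prediction_matrices)
    if not pms:
        warnings.warn("no predictions to write; emitting header only", UserWarning)
        cols = ["row_id", "record_status", "approach", "n_imputations",
                "replicate", "pooled_prediction"]
        pd.DataFrame(columns=cols).to_csv(path, index=False)
        return
    frames = []
    for r, pm in enumerate(pms, start=1):
        frame = pd.DataFrame({
            "row_id": np.asarray(pm.row_id),
            "record_status": np.where(
                pm.fully_observed, "fully_observed", "partially_observed"
            ),
            "approach": pm.approach,
            "n_imputations": pm.n_imputations,
            "replicate": r,
            "pooled_prediction": pm.pooled,
        })
        if include_imputations:
            for k in range(pm.matrix.shape[1]):
                frame[f"prediction_k{k + 1}"] = pm.matrix[:, k]
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"row_id", "record_status", "replicate", "pooled_prediction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"predictions file lacks columns {sorted(missing)}")
    return df


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="records"))
    return obj


def write_summary(summary_frame: pd.DataFrame, csv_path, json_path=None) -> None:
    """Emit a summary table as CSV and JSON (unavailable values stay null)."""
    summary_frame.to_csv(csv_path, index=False, float_format=FLOAT_FORMAT)
    if json_path is None:
        json_path = Path(csv_path).with_suffix(".json")
    payload = _jsonify(summary_frame)
    Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: dict, seed, outputs) -> dict:
    from . import __version__

    manifest = {
        "package": "cvmipred",
        "version": __version__,
        "seed": seed,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": _jsonify(config),
        "outputs": {
            str(p): _sha256(p) for p in outputs if Path(p).exists()
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
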