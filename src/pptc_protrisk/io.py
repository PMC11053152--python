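"""Plain-text readers and writers for the pipeline's tables.

Abundance matrices are tab-separated (rows = proteins, columns = samples)
with ``NA`` for missing entries; sample metadata is TSV; clinical tables are
CSV; ground-truth and report objects are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, validate_clinical
from .synthetic import SyntheticTruth


def write_matrix(matrix: AbundanceMatrix, matrix_path, meta_path) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", na_rep="NA")
    meta = matrix.meta.copy()
    meta["scale"] = matrix.scale
    meta["history"] = ";".join(matrix.history)
    meta.to_csv(meta_path, sep="\t", na_rep="NA")


def read_matrix(matrix_path, meta_path) -> AbundanceMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0, na_values=["NA"])
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, na_values=["NA"])
    scale = meta["scale"].iloc[0] if "scale" in meta.columns else "log2"
    history = []
    if "history" in meta.columns and isinstance(meta["history"].iloc[0], str):
        history = [h for h in meta["history"].iloc[0].split(";") if h]
    meta = meta.drop(columns=[c for c in ("scale", "history") if c in meta.columns])
    if "replicate_of" in meta.columns:
        meta["replicate_of"] = meta["replicate_of"].where(meta["replicate_of"].notna(), None)
    return AbundanceMatrix(values, meta, scale=scale, history=history)


def write_clinical(table: pd.DataFrame, path) -> None:
    table.to_csv(path)


def read_clinical(path) -> pd.DataFrame:
    table = pd.read_csv(path, index_col=0)
    return validate_clinical(table)


class _JSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_JSONEncoder) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_truth(truth: SyntheticTruth, path) -> None:
    payload = {
        "dep_effects": truth.dep_effects,
        "signal_coefs": truth.signal_coefs,
        "baseline_hazard_used": truth.baseline_hazard_used,
        "achieved_event_fraction": truth.achieved_event_fraction,
        "linear_predictors": truth.linear_predictors.to_dict(),
        "n_masked_entries": int(len(truth.masked_entries)),
        "seed": truth.seed,
    }
    write_json(payload, path)
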