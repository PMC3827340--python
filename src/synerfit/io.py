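"""CSV/JSON exchange: design tables, response tables, models and results.

CSV is the sole tabular format (UTF-8, dot decimal); models and optimization
results are serialized to JSON with the seed and a config hash embedded so
reruns are traceable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignTable
from .larspls import LarsPlsModel

__all__ = [
    "read_design_csv",
    "read_response_csv",
    "write_results",
    "model_to_dict",
    "config_hash",
]


def _read_numeric_csv(path, required_numeric=True) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return df


def read_design_csv(path) -> DesignTable:
    """Read a design table: header ``run,<comp1>,...,total`` with optional
    ``label`` and ``level_``-prefixed columns; doses in mg/kg."""
    df = _read_numeric_csv(path)
    cols = list(df.columns)
    if "run" not in cols or "total" not in cols:
        raise ValueError(f"{path}: design header must contain 'run' and 'total'")
    components = [
        c for c in cols
        if c not in ("run", "total", "label") and not c.startswith("level_")
    ]
    if not components:
        raise ValueError(f"{path}: no component dose columns found")
    for c in components + ["total"]:
        bad = pd.to_numeric(df[c], errors="coerce").isna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ValueError(f"{path}: non-numeric cell at row {row + 2}, column {c!r}")
        df[c] = df[c].astype(float)
    return DesignTable(components=components, table=df)


def read_response_csv(path, group_col: str = "group") -> pd.DataFrame:
    """Read an animal- or run-level response table; all non-group columns
    must be numeric endpoints."""
    df = _read_numeric_csv(path)
    endpoint_cols = [c for c in df.columns if c != group_col]
    if not endpoint_cols:
        raise ValueError(f"{path}: no endpoint columns found")
    for c in endpoint_cols:
        if df[c].dtype == object:
            bad = pd.to_numeric(df[c], errors="coerce").isna()
            if bad.any():
                row = int(np.argmax(bad.to_numpy()))
                raise ValueError(
                    f"{path}: non-numeric cell at row {row + 2}, column {c!r}"
                )
            df[c] = df[c].astype(float)
    return df


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def write_results(obj: dict, path, seed: int | None = None, config: dict | None = None):
    """Write a result dict as JSON, embedding the seed and a hash of the
    effective config."""
    out = dict(obj)
    if seed is not None:
        out.setdefault("seed", seed)
    if config is not None:
        out["config_hash"] = config_hash(config)
        out["config"] = config
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(out, indent=2, cls=_NumpyEncoder) + "\n")
    return path


def model_to_dict(model: LarsPlsModel) -> dict:
    """JSON-serializable summary of a fitted LARS-PLS model (term names,
    original-scale coefficients, standardization params, ncomp)."""
    return {
        "components": model.component_names,
        "responses": model.response_names,
        "mode": model.mode,
        "ncomp": model.pls.ncomp,
        "selected_terms": model.term_names,
        "lars_entry_order": (
            [model.expansion.term_names[k] for k in model.lars_path.entry_order]
            if model.lars_path is not None else None
        ),
        "x_mean": model.x_std.column_means.tolist(),
        "x_sd": model.x_std.column_sds.tolist(),
        "original_intercept": model.original_intercept.tolist(),
        "original_coefficients": {
            name: model.original_coefficients[i].tolist()
            for i, name in enumerate(model.expansion.term_names)
        },
        "explained_y_variance": model.pls.explained_y_variance.tolist(),
    }
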