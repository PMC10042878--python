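"""Shared I/O: society CSV, Newick trees, matrix CSV, fit JSON, YAML config.

All raw ethnographic code columns are read as strings so empty cells stay
distinguishable from zeros; round-tripping a table through write/read is
the identity on canonical form.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from .dependence import LabelledCovariance

__all__ = [
    "read_society_csv",
    "write_society_csv",
    "read_newick",
    "write_newick",
    "read_matrix_csv",
    "write_matrix_csv",
    "write_fit_json",
    "load_pipeline_config",
    "file_sha256",
]

_REQUIRED_COLUMNS = ("society_id", "tip_label", "latitude", "longitude")

#: Recognised top-level pipeline configuration keys.
_CONFIG_KEYS = {
    "data_csv", "tree_newick", "output_dir", "dimensions",
    "pca_runs", "seed", "matern", "metric", "covariance_scaling",
    "priors", "mcmc", "responses", "predictors",
}


def read_society_csv(path) -> pd.DataFrame:
    """Read a raw society table; code columns stay as strings, NA = empty."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df["society_id"].duplicated().any():
        dups = df.loc[df["society_id"].duplicated(), "society_id"].tolist()
        raise ValueError(f"{path}: duplicate society ids {dups}")
    for col in ("latitude", "longitude"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if (df["latitude"].abs() > 90).any() or (df["longitude"].abs() > 180).any():
        raise ValueError(f"{path}: coordinates out of range")
    for col in ("paragraph_count", "temperature"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col].replace("", np.nan), errors="raise")
    for col in df.columns:
        if col.startswith("dep_"):
            df[col] = pd.to_numeric(df[col].replace("", np.nan), errors="raise")
    return df


def write_society_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, encoding="utf-8")


def read_newick(path) -> dendropy.Tree:
    """Read a rooted Newick tree, branch lengths at full precision."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=False,
    )
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


def write_matrix_csv(cov: LabelledCovariance, path) -> None:
    cov.to_dataframe().to_csv(path, float_format="%.17g")


def read_matrix_csv(path, kind: str = "unknown") -> LabelledCovariance:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    return LabelledCovariance(labels=[str(l) for l in df.index],
                              matrix=df.to_numpy(float), kind=kind)


def write_fit_json(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def load_pipeline_config(path) -> dict:
    """Load and validate a YAML pipeline config; unknown keys are rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("data_csv", "tree_newick"):
        if key not in cfg:
            raise ValueError(f"{path}: config requires {key!r}")
    return cfg


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
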