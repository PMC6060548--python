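"""Feature-table readers/writers and pipeline configuration files.

Two CSV dialects are supported.  The *wide* dialect has one row per sample:
metadata columns (``sample_id``, optionally ``subject_id``, ``run_id``,
``spot_id``, ``group``, ``creatinine``) followed by one column per feature,
headed by its m/z value.  The *long* dialect has one row per (sample,
feature) cell with ``mz``, ``intensity`` and ``below_lod`` columns and
preserves censoring flags exactly; wide files omit flags, which therefore
default to False on reading.  Comment lines starting with ``#`` record the
normalization state and the generating seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .feature_table import META_COLUMNS, FeatureTable, FeatureTableError

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "load_config",
    "save_config",
]


def write_feature_table(table: FeatureTable, path, dialect: str = "wide",
                        seed=None) -> None:
    path = Path(path)
    header = [f"# state: {table.state}"]
    if seed is not None:
        header.append(f"# seed: {seed}")
    if dialect == "wide":
        frame = table.to_frame()
    elif dialect == "long":
        frame = table.to_long()
    else:
        raise FeatureTableError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        frame.to_csv(fh, index=False)


def _parse_header(path):
    state, seed, skip = "raw", None, 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if body.startswith("state:"):
                state = body.split(":", 1)[1].strip()
            elif body.startswith("seed:"):
                seed = int(body.split(":", 1)[1].strip())
    return state, seed, skip


def read_feature_table(path, dialect: str = "wide") -> FeatureTable:
    """Read a CSV/TSV feature table; see the module docstring for dialects.

    Malformed input (ragged rows, duplicate sample IDs, non-numeric m/z
    headers) raises :class:`FeatureTableError` naming the offending line or
    column.
    """
    path = Path(path)
    state, seed, skip = _parse_header(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, skiprows=skip, sep=sep)
    except pd.errors.ParserError as exc:
        raise FeatureTableError(f"malformed CSV in {path.name}: {exc}") from exc
    if dialect == "long":
        required = {"sample_id", "mz", "intensity"}
        missing = required - set(df.columns)
        if missing:
            raise FeatureTableError(f"long table missing columns: {sorted(missing)}")
        meta_cols = [c for c in df.columns
                     if c not in {"mz", "intensity", "below_lod"}]
        meta = df[meta_cols].drop_duplicates("sample_id").reset_index(drop=True)
        mz = np.sort(df["mz"].unique())
        wide = df.pivot(index="sample_id", columns="mz", values="intensity")
        wide = wide.reindex(index=meta["sample_id"], columns=mz)
        if "below_lod" in df.columns:
            flags = df.pivot(index="sample_id", columns="mz", values="below_lod")
            flags = flags.reindex(index=meta["sample_id"], columns=mz)
            flags = flags.fillna(False).astype(bool).to_numpy()
        else:
            flags = None
        return FeatureTable(wide.to_numpy(dtype=float), mz, meta,
                            below_lod=flags, state=state)
    if dialect != "wide":
        raise FeatureTableError(f"unknown dialect {dialect!r}")
    if "sample_id" not in df.columns:
        raise FeatureTableError("wide table must start with a sample_id column")
    meta_cols, mz_cols = [], []
    for col in df.columns:
        if col in META_COLUMNS:
            meta_cols.append(col)
            continue
        try:
            mz_cols.append((float(col), col))
        except ValueError:
            raise FeatureTableError(
                f"column header {col!r} is neither metadata nor a numeric m/z"
            ) from None
    mz_cols.sort()
    mz = np.array([m for m, _ in mz_cols])
    values = df[[c for _, c in mz_cols]].to_numpy(dtype=float)
    return FeatureTable(values, mz, df[meta_cols], state=state)


def load_config(path) -> dict:
    """Load a YAML or JSON pipeline configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(config: dict, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(config, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=True))
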