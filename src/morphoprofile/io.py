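"""Reading and writing CalMorph-style delimited tables.

Tables are plain TSV/CSV with one row per (strain, replicate) experiment:
mandatory columns ``strain``, ``replicate``, ``n_cells``, then one column per
morphological parameter and one per trials source.  The delimiter is
auto-detected between tab and comma; values are written with 6 significant
digits.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import MorphDataset, ValidationError
from .meta import MetaTable

log = logging.getLogger(__name__)

MANDATORY = ("strain", "replicate", "n_cells")


class FormatError(ValueError):
    """Structurally invalid input table."""


def _sniff_delimiter(path) -> str:
    with open(path, "r") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_meta_table(path) -> MetaTable:
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str,
                     keep_default_na=False)
    if "unimodal" in df.columns:
        df["unimodal"] = df["unimodal"].replace("", "1")
    return MetaTable.from_frame(df)


def write_meta_table(meta: MetaTable, path, sep="\t"):
    meta.to_frame().to_csv(path, sep=sep, index=False)


def read_morph_table(path, meta: MetaTable, wt_strain_id: str = "WT") -> MorphDataset:
    """Read a replicate-level morphological table and validate it.

    Unparseable numeric cells become missing values (a warning reports how
    many); missing mandatory columns raise :class:`FormatError`; duplicated
    (strain, replicate) keys raise :class:`ValidationError`.
    """
    sep = _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY if c not in raw.columns]
    if missing:
        raise FormatError(f"table missing mandatory columns: {missing}")

    param_cols = [c for c in raw.columns if c in meta]
    trial_cols = [c for c in meta.trials_columns() if c in raw.columns]
    needed_trials = {meta[p].trials_column for p in param_cols
                     if meta[p].data_type == "proportion"}
    lost = sorted(t for t in needed_trials if t not in raw.columns)
    if lost:
        raise FormatError(f"table missing trials columns: {lost}")

    idx = pd.MultiIndex.from_arrays(
        [raw["strain"].astype(str), raw["replicate"].astype(str)],
        names=("strain", "replicate"))
    if idx.duplicated().any():
        dup = idx[idx.duplicated()][0]
        raise ValidationError(f"duplicate (strain, replicate) key: {dup}")

    numeric = raw[["n_cells", *param_cols, *trial_cols]].apply(
        pd.to_numeric, errors="coerce")
    blank = (raw[["n_cells", *param_cols, *trial_cols]] == "").to_numpy().sum()
    n_bad = int(numeric.isna().to_numpy().sum()) - int(blank)
    if n_bad > 0:
        log.warning("read_morph_table: %d unparseable cells set to missing", n_bad)

    values = numeric[param_cols].set_axis(idx)
    trials = numeric[trial_cols].set_axis(idx)
    cell_count = numeric["n_cells"].set_axis(idx)
    ds = MorphDataset(values=values, cell_count=cell_count, meta=meta,
                      wt_strain_id=wt_strain_id, trials=trials)
    return ds.validate()


def write_morph_table(ds: MorphDataset, path, sep="\t"):
    """Write a dataset back to delimited text (6 significant digits)."""
    out = pd.DataFrame(index=ds.values.index)
    out["n_cells"] = ds.cell_count.astype("Int64")
    for c in ds.values.columns:
        if c in ds.meta and ds.meta[c].data_type == "proportion":
            out[c] = ds.values[c].round().astype("Int64")
        else:
            out[c] = ds.values[c].map(
                lambda v: "" if pd.isna(v) else f"{v:.6g}")
    for c in ds.trials.columns:
        out[c] = ds.trials[c].round().astype("Int64")
    out.reset_index().to_csv(path, sep=sep, index=False)
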