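"""Reading and writing the tabular formats the pipeline consumes.

All inputs are plain CSV/TSV: a specimen-level isotope table, a zOTU
count table (samples in rows or columns, auto-detected from the
header), a taxonomy map and a sample-metadata table.  Validation
errors name the offending rows.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .isotopes import ISOTOPE_COLUMNS

__all__ = [
    "read_isotope_table",
    "read_count_table",
    "read_taxonomy",
    "read_sample_meta",
]

_FLAGS = ("is_spike_in", "is_anaplasmataceae", "is_weissella_target")


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_isotope_table(path) -> pd.DataFrame:
    """Load and validate a specimen-level isotope CSV/TSV."""
    df = pd.read_csv(path, sep=_sep(path), dtype={"nest_id": str})
    missing = [c for c in ISOTOPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["nest_id"] = df["nest_id"].fillna("")
    vals = df[["d13C", "d15N"]].apply(pd.to_numeric, errors="coerce").to_numpy()
    bad = np.flatnonzero(~np.isfinite(vals).all(axis=1))
    if bad.size:
        rows = (bad + 2).tolist()  # 1-based file rows incl. header
        raise ValueError(f"{path}: non-numeric isotope values at file rows {rows[:10]}")
    df[["d13C", "d15N"]] = vals
    return df


def read_count_table(path) -> pd.DataFrame:
    """Load a zOTU count table; rows are samples after auto-orientation.

    If the first header field names the zOTU axis (``zotu``/``otu_id``/
    ``#OTU ID`` in any case), the file is taken as zOTUs × samples and
    transposed.
    """
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    first = str(df.index.name or "").strip().lstrip("#").lower().replace(" ", "_")
    if first in ("zotu", "zotu_id", "otu", "otu_id"):
        df = df.T
    df.index.name = "sample_id"
    try:
        out = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric count entries ({exc})") from exc
    if np.any(out.to_numpy() < 0):
        raise ValueError(f"{path}: negative counts")
    if not np.allclose(out.to_numpy(), np.round(out.to_numpy())):
        raise ValueError(f"{path}: counts must be integers")
    return out.round().astype(int)


def read_taxonomy(path) -> pd.DataFrame:
    """Load a zOTU taxonomy map (zotu, order, family, genus, flags)."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    df.index.name = "zotu"
    for col in ("order", "family", "genus"):
        if col not in df.columns:
            df[col] = "unassigned"
        df[col] = df[col].fillna("unassigned")
    for col in _FLAGS:
        if col not in df.columns:
            df[col] = False
        df[col] = (
            df[col].astype(str).str.strip().str.lower().isin(("true", "1", "yes"))
        )
    conflict = df["is_spike_in"] & (df["is_anaplasmataceae"] | df["is_weissella_target"])
    if conflict.any():
        raise ValueError(
            f"{path}: spike-in zOTUs cannot carry bacterial flags: "
            f"{list(df.index[conflict])[:5]}"
        )
    return df


def read_sample_meta(path) -> pd.DataFrame:
    """Load per-sample metadata (role, taxon_group, lifestyle, nest, ng)."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0, dtype={"nest_id": str})
    df.index.name = "sample_id"
    if "role" not in df.columns:
        raise ValueError(f"{path}: metadata needs a 'role' column")
    bad_role = ~df["role"].isin(("experimental", "blank", "control"))
    if bad_role.any():
        raise ValueError(
            f"{path}: unknown role for samples {list(df.index[bad_role])[:5]}"
        )
    for col, default in (
        ("taxon_group", "n/a"),
        ("species", ""),
        ("lifestyle", ""),
        ("nest_id", ""),
    ):
        if col not in df.columns:
            df[col] = default
        df[col] = df[col].fillna(default)
    if "template_ng" not in df.columns:
        df["template_ng"] = np.nan
    df["template_ng"] = pd.to_numeric(df["template_ng"], errors="coerce")
    exp = df["role"] == "experimental"
    bad = exp & ~(df["template_ng"] > 0)
    if bad.any():
        raise ValueError(
            f"{path}: experimental samples need template_ng > 0: "
            f"{list(df.index[bad])[:5]}"
        )
    return df
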