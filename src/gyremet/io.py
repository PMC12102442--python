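"""Readers and writers for the pipeline's plain-text formats (TSV/JSON).

ASV tables are held in memory as pandas DataFrames with samples as rows and
ASVs as columns (integer counts).  On disk the conventional orientation is
transposed — first column ``asv_id``, remaining columns samples — and the
reader auto-detects orientation from the header sentinel.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

RATES_INPUT_COLUMNS = {
    "sample_id": "sample_id",
    "leu_nmol_L_d": "leu_incorporation",
    "int_total_umol_L_d": "int_total",
    "int_02_08_umol_L_d": "int_02_08",
    "abs_sample": "abs_sample",
    "abs_blank": "abs_blank",
    "ba_cells_mL": "ba",
}

PANEL_OUTPUT_COLUMNS = {
    "sample_id": "sample_id",
    "bp": "bp_mgC_m3_d",
    "cr_o2": "cr_o2_umolO2_L_d",
    "br": "br_mgC_m3_d",
    "cs_bp": "csbp_fgC_cell_d",
    "cs_br": "csbr_fgC_cell_d",
}


def read_rate_inputs(path: str | Path) -> pd.DataFrame:
    """Read the raw-rate TSV; empty fields and "NA" become NaN."""
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""])
    missing = set(RATES_INPUT_COLUMNS) - {"abs_sample", "abs_blank"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df.rename(columns=RATES_INPUT_COLUMNS)


def write_rate_panel(panel: pd.DataFrame, path: str | Path) -> None:
    out = panel.rename(columns=PANEL_OUTPUT_COLUMNS)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""])
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing sample_id column")
    return df.set_index("sample_id")


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")


def read_asv_table(path: str | Path) -> pd.DataFrame:
    """Read an ASV count table, auto-detecting orientation.

    Files whose first column is named ``asv_id`` hold ASVs as rows and are
    transposed to the in-memory samples × ASVs layout; files whose first
    column is ``sample_id`` are read as-is.
    """
    df = pd.read_csv(path, sep="\t")
    first = df.columns[0]
    if first == "asv_id":
        table = df.set_index("asv_id").T
        table.index.name = "sample_id"
        table.columns.name = "asv_id"
    elif first == "sample_id":
        table = df.set_index("sample_id")
        table.columns.name = "asv_id"
    else:
        raise ValueError(
            f"{path}: first column must be 'asv_id' or 'sample_id', got {first!r}"
        )
    if table.index.duplicated().any() or table.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample or ASV identifiers")
    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or np.isnan(values.astype(float)).any():
        raise ValueError(f"{path}: counts must be numeric and complete")
    if (values < 0).any() or (values != np.round(values)).any():
        raise ValueError(f"{path}: counts must be non-negative integers")
    return table.astype(np.int64)


def write_asv_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write in the conventional on-disk orientation (ASVs as rows)."""
    table.T.to_csv(path, sep="\t", index_label="asv_id")


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read ``asv_id<TAB>domain;phylum;class;order;family;genus`` lineages."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["asv_id", "lineage"]:
        raise ValueError(f"{path}: expected columns 'asv_id', 'lineage'")
    parts = df["lineage"].str.split(";", expand=True).reindex(columns=range(len(RANKS)))
    parts = parts.fillna("")
    parts.columns = list(RANKS)
    parts.index = df["asv_id"]
    if parts.index.duplicated().any():
        raise ValueError(f"{path}: duplicate asv_id in taxonomy")
    return parts


def write_taxonomy(tax: pd.DataFrame, path: str | Path) -> None:
    lineage = tax[list(RANKS)].agg(";".join, axis=1)
    out = pd.DataFrame({"asv_id": tax.index, "lineage": lineage.to_numpy()})
    out.to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    """Write canonical JSON (sorted keys, stable float repr)."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
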