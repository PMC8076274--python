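"""Readers and writers for the tabular formats.

One fixed dialect at the door: comma-separated, UTF-8, "." decimal; TSV via
``sep="\\t"``.  Because deposited palaeo tables name their columns
inconsistently, every reader accepts a ``column_map`` translating logical
names (``sample_id``, ``depth_m`` ...) to the file's headers instead of
hard-coding a layout.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import TableValidationError
from .tables import CountTable, MeasurementTable, TiePointTable
from .taxonomy import TaxonCatalogue

INDETERMINATE = "Indeterminate"

_COUNT_META = {"sample_id": "sample_id", "depth_m": "depth_m",
               "weight_g": "weight_g", "counted_fraction": "counted_fraction"}


def _apply_map(df: pd.DataFrame, column_map: Mapping[str, str] | None,
               logical: dict) -> pd.DataFrame:
    """Rename file headers to logical names via ``column_map``."""
    if column_map:
        rename = {v: k for k, v in column_map.items() if v in df.columns}
        df = df.rename(columns=rename)
    return df


def read_count_table(
    path,
    catalogue: TaxonCatalogue,
    *,
    sep: str = ",",
    unknown_policy: str = "reject",
    column_map: Mapping[str, str] | None = None,
) -> CountTable:
    """Read a wide sample x taxon count CSV into a validated CountTable.

    The file carries one row per sample with metadata columns
    (``sample_id``, ``depth_m``, optional ``weight_g`` and
    ``counted_fraction``) followed by one column per taxon.  Taxa not in
    the catalogue are handled per ``unknown_policy``: ``"reject"`` raises,
    ``"indeterminate"`` pools them into a single out-of-sum column and
    warns.
    """
    if unknown_policy not in ("reject", "indeterminate"):
        raise ValueError(f"unknown_policy {unknown_policy!r}")
    df = pd.read_csv(path, sep=sep)
    df = _apply_map(df, column_map, _COUNT_META)
    for col in ("sample_id", "depth_m"):
        if col not in df.columns:
            raise TableValidationError("missing required column", column=col)
    meta_cols = [c for c in _COUNT_META if c in df.columns]
    taxon_cols = [c for c in df.columns if c not in meta_cols]
    unknown = [c for c in taxon_cols if c not in catalogue]
    if unknown:
        if unknown_policy == "reject":
            raise TableValidationError(
                f"taxa not in catalogue: {sorted(unknown)}"
            )
        warnings.warn(
            f"{len(unknown)} unknown taxa pooled into {INDETERMINATE!r}: "
            f"{sorted(unknown)}", stacklevel=2,
        )
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise TableValidationError(f"duplicate sample_id: {dupes}")
    counts = df[taxon_cols].copy()
    for col in taxon_cols:
        vals = pd.to_numeric(counts[col], errors="coerce")
        bad = vals.isna() & counts[col].notna()
        if bad.any():
            i = counts.index[bad][0]
            raise TableValidationError(
                f"non-numeric count {counts.at[i, col]!r}",
                row=df.at[i, "sample_id"], column=col,
            )
        frac = vals.dropna() % 1 != 0
        if frac.any():
            i = frac.index[frac][0]
            raise TableValidationError(
                f"non-integer count {vals[i]!r}",
                row=df.at[i, "sample_id"], column=col,
            )
        counts[col] = vals.fillna(0)
    counts.index = df["sample_id"]
    if unknown and unknown_policy == "indeterminate":
        pooled = counts[unknown].sum(axis=1)
        counts = counts.drop(columns=unknown)
        counts[INDETERMINATE] = counts.get(INDETERMINATE, 0) + pooled
    # canonical catalogue spelling
    counts.columns = [
        catalogue.canonical_name(c) if c in catalogue else c
        for c in counts.columns
    ]
    meta = df[meta_cols].set_index(df["sample_id"]).drop(columns="sample_id")
    return CountTable(counts=counts, meta=meta)


def write_count_table(table: CountTable, path, *, sep: str = ",") -> None:
    out = table.meta.join(table.counts)
    out.to_csv(path, sep=sep, index_label="sample_id", float_format="%.10g")


def read_measurements(
    path, *, sep: str = ",", column_map: Mapping[str, str] | None = None
) -> MeasurementTable:
    """Read a per-grain morphometrics CSV.

    Rows lacking a longest-axis measurement are dropped (the count is
    reported as a warning); a row whose pore + annulus is smaller than its
    pore is a hard error.
    """
    df = pd.read_csv(path, sep=sep)
    df = _apply_map(df, column_map, {})
    if "longest_axis_um" not in df.columns:
        raise TableValidationError("missing column", column="longest_axis_um")
    if df.empty:
        warnings.warn("measurement file contains no grains", stacklevel=2)
        df = pd.DataFrame(columns=["sample_id", "grain_id", "longest_axis_um",
                                   "pore_um", "pore_annulus_um", "sculpture"])
        return MeasurementTable(df)
    n0 = len(df)
    df = df[pd.to_numeric(df["longest_axis_um"], errors="coerce").notna()]
    dropped = n0 - len(df)
    if dropped:
        warnings.warn(f"dropped {dropped} grains lacking a longest-axis "
                      "measurement", stacklevel=2)
    return MeasurementTable(df.reset_index(drop=True))


def write_measurements(table: MeasurementTable, path, *, sep: str = ",") -> None:
    table.data.to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_tie_points(
    path, *, sep: str = ",", column_map: Mapping[str, str] | None = None
) -> TiePointTable:
    """Read a (depth_m, age_ma, label) tie-point CSV."""
    df = pd.read_csv(path, sep=sep)
    df = _apply_map(df, column_map, {})
    return TiePointTable(df)


def write_tie_points(table: TiePointTable, path, *, sep: str = ",") -> None:
    table.data.to_csv(path, sep=sep, index=False, float_format="%.10g")


def write_results(tables: Mapping[str, pd.DataFrame], out_dir, *,
                  sep: str = ",") -> dict[str, Path]:
    """Write computed result tables as CSVs with stable column order.

    Reals are written with 10 significant figures so a re-read reproduces
    them well inside 6 significant figures; integers round-trip exactly.
    Returns the mapping name -> written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        written[name] = p
    return written
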