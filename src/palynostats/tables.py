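"""Validated in-memory containers for the tabular inputs.

Thin wrappers around pandas DataFrames that enforce the palynological
invariants at construction: counts are non-negative integers, samples are
ordered stratigraphically (increasing core depth), tie points never reverse
age, and pore + annulus is at least the pore diameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import TableValidationError

SCULPTURES = frozenset({"psilate", "scabrate", "verrucate", "other", "unrecorded"})

META_COLUMNS = ("depth_m", "weight_g", "counted_fraction")


@dataclass
class CountTable:
    """Sample x taxon integer counts plus per-sample core metadata.

    ``counts`` is wide (index sample_id, one column per taxon; a taxon
    absent from a sample is 0, not missing — uncounted and absent are not
    distinguishable on a count sheet).  ``meta`` is indexed identically and
    carries ``depth_m`` (m), ``weight_g`` (g dry sediment, may be NaN),
    ``counted_fraction`` (fraction of the extracted residue examined,
    in (0, 1]) and optionally ``age_ma`` once an age model is applied.
    Rows are stored in stratigraphic order (increasing depth).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        counts, meta = self.counts, self.meta
        if counts.index.duplicated().any():
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate sample_id: {dupes}")
        if not counts.index.equals(meta.index):
            raise TableValidationError("counts and meta must share sample ids")
        if "depth_m" not in meta.columns:
            raise TableValidationError("missing depth column", column="depth_m")
        arr = counts.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.integer):
                frac = np.mod(arr.astype(float), 1) != 0
                if frac.any():
                    i, j = np.argwhere(frac)[0]
                    raise TableValidationError(
                        f"non-integer count {arr[i, j]!r}",
                        row=counts.index[i], column=counts.columns[j],
                    )
            neg = arr.astype(float) < 0
            if neg.any():
                i, j = np.argwhere(neg)[0]
                raise TableValidationError(
                    f"negative count {arr[i, j]!r}",
                    row=counts.index[i], column=counts.columns[j],
                )
        counts = counts.astype(np.int64)
        depth = meta["depth_m"].to_numpy(float)
        if np.isnan(depth).any() or (depth < 0).any():
            bad = meta.index[np.isnan(depth) | (depth < 0)][0]
            raise TableValidationError("invalid depth", row=bad, column="depth_m")
        if "weight_g" not in meta.columns:
            meta = meta.assign(weight_g=np.nan)
        w = meta["weight_g"].to_numpy(float)
        if (w[~np.isnan(w)] <= 0).any():
            bad = meta.index[np.nan_to_num(w, nan=1.0) <= 0][0]
            raise TableValidationError("weight must be > 0", row=bad,
                                       column="weight_g")
        if "counted_fraction" not in meta.columns:
            meta = meta.assign(counted_fraction=1.0)
        f = meta["counted_fraction"].to_numpy(float)
        if np.isnan(f).any() or (f <= 0).any() or (f > 1).any():
            bad = meta.index[np.isnan(f) | (f <= 0) | (f > 1)][0]
            raise TableValidationError("counted_fraction must be in (0, 1]",
                                       row=bad, column="counted_fraction")
        order = np.argsort(depth, kind="stable")
        counts, meta = counts.iloc[order], meta.iloc[order]
        counts.index.name = meta.index.name = "sample_id"
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "meta", meta)

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def taxa(self) -> pd.Index:
        return self.counts.columns

    def __len__(self) -> int:
        return len(self.counts)

    def subset_taxa(self, taxa) -> pd.DataFrame:
        """Counts restricted to ``taxa``; missing taxa contribute zeros."""
        present = [t for t in taxa if t in self.counts.columns]
        return self.counts[present]


@dataclass
class MeasurementTable:
    """Per-grain Poaceae morphometrics.

    Columns: ``sample_id``, ``grain_id``, ``longest_axis_um`` (> 0),
    ``pore_um`` and ``pore_annulus_um`` (> 0 or NaN when not measured) and
    ``sculpture`` (psilate/scabrate/verrucate/other/unrecorded).
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data.copy().reset_index(drop=True)
        for col in ("sample_id", "longest_axis_um"):
            if col not in df.columns:
                raise TableValidationError("missing column", column=col)
        if "grain_id" not in df.columns:
            df["grain_id"] = [f"g{i}" for i in range(len(df))]
        for col in ("pore_um", "pore_annulus_um"):
            if col not in df.columns:
                df[col] = np.nan
        if "sculpture" not in df.columns:
            df["sculpture"] = "unrecorded"
        df["sculpture"] = df["sculpture"].fillna("unrecorded")
        bad_sc = ~df["sculpture"].isin(SCULPTURES)
        if bad_sc.any():
            i = df.index[bad_sc][0]
            raise TableValidationError(
                f"unknown sculpture {df.at[i, 'sculpture']!r}",
                row=i, column="sculpture",
            )
        la = df["longest_axis_um"].to_numpy(float)
        if np.isnan(la).any() or (la <= 0).any():
            i = df.index[np.isnan(la) | (la <= 0)][0]
            raise TableValidationError("longest axis must be > 0", row=i,
                                       column="longest_axis_um")
        for col in ("pore_um", "pore_annulus_um"):
            v = df[col].to_numpy(float)
            if (v[~np.isnan(v)] <= 0).any():
                i = df.index[np.nan_to_num(v, nan=1.0) <= 0][0]
                raise TableValidationError(f"{col} must be > 0", row=i,
                                           column=col)
        p = df["pore_um"].to_numpy(float)
        pa = df["pore_annulus_um"].to_numpy(float)
        both = ~np.isnan(p) & ~np.isnan(pa)
        if (pa[both] < p[both]).any():
            i = df.index[both][np.argwhere(pa[both] < p[both])[0, 0]]
            raise TableValidationError(
                "pore + annulus smaller than pore", row=i,
                column="pore_annulus_um",
            )
        object.__setattr__(self, "data", df[
            ["sample_id", "grain_id", "longest_axis_um", "pore_um",
             "pore_annulus_um", "sculpture"]
        ])

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class TiePointTable:
    """Depth/age anchor points for the age-depth model.

    Rows of (depth_m, age_ma, label); depth strictly increasing implies age
    strictly increasing — a reversal is a hard error.  At least two rows.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data.copy().reset_index(drop=True)
        for col in ("depth_m", "age_ma"):
            if col not in df.columns:
                raise TableValidationError("missing column", column=col)
        if "label" not in df.columns:
            df["label"] = [f"tie{i}" for i in range(len(df))]
        if len(df) < 2:
            raise TableValidationError("at least 2 tie points required")
        d = df["depth_m"].to_numpy(float)
        a = df["age_ma"].to_numpy(float)
        if np.isnan(d).any() or (d < 0).any():
            raise TableValidationError("depths must be finite and >= 0",
                                       column="depth_m")
        if np.isnan(a).any() or (a < 0).any():
            raise TableValidationError("ages must be finite and >= 0",
                                       column="age_ma")
        order = np.argsort(d, kind="stable")
        df = df.iloc[order].reset_index(drop=True)
        df["depth_m"] = df["depth_m"].astype(float)
        df["age_ma"] = df["age_ma"].astype(float)
        d, a = d[order], a[order]
        if (np.diff(d) <= 0).any():
            i = int(np.argwhere(np.diff(d) <= 0)[0, 0])
            raise TableValidationError(
                f"duplicate tie depth {d[i + 1]} m", row=i + 1,
                column="depth_m",
            )
        if (np.diff(a) <= 0).any():
            i = int(np.argwhere(np.diff(a) <= 0)[0, 0])
            raise TableValidationError(
                "age reversal between ties "
                f"({d[i]} m, {a[i]} Ma) and ({d[i + 1]} m, {a[i + 1]} Ma)",
                row=i + 1, column="age_ma",
            )
        object.__setattr__(self, "data", df[["depth_m", "age_ma", "label"]])

    def __len__(self) -> int:
        return len(self.data)

    @property
    def depths(self) -> np.ndarray:
        return self.data["depth_m"].to_numpy(float)

    @property
    def ages(self) -> np.ndarray:
        return self.data["age_ma"].to_numpy(float)
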