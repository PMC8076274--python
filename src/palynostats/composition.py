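"""Pollen Sum, percentages, AP%, coprophilous % and concentrations.

Percentages follow standard pollen-diagram practice: every taxon —
including out-of-sum palynomorphs such as fern spores and NPP — is
expressed relative to the Pollen Sum (PS).  In-sum percentages therefore
total 100; out-of-sum percentages come on top and may jointly exceed it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import CountTable
from .taxonomy import TaxonCatalogue

DEFAULT_MIN_PS = 100


@dataclass
class SampleComposition:
    """Percentages and summary quantities for one sample."""

    sample_id: str
    ps_count: int
    total_count: int
    percent: pd.Series          # taxon -> % of PS (NaN when withheld)
    ap_percent: float
    coprophilous_percent: float
    concentration_per_g: float  # NaN when weight is unknown
    polliniferous: bool


def pollen_sum(counts: pd.Series, catalogue: TaxonCatalogue) -> int:
    """Grains in the Pollen Sum: seed-plant pollen only.

    Ferns, bryophytes, algae and NPP are excluded by catalogue flag.
    """
    in_sum = [t for t in counts.index
              if t in catalogue and catalogue.lookup(t)["in_pollen_sum"]]
    return int(counts[in_sum].sum())


def concentration(total_count: int, weight_g: float,
                  counted_fraction: float = 1.0) -> float:
    """Palynomorph concentration per gram dry sediment (weighting method).

    counted grains / (sediment weight x fraction of the residue examined).
    Returns NaN with a warning when the weight is unknown.
    """
    if weight_g is None or np.isnan(weight_g):
        warnings.warn("sample weight unknown; concentration not computed",
                      stacklevel=2)
        return float("nan")
    return total_count / (weight_g * counted_fraction)


def sample_composition(
    counts: pd.Series,
    catalogue: TaxonCatalogue,
    *,
    sample_id: str = "",
    weight_g: float = float("nan"),
    counted_fraction: float = 1.0,
    min_ps: int = DEFAULT_MIN_PS,
) -> SampleComposition:
    """Compute one sample's composition.

    When the Pollen Sum falls below ``min_ps`` the sample is flagged
    non-polliniferous and percentages are withheld (NaN) — a tiny sum
    makes ratio statistics meaningless.
    """
    ps = pollen_sum(counts, catalogue)
    total = int(counts.sum())
    if np.isnan(weight_g):
        conc = float("nan")
    else:
        conc = concentration(total, weight_g, counted_fraction)
    if ps < min_ps:
        percent = pd.Series(np.nan, index=counts.index)
        return SampleComposition(sample_id, ps, total, percent,
                                 float("nan"), float("nan"), conc, False)
    percent = 100.0 * counts / ps
    flags = pd.DataFrame(
        {t: catalogue.lookup(t) if t in catalogue else
         pd.Series(False, index=catalogue.table.columns)
         for t in counts.index}
    ).T
    ap = float(percent[flags["arboreal"].astype(bool)].sum())
    copro = float(percent[flags["is_coprophilous_fungus"].astype(bool)].sum())
    return SampleComposition(sample_id, ps, total, percent, ap, copro,
                             conc, True)


def compose(
    table: CountTable, catalogue: TaxonCatalogue, *,
    min_ps: int = DEFAULT_MIN_PS,
) -> pd.DataFrame:
    """Per-sample composition table for a whole core.

    Returns one row per sample (stratigraphic order) with ``ps_count``,
    ``total_count``, ``ap_percent``, ``coprophilous_percent``,
    ``concentration_per_g``, ``polliniferous`` and a ``pct:<taxon>`` column
    per taxon; ``age_ma`` is carried through when present in the metadata.
    """
    rows = []
    for sid in table.sample_ids:
        meta = table.meta.loc[sid]
        comp = sample_composition(
            table.counts.loc[sid], catalogue, sample_id=sid,
            weight_g=float(meta.get("weight_g", np.nan)),
            counted_fraction=float(meta.get("counted_fraction", 1.0)),
            min_ps=min_ps,
        )
        row = {
            "sample_id": sid,
            "depth_m": float(meta["depth_m"]),
            "ps_count": comp.ps_count,
            "total_count": comp.total_count,
            "ap_percent": comp.ap_percent,
            "coprophilous_percent": comp.coprophilous_percent,
            "concentration_per_g": comp.concentration_per_g,
            "polliniferous": comp.polliniferous,
        }
        if "age_ma" in table.meta.columns:
            row["age_ma"] = float(meta["age_ma"])
        for t, v in comp.percent.items():
            row[f"pct:{t}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
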