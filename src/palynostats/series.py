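"""Cerealia/Poaceae ratio and indicator time series on the age model.

The headline statistic is the cereal-type share of all Poaceae pollen
("x% of all Poaceae are proto-cereals"): the denominator includes the
cereal-type counts, so ratio = cereal / (cereal + wild).  A
``denominator="wild_only"`` switch gives cereal / wild for sensitivity.
Aggregates are offered both pooled (count-weighted, summing counts over
samples before dividing) and as the arithmetic mean of per-sample ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PalynError
from .tables import CountTable
from .taxonomy import TaxonCatalogue

DENOMINATORS = ("all_poaceae", "wild_only")


def cereal_ratio_series(
    table: CountTable,
    catalogue: TaxonCatalogue,
    *,
    composition: pd.DataFrame | None = None,
    denominator: str = "all_poaceae",
) -> pd.DataFrame:
    """Per-sample Cerealia/Poaceae ratio rows.

    Columns: sample_id, depth_m, (age_ma when known), cereal_count,
    poaceae_total, ratio_percent, cereal_percent_of_ps, flagged.  A sample
    with no Poaceae at all has an undefined ratio: it is flagged and
    excluded from aggregates.  ``cereal_percent_of_ps`` is taken from a
    supplied composition table (NaN otherwise).
    """
    if denominator not in DENOMINATORS:
        raise PalynError(f"denominator must be one of {DENOMINATORS}")
    cereal_taxa = [t for t in catalogue.taxa_where("is_cereal_type")]
    poaceae_taxa = [t for t in catalogue.taxa_where("is_poaceae")]
    cereal = table.subset_taxa(cereal_taxa).sum(axis=1)
    poaceae = table.subset_taxa(poaceae_taxa).sum(axis=1)
    wild = poaceae - cereal
    denom = poaceae if denominator == "all_poaceae" else wild
    out = pd.DataFrame({
        "sample_id": table.sample_ids,
        "depth_m": table.meta["depth_m"].to_numpy(float),
        "cereal_count": cereal.to_numpy(),
        "poaceae_total": poaceae.to_numpy(),
        "denominator_count": denom.to_numpy(),
    })
    if "age_ma" in table.meta.columns:
        out["age_ma"] = table.meta["age_ma"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["ratio_percent"] = np.where(
            out["denominator_count"] > 0,
            100.0 * out["cereal_count"] / out["denominator_count"], np.nan,
        )
    out["flagged"] = out["denominator_count"] == 0
    if composition is not None:
        pct_cols = [f"pct:{t}" for t in cereal_taxa
                    if f"pct:{t}" in composition.columns]
        cpct = composition.set_index("sample_id")[pct_cols].sum(axis=1)
        out["cereal_percent_of_ps"] = cpct.reindex(out["sample_id"]).to_numpy()
    else:
        out["cereal_percent_of_ps"] = np.nan
    return out


def window_aggregate(
    series: pd.DataFrame, age_lo_ma: float, age_hi_ma: float,
) -> dict:
    """Aggregate the ratio over the closed age window [lo, hi].

    Returns both aggregation conventions: ``pooled`` (sum of cereal counts
    over sum of denominators — a count-weighted mean of per-sample ratios)
    and ``mean_of_samples``.
    """
    if "age_ma" not in series.columns:
        raise PalynError("series has no ages; apply an age model first")
    w = series[(series["age_ma"] >= age_lo_ma) & (series["age_ma"] <= age_hi_ma)
               & ~series["flagged"]]
    if w.empty:
        raise PalynError(
            f"no usable samples in age window [{age_lo_ma}, {age_hi_ma}] Ma"
        )
    pooled = 100.0 * w["cereal_count"].sum() / w["denominator_count"].sum()
    return {
        "pooled": float(pooled),
        "mean_of_samples": float(w["ratio_percent"].mean()),
        "n_samples": int(len(w)),
    }


def step_change(
    series: pd.DataFrame, candidate_ages: np.ndarray | None = None,
) -> dict:
    """Descriptive single-step summary of a ratio series.

    Scans candidate breakpoint ages and reports the one maximising the
    absolute difference between the mean per-sample ratio on the old side
    (age >= breakpoint) and the young side (age < breakpoint), requiring
    at least two samples on each side.  Ties go to the oldest candidate.
    Purely descriptive — no significance machinery.
    """
    s = series[~series["flagged"]].dropna(subset=["ratio_percent"])
    if "age_ma" not in s.columns:
        raise PalynError("series has no ages; apply an age model first")
    if len(s) < 4:
        raise PalynError("need at least 4 unflagged samples")
    ages = np.sort(s["age_ma"].to_numpy(float))
    if candidate_ages is None:
        candidate_ages = (ages[1:] + ages[:-1]) / 2.0
    candidate_ages = np.asarray(candidate_ages, float)
    r = s["ratio_percent"].to_numpy(float)
    a = s["age_ma"].to_numpy(float)
    best = None
    for bp in candidate_ages:
        old, young = r[a >= bp], r[a < bp]
        if len(old) < 2 or len(young) < 2:
            continue
        contrast = float(old.mean() - young.mean())
        key = abs(contrast)
        # ties -> oldest candidate
        if best is None or key > best[0] + 1e-12 or (
            abs(key - best[0]) <= 1e-12 and bp > best[1]
        ):
            best = (key, float(bp), float(old.mean()), float(young.mean()),
                    contrast)
    if best is None:
        raise PalynError(
            "no candidate breakpoint leaves >= 2 samples on each side"
        )
    if best[0] < 1e-9:
        warnings.warn("series is constant; breakpoint is arbitrary",
                      stacklevel=2)
    return {
        "breakpoint_age_ma": best[1],
        "before_mean": best[2],   # old side (age >= breakpoint)
        "after_mean": best[3],    # young side
        "contrast": best[4],
    }


def _pooled(series: pd.DataFrame) -> float:
    w = series[~series["flagged"]]
    return float(100.0 * w["cereal_count"].sum() / w["denominator_count"].sum())


def compare_modern(
    fossil: pd.DataFrame,
    modern: pd.DataFrame,
    n_boot: int = 2000,
    seed: int | None = 0,
) -> dict:
    """Fossil vs modern pooled ratio with a bootstrap confidence interval.

    Resamples whole samples (with replacement) within each series,
    recomputes the pooled ratios, and returns the percentile 95% CI of the
    difference (fossil − modern), in percentage points.  Deterministic
    given the seed.
    """
    if fossil.empty or modern.empty:
        raise PalynError("both series must be non-empty")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; CI will be unstable",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    out = {
        "fossil_pooled": _pooled(fossil),
        "modern_pooled": _pooled(modern),
    }
    out["difference"] = out["fossil_pooled"] - out["modern_pooled"]

    def boot(series):
        w = series[~series["flagged"]]
        c = w["cereal_count"].to_numpy(float)
        d = w["denominator_count"].to_numpy(float)
        idx = rng.integers(0, len(w), size=(n_boot, len(w)))
        num, den = c[idx].sum(axis=1), d[idx].sum(axis=1)
        return np.where(den > 0, 100.0 * num / np.maximum(den, 1), np.nan)

    diff = boot(fossil) - boot(modern)
    lo, hi = np.nanpercentile(diff, [2.5, 97.5])
    out["bootstrap_ci95"] = (float(lo), float(hi))
    out["n_boot"] = int(n_boot)
    return out


def coprophilous_continuity(composition: pd.DataFrame) -> dict:
    """Continuity of the dung-fungus signal along the core.

    Presence = coprophilous % > 0.  Returns the share of samples with
    presence and the longest age gap (Ma) between consecutive
    presence samples — a continuous signal means large herbivores never
    left the lake surroundings.
    """
    if composition.empty:
        raise PalynError("composition table is empty")
    present = composition["coprophilous_percent"].to_numpy(float) > 0
    frac = 100.0 * present.sum() / len(present)
    gap = float("nan")
    if "age_ma" in composition.columns and present.sum() >= 2:
        ages = np.sort(composition.loc[present, "age_ma"].to_numpy(float))
        gap = float(np.diff(ages).max())
    return {"fraction_of_samples_present": float(frac), "longest_gap_ma": gap}
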