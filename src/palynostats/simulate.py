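"""Synthetic assemblages with the statistical structure of a long lake core.

The generator emulates a 72-sample, 0–2.3 Ma record from a 598 m core at a
constant 26 cm/ka sedimentation rate: an arboreal-pollen fraction
oscillating with ~100 ka (orbital) cyclicity around a low mean, a Poaceae
component whose cereal-type sub-fraction steps down from 24.66% of all
Poaceae in the oldest interval to a few percent after 1.5 Ma, ever-present
coprophilous fungal spores, and per-grain morphometrics drawn from a
bimodal normal mixture (wild mode near 31 µm, cereal mode near 45 µm) with
pore size independent of grain diameter.  Counts are multinomial over the
expected composition, optionally Dirichlet-overdispersed; every draw is
reproducible from the seed and every generating parameter is returned in a
truth record so downstream recovery tests never re-derive it from config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import PalynError
from .tables import CountTable, MeasurementTable, TiePointTable
from .taxonomy import TaxonCatalogue, default_catalogue

# Relative abundance of the in-sum taxa apart from Poaceae, used to split
# the AP and non-Poaceae-herb shares of the Pollen Sum.
_AP_SPLIT = {
    "Pinus": 0.35, "Quercus deciduous": 0.20, "Cedrus": 0.10,
    "Cupressaceae": 0.10, "Abies": 0.07, "Picea": 0.05, "Olea": 0.05,
    "Juglans": 0.03, "Alnus": 0.03, "Salix": 0.02,
}
_HERB_SPLIT = {
    "Artemisia": 0.45, "Chenopodiaceae": 0.30, "Plantago": 0.10,
    "Compositae": 0.10, "Convolvulus": 0.05,
}
# Out-of-sum taxa: expected counts as a fraction of the Pollen Sum.
_COPRO_TAXA = ("Sporormiella", "Podospora", "Delitschia", "Sordaria",
               "Valsaria variospora")
_OUT_OF_SUM = {"Filicophyta": 0.02, "Botryococcus": 0.03}


@dataclass(frozen=True)
class CoreSimConfig:
    """Generating parameters of the synthetic core."""

    n_samples: int = 72
    depth_span_m: tuple[float, float] = (0.0, 598.0)
    sed_rate_cm_ka: float = 26.0
    mean_ps: float = 558.0
    ap_mean_percent: float = 27.5
    ap_cycle_amplitude_percent: float = 15.0
    ap_cycle_period_ka: float = 100.0
    poaceae_percent_of_ps: float = 20.0
    cereal_fraction_old: float = 0.2466
    cereal_fraction_young: float = 0.03
    step_age_ma: float = 1.5
    step_ramp_ma: float = 0.0
    coprophilous_presence_prob: float = 1.0
    coprophilous_percent_of_ps: float = 2.0
    overdispersion: float = 500.0   # Dirichlet concentration; inf = multinomial
    mean_weight_g: float = 11.24
    seed: int = 0

    def __post_init__(self):
        for name in ("cereal_fraction_old", "cereal_fraction_young",
                     "coprophilous_presence_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise PalynError(f"{name} must be in [0, 1], got {v}")
        if self.n_samples < 2:
            raise PalynError("n_samples must be >= 2")
        if self.ap_cycle_period_ka <= 0:
            raise PalynError("cycle period must be > 0")
        if self.sed_rate_cm_ka <= 0:
            raise PalynError("sedimentation rate must be > 0")


@dataclass(frozen=True)
class ModernSimConfig:
    """Generating parameters for the modern moss-pollster samples."""

    n_samples: int = 8
    mean_ps: float = 400.0
    poaceae_percent_of_ps: float = 20.0
    cereal_fraction: float = 0.045
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.cereal_fraction <= 1:
            raise PalynError("cereal_fraction must be in [0, 1]")


@dataclass(frozen=True)
class MeasureSimConfig:
    """Generating parameters for the grain-measurement table."""

    n_grains: int = 991
    wild_mean_um: float = 31.01
    wild_sd_um: float = 2.5
    cereal_mean_um: float = 45.07
    cereal_sd_um: float = 2.5
    cereal_weight: float = 0.25
    pore_mean_um: float = 4.28
    pore_sd_um: float = 0.5
    annulus_extra_mean_um: float = 5.84
    annulus_extra_sd_um: float = 1.0
    pore_independent_of_diameter: bool = True
    pore_diameter_slope: float = 0.1  # used only when not independent
    seed: int = 0

    def __post_init__(self):
        for name in ("wild_mean_um", "cereal_mean_um", "wild_sd_um",
                     "cereal_sd_um", "pore_mean_um"):
            if getattr(self, name) <= 0:
                raise PalynError(f"{name} must be > 0")
        if not 0 <= self.cereal_weight <= 1:
            raise PalynError("cereal_weight must be in [0, 1]")


def _age_of_depth(depth_m, cfg: CoreSimConfig):
    # constant sedimentation rate: cm depth / (cm/ka) = ka
    return np.asarray(depth_m, float) * 100.0 / cfg.sed_rate_cm_ka / 1000.0


def cereal_fraction_at(age_ma, cfg: CoreSimConfig) -> np.ndarray:
    """True cereal-type fraction of Poaceae at each age (hard step
    at ``step_age_ma``, optional linear ramp of width ``step_ramp_ma``)."""
    age = np.asarray(age_ma, float)
    if cfg.step_ramp_ma <= 0:
        return np.where(age >= cfg.step_age_ma, cfg.cereal_fraction_old,
                        cfg.cereal_fraction_young)
    lo = cfg.step_age_ma - cfg.step_ramp_ma / 2
    t = np.clip((age - lo) / cfg.step_ramp_ma, 0, 1)
    return cfg.cereal_fraction_young + t * (
        cfg.cereal_fraction_old - cfg.cereal_fraction_young)


def expected_composition(age_ma: float, cfg: CoreSimConfig) -> pd.Series:
    """Expected in-sum proportions at one age (sums to 1)."""
    ap = cfg.ap_mean_percent + cfg.ap_cycle_amplitude_percent * np.sin(
        2 * np.pi * age_ma * 1000.0 / cfg.ap_cycle_period_ka)
    ap = float(np.clip(ap, 2.0, 90.0)) / 100.0
    poa = cfg.poaceae_percent_of_ps / 100.0
    herbs = max(1.0 - ap - poa, 0.02)
    # renormalise in case clipping pushed the total off 1
    total = ap + poa + herbs
    ap, poa, herbs = ap / total, poa / total, herbs / total
    cf = float(cereal_fraction_at(age_ma, cfg))
    p = {}
    for t, w in _AP_SPLIT.items():
        p[t] = ap * w
    for t, w in _HERB_SPLIT.items():
        p[t] = herbs * w
    p["Cerealia-type"] = poa * cf
    p["Poaceae"] = poa * (1.0 - cf)
    return pd.Series(p)


def simulate_core(
    cfg: CoreSimConfig = CoreSimConfig(),
    catalogue: TaxonCatalogue | None = None,
) -> tuple[CountTable, TiePointTable, dict]:
    """Generate a synthetic core: counts, tie points and the truth record.

    Depths are equally spaced over the span; true ages follow the constant
    sedimentation rate; in-sum counts are multinomial (optionally
    Dirichlet-overdispersed) around the forced composition with a Poisson
    Pollen Sum; coprophilous and other out-of-sum counts are Poisson at a
    fixed fraction of the PS.  Tie points are emitted at both core ends
    plus two interior geomagnetic reversals, all exactly on the true
    age-depth line.
    """
    if catalogue is None:
        catalogue = default_catalogue()
    rng = np.random.default_rng(cfg.seed)
    depths = np.linspace(*cfg.depth_span_m, cfg.n_samples)
    ages = _age_of_depth(depths, cfg)

    rows, truth_rows = [], []
    for i, (d, age) in enumerate(zip(depths, ages)):
        base = expected_composition(age, cfg)
        ps_n = int(rng.poisson(cfg.mean_ps))
        if np.isfinite(cfg.overdispersion):
            p = rng.dirichlet(cfg.overdispersion * base.to_numpy())
        else:
            p = base.to_numpy()
        counts = pd.Series(rng.multinomial(ps_n, p), index=base.index)
        copro_present = rng.random() < cfg.coprophilous_presence_prob
        for t in _COPRO_TAXA:
            lam = ps_n * cfg.coprophilous_percent_of_ps / 100.0 / len(_COPRO_TAXA)
            counts[t] = rng.poisson(lam) if copro_present else 0
        if copro_present and counts[list(_COPRO_TAXA)].sum() == 0:
            counts["Sporormiella"] = 1  # presence probability is exact
        for t, frac in _OUT_OF_SUM.items():
            counts[t] = rng.poisson(ps_n * frac)
        rows.append(counts)
        truth_rows.append({
            "sample_id": f"S{i:03d}", "depth_m": float(d),
            "age_ma": float(age),
            "ap_expected_percent": float(100 * sum(
                base[t] for t in _AP_SPLIT)),
            "cereal_fraction": float(cereal_fraction_at(age, cfg)),
            "coprophilous_present": bool(copro_present),
        })

    counts = pd.DataFrame(rows).fillna(0).astype(int)
    counts.index = [r["sample_id"] for r in truth_rows]
    weight = np.clip(rng.normal(cfg.mean_weight_g, 2.5, cfg.n_samples),
                     3.5, 16.6)
    meta = pd.DataFrame({
        "depth_m": depths, "weight_g": weight, "counted_fraction": 1.0,
    }, index=counts.index)
    table = CountTable(counts=counts, meta=meta)

    # tie points: core ends + two interior reversals, all on the true line
    max_age = float(ages[-1])
    interior = [a for a in (0.773, 1.775) if 0 < a < max_age] or \
        [max_age / 3, 2 * max_age / 3]
    tie_ages = [0.0, *interior, max_age]
    tie_depths = [a * cfg.sed_rate_cm_ka * 10.0 for a in tie_ages]
    labels = ["core top", "Brunhes-Matuyama", "Olduvai top", "core base"][
        : len(tie_ages)]
    ties = TiePointTable(pd.DataFrame({
        "depth_m": tie_depths, "age_ma": tie_ages, "label": labels,
    }))

    truth = {
        "config": asdict(cfg),
        "samples": pd.DataFrame(truth_rows),
        "true_sed_rate_cm_ka": cfg.sed_rate_cm_ka,
        "true_step_age_ma": cfg.step_age_ma,
        "true_cereal_fraction_old": cfg.cereal_fraction_old,
        "true_cereal_fraction_young": cfg.cereal_fraction_young,
    }
    return table, ties, truth


def simulate_measurements(
    cfg: MeasureSimConfig = MeasureSimConfig(),
) -> tuple[MeasurementTable, dict]:
    """Generate per-grain morphometrics from the two-mode size model.

    Longest axes come from the wild/cereal normal mixture; pore and
    pore + annulus are drawn independently of diameter by default (so an
    OLS R² of pore on diameter tends to zero as n grows); sculpture is
    scabrate/verrucate for cereal-mode grains and mixed otherwise.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_grains
    is_cereal = rng.random(n) < cfg.cereal_weight
    la = np.where(
        is_cereal,
        rng.normal(cfg.cereal_mean_um, cfg.cereal_sd_um, n),
        rng.normal(cfg.wild_mean_um, cfg.wild_sd_um, n),
    )
    la = np.clip(la, 10.0, None)
    pore = np.clip(rng.normal(cfg.pore_mean_um, cfg.pore_sd_um, n), 0.5, None)
    if not cfg.pore_independent_of_diameter:
        pore = pore + cfg.pore_diameter_slope * (la - la.mean())
        pore = np.clip(pore, 0.5, None)
    annulus_extra = np.clip(
        rng.normal(cfg.annulus_extra_mean_um, cfg.annulus_extra_sd_um, n),
        0.1, None)
    sculpt_cereal = rng.choice(["scabrate", "verrucate"], size=n)
    sculpt_wild = rng.choice(["psilate", "scabrate", "other"], size=n,
                             p=[0.6, 0.3, 0.1])
    df = pd.DataFrame({
        "sample_id": [f"S{i % 10:03d}" for i in range(n)],
        "grain_id": [f"g{i}" for i in range(n)],
        "longest_axis_um": la,
        "pore_um": pore,
        "pore_annulus_um": pore + annulus_extra,
        "sculpture": np.where(is_cereal, sculpt_cereal, sculpt_wild),
    })
    truth = {"config": asdict(cfg), "is_cereal": is_cereal,
             "true_means_um": (cfg.wild_mean_um, cfg.cereal_mean_um),
             "true_weights": (1 - cfg.cereal_weight, cfg.cereal_weight)}
    return MeasurementTable(df), truth


def simulate_modern(
    cfg: ModernSimConfig = ModernSimConfig(),
    catalogue: TaxonCatalogue | None = None,
) -> tuple[CountTable, dict]:
    """Generate the small modern moss-pollster analogue.

    Same compositional machinery as the fossil core but few samples, no
    age axis (depths are nominal sample positions) and its own — much
    lower — cereal fraction.
    """
    if catalogue is None:
        catalogue = default_catalogue()
    rng = np.random.default_rng(cfg.seed)
    core_like = CoreSimConfig(
        n_samples=max(cfg.n_samples, 2), mean_ps=cfg.mean_ps,
        poaceae_percent_of_ps=cfg.poaceae_percent_of_ps,
        cereal_fraction_old=cfg.cereal_fraction,
        cereal_fraction_young=cfg.cereal_fraction,
        ap_cycle_amplitude_percent=5.0, seed=cfg.seed,
    )
    rows = []
    for i in range(cfg.n_samples):
        base = expected_composition(0.0, core_like)
        ps_n = int(rng.poisson(cfg.mean_ps))
        counts = pd.Series(rng.multinomial(ps_n, base.to_numpy()),
                           index=base.index)
        rows.append(counts)
    counts = pd.DataFrame(rows).fillna(0).astype(int)
    counts.index = [f"moss{i + 1}" for i in range(cfg.n_samples)]
    meta = pd.DataFrame({
        "depth_m": np.arange(cfg.n_samples, dtype=float),
        "weight_g": np.nan, "counted_fraction": 1.0,
    }, index=counts.index)
    truth = {"config": asdict(cfg), "true_cereal_fraction": cfg.cereal_fraction}
    return CountTable(counts=counts, meta=meta), truth
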