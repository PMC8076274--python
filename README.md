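# palynostats

Quantitative palynology for long lacustrine pollen records: pollen-sum
percentages, piecewise-linear age-depth models, morphometric
classification of cereal-type (proto-cereal) Poaceae pollen, Gaussian-
mixture decomposition of grain-size distributions, Cerealia/Poaceae ratio
time series, coprophilous-fungus (dung fungus) indicator series, and a
fossil-vs-modern pollen-rain comparison — plus a synthetic assemblage
generator so the whole pipeline can be exercised and validated without
any deposited data.

It is written for palaeoecologists working with counted pollen slides
from long cores: the kind of record where 10²–10³ grains per sample are
identified over tens of samples spanning 10⁵–10⁶ years, and where every
published percentage depends on an explicit denominator convention.

## The statistics at the core

**Pollen Sum.** Percentages are computed on a Pollen Sum (PS) containing
all seed-plant pollen and excluding fern and bryophyte spores, algae and
non-pollen palynomorphs (NPP). For taxon *t* in sample *i*,
`p_it = 100 · c_it / PS_i`; out-of-sum taxa (including NPP such as dung-
fungus spores) are still expressed relative to PS, so in-sum percentages
total exactly 100 while out-of-sum percentages come on top. Arboreal
pollen (AP%) is the summed percentage of tree/shrub taxa and tracks
landscape openness. Concentration uses the weighting method:
`grains counted / (sediment weight (g) × fraction of residue counted)`.

**Age model.** Depth→age is piecewise linear through magnetostratigraphic
tie points (geomagnetic reversals with known ages); each segment's slope
is a sedimentation rate in cm/ka. Outside the dated span the edge
segment's rate is extended (configurable).

**Proto-cereal classification.** A Poaceae grain is cereal-type when its
longest axis is ≥ 40 µm, its pore + annulus diameter is ≥ 8 µm and its
exine sculpture is scabrate-to-verrucate — a conjunctive rule with
inclusive thresholds. The 37 µm size threshold (Andersen) and the 10 µm
annulus threshold are available as variants, as is a size-only rule for
histogram work.

**Size mixture.** The longest-axis distribution is modelled as a k-
component univariate normal mixture fitted by EM with seeded restarts,
k chosen by BIC — testing whether large grains form distinct modes
rather than the tail of the wild-grass distribution. Independence of
pore size from grain diameter is quantified by the OLS R².

**Ratio series.** The Cerealia/Poaceae ratio is
`100 · cereal-type / (cereal-type + wild Poaceae)` per sample; window
aggregates are offered pooled (count-weighted) and as means of per-sample
ratios, a descriptive step-change scan locates the largest mean shift on
the age axis, and the fossil series is compared with a modern moss-
pollster series via a percentile bootstrap CI on the difference of pooled
ratios.

## Worked example

```python
import palynostats as ps

core, ties, truth = ps.simulate_core(ps.CoreSimConfig(seed=42))
model = ps.build_age_model(ties)
core = ps.assign_ages(model, core)
cat = ps.default_catalogue()
comp = ps.compose(core, cat)
print(f"mean PS: {comp.ps_count.mean():.1f} grains; "
      f"mean AP: {comp.ap_percent.mean():.1f}%")

series = ps.cereal_ratio_series(core, cat, composition=comp)
old = ps.window_aggregate(series, 2.0, 2.3)
print(f"pooled Cerealia/Poaceae ratio 2.0-2.3 Ma: {old['pooled']:.2f}% "
      f"(n={old['n_samples']})")
step = ps.step_change(series)
print(f"step: {step['before_mean']:.1f}% -> {step['after_mean']:.1f}% "
      f"at {step['breakpoint_age_ma']:.2f} Ma")

meas, _ = ps.simulate_measurements(ps.MeasureSimConfig(seed=42))
print(ps.fit_size_mixture(meas, k_max=4, seed=42).summary())
print(f"R^2 diameter vs pore: {ps.diameter_pore_r2(meas, 'pore'):.4f}")
```

prints

```
mean PS: 554.7 grains; mean AP: 27.6%
pooled Cerealia/Poaceae ratio 2.0-2.3 Ma: 21.33% (n=10)
step: 22.4% -> 2.3% at 1.51 Ma
Grain-size Gaussian mixture
  components: 2   n grains: 991
  log-likelihood: -2886.062   BIC: 5806.617   converged: True
  comp   weight   mean (um)   sd (um)
     1    0.735       31.16      2.48
     2    0.265       44.65      2.63
R^2 diameter vs pore: 0.0001
```

The synthetic 72-sample core spans 0–2.3 Ma at 26 cm/ka. Its arboreal
fraction oscillates with ~100 ka cyclicity around a 27.5% mean (an open
landscape), and its cereal-type share of Poaceae steps from 24.66% in the
oldest interval down to 3% after 1.5 Ma; the window aggregate and the
step-change scan recover both from counts alone (the 2.0–2.3 Ma window
holds only 10 samples, hence its sampling scatter around 24.66). The
991-grain measurement table decomposes into a wild mode near 31 µm and a
cereal mode near 45 µm, with pore size carrying essentially no
information about grain diameter (R² ≈ 0).

A `palynostats` command-line tool exposes each stage (`simulate`,
`agemodel`, `percent`, `classify`, `ratio`, `compare-modern`, `run`);
`palynostats run --config cfg.json` executes the full pipeline and writes
composition, ratio-series, classification CSVs and a run manifest that
suffices to reproduce the run exactly.

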