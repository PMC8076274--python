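# Methods

## Denominators and percentages

Every percentage in a pollen diagram is a ratio of counts, and the choice
of denominator is the single largest source of incomparability between
studies. `palynostats` fixes one convention, carried by the taxon
catalogue rather than by the data: the Pollen Sum (PS) contains all
seed-plant pollen; fern and bryophyte spores, algae and non-pollen
palynomorphs (NPP) are outside it, but their percentages are still
expressed relative to PS. Consequences the test-suite asserts: in-sum
percentages total exactly 100 (a rational-arithmetic identity on integer
counts), out-of-sum percentages may jointly exceed 100, and percentages
are invariant under scaling all counts.

A sample whose PS falls below `min_ps` (default 100 grains) is flagged
non-polliniferous and its percentages are withheld rather than reported
with huge sampling error. Counts of 300–400 grains per sample are the
field's norm, so real samples clear the gate comfortably; the default
protects ratio statistics from tephra or algal-bloom horizons that yield
only a handful of grains. Concentration per gram uses the weighting
method, `counted / (weight_g × counted_fraction)`; when a table does not
record the counted fraction it is taken as 1.0, which makes the result a
lower bound, and a missing weight yields a missing value with a warning
rather than a guess.

## Taxon catalogue

Group membership (tree/shrub, herb, fern, bryophyte, alga, NPP) and the
derived flags (arboreal, Poaceae, cereal-type, coprophilous fungus,
cultivated-tree ancestor, edible + organ) are data, not code: users merge
overrides by taxon name (case-insensitive) and every changed flag is
reported. Construction re-validates the invariants after any merge:
out-of-sum groups can never enter the PS, cereal-type implies Poaceae,
arboreal implies tree/shrub, coprophilous implies NPP. The shipped
default catalogue covers the taxa of a south-west Anatolian steppe-lake
record (steppic herbs, Mediterranean conifer/oak woodland, riverine and
relictual trees, the five classic dung fungi, cereal-type Poaceae);
its edibility flags are interpretive defaults meant to be overridden, so
the edible-plant summary on the default catalogue illustrates the
computation rather than reproducing any particular inventory.

"Cerealia-type" exists both as a count-sheet taxon and as a morphometric
class. The two routes are kept separate by design: counts drive the
ratio series and measurements drive the size analysis, because they are
independent lines of evidence; re-deriving per-sample cereal counts from
the classified fraction of measured grains is possible but not the
default.

## Age-depth model

Piecewise-linear interpolation through tie points (depth m, age Ma), each
a geomagnetic reversal or equivalent dated horizon. Segment slopes are
sedimentation rates in cm/ka (1 m/Ma = 0.1 cm/ka); rates must be
positive, tie depths map to tie ages exactly, and an age reversal is a
hard error naming the offending pair. Default extrapolation beyond the
dated span extends the edge segment's rate — that is how a core top at
0 Ma and a base age beyond the last reversal are obtained — and a
`forbid` policy raises instead. No uncertainty is propagated: tie-point
ages come without errors, so the model is deliberately deterministic.
Bayesian age-depth modelling is out of scope.

## Proto-cereal decision rule

A grain is cereal-type iff longest axis ≥ 40 µm AND pore + annulus
≥ 8 µm AND sculpture ∈ {scabrate, verrucate}; thresholds are inclusive
and the conjunction means a large grain failing the annulus or sculpture
criterion stays wild. The literature is split between an 8 µm and a
10 µm annulus threshold; both are provided (`CerealCriteria()` vs
`CerealCriteria.strict_annulus()`) and the package takes no position.
The 37 µm size threshold (`CerealCriteria.andersen()`) can only enlarge
the cereal set — a monotonicity the tests check on random fixtures.
Grains lacking pore or sculpture data are classified on size alone and
flagged `partial` by default (size is what histograms use); a `strict`
policy sends them to wild instead, and `size_only=True` reproduces the
one-criterion ≥ 40 µm split. Whether a published 991-grain data set was
classified on size alone or on all three criteria is generally not
recoverable, which is exactly why both modes exist.

Classification is monotone in both thresholds: growing a grain's axis or
annulus never flips it from cereal to wild.

## Grain-size mixture

The longest-axis distribution is modelled as a k-component univariate
normal mixture, k = 1..k_max (default 4), fitted by EM and selected by
BIC. Numerical choices: 10 restarts per k — one deterministic start with
component means at the (i+½)/k quantiles of the data, nine random
restarts drawn from the seeded generator — max 500 EM iterations,
log-likelihood tolerance 1e-8, unequal variances by default (equal
variance is an option for small n). A fit that exhausts its iterations
is returned with `converged=False` rather than discarded. The model
object / results object split follows the convention of statistical
modelling packages: `GrainSizeMixture(x, k).fit(seed)` returns a
`SizeMixtureResults` with weights, means, sds, BIC and a `summary()`
table, and `fit_size_mixture` wraps the BIC scan. EM is delegated to
scikit-learn's `GaussianMixture` behind this surface.

The diameter–pore relationship is summarised by the R² of an OLS fit of
pore (or pore + annulus) on longest axis; a constant response returns 0,
a constant predictor is an error. Near-zero R² supports reading the
large-grain mode as a distinct population rather than scaled-up wild
grains.

## Ratio series and comparisons

The Cerealia/Poaceae ratio counts cereal-type in the denominator
(`cereal / (cereal + wild)`), which is what "x% of all Poaceae" means;
`wild_only` is available for sensitivity. Samples with no Poaceae have
an undefined ratio and are flagged out of every aggregate. Window
aggregation (closed bounds, on the age axis) reports both the pooled
ratio — algebraically a count-weighted mean of per-sample ratios, an
identity the tests verify — and the arithmetic mean of per-sample
ratios, because published numbers rarely say which convention they used.

The step-change scan is deliberately descriptive: over candidate
breakpoint ages (default: midpoints between consecutive samples) it
maximises |mean(old side) − mean(young side)| with ≥ 2 samples per side,
breaking ties toward the oldest candidate, and reports no p-value — the
underlying claim it summarises is qualitative, and formal change-point
inference (PELT, binary segmentation) is out of scope.

The fossil-vs-modern comparison resamples whole samples with replacement
within each series (2000 replicates by default), recomputes pooled
ratios, and reports the percentile 95% CI of the difference. Sample-level
resampling respects the clustered structure of count data; with as few
as 8 modern samples the percentile interval is approximate, which is why
the calibration test demands ≥ 90% empirical coverage at nominal 95%
rather than exact coverage.

Coprophilous continuity reduces the dung-fungus record to the fraction
of samples with any coprophilous spores and the longest age gap between
presences — the summary relevant to "were large herbivores always
there?".

## Synthetic data generator

The generator produces data with the statistical structure the analysis
assumes, at the scale of a long Quaternary lake record: 72 samples
equally spaced over 0–598 m, constant 26 cm/ka sedimentation (so the base
is 2.3 Ma), mean PS 558 drawn Poisson, AP oscillating with a 100-ka
sinusoid of ±15 points around 27.5% (clipped to [2, 90] %), Poaceae at
20% of PS, and a cereal-type fraction of Poaceae stepping from 0.2466
before 1.5 Ma to 0.03 after (a hard step by default; a linear ramp width
is available). In-sum counts are multinomial over the forced
composition, by default mildly Dirichlet-overdispersed (concentration
500) because real percentage diagrams are noisier than multinomial;
`overdispersion=inf` recovers the pure multinomial limit. Coprophilous
spores appear with probability 1.0 per sample at ~2% of PS across five
taxa; ferns and algae are Poisson at fixed fractions of PS. Tie points
are emitted at the core ends plus two interior reversals, all exactly on
the true age-depth line. Grain measurements mix two normal modes
(31.01 and 45.07 µm, sd 2.5, cereal weight 0.25, n = 991) with pore
(4.28 ± 0.5 µm) and annulus increment (5.84 ± 1.0 µm) drawn independently
of diameter, so the OLS R² tends to 0 as n grows; sculpture is
scabrate/verrucate on cereal-mode grains and mixed otherwise. The modern
moss-pollster generator reuses the compositional machinery with 8
samples, mean PS 400 and a cereal fraction of 0.045. Every generating
parameter is returned in a truth record alongside the data, so recovery
tests compare against the truth, never against re-derived configuration.

What the generator does **not** emulate — and therefore what passing
tests do not demonstrate about real data: taphonomic loss and
differential preservation, non-polliniferous horizons (tephra, charcoal,
algal blooms), count-sheet heterogeneity across analysts, age-model
error from misidentified reversals, long-memory climate forcing beyond a
single sinusoid, and any spatial structure in the modern pollen rain.
Parameter-recovery results show the estimators are consistent under the
assumed sampling model, not that the assumptions hold in any core.

## Degenerate inputs and tie-breaks

Zero PS: composition flagged, no division. Empty measurement file:
empty table plus warning. All-equal grain sizes: single histogram bin
(bins left-closed, aligned at 0, counts conserved). Constant ratio
series: step contrast 0 with a warning, breakpoint arbitrary but
reported. Identical bootstrap series: difference 0, CI containing 0.
Ties in the step scan go to the oldest candidate age; mixture components
are reported sorted by ascending mean.

## Known limitations

- Concentration requires the counted fraction per sample; absent that
  metadata the value is a lower bound (fraction treated as 1.0).
- The edible-plant summary is only as good as the catalogue's
  interpretive edibility flags.
- The step-change scan finds a single breakpoint; multi-step histories
  need proper change-point methods.
- The percentile bootstrap undercovers slightly at very small sample
  numbers; the modern series should carry at least a handful of samples.
- Problem sizes in the test-suite simulations (e.g. 200 bootstrap
  coverage replicates at 500 resamples, mixtures at n = 1000–5000) were
  chosen as the smallest scales at which the checked asymptotics are
  expressed.
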