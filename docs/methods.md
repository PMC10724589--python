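# Methods

`nutriadequacy` estimates, for each agroecological zone (AEZ) of a rural
food system, how adequately local agricultural production could cover
the population's nutrient requirements. It is a supply-side (food
balance sheet style) analysis: the unit of account is production, not
observed consumption. The packaged defaults describe a three-zone
Ethiopian highland system (midland 1500–2300 m, highland 2300–3200 m,
upper highland 3200–3700 m) in which teff, wheat, sorghum, beans and
barley are the major crops and milk, eggs and honey the main livestock
products.

## Food-composition arithmetic

All crop composition is handled per 100 g on a dry-weight basis (as-
analysed profiles are converted through the moisture content).
Carbohydrate is obtained by difference:

- total carbohydrate = 100 − (moisture + crude protein + crude fat + ash)
- available carbohydrate = total carbohydrate − crude fiber

Gross energy uses Atwater factors, in kcal/100 g:

    E = 9·fat + 4·protein + 4·available carbohydrate + 2·fiber

Component energy shares are `100·f_x·m_x/E` and sum to 100 exactly when
`E` is computed internally. Inputs whose components overshoot 100 g/100 g
by more than 0.5 g are rejected; smaller overshoots (rounding noise in
published tables) are tolerated, with negative by-difference
carbohydrate clamped to zero under a warning.

Derived quantities (energy, molar ratios) are computed **per sample
before averaging**. This matters: the mean of per-sample phytate:iron
ratios is systematically larger than the ratio of the means on
right-skewed mineral data (Jensen's inequality), and the reporting
convention here follows the per-sample-first order. A regression test
documents the disagreement of the two conventions on skewed data.

## Mineral bioavailability screening

Phytate (myo-inositol hexakisphosphate) chelates divalent minerals;
molar ratios of phytate to iron, zinc and calcium index expected
absorption. Ratios use molar masses (g/mol) 660.04 (phytic acid),
55.845 (Fe), 65.38 (Zn) and 40.078 (Ca), stored in configuration.
Categories:

| ratio  | thresholds |
|--------|------------|
| Phy:Fe | < 1 desired; ≥ 1 above the critical value |
| Phy:Zn | < 5 high; 5–15 (closed interval) moderate; > 15 poor |
| Phy:Ca | unclassified — no accepted critical value is adopted |

The Phy:Zn boundary values 5 and 15 are assigned to the moderate
category because the category is defined as ratios *between* 5 and 15.

## Requirements

Reference nutrient intakes (RNI; sufficient for ~97.5% of a group) are
converted to estimated average requirements as

    EAR = RNI / (1 + 2·CV_req)

with a default requirement CV of 0.10 (the familiar RNI/1.2),
configurable per nutrient. Per-capita requirements weight group EARs by
the population age–sex structure. Pregnant and lactating fractions are
carved out of the childbearing female bands using the crude birth rate
(CBR, births/person/year):

- pregnant fraction of the population = CBR × 280/365 (280-day gestation)
- lactating fraction = CBR × 2 (two years of breastfeeding)

Because no information is available on how these fractions distribute
across age bands, they are allocated proportionally to each band's
share of childbearing-age women; adjusted shares still sum to 1. Iron
and zinc requirement tiers should be chosen for low bioavailability and
calcium for low animal-protein diets in this food system; tiers are
data the user loads, not code. The bundled aggregate per-capita EARs
for the study region are shipped as reference constants because the
underlying demographic requirement table is not public; they are inputs
to the adequacy step, never recomputed.

## Supply accounting

Seasonal production records (meher/belg/annual; kg for crops and honey,
liters for milk, egg counts) are summed to annual totals per zone and
item, converted to edible grams (milk density 1.03 g/mL, egg mass 50 g,
edible portion 1.0 for whole grains — all configurable), and divided by
the zone population and 365 to give per-person per-day supply of
energy and ten nutrients. Mass is also profiled into the WHO seven food
groups (grains/roots/tubers, legumes/nuts, dairy, flesh foods, eggs,
vitamin-A-rich and other fruits/vegetables); group percent shares sum
to 100 per zone. Crop-cut yield estimation (mean subplot mass per m²
scaled to kg/ha) is provided for survey workflows. Post-harvest losses
default to zero, with a single optional uniform loss fraction;
markets, cooking losses and intra-household allocation are out of
scope. Vitamin A, folate and livestock-product compositions in the
packaged item table are borrowed non-local defaults from generic food
composition tables and should be replaced with local values where
available.

## Adequacy: the EAR cut-point method

For each (zone, nutrient) the prevalence of a supply deficit is the
mass of an assumed intake distribution below the EAR. The distribution
is anchored at the per-capita supply mean with spread set by a
per-nutrient coefficient of variation: energy, protein, zinc and
calcium 0.25; vitamin A 0.45; vitamin C and iron 0.40 (within-subject
variation from the published literature); fat 0.25, folate 0.30 and
carbohydrate/fiber 0.25 are assumed defaults. The distribution is
normal for CV ≤ 0.3 and lognormal above.

Normal model: prevalence = Φ((EAR − mean)/σ). The SD is anchored to the
EAR (σ = CV·EAR) by default; σ = CV·mean is available via
configuration. The EAR anchor is the package default because, with the
bundled supply/EAR tables, it reproduces the reported deficit
percentages for energy, protein, fat and folate to one decimal, while
the mean anchor reproduces none of them.

Lognormal model (CV > 0.3): moment-matched to (mean, CV) with
σ_log² = ln(1 + CV²) and µ_log = ln(mean) − σ_log²/2; prevalence =
Φ((ln EAR − µ_log)/σ_log). No parameterization is prescribed by the
method's sources; moment matching keeps the two models comparable at
the same mean and CV. A seeded 10⁶-draw Monte-Carlo sampler exists only
as a test oracle; the production path is the closed form.

Report exports round percentages half-up to one decimal. Several
published deficit figures for this system (energy/midland, zinc,
calcium, iron, vitamins A and C) are not reproducible under any
cut-point parameterization tested and are deliberately not targets of
the test suite; the adequacy of those nutrients should be read
qualitatively.

## Inferential statistics

Group comparisons are gated on normality: Shapiro–Wilk per group at
α = 0.05; a single rejection routes the comparison to nonparametric
tests (the aggregation rule is a package choice; per-group testing on
the raw values is equivalent to testing group-centred residuals).
Constant groups, for which W is undefined, route to nonparametric with
a warning. Two groups use Student's t or Mann–Whitney U; three or more
use one-way ANOVA (with η² and Duncan letters) or Kruskal–Wallis.

Two-way ANOVA (crop × zone) uses Type II sums of squares because the
crop–zone design is inherently unbalanced (not all crops grow in all
zones); percent variance explained is SS_term/SS_total·100 with
SS_total the sum over terms plus residual.

Duncan's multiple range test computes least significant ranges from the
studentized-range distribution at protection level (1 − α)^(p−1) for
means p ranks apart (no lookup tables), uses the harmonic mean n for
unequal group sizes, applies the containment protection rule, and
emits letter displays. Quantiles are cached because the studentized-
range ppf is expensive. Chi-square contingency tests warn when any
expected count is below 5.

## Synthetic data generator

The generator emulates the study conditions so the pipeline is testable
without the unpublished survey data:

- **Crop samples.** Per-field zero-truncated normal draws at the
  locally analysed means/SDs (teff n=30, wheat 30, sorghum 24, bean 18,
  barley 18), assigned to zones per the growing pattern; zone-specific
  teff/wheat means (e.g. midland teff phytate ≈ 25% above highland) are
  applied when `aez_crop_effects` is on. Truncation at zero means the
  generator's true mean for low mean/SD fields (e.g. wheat calcium) is
  the truncated-normal mean, which the recovery tests use.
- **Production.** Cultivated area = households × mean holding (0.52 /
  0.76 / 0.80 ha per household by zone, 2000 households per zone by
  default, 4.6 persons/household); crop-mix land shares put 38% of
  midland and 18% of highland land under teff, beans only in the
  highland and barley monocropping in the upper highland; yields
  (teff 1.5, wheat 2.2, sorghum 2.3, bean 1.6, barley 1.8 t/ha, 15%
  CV) are typical smallholder magnitudes. Season splits follow the
  zones' meher/belg adoption patterns. Livestock output combines
  household counts with survey ownership fractions and productivities;
  printed dispersions are standard errors of means, and 180 milking
  days/year reflects seasonal, partial lactation (this reproduces
  realistic per-capita milk volumes of ~60 mL/day in the midland). The
  resulting midland mass profile is ≈ 78–80% cereals, ≈ 8% legumes and
  ≈ 9% dairy by construction.
- **Population.** A young, Ethiopian-style pyramid over nine age bands
  with near-even sex ratio and CBR 0.032; the synthetic requirement
  table scales plausible adult reference intakes by age and life stage
  and is explicitly not a reproduction of any published table.
- **Determinism.** One global seed; each generator consumes its own
  `SeedSequence` substream, so adding a stream never perturbs existing
  draws. `sd_scale = 0` collapses all distributions to their means,
  making the expected per-capita supply available in closed form;
  `end_to_end_fixture` writes all input CSVs together with the deficit
  table implied by the true means for pipeline-vs-analytic comparison.

What passing tests show — and do not show. Synthetic data reproduce
the assumed statistical structure (independent truncated-normal
compositions, deterministic area×yield production). Real survey data
carry spatial correlation, measurement error, market flows and
within-zone heterogeneity that the generator does not emulate, so
green tests validate the arithmetic and its implementation, not the
field accuracy of any particular estimate.

## Numerical choices and problem sizes

- Φ is evaluated by `scipy.stats.norm.cdf`; no simulation in production
  paths. Monte-Carlo oracles use 10⁶ draws and 3-SE tolerances.
- Composition-sum validation tolerance 0.5 g/100 g; share sums checked
  to 1e-9; deficit exports rounded half-up to one decimal.
- Test problem sizes (n = 30/crop for recovery, 2000 replicates for the
  type-I calibration, 100–150 random configurations for the Duncan
  enumeration checks) were chosen to give stable statistical assertions
  at desk scale.

## Known limitations

- Supply ≠ intake: no deconvolution of usual-intake distributions, no
  individual-level requirement distributions (the full probability
  method is out of scope).
- The bundled EARs are aggregate constants; users with demographic
  requirement tables should recompute them via the requirements module.
- Vitamin A and folate supply rest on borrowed composition defaults and
  are the least locally grounded nutrients in the packaged tables.
- The two-way ANOVA assumes homoscedastic normal errors; the package
  reports but does not correct for violations beyond the normality
  gate's routing.
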