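# Methods

This note documents the models, parameter choices and numerical decisions
behind `palaeofeed`, and what passing its tests does and does not establish.

## Diet-scale conversion

All three carbon proxies are mapped to one diet δ¹³C scale by additive
trophic-enrichment offsets: −5.1 ‰ for bone collagen, +1.5 ‰ for the dairy
C₁₆:₀ fatty acid (derived from a lipid–collagen spacing of −6.6 ‰ combined
with the collagen offset) and −14.5 ‰ for enamel bioapatite carbonate.
The conversion is exact addition with no rounding; the inverse map is used
by the synthetic generator so that all proxies agree on the diet scale by
construction. Round-trip identity holds to one IEEE rounding of the
intermediate sum (~1e-15 relative), which is how the tests assert it.

The offsets are single constants, not distributions: the package performs
offset-and-baseline comparison, deliberately not Bayesian mixing of food
sources. Real offsets vary with physiology and diet quality by a few
tenths of a per-mil; users can supply their own `OffsetTable`.

**Dairy identification.** An extract is ruminant dairy fat when
δ¹³C₁₈:₀ − δ¹³C₁₆:₀ ≤ −3.1 ‰, boundary inclusive. Species cannot be
resolved from the lipids, so dairy samples carry the generic taxon
`ruminant_dairy`, never `cattle`.

**Forest baseline.** Mean and *sample* standard deviation of
diet-converted deer collagen (≥ 2 samples required; sd 0 is legal).
Classification against the band mean ± k·sd (default k = 1) assigns
boundary points to `within`, so the three labels partition the line.

**"Average s.d."** in the per-tissue summary is the mean over sites (with
≥ 2 samples) of per-site sample standard deviations — a dispersion summary
robust to very unequal site sizes, as opposed to a pooled sd which a
handful of large sites would dominate.

## Intra-tooth seasonal model

Sequential enamel δ¹⁸O is fitted with A·cos(2π(x − x₀)/X) + M, with x the
position in mm from the enamel–root junction (ERJ). Positions increase
toward the occlusal surface and hypsodont crowns mineralize
occlusal-to-cervical, so the earliest enamel has the largest position.

Numerical choices:

* For fixed period X the model is linear in (a, b, M) with
  a·cos + b·sin; the fit therefore scans a dense X grid (241 candidates),
  refines the best cell by bounded scalar minimisation (xatol 1e-10), and
  reports A = √(a² + b²) > 0 with x₀ the position of a maximum reduced into
  [0, X). Among equal-residual candidates the smallest X wins.
* X is bounded to [0.3, 3] × crown height to prevent aliasing on sparse
  series; fits additionally require ≥ 5 increments spanning > 40% of the
  crown, and reject constant series (amplitude not identifiable).
* Recovery (asserted in tests): on noisy teeth (noise sd 0.3 ‰, 10–14
  increments) the median period error is ≲ 0.6 mm and the median circular
  phase error ≲ 0.3 mm over 200 teeth — comfortably inside the 2 mm /
  1.5 mm acceptance bounds.

**Cold-season windows.** Cold is where the fitted curve is below M − k·A
(default k = 0.5, i.e. the central third of each cycle, centred on the
δ¹⁸O minimum). The boundaries are solved in closed form, clipped to the
sampled interval, and the complement labelled warm, so windows tile the
interval exactly. The multiplier is configurable; 0.5 is this package's
operationalization of "approximately the cold season", not a measured
quantity.

**Crown clock.** With f the crown-height fraction (position/crown height),
dentine age = (1 − f)·12 + 6 months and enamel age = (1 − f)·12 + 12
months: the crown is assumed to form over 12 months, dentine mineralizing
6 months before the enamel at the same height. The percent form is I/O
only; internally fractions are used (the month maps are only dimensionally
sensible with fractions). The 6-month enamel−dentine lag is exact and
position-independent by construction. These are estimates of real tooth
development, which varies by individual and wear stage.

**Amplitude** (max − min) is computed on the *raw* δ¹³C increments, not on
fitted values.

## β values and plant source

β = (δ¹⁵N_Glx − δ¹⁵N_Phe) + trophic offset, with the offset −4.0 ‰ applied
in the direction diet = consumer + offset — the only direction that places
a woody-diet consumer's spacing above the plant value, consistent with
glutamate trophic enrichment. The offset is configurable.

Classification uses the modern reference distributions woody −9.3 ± 1.6 ‰
and herbaceous −5.4 ± 2.1 ‰. Woody: β ≤ −7.7 (woody mean + 1σ);
herbaceous: β ≥ −7.5 (herbaceous mean − 1σ); the narrow gap between is
`borderline`. Boundaries are inclusive with a 1e-9 ‰ tolerance that only
absorbs float rounding of the reference sums (δ¹⁵N is measured to
~0.1 ‰). Because the per-tooth statistic entering downstream correlation
is a convention choice, the summary emits mean, minimum and woody-call
fraction side by side.

## Spatial enrichment and the correlation screen

* **MFC**: nearest-node sampling of three forest-cover time-slice grids
  (7500/7250/7000 cal BP), then the arithmetic mean. Nearest-node is the
  default because the source reconstructions are already interpolated.
* **IDW**: weights d⁻ᵖ over all points; haversine km by default
  (geographic coordinates; a euclidean-degrees metric is available for
  strict replication of projection-agnostic workflows). Targets within
  1e-9 of a data point return that point's value exactly. Predictions are
  convex combinations, hence bounded by the data.
* **LOOCV**: p chosen from {1, 1.5, 2, 2.5, 3, 3.5, 4} by minimum
  leave-one-out RMSE, ties to the smallest p.
* **Isoscapes** interpolate per-site *medians* (robust to skewed per-site
  sampling), selected power per variable.
* **Screen**: Pearson/Spearman tests (scipy), Spearman's S reported as
  (n³ − n)(1 − ρ)/6 (the tie-corrected value R prints), one-way ANOVA
  across the three diet datasets (collagen, dairy, bioapatite per-tooth
  max/min — two records per tooth). Bonferroni uses the number of tests
  actually run in the screen; Benjamini–Hochberg step-up is applied to the
  same family. Degenerate (zero-variance) vectors are errors naming the
  vector, not silent NaNs.

## Synthetic worlds

The generator's defaults define the study conditions used throughout the
tests: 40 sites (10 samples per site per proxy, within-site sd 1.0 ‰) on a
west→east forest-cover gradient (60% → 85%, site noise sd 5), diet mean
per site = −25.0 ‰ + (−3.0 ‰) × forest-use fraction with forest use
proportional to MFC; 35 deer at diet −27.7 ± 1 ‰; 14 molars (7 sites × 2)
with crown height 45 mm, annual cosine A = 2 ‰, X = 30 mm, M = −6 ‰,
noise 0.3 ‰, 12 enamel and 6 dentine increments; dairy spacing
−4.3 ± 0.5 ‰; dentine β noise 0.5 ‰. The default `winter_woody` scenario
depresses cold-window enamel δ¹³C by 2.5 ‰ (below the −13.2 ‰ forest
reference) and draws cold-month dentine β from the woody distribution, so
every classification threshold is exercised from both sides. Tissue values
are produced by inverting the diet offsets, and fixtures are written
through the same readers/writers users consume, so the format contracts
are exercised too.

What the generator does **not** emulate: spatially autocorrelated forest
cover beyond a linear gradient, diagenesis and collagen preservation,
enamel-maturation smoothing of the input signal, analytical drift, or
inter-laboratory offsets. Passing the recovery tests therefore shows the
*statistical machinery* is sound at realistic noise levels — not that
archaeological data of this quality will always yield equally clean
signals.

## Degenerate inputs and tie rules

Row-level invariant violations reject the row with a machine-readable
diagnostic (accepted + rejected = total always); duplicate site ids and
missing mandatory columns refuse the whole file, since sites key
everything downstream. Constant tooth series, < 5 increments, < 40% crown
span, < 2 baseline samples, < 3 LOOCV points and zero-variance correlation
inputs are all explicit errors. Ties: smallest X in the cosine fit,
smallest p in LOOCV, boundary-inclusive thresholds exactly as printed.

## Problem sizes

The default test suite runs entirely on generated data: worlds of 40–61
sites, 200-tooth recovery experiments, and 100 replicate worlds for the
canopy-correlation rate — sizes chosen to estimate each rate or median
stably while keeping the whole suite in the tens of seconds. Replication
against the published supplementary tables (not redistributable here) is
wired through the same loaders and left as an explicit, data-gated check.

## Known limitations

* The cosine season scale assumes one stable annual cycle per tooth;
  migratory or multi-year signals violate it.
* The crown clock's 12-month crown formation and 6-month dentine lead are
  point estimates; month values should be read as relative, not calendar,
  ages.
* The borderline β band spans only 0.2 ‰, far below biological variance;
  it is a labelling convention for values the references cannot separate.
* IDW isoscapes are exact interpolators with no uncertainty surface;
  kriging is deliberately out of scope.
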