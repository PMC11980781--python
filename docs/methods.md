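# Methods

This note documents the models implemented in `streamtherm`, the
assumptions behind them, the numerical choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show.

## Data model and preparation

The unit of analysis is a macroinvertebrate sample linked to one modeled
stream temperature. Temperatures are MWMT (°C), the highest 7-day moving
average of daily maximum temperature, modeled per 1-km stream segment.
Linkage priority per sample: the modeled annual value for the sampling
year; else the long-term mean; else a value imputed from mean August
temperature through a Deming regression fitted across segments where
both quantities exist. Deming (errors-in-both-variables) regression is
used because both temperatures are model outputs with comparable error;
the error-variance ratio δ defaults to 1 (orthogonal regression) and is
exposed as a parameter, since no empirical ratio is available.

Preparation then drops samples with fewer than 150 counted individuals,
keeps one sample per stream segment (highest taxa richness, then most
recent year, then smallest sample id — fully deterministic), and rolls
child-taxon counts up into genus-or-coarser parents so that responses can
be estimated at every taxonomic rank. The low-count filter runs before
segment deduplication by default; the order is switchable because it
changes which sample is "richest" within a segment. Relative abundance of
a (possibly rolled-up) taxon uses the sample's pre-rollup total as the
denominator: rollup intentionally double-counts individuals across ranks,
and within a rank the sample total is the only consistent denominator.

Duplicate (sample, taxon) count rows are rejected rather than summed —
silent summing would mask upstream data errors. Taxa affected by uneven
identification effort (e.g. midges identified only to subfamily in older
datasets) cannot be detected automatically; they enter as an external
flag file.

## Per-taxon thermal response

Three measures, each capturing a different facet of the thermal niche:

1. **WA optimum and tolerance.** Abundance-weighted mean and SD of MWMT
   over samples. Zero-abundance samples carry zero weight, so restricting
   to occurrences is mathematically equivalent.
2. **Occurrence limits.** 10th/90th percentiles of MWMT at occurrences,
   using linear-interpolation quantiles (h = (n−1)p + 1). The convention
   is configurable; no single convention is canonical and differences are
   O(1/n).
3. **Response shape.** A binomial GAM of presence/absence on MWMT:
   penalized cubic B-splines (df = 8), intercept plus smooth, fitted by
   penalized IRLS. The penalty weight is selected by AIC over a
   log-spaced grid (10⁻¹…10⁴), which approximates automatic smoothness
   selection while remaining robust. Pointwise 90 % confidence bands come
   from the coefficient covariance on the logit scale mapped through the
   inverse link. If no spline fit converges the model falls back to a
   logistic regression with a quadratic term (logged, and visible in the
   fit's `method` field). Ubiquitous or absent taxa short-circuit to a
   constant curve. Ten equal-width binned occurrence frequencies are
   attached for plotting only.

### Shape classification

The seven curve categories are defined narratively in the bioassessment
literature; turning them into code requires explicit thresholds. The
decision sequence, with all thresholds exposed as keyword arguments:

1. *flat* if the POC range over the grid is < 0.02;
2. *unclear* if max POC < 0.15 while all CI widths are < 0.1 (a
   confidently negligible response). "Confidence interval < 0.1" is read
   as band *width*; half-width would halve the threshold, and the choice
   is flagged here because the narrative source is ambiguous;
3. *decreaser*/*increaser* if ≥ 75 % of grid-point slopes share a sign
   ("the majority of the gradient");
4. *unimodal* if the maximum is interior and both endpoints are < 25 % of
   the peak; *uni-decreaser* if the warm endpoint is < 25 % of peak but
   the cold endpoint retains ≥ 50 % (a cold shoulder with a sharp warm
   decline); *uni-increaser* mirrored;
5. otherwise *unclear*.

The 100-point evaluation grid and the 75 % / 25 % / 50 % thresholds
operationalize qualitative definitions; they are deliberately
configurable, and reviewer overrides of the automated shape are supported
and recorded.

## Preference classes

The rule table (°C bounds on WA optimum, p10, p90, plus excluded shapes)
is encoded with the printed strict/non-strict inequality semantics
preserved exactly — boundary values change assignments, and the engine is
tested against an independent literal transcription of the rules over a
dense grid. A taxon matching several rules takes the **last** match in
the order cool-warm, cool, cold, cold stenotherm, warm, warm stenotherm,
eurythermal; matching none is *inconclusive*; occurring in fewer than 30
samples leaves a taxon unassigned (weighted averages on fewer samples are
too noisy to classify). Parent taxa at genus, tribe, subfamily or family
rank with ≥ 2 assigned descendant taxa spanning ≥ 2 classes are flagged
as thermally variable; flagged taxa are excluded from community metrics
because their class label is not trustworthy.

## Preference metrics

Per sample and per class (and for four default cold-side/warm-side
combination groups): taxa richness, percent taxa, percent individuals —
33 metrics. Non-distinct taxa (a record whose descendant occurs in the
same sample) are excluded from richness-type metrics only; their
individuals still count in abundance metrics, where parent and child
records do not double-count the same individuals. Inconclusive and
unassigned taxa stay in denominators — they are real taxa and
individuals — but belong to no class; the percent-taxa denominator is all
distinct unflagged taxa.

## The MTTI

Weighted-averaging calibration and regression on OTUs. OTUs exist to
remove parent/child ambiguity: per sample, non-distinct records are
dropped, remaining taxa are mapped into OTUs (curated externally; the
synthetic generator emits a genus-level map) and summed, and samples
falling below 150 individuals after this are dropped.

Calibration estimates u_k and t_k per OTU by WA. The regression step
scores a sample as the relative-abundance-weighted mean of its OTUs'
optima, downweighting each OTU by 1/t_k² so broad-niche OTUs contribute
less. Tolerances are floored at the 5th percentile of the tolerance
distribution (absolute minimum 0.01 °C): without a floor, an OTU observed
in very few samples can have near-zero tolerance and dominate every
downweighted sum. The floor quantile is a parameter.

Double weighted averaging shrinks scores toward the gradient centre.
Classical deshrinking fits OLS of raw scores on observed MWMT
(x̂0 = a + b·x) and reports (x̂0 − a)/b; this makes the OLS of final
predictions on observations the identity (slope 1, intercept 0 —
algebraic, and tested to 1e-8), which is why classical deshrinking has no
systematic residual trend along the gradient. Inverse deshrinking
(regress x on x̂0, smaller global RMSEP but larger edge bias) and no
deshrinking are available as alternatives.

**Performance.** RMSEP, R² (squared Pearson correlation of predictions
and observations — identical to the simple-OLS R² here), and maximum
bias: the largest absolute mean residual across 10 equal-width segments
of the observed calibration gradient. Validation predictions reuse the
calibration segment edges so CAL and VAL biases are comparable. The
CAL/VAL split draws round(0.10 n) samples per (processing unit, MWMT
quintile) stratum, quintiles computed per unit; units smaller than the
bin count form a single stratum.

**Bootstrap cross-validation.** Each replicate refits the entire model on
a bootstrap resample and predicts the out-of-bag samples; per-sample
out-of-bag predictions are averaged across replicates and the pooled
pairs scored. This per-sample aggregation is one of two common
conventions (the other scores each replicate then averages statistics);
it was chosen because it yields one residual per sample and hence a
well-defined maximum bias. Replicates with degenerate fits are skipped
and counted.

## The synthetic generator

Defaults: 300 sites, 60 genus-level taxa (8 of them with two thermally
divergent sister species, optima ±2 °C around the genus), 500 counted
individuals per sample, MWMT gradient 4–31 °C with site density peaked
mid-gradient (normal(17, 5) with a 15 % uniform floor) and sparse
extremes, three processing units. Taxon responses are Gaussian in
expectation (peak abundance lognormal, tolerance uniform on 1.5–4 °C —
realistic niche breadths on an MWMT scale), thinned by a per-taxon
occupancy probability (0.55–0.95) so that even optimal sites miss taxa,
then subsampled to exactly 500 individuals by a multinomial draw —
mirroring fixed-count laboratory subsampling. 80 % of segments carry an
annual temperature, 15 % only a long-term mean, 5 % only mean August
temperature (exercising Deming imputation). A skewed site distribution,
spatial autocorrelation along stream networks, collection-protocol
differences, taxonomic misidentification and temperature-model error are
**not** simulated; passing recovery tests therefore demonstrates
correctness of the estimators under their own assumptions, not field
accuracy.

"Interior" taxa in recovery statements are those whose true optimum lies
within the central 80 % of *sampled* MWMT values (10th–90th percentile of
site temperatures). Outside that range WA optima carry irreducible
truncation bias — sites cover only one flank of the niche — which is a
property of weighted averaging itself, not of the implementation; on the
default scenario this bias reaches 2–3 °C for taxa with optima near 27 °C
and would dominate an RMSE taken over the nominal gradient.

## Problem sizes and numerical choices

Default test/verification sizes — 300 sites, ~80 taxa, 100 bootstrap
replicates, 100-point GAM grids — were chosen so the complete pipeline
runs in seconds while leaving all statistical conclusions stable across
seeds. Ties in segment deduplication and rule resolution are broken
deterministically (documented above); weighted statistics are computed
vectorized in float64 and agree with naive loops to 1e-12; the WA model
requires ≥ 2 OTUs and ≥ 10 samples and raises on an all-zero sample row,
a zero-variance observed gradient, or a singular deshrinking regression.

## Known limitations

- GAM confidence bands are conditional on the selected penalty weight
  (no selection uncertainty), as is standard for penalized smoothers.
- The rule thresholds are tied to Pacific Northwest temperature
  standards; applying them to other regions requires editing the rule
  table, which is plain data in `streamtherm.rules`.
- WA optima inherit bias from uneven site distributions along the
  gradient; no binning correction is applied.
- The OTU map is an input. The package validates and applies it but
  cannot judge its taxonomic quality.
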