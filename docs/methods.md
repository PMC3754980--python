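# Methods

## Data model

The central object is the feature table: an (features × samples) matrix of
integrated ion intensities with per-feature m/z (Daltons, singly charged
positive mode assumed) and retention time (seconds).  Missingness is
distinct from numeric zero; the default file dialect coerces zeros to
missing because untargeted peak-extraction software writes 0 for "not
detected", and the presence filter presupposes a presence/absence notion.
Duplicate m/z values are allowed only at distinct retention times (two ions
can share a mass but elute apart); duplicate (m/z, rt) pairs are rejected.
Feature identifiers are `mz@rt` strings.

Intensities are treated as given.  Instrument vendors do not define units
for integrated ion counts, and whether internal-standard normalization was
applied upstream cannot be recovered from a feature table, so no
normalization is imposed.

## Univariate screen

1. **Presence filter**: keep features non-missing in ≥ 50 % of samples
   (all samples, not per group — the filter models detectability of the ion,
   not group structure).
2. **Tests**: two-tailed two-sample t-test per feature, Welch by default
   (configurable pooled), on the raw scale and on log2 intensities.
   Missing values are excluded pairwise; log2 of a non-positive value is
   missing (an optional offset supports data with true zeros).  Features
   with fewer than two present values in a group are untestable and are
   excluded from the multiple-testing denominator, keeping the p-value set
   well defined.  No imputation is ever performed at this stage.
3. **FDR**: Benjamini–Hochberg step-up, implemented directly (sort, reject
   all i ≤ max{i : p(i) ≤ i·q/m}; adjusted values are the monotone minimum
   of p(i)·m/i capped at 1, so flags coincide with q-value thresholding by
   construction).  Defaults: q = 0.05 on the raw scale, q = 0.2 on the log2
   scale.  The intersection of the two significant lists — features robust
   to the transformation choice — seeds the downstream stages.
4. **Direction**: higher/lower in cases from raw group means of present
   values.

The dual-scale design trades power for robustness: skewed intensity
distributions can make either single scale anticonservative for individual
features, and requiring significance on both suppresses outlier-driven
hits.

## Ion-correlation clustering

Pearson correlations are computed feature-by-feature with
pairwise-complete observations (minimum overlap 10 samples; constant
features yield missing r).  Correlations are taken on the log2 scale by
default — multiplicative intensity noise is closer to additive there — with
a raw-scale option.

Given discriminatory seed features, the threshold rule is strict r > 0.81,
an empirical regime in which ions of one chemical typically correlate.
Seeds correlated with at least one feature are retained; connected
components of the **seed–seed** edge graph define clusters; retained seeds
with only non-seed correlates are "Independent".  Shared-satellite merging
is deliberately not used: two unrelated seeds often co-correlate with a
single background feature, and merging through it would fuse chemically
distinct clusters.  (In the transcribed reference cluster table, one seed
printed inside a cluster shares no printed seed–seed edge with the other
members; under the seed-edge rule implemented here it would be labelled
independent.  The fixture preserves the printed labels and is used only for
count and format checks.)

Satellites attach to a cluster ranked by their best correlation against the
cluster's seeds.  Output ordering is canonical (seeds by m/z then rt), so
results do not depend on input order.  Raising the threshold refines the
partition: clusters can only split or shrink.

## Adduct annotation

Monoisotopic masses are summed from element masses (C 12 exactly,
H 1.0078250319, N 14.0030740052, O 15.9949146221, S, P, Na, K, Cl) over a
Hill-style formula parser.  Five singly charged positive-mode adducts are
searched, with electron-corrected cation shifts:

| form | shift (Da) |
|---|---|
| M+H | +1.007276 |
| M+Na | +22.989218 |
| M+K | +38.963158 |
| M+H−H₂O | −17.003289 |
| M+H+2H₂O | +37.028406 |

The two-water form is interpreted as a water cluster on the protonated ion,
symmetric to the water-loss form; this interpretation is a package
decision and is stated here prominently because conventions differ.
A match requires |ppm| ≤ tolerance with signed
ppm = 10⁶·(observed − theoretical)/theoretical; hits sort by |ppm| with
ties broken by adduct order.  The default tolerance is 10 ppm (realistic
FTMS accuracy for plasma surveys); 9 and 5 ppm are common stricter presets,
and a `METLIN_BATCH_ADDUCTS` preset drops M+K for four-form batch searches.
`background_match_rate` estimates the chance-match probability of a
configuration by drawing uniform m/z over the acquisition window — a
reminder that single matches at 10 ppm carry limited evidence; correlation
batches and confirmed standards are needed for identification.

## Multivariate panel

**Scaling**: autoscaling (unit variance) by default — the metabolomics
convention for OPLS-DA — with mean-centring as the alternative; constant
features are an error under autoscale.

**OPLS-DA** (Trygg–Wold): with class contrast y (±1, centred), weight
w ∝ Xᵀy; per orthogonal component, p = Xᵀt/(tᵀt) with t = Xw,
w_orth = p − (wᵀp)w normalized, t_orth = X·w_orth, deflate
X ← X − t_orth·p_orthᵀ (w recomputed from the deflated matrix each round);
then NIPALS PLS1 predictive components on the deflated matrix.  Per
component, explained variance is (tᵀt)(pᵀp) divided by the total scaled sum
of squares; fractions are non-negative and sum to ≤ 1.  With zero
orthogonal components the predictive scores equal plain PLS-DA scores
exactly.

**Selection**: features rank by Σₐ loading²ₐ · variance_explainedₐ over
predictive components; top ⌈fraction·p⌉ (default 5 %) are selected, ties
broken by m/z.  This variance-weighted loading statistic is the package's
operationalization of "principal component loading" ranking; a raw
first-component |loading| alternative is a one-line change in user code via
the exposed loadings.

**LDA**: two-class linear discriminant with shrinkage-regularized pooled
covariance (Ledoit–Wolf `auto` default); an unregularized fit with
features ≥ samples is refused with advice rather than silently
pseudo-inverted.

**Cross-validation**: stratified 10-fold and leave-one-out.  The engine
takes any fit/predict classifier; the shipped `PanelClassifier` performs
median imputation, scaling, OPLS fitting, loading selection and LDA
entirely inside `fit`, so fold accuracies are free of selection leakage.
Multivariate stages median-impute missing values (training-fold statistics
only); the univariate screen never does.  Kernel SVMs are not implemented —
the classifier contract accepts any external implementation.

## Synthetic cohort generator

Defaults emulate the motivating study design: 26 cases / 19 controls,
positive-mode ESI window m/z 85–850, three adduct features per chemical.
Latent chemical abundance on log2 scale: a_ji = μ_j + β_j·1[case] + ε with
ε ~ N(0, σ_between²), μ_j ~ N(20, 2²) (ion counts around 10⁶), σ_between = 1.
A fraction (default 10 %) of chemicals is differential with
|β| = effect_size_log2 (default 1.0) and random sign.  Each chemical's
adduct efficiencies are drawn once from a Dirichlet(2,…,2), giving unequal
but perfectly co-varying ion heights; per-measurement noise
N(0, σ_adduct²), σ_adduct = 0.2, reproduces the empirical within-chemical
correlation regime (median pairwise r > 0.81 at the defaults).  Observed
m/z adds N(0, (3 ppm · mz/10⁶)²) mass error.  Missingness is MNAR
(censoring below the 5 % global intensity quantile) plus 5 % MCAR dropout.
One `numpy` Generator seeded from the config drives the whole run;
identical seeds give bit-identical tables.

What the generator does **not** emulate: isotope envelopes, in-source
fragments beyond the fixed adduct set, retention-time drift, batch effects,
heteroscedastic intensity-dependent noise, and correlated biology between
chemicals (chemicals are independent given group).  Passing recovery tests
therefore demonstrates correctness of the statistical machinery under the
model's assumptions, not performance on any real cohort; in particular
between-chemical biological correlation would make cluster/chemical
agreement an upper bound.

`synthetic_metabolite_db` builds database records with neutral masses
spaced ≥ 25 ppm apart (labelled synthetic), which makes round-trip top-hit
annotation identifiable; real databases contain isomers and near-isobars
that no mass-only search can resolve.

## Numerical choices and degenerate inputs

- Fisher exact two-sided p sums hypergeometric point probabilities
  ≤ (1 + 10⁻⁷)·P(observed), computed via log-gamma; a degenerate margin
  returns p = 1 with a warning.  Exhaustive enumeration agrees to 10⁻¹²
  for tables with N ≤ 60.
- Zero variance in both t-test groups: t = 0, p = 1 on equal means, p = 0
  otherwise.
- BH with all-missing p-values returns empty rejections; q-values of
  untestable features stay missing.
- Correlation of a constant feature is missing, never 0; diagonal is 1.
- Ties at exactly r = 0.81 are excluded (strict inequality).
- Pipeline stages write through `.partial` temp files renamed on success;
  the manifest hashes every artifact, and reruns under a fixed seed are
  byte-identical.

## Problem sizes in the test suite

Recovery tests run 45-sample cohorts with 100–250 chemicals (300–750
features), 60 null replicates for FDR calibration, and 20 label
permutations for the classifier null — sizes at which every Monte-Carlo
tolerance used is comfortably wider than the simulation error, chosen as
the smallest designs that make the checked properties identifiable.

## Known limitations

- Mass-only annotation cannot distinguish isomers; the package reports all
  matches within tolerance and the background match rate, but confident
  identification requires MS/MS or coelution evidence outside its scope.
- The screen is unadjusted two-group testing; covariate-adjusted models are
  out of scope by design.
- apLCMS-style input is assumed already aligned and quantified; no raw
  spectral processing (mzML parsing, peak picking) is included.
- The printed reference tables ship as transcription fixtures for count and
  format checks only; the underlying cohort data are not public, so the
  published headline counts (e.g. 1680 → 1168 features) are not
  recomputable and are exercised only as ordering/shape properties.
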