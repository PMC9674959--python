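# Methods

## Assay model

A variant's function is expressed relative to wild type after background
subtraction:

    function_pct = 100 · (Variant − EV) / (WT − EV)

where `Variant`, `WT` and `EV` are protein-normalized uptake means
(counts/µg) and EV is the empty-vector background. The statistic is affine
invariant (a shared additive background cancels) and is deliberately *not*
clipped: genuinely dead transporters can measure slightly below 0 %WT and
hyperactive ones above 100 %WT, and both tails carry information.

Replicates are aggregated hierarchically: technical wells are averaged
within each biological replicate first, and the reported mean and SEM are
taken across biological-replicate means (SEM = sd/√n with n = biological
replicates; a single biological replicate yields mean with SEM reported
missing, with a warning). When control records are supplied, each
biological replicate is normalized against the WT/EV means of the *same*
replicate within its batch, so plate-level drift cancels pairwise. Whether
the original analysis paired replicates this way is not documented
anywhere we could consult; pairing is this package's choice, and the
unpaired raw-count comparison remains available through the lower-level
functions.

Significance versus wild type uses the classical equal-variance two-sample
t test (Welch available via `equal_var=False`), Bonferroni-corrected:
significant ⇔ p < α/n_tests (α = 0.05; n = 150 gives 3.3 × 10⁻⁴).

LOF is called strictly: `function_pct < threshold`, default 20 %WT — the
level below which transporter deficiency risk rises. A variant at exactly
20 %WT is classified functional; the threshold is a parameter everywhere.

Group summaries use one-way ANOVA with Tukey HSD post-hoc comparisons;
localization-class summaries use Welch's ANOVA with Games-Howell post-hoc
comparisons, the appropriate pair under unequal class variances. Groups or
classes with n < 2 are excluded from tests (with a warning) but still
summarized descriptively. Tukey comes from statsmodels and Welch/
Games-Howell from pingouin; both are cross-checked in the test suite
against an independent implementation (scipy's Tukey HSD) and a hand-coded
studentized-range oracle respectively.

## Features

Sequence features depend only on (position, ref, alt, topology) — never on
assay outcomes, so there is no label leakage by construction: residue
position; one-hot indicators for the five region classes (N-term, TM, EL,
IL, C-term) and for each of the 25 individual regions; Kyte–Doolittle
Δhydropathy (alt − ref); Δ side-chain charge at pH 7 (His neutral);
Δresidue volume (Zamyatnin); BLOSUM62 substitution score; indicators for
proline introduced and glycine removed. Property tables are plain
dictionaries and can be swapped.

Structure features come from a Cα coordinate model with per-residue
confidence (pLDDT read from the B-factor field of AlphaFold-style files):
contact number (Cα neighbours within 10 Å, a documented constant),
relative burial (contact number normalized by the model maximum), and the
distance from the residue to the first principal axis through the
coordinate centroid — for an elongated transporter this axis approximates
the membrane normal through the translocation pore, so small values flag
pore-lining residues. Residues without coordinates yield missing values.

External predictor scores join by variant label as pass-through features.
Missing scores are mean-imputed from training rows and flagged by a
binary `<name>_missing` indicator, keeping the full panel usable without
dropping variants or predictors.

Scaling is per-feature min–max to [0, 1], fitted on training rows only
(inside each evaluation split, so no test leakage); held-out values are
clipped into [0, 1]; constant columns scale to 0 and are reported. Because
all features share the [0, 1] range, penalized-model coefficients are
directly comparable and double as feature importances.

## Classifier and evaluation protocol

The classifier minimizes mean negative log-likelihood plus an L1 penalty,
`(1/n)·Σ NLL + λ·Σ|βⱼ|`, intercept unpenalized. Fits delegate to
scikit-learn's liblinear path (with `C = 1/(nλ)`); because liblinear only
approximates an unpenalized intercept, a final one-dimensional Newton pass
re-solves the intercept exactly at the fitted coefficients. At λ = 0 the
unpenalized fit matches a maximum-likelihood oracle (statsmodels) to 10⁻⁴
in the test suite; the linear analogue (mean squared error + λ‖β‖₁)
matches OLS normal equations to 10⁻⁶ at λ = 0. Solver tolerance is 10⁻⁷,
and all fits are deterministic given (X, y, λ).

λ is tuned by inner repeated stratified cross-validation maximizing mean
validation AUC over a log-spaced grid (default 50 values, 10⁻⁴…10⁰·⁵,
5 folds × 5 repeats; the shape is configurable and smaller shapes are used
where runtime matters — see Problem sizes). AUC ties break toward the
larger λ, preferring the sparser model.

Evaluation is repeated random subsampling: independent stratified
train/test splits (stratification by label prevents degenerate folds at
n = 150 with ~25% prevalence), scaling and tuning on the training side
only, and the probability cutoff chosen **on training scores** by
maximizing sensitivity + specificity over all midpoints between adjacent
sorted unique scores (±∞ sentinels; ties to the smallest cutoff). Choosing
the cutoff on test scores is a known leaky variant and remains available
behind `cutoff_on_test=True` for comparison. Metrics at the cutoff (LOF is
the positive class): sensitivity, specificity, PPV, NPV, accuracy, MCC;
ratios with zero denominators are reported missing, never 0. AUC is the
rank (Mann–Whitney) statistic with midrank ties, identical to the area
under the empirical ROC curve. Aggregates are mean ± SD over splits, and a
fixed seed makes the whole report bit-reproducible.

Default split fractions: 0.2 for model selection, 0.3 (105/45) available
for a final-classifier evaluation, and a 110/40 split for the regression —
all exposed as `test_fraction`. Tree-ensemble baselines (random forest,
gradient boosting) run under the identical protocol through a generic
fit/predict adapter with fixed seeds and default hyperparameters.

Localization uses two independent one-vs-rest classifiers — full membrane
localization vs {mixed, intracellular}, and full intracellular retention
vs {membrane, mixed} — because mixed-localization variants are genuinely
intermediate and a single three-class model would force an ordering.

## Saturation scores and carrier frequencies

Every residue admits 19 substitutions; the saturation table has 19·L rows
(10,583 at L = 557). The classifier's LOF probability p maps to a
normalized functional score by a piecewise-linear calibration pinning the
decision cutoff c to 0.5:

    s = 0.5 + 0.5·(c − p)/c        for p ≤ c
    s = 0.5 − 0.5·(p − c)/(1 − c)  for p > c

This is the simplest strictly decreasing bijection of [0, 1] with s(0)=1,
s(c)=0.5, s(1)=0, so thresholding s at 0.5 is *exactly* the probability
rule p < c; scores near 1 or 0 indicate confident calls. It is a display
calibration, not a probability. Saturation prediction uses the feature set
available for every possible substitution (sequence features by default).

Carrier frequency per population pools the allele frequencies of LOF
variants, q = Σ AF, treating unobserved frequencies as 0 — a *minimum*
estimate — and reports the Hardy–Weinberg heterozygote fraction
2q(1 − q) as 1:N with N = round(1/frequency). The 2q approximation is
available via `formula="2q"`; at q ≤ 0.003 the two differ negligibly.

## Synthetic-study generator

The generator emulates the statistical structure the analysis assumes,
with known ground truth. Defaults mirror a 150-variant study of a
557-residue transporter:

- **Topology/sequence**: 25 regions (1 N-term, 12 TM, 6 EL, 5 IL, 1
  C-term) scaled from a canonical layout (large EL1; EL2/EL5 only a few
  residues); TM segments sampled hydrophobic-biased, loops hydrophilic, so
  hydropathy co-varies with topology as in a real transporter.
- **Truth**: a sparse coefficient vector on 0–1 scaled sequence features —
  class_TM +2.0, blosum62 −3.0, delta_hydropathy −1.5 — chosen to be
  common and non-collinear so recovery is well posed. Latent liability
  ℓ = β₀ + xᵀβ*; true function = 120·logistic(−ℓ), which spans a realistic
  range with tails slightly below 0 and above 100 %WT. β₀ is set from the
  liability quantile so that the design fraction (25%) of variants falls
  below the 20 %WT threshold in true function.
- **Assay**: replicate uptake counts are the affine inverse of the
  normalization (WT 1000, EV 50 counts/µg), with Gaussian noise of 8 %WT
  between biological replicates and 4 %WT-equivalent between technical
  wells — SEMs of ~4–6 %WT, typical of transport assays. Batches of 30
  variants each carry their own WT/EV controls.
- **Localization**: intracellular below 30 %WT true function, mixed below
  65, membrane above, then 15% label noise — localization associates with,
  but does not determine, function.
- **Groups**: a 10-variant Clinical analogue enriched ~8× for LOF by
  weighted sampling; remaining variants spread evenly over 7 further
  groups. **Allele frequencies**: truncated exponential (scale 5 × 10⁻⁴,
  capped at 0.01 — all variants rare), with population presence patterns
  by group.
- **External predictor stand-ins**: two score tables equal to the liability
  plus unit Gaussian noise, 5% missing.

Identical (config, seed) reproduces a study byte for byte. What the
generator does *not* emulate: real residue identities or region
boundaries, nucleotide-level mutation processes, realistic site-frequency
spectra, linkage between variants, plate/position effects, or real protein
structures (an ideal helix suffices for structure features). Passing tests
therefore demonstrate that the pipeline's machinery is correct and
well-calibrated under its own assumptions — not that the feature set
suffices for any particular real protein.

## Numerical choices and degenerate inputs

- Strict `<` at the LOF threshold; boundary value is functional.
- Cutoff ties resolve to the smallest candidate; all-identical scores
  resolve to the −∞ sentinel (everything predicted positive).
- Constant feature columns scale to 0; the L1 penalty removes them.
- Splits that lose a class on either side are re-drawn (bounded retries,
  then an error); single-class label vectors are rejected outright.
- Zero-denominator metrics are missing (NaN), never silently 0.
- Duplicate variant labels, duplicate score-table keys, and variants
  measured in more than one batch are hard errors — silent deduplication
  hides data problems.

## Problem sizes

Test-suite and acceptance-script runs use reduced protocol shapes chosen
as sensible defaults for exploratory runs: inner tuning 3 folds × 1 repeat
over 15 grid points, 30–100 outer iterations, and 30–100 generator seeds
for calibration checks. The protocol-shape parameters are all explicit
arguments, so the full 5 × 5 × 50 tuning and any number of iterations are
one call away.

## Known limitations

- The packaged transporter fixtures are synthetic stand-ins (canonical
  dimensions only); quantities depending on residue identity or exact
  region boundaries will differ from the real protein until the UniProt
  records are substituted.
- The replication checks against the published 150-variant panel require
  the per-variant supplementary table, which is not redistributed; the
  corresponding test stays red until it is transcribed locally.
- The exact published feature list is configurable rather than fixed: the
  registry realizes the named categories (sequence / structure /
  prediction) with standard descriptors, and alternates can be swapped in.
- Probability calibration of the classifier is not attempted; the
  functional score is a monotone display transform, not a calibrated
  probability of function.
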