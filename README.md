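# octnvep

Protein-specific variant effect prediction for the carnitine transporter
OCTN2 (*SLC22A5*), whose biallelic loss-of-function (LOF) variants cause
Carnitine Transporter Deficiency — a rare, treatable, potentially lethal
inborn error of metabolism. Most cataloged OCTN2 missense variants lack a
clinical interpretation, so a transporter-specific functional predictor is
directly useful for newborn-screening follow-up and variant curation.

The package implements the full analysis as a reusable, tested pipeline:

1. **Assay processing** — raw radiolabeled-uptake replicates to percent of
   wild-type function, `f = 100·(Variant − EV)/(WT − EV)` (EV = empty-vector
   background), technical wells averaged within each biological replicate
   before the mean ± SEM; per-variant *t* tests against wild type with
   Bonferroni correction (α = 0.05/n); LOF called when `f < 20 %WT`;
   ancestry-group summaries (ANOVA + Tukey HSD) and localization-class
   summaries (Welch's ANOVA + Games-Howell).
2. **Featurization** — sequence features (membrane-topology region classes,
   Kyte–Doolittle Δhydropathy, Δcharge, Δvolume, BLOSUM62 score,
   proline/glycine flags), structure features (pLDDT, Cα contact number,
   relative burial, pore-axis distance), and pass-through scores from
   external predictors; every feature min–max scaled to [0, 1] on training
   rows only.
3. **Prediction** — L1 (lasso) penalized logistic regression minimizing
   `(1/n)·Σᵢ −log P(yᵢ|xᵢ,β) + λ‖β‖₁` (intercept unpenalized), λ tuned by
   inner cross-validated AUC; evaluated by repeated stratified random
   train/test subsampling with the classification cutoff chosen on training
   scores by maximizing sensitivity + specificity; metric suite AUC,
   accuracy, sensitivity, specificity, PPV, NPV, MCC; a penalized linear
   model for quantitative %WT prediction (R²); random-forest and
   gradient-boosting baselines under the same protocol; two one-vs-rest
   localization classifiers (full membrane localization; full intracellular
   retention).
4. **Saturation and population genetics** — predictions for all 19·L
   possible missense variants (19 × 557 = 10,583 for OCTN2), mapped to a
   normalized functional score `s ∈ [0, 1]` with the decision cutoff pinned
   at 0.5 (`s > 0.5` ⇔ predicted functional); per-residue tolerance
   profiles; minimum carrier frequencies per population from pooled LOF
   allele frequencies `q` as the Hardy–Weinberg heterozygote fraction
   `2q(1 − q)`, reported as 1:N.
5. **Synthetic studies** — a generator that emulates a complete
   characterization study (sequence, 25-region topology, replicate-level
   assay data, localization, ancestry groups, rare allele frequencies) from
   a known sparse ground truth, so every stage is testable offline.

The packaged OCTN2 sequence/topology fixtures are *synthetic stand-ins*
with the canonical dimensions (557 residues; 25 regions: N-terminus, 12
transmembrane domains, 6 extracellular and 5 intracellular loops,
C-terminus); swap in the UniProt O76082 records for production use.

## Worked example

```python
import numpy as np
from octnvep import TuneConfig, feature_importance, repeated_evaluation, simulate_study

study = simulate_study(seed=7)                    # 150 variants, L=557
y = study.characterized["lof"].to_numpy()         # 40 LOF (27%)
tune = TuneConfig(grid=tuple(np.logspace(-4, 0, 15)), folds=3, repeats=1)
report = repeated_evaluation(study.X_raw, y, iterations=30,
                             test_fraction=0.2, seed=7, tune=tune)
print(report.aggregate().round(3))
print(feature_importance(report).head(3).round(3))
```

prints (abridged):

```
              mean     sd
auc          0.986  0.014
accuracy     0.929  0.039
mcc          0.834  0.087

                  median     q1     q3  frac_nonzero
class_TM           3.424  3.129  3.839         1.000
blosum62          -2.304 -3.973 -1.786         1.000
delta_hydropathy  -2.041 -3.119 -1.498         0.933
```

The held-out AUC of 0.986 ± 0.014 says the classifier separates LOF from
functional variants almost perfectly at this signal-to-noise; the three
features with nonzero median coefficients are exactly the generator's true
predictors, with the expected signs (transmembrane location damaging,
conservative and hydropathy-preserving substitutions protective).

The `examples/` directory holds one short script per capability (assay
processing, classifier evaluation, saturation scan, carrier frequencies),
and the `octnvep` command line exposes the same stages
(`simulate`, `assay`, `featurize`, `train`, `evaluate`, `predict-all`,
`localization`, `carriers`, `report`), each writing a JSON run manifest
with input checksums and seeds.

## Layout

- `src/octnvep/core.py` — sequences, topology maps, variant nomenclature
- `src/octnvep/assay.py` — uptake normalization, LOF calls, group statistics
- `src/octnvep/features.py` — feature extraction and 0–1 scaling
- `src/octnvep/model.py` — penalized models, resampling evaluation, metrics
- `src/octnvep/saturation.py` — saturation scans, carrier frequencies
- `src/octnvep/synth.py` — synthetic-study generator
- `src/octnvep/cli.py` — thin command-line front end
- `docs/methods.md` — model assumptions, parameter choices, limitations
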