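"""Train and evaluate the LOF classifier on a synthetic study.

Generates a full characterization study (150 variants on a 557-residue
transporter), evaluates an L1-penalized logistic regression under repeated
stratified subsampling, and prints the held-out metric suite and the
top-ranked features by coefficient magnitude.
"""

import numpy as np

from octnvep import TuneConfig, feature_importance, repeated_evaluation, simulate_study

study = simulate_study(seed=7)
y = study.characterized["lof"].to_numpy()
print(f"study: {len(y)} variants, {y.sum()} LOF ({100*y.mean():.0f}%)")

tune = TuneConfig(grid=tuple(np.logspace(-4, 0, 15)), folds=3, repeats=1)
report = repeated_evaluation(
    study.X_raw, y, iterations=30, test_fraction=0.2, seed=7, tune=tune
)
print("\nheld-out performance over 30 random 120/30 splits (mean +/- SD):")
print(report.aggregate().round(3))

print("\ntop features by |median coefficient| across splits:")
print(feature_importance(report).head(6).round(3))
print()
print("AUC near 1 reflects the generator's strong signal-to-noise; features")
print("with nonzero medians are the ones the L1 penalty consistently keeps.")
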