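"""Prioritizing non-loss-of-function disease genes with a lasso model.

An L1-penalized logistic regression separates genes with non-LOF
(dominant-negative or gain-of-function) mechanisms from plain LOF genes.
On synthetic data with two known signal features the pipeline — k-NN
imputation, scaling, cross-validated lambda tuning, importance scaling and
threshold derivation — should recover the signals and produce calibrated
decision cutoffs.
"""

import numpy as np
import pandas as pd

from assembly_buffer import (
    Preprocessor,
    derive_thresholds,
    fit_lasso_cv,
    gen_logistic_features,
    predict,
    variable_importance,
)

X, y = gen_logistic_features(
    2000, 10, (2.0, -2.0), sparsity=2, missing_rate=0.05, seed=1
)
df = pd.DataFrame(X, columns=[f"feat_{j}" for j in range(10)])

prep = Preprocessor(k_neighbors=5).fit(df)
Xp = prep.transform(df)
fit = fit_lasso_cv(Xp, y, seed=1, feature_names=prep.feature_names_)
fit.preprocessor = prep

print(f"selected lambda: {fit.chosen_lambda:.5f}")
print(f"nonzero coefficients: {int((fit.coef != 0).sum())} of {len(fit.coef)}")

imp = variable_importance(fit)
order = np.argsort(imp)[::-1]
print("top features by importance (|beta| scaled to [0, 1]):")
for j in order[:4]:
    print(f"  {fit.feature_names[j]:8s} importance {imp[j]:.2f}  "
          f"beta sign {'+' if fit.coef[j] > 0 else '-' if fit.coef[j] < 0 else '0'}")

scores = predict(fit, Xp)["score"].to_numpy()
fit.t1, fit.t2 = derive_thresholds(scores, y.astype(bool))
print(f"\nthresholds: T1 (max Youden J) = {fit.t1:.3f}, "
      f"T2 (100% specificity) = {fit.t2:.3f}")
flags = predict(fit, Xp)
print(f"genes above T1: {int(flags['above_T1'].sum())}, "
      f"above T2: {int(flags['above_T2'].sum())} of {len(flags)}")
print(
    "\nfeat_0 and feat_1 carry the real signal and should rank top-2; "
    "scores above T2 are the most confident non-LOF calls (no known LOF "
    "gene scores that high)."
)
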