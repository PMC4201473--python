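"""Patient-specific biomarker selection on synthetic drug-response data.

Builds a small expression matrix whose response depends on two genes -- one
with a constant effect, one whose effect grows with a modulator (e.g., a
sensitivity index) -- picks hyperparameters by 3-fold CV, fits one robust
local model per sample, and prints the biomarker table plus the estimated
varying coefficient.
"""

import numpy as np

from robustprofiler import (
    KernelSpec,
    PenaltySpec,
    biomarker_frequency,
    compute_sample_weights,
    fit_all_targets,
    kfold_cv,
    make_grid,
)

rng = np.random.default_rng(0)
n, p = 60, 15
X = rng.standard_normal((n, p))
m = rng.uniform(0, 1, n)                       # modulator in [0, 1]
# gene 0: constant effect; gene 1: effect proportional to the modulator
y = 2.0 * X[:, 0] + 3.0 * m * X[:, 1] + 0.3 * rng.standard_normal(n)

grid = make_grid(X, y, m, n_lambda=5, deltas=(1.0,), bandwidths=[0.2, 0.5])
cv = kfold_cv(X, y, m, grid, k=3, seed=0, outlier=None)
lam, delta, h = cv.selected
print("CV selected: lambda=%.3f delta=%.1f bandwidth=%.2f" % (lam, delta, h))

weights = compute_sample_weights(X, y, seed=0)
fits = fit_all_targets(X, y, m, KernelSpec(h), PenaltySpec(lam=lam, delta=delta),
                       outlier=weights)
table = biomarker_frequency(fits, threshold=0.80,
                            feature_ids=["g%d" % j for j in range(p)])
print(table.sort_values("selection_fraction", ascending=False).head(4).to_string(index=False))

coef1 = np.array([tf.fit.coefficients[1] for tf in fits])
lo, hi = m < 0.33, m > 0.67
print("\nestimated g1 coefficient: %.2f at low m, %.2f at high m (truth: 3m)"
      % (coef1[lo].mean(), coef1[hi].mean()))
print("estimated g0 coefficient: %.2f overall (truth: 2)"
      % np.mean([tf.fit.coefficients[0] for tf in fits]))
print(
    "\nBoth true genes are flagged biomarkers (selected in >80% of models),\n"
    "while noise genes are not, and the local fits trace g1's\n"
    "modulator-dependent effect."
)
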