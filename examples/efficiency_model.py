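"""Barcode sequence biases write efficiency: generate editing scores in
which folding stability of the assembled pegRNA suppresses editing, then
recover that structure effect with the 85-feature lasso regression
(one-hot mono- and dinucleotide content + rescaled folding energy)."""

import numpy as np

from engram import build_feature_matrix, fit_lasso_cv

rng = np.random.default_rng(5)
barcodes = sorted({"".join(rng.choice(list("ACGT"), 5)) for _ in range(500)})
X, bounds = build_feature_matrix(barcodes)  # 85 columns, last = stability

# synthetic ground truth: stable folds (structure feature near 0) edit worse,
# plus a small first-position A preference
w = np.zeros(85)
w[0] = 0.25       # pos1_A
w[-1] = 1.0       # rescaled folding energy
y = X @ w + 0.5 + rng.normal(0, 0.05, len(barcodes))

model, report = fit_lasso_cv(X, y, folds=10, train_fraction=0.7, seed=5,
                             mfe_bounds=bounds)
print(f"{len(barcodes)} barcodes, {X.shape[1]} features, "
      f"{len(report['train_idx'])}/{len(report['test_idx'])} train/test split")
print(f"held-out Pearson r = {report['pearson_r']:.3f}")
print(f"penalty chosen by 10-fold CV: {model.penalty:.4g}")
print(f"weight on folding-stability feature: {model.mfe_weight:+.3f} "
      f"(generating weight {w[-1]:+.1f})")
nz = int((model.weights != 0).sum())
print(f"non-zero weights: {nz}/85 (lasso sparsity)")
print("A positive stability weight says less-stable pegRNA folds (feature "
      "closer to 1) carry higher editing scores.")
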