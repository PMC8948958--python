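"""Fit the Indica-vs-Sativa OPLS-DA model and inspect it.

One predictive component separates the two genetics classes; one
orthogonal component absorbs within-class spectral variation unrelated to
the separation.  R2X fractions say how much of the (Pareto-scaled) X
variation each part models; Q2 is the 7-fold cross-validated predictive
fraction; the Hotelling T-squared ellipse flags score-plot outliers at the
95% level.
"""

import trichospec as ts

dataset = ts.generate_dataset(ts.default_design(seed=1))
clean = ts.preprocess_dataset(dataset)
labels = clean.labels["genetics"].tolist()

model = ts.fit_oplsda(clean.matrix, labels, n_pred=1, n_orth=1)
cv = ts.cross_validate(clean.matrix, labels, 1, 1, ts.CvConfig(k=7, seed=1))

print(f"R2X[1] (predictive):  {100 * model.r2x_pred[0]:.1f}% of X variation")
print(f"R2Xo[1] (orthogonal): {100 * model.r2x_orth[0]:.1f}% of X variation")
print(f"R2Y (fit):            {model.r2y_cum:.3f}")
print(f"Q2 (7-fold CV):       {cv.q2:.3f}")

import numpy as np
scores = np.column_stack([model.T[:, 0], model.To[:, 0]])
ellipse = ts.hotelling_limit(scores, alpha=0.05)
inside = ellipse.contains(scores).mean()
print(f"scores inside the 95% Hotelling ellipse: {100 * inside:.1f}%")

matrix = ts.confusion(labels, cv.predictions)
matrix.fisher_p = ts.fisher_rxc(matrix.counts, seed=1)
print()
print(matrix.to_text())
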