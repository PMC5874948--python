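"""Train the weighted Poisson-Lasso passing-rate model and predict.

Simulates a 700-unit QA study from the generative model (mean failing rate
3%, six true effects among 90 features), selects the penalty by 5-fold
cross-validation on 500 training units, and evaluates out-of-sample
residuals on the 200 held-out units.
"""

import numpy as np

from virtualqa import cross_validate, fit, predict_passing_rate
from virtualqa.evaluation import residual_report
from virtualqa.synthetic import GeneratorConfig, generate_qa_dataset

ds, truth = generate_qa_dataset(GeneratorConfig(n_units=700, seed=0))
train, test = ds.subset(np.arange(500)), ds.subset(np.arange(500, 700))

cv = cross_validate(train, k=5, seed=0, n_lambda=40, lambda_min_ratio=1e-3)
model = fit(train, cv.lambda_min)
print(f"lambda_min = {cv.lambda_min:.4g}; "
      f"{len(model.selected)} of {len(model.feature_names) - 1} features "
      f"selected")

true_support = {n for n, b in zip(truth.feature_names, truth.beta)
                if b != 0 and n != "intercept"}
print(f"true effects recovered: "
      f"{sorted(true_support & set(model.selected))}")

rep = residual_report(model, test, bound_pp=3.5)
print(f"held-out: {rep.summary()}")
print("Residuals are predicted minus measured passing rate in percentage "
      "points; the mean absolute residual is the model's typical error on "
      "unseen plans.")

pred = predict_passing_rate(model, test.X[:5])
meas = [r.passing_rate for r in test.records[:5]]
for unit, p, m in zip(test.records[:5], pred, meas):
    flag = "  <- review" if p < 93.5 else ""
    print(f"  {unit.unit_id}: predicted {p:6.2f}%  measured {m:6.2f}%{flag}")
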