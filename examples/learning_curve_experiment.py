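"""How many measured QA plans does the model need?

Runs the repeated-subsampling learning-curve experiment on a 400-unit
synthetic study: for each training size, 10 seeded repetitions of
CV-fit / held-out evaluation, with t-based 95% confidence intervals.
"""

from virtualqa.evaluation import learning_curve
from virtualqa.synthetic import GeneratorConfig, generate_qa_dataset

ds, _ = generate_qa_dataset(GeneratorConfig(n_units=400, seed=19))
curve = learning_curve(ds, sizes=[30, 60, 120, 240], repetitions=10,
                       seed=2, cv_folds=3, n_lambda=15,
                       lambda_min_ratio=1e-2)

print("size  train err (pp)      test err (pp)")
for s, tm, th, em, eh in zip(curve.sizes, curve.train_mean,
                             curve.train_ci_halfwidth, curve.test_mean,
                             curve.test_ci_halfwidth):
    print(f"{s:4d}  {tm:5.2f} +/- {th:4.2f}     {em:5.2f} +/- {eh:4.2f}")
print(f"plateau: no mean test-error improvement beyond "
      f"{curve.plateau_size()} training units")
print("Errors are mean absolute residuals of predicted vs measured passing "
      "rate; the plateau size estimates the QA history needed before more "
      "measurements stop improving the model.")
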