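"""Model evaluation: residual-error reports and learning-curve experiments.

The residual of a unit is *predicted minus measured* gamma passing rate in
percentage points (over-prediction is positive).  The learning curve repeats,
for each training-set size, a seeded subsample / CV-fit / held-out-error
cycle and summarizes mean and t-based 95% confidence interval of the error
across repetitions — the experiment used to ask "how many measured plans does
the model need before the testing error stops improving?".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .plans import QADataset
from .poisson_lasso import (
    LassoFit,
    cross_validate,
    fit,
    predict_passing_rate,
    DegenerateDataError,
)

__all__ = ["ResidualReport", "LearningCurve", "residual_report",
           "learning_curve", "plateau_size"]


@dataclass
class ResidualReport:
    unit_ids: list[str]
    residuals_pp: np.ndarray          # predicted - measured passing rate
    bound_pp: float
    max_abs_pp: float
    mean_abs_pp: float
    fraction_within_bound: float
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray

    def summary(self) -> str:
        return (f"n={len(self.unit_ids)}  max|res|={self.max_abs_pp:.2f} pp  "
                f"mean|res|={self.mean_abs_pp:.2f} pp  "
                f"within {self.bound_pp:g} pp: "
                f"{100 * self.fraction_within_bound:.1f}%")


@dataclass
class LearningCurve:
    sizes: np.ndarray
    train_mean: np.ndarray
    train_ci_halfwidth: np.ndarray
    test_mean: np.ndarray
    test_ci_halfwidth: np.ndarray
    repetitions: int
    seed: int

    def plateau_size(self) -> int:
        """First size whose mean test error is within one CI half-width of
        the largest size's mean test error."""
        final_mean = self.test_mean[-1]
        final_hw = self.test_ci_halfwidth[-1]
        for s, m in zip(self.sizes, self.test_mean):
            if m <= final_mean + final_hw:
                return int(s)
        return int(self.sizes[-1])


def residual_report(fit_: LassoFit, dataset: QADataset,
                    bound_pp: float = 3.5,
                    holdout_mask=None,
                    histogram_bins: int = 20) -> ResidualReport:
    """Residuals of predicted vs measured passing rates, in percentage points.

    When ``holdout_mask`` is given, only those units are reported (the
    out-of-sample convention); an empty holdout is an error.
    """
    if holdout_mask is not None:
        idx = np.nonzero(np.asarray(holdout_mask))[0]
        if idx.size == 0:
            raise ValueError("empty holdout")
        dataset = dataset.subset(idx)
    predicted = predict_passing_rate(fit_, dataset.X)
    measured = np.array([r.passing_rate for r in dataset.records])
    residuals = predicted - measured
    counts, edges = np.histogram(residuals, bins=histogram_bins)
    return ResidualReport(
        unit_ids=[r.unit_id for r in dataset.records],
        residuals_pp=residuals,
        bound_pp=bound_pp,
        max_abs_pp=float(np.max(np.abs(residuals))),
        mean_abs_pp=float(np.mean(np.abs(residuals))),
        fraction_within_bound=float(np.mean(np.abs(residuals) <= bound_pp)),
        histogram_counts=counts,
        histogram_edges=edges,
    )


def _mean_abs_residual_pp(fit_: LassoFit, dataset: QADataset) -> float:
    predicted = predict_passing_rate(fit_, dataset.X)
    measured = np.array([r.passing_rate for r in dataset.records])
    return float(np.mean(np.abs(predicted - measured)))


def learning_curve(dataset: QADataset, sizes, repetitions: int = 10,
                   seed: int = 0, cv_folds: int = 5, n_lambda: int = 30,
                   lambda_min_ratio: float = 1e-3) -> LearningCurve:
    """Training/testing error versus training-set size.

    For each size and repetition: sample a training subset without
    replacement (seeded), pick lambda by K-fold CV on the subset, fit, and
    evaluate mean absolute passing-rate residual (pp) on both the subset
    (training error) and the untouched remainder (testing error).  Confidence
    intervals are t-based 95% across repetitions.  Sizes too small for CV are
    skipped with a warning.
    """
    if repetitions < 2:
        raise ValueError("repetitions must be >= 2 (CI undefined otherwise)")
    sizes = np.asarray(sorted(int(s) for s in sizes))
    n = len(dataset)
    usable, skipped = [], []
    for s in sizes:
        if s < max(cv_folds, 2) or s >= n:
            skipped.append(int(s))
        else:
            usable.append(int(s))
    if skipped:
        warnings.warn(f"sizes skipped (too small for {cv_folds}-fold CV or "
                      f">= n={n}): {skipped}", RuntimeWarning)
    if not usable:
        raise ValueError("no usable sizes")

    rng = np.random.default_rng(seed)
    train_err = np.full((len(usable), repetitions), np.nan)
    test_err = np.full((len(usable), repetitions), np.nan)
    for rep in range(repetitions):
        for si, s in enumerate(usable):
            perm = rng.permutation(n)
            tr, te = perm[:s], perm[s:]
            assert not set(tr) & set(te)
            train = dataset.subset(tr)
            test = dataset.subset(te)
            try:
                cv = cross_validate(train, k=cv_folds, seed=int(rng.integers(2**31)),
                                    n_lambda=n_lambda,
                                    lambda_min_ratio=lambda_min_ratio)
                f = fit(train, cv.lambda_min)
            except DegenerateDataError as exc:
                warnings.warn(f"size {s} rep {rep} skipped: {exc}",
                              RuntimeWarning)
                continue
            train_err[si, rep] = _mean_abs_residual_pp(f, train)
            test_err[si, rep] = _mean_abs_residual_pp(f, test)

    tcrit = stats.t.ppf(0.975, repetitions - 1)

    def _summ(err):
        mean = np.nanmean(err, axis=1)
        sd = np.nanstd(err, axis=1, ddof=1)
        return mean, tcrit * sd / np.sqrt(repetitions)

    tr_m, tr_hw = _summ(train_err)
    te_m, te_hw = _summ(test_err)
    return LearningCurve(
        sizes=np.asarray(usable),
        train_mean=tr_m, train_ci_halfwidth=tr_hw,
        test_mean=te_m, test_ci_halfwidth=te_hw,
        repetitions=repetitions, seed=seed,
    )


def plateau_size(curve: LearningCurve) -> int:
    return curve.plateau_size()
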