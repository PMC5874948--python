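"""Weighted Poisson regression with L1 (Lasso) regularization.

The model: a QA unit with complexity vector x (intercept first) fails at rate
fr(x) = exp(beta' x); observed failing counts y_i over D_i detectors are
Poisson with mean D_i * fr(x_i).  Up to constants, the maximum a-posteriori
estimate under a zero-mean Laplace prior minimizes

    L(beta) = - sum_i w_i * ( fr_i * beta'x_i - exp(beta'x_i) )  +  lam * ||beta||_1

with fr_i = y_i / D_i and observation weights w_i = D_i / D_max.  Following
universal Lasso practice the intercept is left unpenalized, and non-intercept
columns are standardized to weighted mean 0 / variance 1 internally so the
penalty treats indicator and continuous features alike; coefficients are
reported on the original scale.

The solver is cyclic coordinate descent with soft-thresholding on the
iteratively reweighted quadratic approximation (the standard penalized-GLM
scheme), with active-set sweeps, warm starts along the regularization path,
and a step-halving safeguard that keeps the objective non-increasing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .plans import QADataset

__all__ = [
    "LassoFit",
    "RegularizationPath",
    "CVResult",
    "KKTReport",
    "objective",
    "fit",
    "lambda_max",
    "fit_path",
    "cross_validate",
    "predict_failing_rate",
    "predict_passing_rate",
    "kkt_report",
    "poisson_deviance",
    "save_fit",
    "load_fit",
    "AlignmentError",
    "DegenerateDataError",
]

_ETA_CLIP = 30.0          # linear-predictor clamp inside the solver
_OBJ_TOL = 1e-8           # relative objective change declaring convergence
_MAX_SWEEPS = 100_000     # total coordinate-sweep budget per fit
_INNER_TOL = 1e-10        # max coefficient change ending an inner CD cycle


class AlignmentError(ValueError):
    """Feature names of a prediction input do not match the fit."""


class DegenerateDataError(ValueError):
    """Dataset cannot identify a model (too few rows, constant features,
    no failing detectors anywhere)."""


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class LassoFit:
    """A fitted weighted Poisson-Lasso model.

    ``beta`` is on the original feature scale, aligned with
    ``feature_names`` (index 0 = intercept).  ``objective`` is the minimized
    value of the penalized objective (penalty measured on the internally
    standardized coefficients, which is what the solver minimizes).
    """

    feature_names: list[str]
    beta: np.ndarray
    lam: float
    objective: float
    n_iter: int
    converged: bool
    d_max: float
    # solver internals, kept for optimality checks and serialization
    beta_std: np.ndarray = field(repr=False, default=None)
    col_mean: np.ndarray = field(repr=False, default=None)
    col_scale: np.ndarray = field(repr=False, default=None)
    config_hash: str | None = None
    stratum: dict | None = None

    @property
    def selected(self) -> list[str]:
        """Names of non-intercept features with nonzero coefficients."""
        return [n for n, b in zip(self.feature_names[1:], self.beta[1:])
                if b != 0.0]

    @property
    def intercept(self) -> float:
        return float(self.beta[0])


@dataclass
class RegularizationPath:
    lambdas: np.ndarray
    fits: list[LassoFit]

    def __len__(self):
        return len(self.fits)


@dataclass
class CVResult:
    lambdas: np.ndarray
    mean_deviance: np.ndarray
    se_deviance: np.ndarray
    lambda_min: float
    lambda_1se: float
    fold_assignments: np.ndarray
    seed: int


@dataclass
class KKTReport:
    violations: list[str]
    max_zero_excess: float      # max(|grad| - lam) over zero coefficients
    max_nonzero_residual: float  # max|grad + lam*sign(beta)| over nonzero

    @property
    def ok(self) -> bool:
        return not self.violations


# ---------------------------------------------------------------------------
# Design-matrix plumbing
# ---------------------------------------------------------------------------

def _design(dataset: QADataset):
    X = dataset.X
    if dataset.feature_names[0] != "intercept" or not np.allclose(X[:, 0], 1.0):
        raise ValueError("dataset features must start with an intercept column")
    return X, dataset.failing_rates, dataset.weights


def _standardize(X: np.ndarray, w: np.ndarray):
    """Weighted standardization; intercept column untouched.  Zero-variance
    columns get scale 0 and are frozen at coefficient 0."""
    wn = w / w.sum()
    mean = wn @ X
    var = wn @ (X - mean) ** 2
    scale = np.sqrt(var)
    mean[0], scale[0] = 0.0, 1.0
    usable = scale > 1e-12
    Xs = np.zeros_like(X)
    Xs[:, usable] = (X[:, usable] - mean[usable]) / scale[usable]
    Xs[:, 0] = 1.0
    return Xs, mean, scale, usable


def _check_dataset(dataset: QADataset):
    if len(dataset) < 2:
        raise DegenerateDataError("need at least 2 records")
    X, fr, w = _design(dataset)
    if np.all(fr * w == 0):
        raise DegenerateDataError("no failing detectors anywhere")
    if X.shape[1] < 2 or not np.any(X[:, 1:].std(axis=0) > 0):
        raise DegenerateDataError("no non-constant features")
    return X, fr, w


def _nll_std(Xs, fr, w, beta):
    eta = Xs @ beta
    if np.any(np.abs(eta) > 700):
        raise OverflowError("linear predictor overflow")
    return -float(w @ (fr * eta - np.exp(eta)))


def _objective_std(Xs, fr, w, beta, lam):
    return _nll_std(Xs, fr, w, beta) + lam * float(np.abs(beta[1:]).sum())


def objective(beta, dataset: QADataset, lam: float) -> float:
    """The penalized objective on the original feature scale:
    -sum w_i (fr_i beta'x_i - exp(beta'x_i)) + lam * sum_{j>=1} |beta_j|.
    """
    X, fr, w = _design(dataset)
    beta = np.asarray(beta, dtype=float)
    eta = X @ beta
    if not np.all(np.isfinite(eta)) or np.any(np.abs(eta) > 700):
        raise OverflowError("non-finite or overflowing linear predictor")
    return (-float(w @ (fr * eta - np.exp(eta)))
            + lam * float(np.abs(beta[1:]).sum()))


# ---------------------------------------------------------------------------
# Core solver (standardized space)
# ---------------------------------------------------------------------------

def _soft(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def _fit_std(Xs, fr, w, lam, usable, beta0=None,
             obj_tol=_OBJ_TOL, max_sweeps=_MAX_SWEEPS):
    """IRLS + coordinate descent in standardized space.  Returns
    (beta_std, objective, total_sweeps, converged)."""
    n, P = Xs.shape
    if beta0 is not None:
        beta = beta0.copy()
    else:
        beta = np.zeros(P)
        beta[0] = np.log(max((w @ fr) / w.sum(), 1e-12))
    idx_all = [j for j in range(P) if usable[j]]
    sweeps = 0
    converged = False
    prev_obj = _objective_std(Xs, fr, w, beta, lam)

    for _outer in range(200):
        beta_start = beta.copy()
        eta = np.clip(Xs @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        v = w * mu
        z = eta + (fr - mu) / mu
        r = z - Xs @ beta
        vx2 = (Xs * Xs).T @ v

        def sweep(indices):
            nonlocal sweeps, r
            sweeps += 1
            max_d = 0.0
            for j in indices:
                denom = vx2[j]
                if denom <= 0:
                    continue
                num = Xs[:, j] @ (v * r) + beta[j] * denom
                bj = _soft(num, lam) / denom if j > 0 else num / denom
                d = bj - beta[j]
                if d != 0.0:
                    r -= d * Xs[:, j]
                    beta[j] = bj
                    ad = abs(d)
                    if ad > max_d:
                        max_d = ad
            return max_d

        # active-set cycling: converge on the current support, then verify
        # with a full sweep; repeat until the full sweep changes nothing.
        while sweeps < max_sweeps:
            active = [j for j in idx_all if j == 0 or beta[j] != 0.0]
            while sweeps < max_sweeps:
                if sweep(active) < _INNER_TOL:
                    break
            if sweep(idx_all) < _INNER_TOL:
                break

        # the quadratic approximation can overshoot the true objective:
        # halve the step back toward the iterate this outer loop started from
        new_obj = _objective_std(Xs, fr, w, beta, lam)
        halvings = 0
        while new_obj > prev_obj + 1e-12 and halvings < 30:
            beta = 0.5 * (beta + beta_start)
            new_obj = _objective_std(Xs, fr, w, beta, lam)
            halvings += 1

        if abs(prev_obj - new_obj) <= obj_tol * (abs(prev_obj) + 1e-10):
            converged = True
            prev_obj = new_obj
            break
        prev_obj = new_obj
        if sweeps >= max_sweeps:
            break

    if not converged:
        warnings.warn("coordinate descent did not converge "
                      f"within {max_sweeps} sweeps", RuntimeWarning)
    # snap boundary artifacts (e.g. at lambda == lambda_max, float drift in
    # the score can leave coefficients of order 1e-12) to exact zero
    tiny = np.abs(beta[1:]) < 1e-10
    beta[1:][tiny] = 0.0
    return beta, prev_obj, sweeps, converged


# ---------------------------------------------------------------------------
# Public fitting API
# ---------------------------------------------------------------------------

def _destandardize(beta_std, mean, scale, usable):
    beta = np.zeros_like(beta_std)
    nz = usable.copy()
    nz[0] = False
    beta[nz] = beta_std[nz] / scale[nz]
    beta[0] = beta_std[0] - float(beta[nz] @ mean[nz])
    return beta


def fit(dataset: QADataset, lam: float, *, beta0_std=None,
        config_hash: str | None = None, stratum: dict | None = None,
        max_sweeps: int = _MAX_SWEEPS) -> LassoFit:
    """Minimize the penalized weighted Poisson objective at one lambda.

    Deterministic given inputs.  Non-convergence within the sweep budget
    returns a fit flagged ``converged=False`` (with a RuntimeWarning) rather
    than raising.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    X, fr, w = _check_dataset(dataset)
    Xs, mean, scale, usable = _standardize(X, w)
    beta_std, obj, sweeps, conv = _fit_std(
        Xs, fr, w, lam, usable, beta0=beta0_std, max_sweeps=max_sweeps)
    return LassoFit(
        feature_names=list(dataset.feature_names),
        beta=_destandardize(beta_std, mean, scale, usable),
        lam=float(lam),
        objective=float(obj),
        n_iter=sweeps,
        converged=conv,
        d_max=float(dataset.d_max),
        beta_std=beta_std,
        col_mean=mean,
        col_scale=scale,
        config_hash=config_hash,
        stratum=stratum,
    )


def lambda_max(dataset: QADataset) -> float:
    """Smallest lambda whose minimizer keeps every non-intercept coefficient
    at zero: the largest absolute weighted score of any standardized feature
    at the intercept-only solution."""
    X, fr, w = _check_dataset(dataset)
    Xs, _, _, usable = _standardize(X, w)
    mu0 = (w @ fr) / w.sum()
    score = Xs.T @ (w * (fr - mu0))
    score[0] = 0.0
    score[~usable] = 0.0
    lmax = float(np.abs(score).max())
    if lmax <= 0:
        raise DegenerateDataError("all features uncorrelated with outcomes; "
                                  "lambda_max is undefined")
    return lmax


def fit_path(dataset: QADataset, n_lambda: int = 100,
             lambda_min_ratio: float = 1e-4, **fit_kwargs
             ) -> RegularizationPath:
    """Warm-started fits on a log-spaced lambda grid from lambda_max down."""
    lmax = lambda_max(dataset)
    lambdas = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)
    fits = []
    beta0 = None
    for lam in lambdas:
        f = fit(dataset, lam, beta0_std=beta0, **fit_kwargs)
        beta0 = f.beta_std
        fits.append(f)
    return RegularizationPath(lambdas=lambdas, fits=fits)


def poisson_deviance(fit_or_beta, dataset: QADataset) -> float:
    """Mean weighted Poisson deviance of a fit on a dataset:
    (2/n) * sum_i w_i [ fr_i log(fr_i/mu_i) - (fr_i - mu_i) ], with the
    fr log fr term zero for perfectly passing units."""
    beta = fit_or_beta.beta if isinstance(fit_or_beta, LassoFit) else fit_or_beta
    X, fr, w = _design(dataset)
    mu = np.exp(np.clip(X @ np.asarray(beta, dtype=float), -700, 700))
    term = np.where(fr > 0, fr * np.log(np.where(fr > 0, fr, 1.0) / mu), 0.0)
    return float(2.0 * np.mean(w * (term - (fr - mu))))


def cross_validate(dataset: QADataset, k: int = 10, seed: int = 0,
                   n_lambda: int = 100, lambda_min_ratio: float = 1e-4
                   ) -> CVResult:
    """K-fold cross-validation of the regularization path.

    The lambda grid is computed once on the full dataset; each fold's model
    is fit on the remaining folds (warm-started along the path) and scored by
    mean weighted Poisson deviance on the held-out fold.  Folds with no
    failing detectors in training are skipped with a warning.
    """
    n = len(dataset)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"n={n} < k={k}")
    lmax = lambda_max(dataset)
    lambdas = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)

    rng = np.random.default_rng(seed)
    assignment = np.repeat(np.arange(k), int(np.ceil(n / k)))[:n]
    rng.shuffle(assignment)

    dev = []
    for fold in range(k):
        test_idx = np.nonzero(assignment == fold)[0]
        train_idx = np.nonzero(assignment != fold)[0]
        train = dataset.subset(train_idx)
        test = dataset.subset(test_idx)
        try:
            _check_dataset(train)
        except DegenerateDataError as exc:
            warnings.warn(f"fold {fold} skipped: {exc}", RuntimeWarning)
            continue
        row = []
        beta0 = None
        X, fr, w = _design(train)
        Xs, mean, scale, usable = _standardize(X, w)
        for lam in lambdas:
            beta_std, _, _, _ = _fit_std(Xs, fr, w, lam, usable, beta0=beta0)
            beta0 = beta_std
            row.append(poisson_deviance(
                _destandardize(beta_std, mean, scale, usable), test))
        dev.append(row)
    if not dev:
        raise DegenerateDataError("every CV fold was degenerate")
    dev = np.asarray(dev)
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(dev.shape[0]) \
        if dev.shape[0] > 1 else np.zeros_like(mean_dev)
    i_min = int(np.argmin(mean_dev))
    thresh = mean_dev[i_min] + se_dev[i_min]
    i_1se = int(np.nonzero(mean_dev <= thresh)[0][0])  # largest lambda first
    return CVResult(
        lambdas=lambdas,
        mean_deviance=mean_dev,
        se_deviance=se_dev,
        lambda_min=float(lambdas[i_min]),
        lambda_1se=float(lambdas[i_1se]),
        fold_assignments=assignment,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _align(fit: LassoFit, x) -> np.ndarray:
    from .features import FeatureVector

    if isinstance(x, FeatureVector):
        if x.names != fit.feature_names:
            missing = [n for n in fit.feature_names if n not in x.names]
            extra = [n for n in x.names if n not in fit.feature_names]
            raise AlignmentError(
                f"feature mismatch: missing {missing[:5]}, extra {extra[:5]}")
        return x.values
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != len(fit.feature_names):
        raise AlignmentError(
            f"expected {len(fit.feature_names)} features, got {x.shape[-1]}")
    return x


def predict_failing_rate(fit: LassoFit, x):
    """Predicted failing rate exp(beta' x); unclipped (can exceed 1)."""
    xv = _align(fit, x)
    return np.exp(xv @ fit.beta)


def predict_passing_rate(fit: LassoFit, x):
    """Predicted gamma passing rate in percent: 100 * (1 - min(fr, 1))."""
    fr = predict_failing_rate(fit, x)
    return 100.0 * (1.0 - np.minimum(fr, 1.0))


# ---------------------------------------------------------------------------
# Optimality certificate
# ---------------------------------------------------------------------------

def kkt_report(fit: LassoFit, dataset: QADataset, tol: float = 1e-4
               ) -> KKTReport:
    """Check the subgradient optimality conditions of the penalized objective
    at the fitted coefficients (in the solver's standardized space)."""
    X, fr, w = _design(dataset)
    usable = fit.col_scale > 1e-12
    Xs = np.zeros_like(X)
    Xs[:, usable] = ((X[:, usable] - fit.col_mean[usable])
                     / fit.col_scale[usable])
    Xs[:, 0] = 1.0
    mu = np.exp(np.clip(Xs @ fit.beta_std, -700, 700))
    grad = Xs.T @ (w * (mu - fr))
    lam = fit.lam
    violations = []
    max_zero, max_nonzero = 0.0, 0.0
    scale_ref = max(lam, np.abs(grad).max(), 1.0)
    for j, name in enumerate(fit.feature_names):
        if not usable[j]:
            continue
        if j == 0 or fit.beta_std[j] != 0.0:
            resid = abs(grad[j] + (0.0 if j == 0 else
                                   lam * np.sign(fit.beta_std[j])))
            max_nonzero = max(max_nonzero, resid)
            if resid > tol * scale_ref:
                violations.append(
                    f"{name}: stationarity residual {resid:.3g}")
        else:
            excess = abs(grad[j]) - lam
            max_zero = max(max_zero, excess)
            if excess > tol * scale_ref:
                violations.append(
                    f"{name}: |subgradient| exceeds lambda by {excess:.3g}")
    return KKTReport(violations=violations, max_zero_excess=max_zero,
                     max_nonzero_residual=max_nonzero)


# ---------------------------------------------------------------------------
# Serialization (single JSON text document)
# ---------------------------------------------------------------------------

def save_fit(fit: LassoFit, path) -> None:
    doc = {
        "format": "virtualqa-model-v1",
        "feature_names": fit.feature_names,
        "beta": fit.beta.tolist(),
        "lambda": fit.lam,
        "objective": fit.objective,
        "n_iter": fit.n_iter,
        "converged": fit.converged,
        "d_max": fit.d_max,
        "beta_std": fit.beta_std.tolist(),
        "col_mean": fit.col_mean.tolist(),
        "col_scale": fit.col_scale.tolist(),
        "config_hash": fit.config_hash,
        "stratum": fit.stratum,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_fit(path) -> LassoFit:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "virtualqa-model-v1":
        raise ValueError(f"{path}: not a virtualqa model document")
    return LassoFit(
        feature_names=doc["feature_names"],
        beta=np.asarray(doc["beta"]),
        lam=doc["lambda"],
        objective=doc["objective"],
        n_iter=doc["n_iter"],
        converged=doc["converged"],
        d_max=doc["d_max"],
        beta_std=np.asarray(doc["beta_std"]),
        col_mean=np.asarray(doc["col_mean"]),
        col_scale=np.asarray(doc["col_scale"]),
        config_hash=doc.get("config_hash"),
        stratum=doc.get("stratum"),
    )
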