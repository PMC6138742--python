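"""Composite fatty-acid classification score.

A sparse L1-penalized logistic regression separates germfree (y = 0) from
colonized (y = 1) mice from log2-transformed, standardized fatty-acid
concentrations.  The experiment (batch) indicator enters as a fixed,
*unpenalized* covariate so that batch offsets common to all species cannot
leak into the sparse signature.  The penalty is chosen by leave-one-out
cross-validation of the binomial deviance with the one-standard-error rule:
the largest lambda whose mean held-out deviance is within one standard error
of the minimum.  The classification score of a new sample is the predicted
probability of the colonized class; low scores are germfree-like.

The optimizer is an iteratively-reweighted least squares (IRLS) outer loop
with cyclic coordinate descent and soft-thresholding on the penalized
coefficients, the standard algorithm for L1 generalized linear models.

Objective (n samples, penalized coefficients beta_FA)::

    (1/n) * sum_i [log(1 + exp(eta_i)) - y_i * eta_i]  +  lambda * ||beta_FA||_1
    eta_i = b0 + fixed_i . beta_fixed + x_i . beta_FA
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc, roc_curve

from .datamodel import ConcentrationTable

__all__ = [
    "FittedClassifier",
    "CVCurve",
    "ClassificationScoreResult",
    "fit_penalized_logistic",
    "lambda_max",
    "loo_cv_select_lambda",
    "train_classifier",
    "classify_and_score",
    "roc_sens_spec",
    "design_from_table",
]

_PROB_CLIP = 1e-10
_WEIGHT_FLOOR = 1e-6


@dataclass
class FittedClassifier:
    """A fitted sparse logistic model.

    Coefficients for penalized features are stored on the standardized scale
    (``beta``) and on the original feature scale (``beta_original``);
    standardization parameters are frozen from the training data and reused
    verbatim for any new cohort.
    """

    intercept: float
    beta_fixed: np.ndarray
    beta: np.ndarray
    feature_names: list[str]
    fixed_names: list[str]
    lam: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    standardized: bool = True
    cv_curve: "CVCurve | None" = None

    @property
    def beta_original(self) -> np.ndarray:
        if not self.standardized:
            return self.beta
        return self.beta / self.feature_sds

    @property
    def selected_species(self) -> list[str]:
        return [n for n, b in zip(self.feature_names, self.beta) if b != 0.0]

    def linear_predictor(self, X: np.ndarray,
                         fixed: np.ndarray | None = None) -> np.ndarray:
        Xs = self._standardize(X)
        eta = self.intercept + Xs @ self.beta
        if fixed is not None and len(self.beta_fixed):
            eta = eta + np.asarray(fixed, dtype=float) @ self.beta_fixed
        return eta

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if not self.standardized:
            return X
        return (X - self.feature_means) / self.feature_sds


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _soft_threshold(z: float, gamma: float) -> float:
    if z > gamma:
        return z - gamma
    if z < -gamma:
        return z + gamma
    return 0.0


def _standardize_train(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant feature cannot be standardized")
    return (X - mu) / sd, mu, sd


def _soft_vec(z: np.ndarray, gamma: float) -> np.ndarray:
    return np.sign(z) * np.maximum(np.abs(z) - gamma, 0.0)


def _coordinate_descent(
    D: np.ndarray,
    y: np.ndarray,
    penalized: np.ndarray,
    lam: float,
    coef: np.ndarray,
    *,
    max_outer: int = 300,
    tol: float = 1e-10,
) -> np.ndarray:
    """Solve the L1-penalized logistic problem on the full design ``D``
    (column 0 is the intercept; ``penalized`` masks the columns carrying the
    penalty).

    Proximal gradient (FISTA with restart) drives the iterate near the
    solution and identifies the active set; an active-set Newton polish then
    solves the smooth stationarity conditions ``grad + lam * sign(beta)`` on
    the support to machine accuracy.  Deterministic throughout.
    """
    n = len(y)
    lip = np.linalg.norm(D, 2) ** 2 / (4.0 * n) + 1e-12
    step = 1.0 / lip

    def grad(c: np.ndarray) -> np.ndarray:
        return D.T @ (_sigmoid(D @ c) - y) / n

    def kkt(c: np.ndarray) -> float:
        g = grad(c)
        viol = np.abs(g.copy())
        on = penalized & (c != 0)
        viol[on] = np.abs(g[on] + lam * np.sign(c[on]))
        off = penalized & (c == 0)
        viol[off] = np.maximum(np.abs(g[off]) - lam, 0.0)
        return float(viol.max())

    coef = coef.copy()
    if kkt(coef) > 1e-2:  # far from a solution: let FISTA find the support
        z = coef.copy()
        t = 1.0
        for it in range(max_outer):
            g = grad(z)
            new = z - step * g
            new[penalized] = _soft_vec(new[penalized], step * lam)
            if np.dot(z - new, new - coef) > 0:  # adaptive restart
                t = 1.0
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
            z = new + ((t - 1.0) / t_new) * (new - coef)
            coef, t = new, t_new
            if it % 25 == 24 and kkt(coef) < 1e-4:
                break

    def objective(c: np.ndarray) -> float:
        eta = D @ c
        return float(np.mean(np.logaddexp(0.0, eta) - y * eta)
                     + lam * np.abs(c[penalized]).sum())

    # Newton on the active set with a backtracking line search; entrants
    # violating the KKT conditions are admitted with the sign their gradient
    # demands, exits that cross zero are clipped back onto the boundary
    for _ in range(200):
        g = grad(coef)
        sign = np.sign(coef)
        active = (~penalized) | (coef != 0.0)
        violated = penalized & (coef == 0.0) & (np.abs(g) > lam + 1e-12)
        active |= violated
        sign[violated] = -np.sign(g[violated])
        DA = D[:, active]
        p = _sigmoid(D @ coef)
        w = np.clip(p * (1 - p), _WEIGHT_FLOOR, None)
        rhs = DA.T @ (p - y) / n + lam * (sign[active] * penalized[active])
        H = (DA * w[:, None]).T @ DA / n
        H.flat[:: H.shape[0] + 1] += 1e-12
        try:
            delta = np.linalg.solve(H, rhs)
        except np.linalg.LinAlgError:  # pragma: no cover - guarded by ridge
            break
        f0 = objective(coef)
        pen_active = penalized[active]
        alpha = 1.0
        trial = coef
        for _ in range(30):
            updated = coef[active] - alpha * delta
            # a penalized coefficient may not cross zero within one step
            crossed = (np.sign(updated) != sign[active]) & (sign[active] != 0) \
                & pen_active
            updated = np.where(crossed, 0.0, updated)
            candidate = coef.copy()
            candidate[active] = updated
            if objective(candidate) <= f0 + 1e-12:
                trial = candidate
                break
            alpha *= 0.5
        moved = np.max(np.abs(trial - coef))
        coef = trial
        if moved < tol and not violated.any():
            break
    return coef


def _kkt_violation(D: np.ndarray, y: np.ndarray, coef: np.ndarray,
                   penalized: np.ndarray, lam: float) -> float:
    n = len(y)
    grad = D.T @ (_sigmoid(D @ coef) - y) / n
    viol = 0.0
    for j in range(len(coef)):
        if not penalized[j]:
            viol = max(viol, abs(grad[j]))
        elif coef[j] != 0:
            viol = max(viol, abs(grad[j] + lam * np.sign(coef[j])))
        else:
            viol = max(viol, max(abs(grad[j]) - lam, 0.0))
    return viol


def _assemble_design(Xs: np.ndarray, fixed: np.ndarray | None
                     ) -> tuple[np.ndarray, np.ndarray, int]:
    n = Xs.shape[0]
    fixed = np.zeros((n, 0)) if fixed is None else np.atleast_2d(
        np.asarray(fixed, dtype=float))
    if fixed.shape[0] != n:
        fixed = fixed.T
    D = np.column_stack([np.ones(n), fixed, Xs])
    penalized = np.zeros(D.shape[1], dtype=bool)
    penalized[1 + fixed.shape[1]:] = True
    return D, penalized, fixed.shape[1]


def fit_penalized_logistic(
    X,
    y,
    fixed=None,
    lam: float = 0.0,
    *,
    standardize: bool = True,
    feature_names: list[str] | None = None,
    fixed_names: list[str] | None = None,
    warm_start: np.ndarray | None = None,
    grad_tol: float = 1e-8,
) -> FittedClassifier:
    """Fit the L1-penalized logistic model at a single ``lam``.

    The intercept and the ``fixed`` covariate columns are never penalized.
    Penalized features are standardized internally (mean 0, SD 1) unless
    ``standardize=False``; coefficients are reported on both scales.
    Deterministic given its inputs.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("response has a single class")
    if not set(classes) <= {0.0, 1.0}:
        raise ValueError("response must be coded 0/1")
    if standardize:
        Xs, mu, sd = _standardize_train(X)
    else:
        Xs, mu, sd = X, np.zeros(X.shape[1]), np.ones(X.shape[1])
    D, penalized, n_fixed = _assemble_design(Xs, fixed)
    coef = (np.zeros(D.shape[1]) if warm_start is None
            else np.asarray(warm_start, dtype=float).copy())
    coef = _coordinate_descent(D, y, penalized, lam, coef)
    if _kkt_violation(D, y, coef, penalized, lam) > max(grad_tol, 1e-8) * 10:
        coef = _coordinate_descent(D, y, penalized, lam, coef,
                                   max_outer=500, tol=1e-12)
    names = feature_names or [f"x{j}" for j in range(X.shape[1])]
    return FittedClassifier(
        intercept=float(coef[0]),
        beta_fixed=coef[1:1 + n_fixed].copy(),
        beta=coef[1 + n_fixed:].copy(),
        feature_names=list(names),
        fixed_names=list(fixed_names or
                         [f"fixed{j}" for j in range(n_fixed)]),
        lam=float(lam),
        feature_means=mu,
        feature_sds=sd,
        standardized=standardize,
    )


def lambda_max(X, y, fixed=None, *, standardize: bool = True) -> float:
    """Smallest penalty that zeroes every penalized coefficient.

    Computed from the KKT conditions at the null (intercept + fixed
    covariates only) fit: ``max_j |(1/n) x_j^T (y - p0)|``.
    """
    X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y = np.asarray(y, dtype=float)
    if standardize:
        Xs, _, _ = _standardize_train(X)
    else:
        Xs = X
    D, penalized, n_fixed = _assemble_design(Xs, fixed)
    D0 = D[:, ~penalized]
    coef0 = _coordinate_descent(D0, y, np.zeros(D0.shape[1], bool), 0.0,
                                np.zeros(D0.shape[1]))
    p0 = _sigmoid(D0 @ coef0)
    grad = Xs.T @ (y - p0) / len(y)
    return float(np.max(np.abs(grad)))


@dataclass
class CVCurve:
    lambdas: np.ndarray
    mean_deviance: np.ndarray
    se_deviance: np.ndarray
    lambda_min: float
    lambda_1se: float


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _PROB_CLIP, 1 - _PROB_CLIP)
    return -2 * (y * np.log(p) + (1 - y) * np.log(1 - p))


def default_lambda_grid(lam_max: float, *, n_lambda: int = 40,
                        decades: float = 4.0) -> np.ndarray:
    """Log-spaced grid from ``lam_max`` down ``decades`` orders of magnitude."""
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades,
                       n_lambda)


def loo_cv_select_lambda(
    X,
    y,
    fixed=None,
    lambda_grid: np.ndarray | None = None,
    *,
    n_lambda: int = 40,
    standardize: bool = True,
) -> tuple[float, CVCurve]:
    """Leave-one-out cross-validated penalty with the one-standard-error rule.

    For each lambda on a log-spaced grid (from ``lambda_max`` downward four
    decades by default, >= 30 points), every sample is held out once, the
    model is refit (warm-started along the path) and the held-out binomial
    deviance recorded.  The selected penalty is the largest lambda whose mean
    deviance is within one standard error of the minimum.
    """
    X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("LOO-CV needs at least 10 samples")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(
            lambda_max(X, y, fixed, standardize=standardize),
            n_lambda=max(int(n_lambda), 30))
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("empty lambda grid")
    lambda_grid = np.sort(lambda_grid)[::-1]

    fixed_arr = None
    if fixed is not None:
        fixed_arr = np.atleast_2d(np.asarray(fixed, dtype=float))
        if fixed_arr.shape[0] != n:
            fixed_arr = fixed_arr.T

    deviances = np.zeros((n, len(lambda_grid)))
    for i in range(n):
        keep = np.arange(n) != i
        Xi, yi = X[keep], y[keep]
        fi = fixed_arr[keep] if fixed_arr is not None else None
        warm = None
        for j, lam in enumerate(lambda_grid):
            model = fit_penalized_logistic(
                Xi, yi, fi, lam, standardize=standardize, warm_start=warm)
            warm = np.concatenate(
                [[model.intercept], model.beta_fixed, model.beta])
            eta = model.linear_predictor(
                X[i:i + 1],
                fixed_arr[i:i + 1] if fixed_arr is not None else None)
            deviances[i, j] = _binomial_deviance(y[i:i + 1],
                                                 _sigmoid(eta))[0]
    mean_dev = deviances.mean(axis=0)
    se_dev = deviances.std(axis=0, ddof=1) / np.sqrt(n)
    j_min = int(np.argmin(mean_dev))
    threshold = mean_dev[j_min] + se_dev[j_min]
    within = np.where(mean_dev <= threshold)[0]
    j_1se = int(within[0])  # grid is descending: first index = largest lambda
    curve = CVCurve(
        lambdas=lambda_grid,
        mean_deviance=mean_dev,
        se_deviance=se_dev,
        lambda_min=float(lambda_grid[j_min]),
        lambda_1se=float(lambda_grid[j_1se]),
    )
    return float(lambda_grid[j_1se]), curve


# ---------------------------------------------------------------------------
# Table-level interface


def design_from_table(
    table: ConcentrationTable,
    *,
    features: list[str] | None = None,
    positive_groups: tuple[str, ...] = ("SPF", "control"),
    experiment_levels: list[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, list[str]]:
    """Build (log2 features, y, fixed experiment indicators) from a table.

    Germfree and antibiotic-treated samples are coded 0; SPF/untreated
    controls are coded 1.  Experiment indicator columns are one-hot with the
    first training level as reference; cohorts from unseen experiments get
    all-zero indicators (the reference level).
    """
    features = features or list(table.values.columns)
    X = table.values[features]
    if X.isna().any().any():
        raise ValueError("classifier features must be complete; filter or "
                         "impute first")
    if (X <= 0).any().any():
        raise ValueError("log2 transform requires positive concentrations")
    X = np.log2(X)
    y = table.sample_meta["group"].isin(positive_groups).to_numpy(dtype=float)
    exps = table.sample_meta["experiment"].astype(str)
    if experiment_levels is None:
        experiment_levels = list(pd.unique(exps))
    ref, rest = experiment_levels[0], experiment_levels[1:]
    fixed = np.column_stack(
        [(exps == lvl).to_numpy(dtype=float) for lvl in rest]
    ) if rest else np.zeros((len(exps), 0))
    return X, y, fixed, [f"experiment[{lvl}]" for lvl in rest]


def train_classifier(
    table: ConcentrationTable,
    *,
    features: list[str] | None = None,
    lambda_grid: np.ndarray | None = None,
    standardize: bool = True,
) -> FittedClassifier:
    """LOO-CV-selected sparse logistic signature from a training table."""
    X, y, fixed, fixed_names = design_from_table(table, features=features)
    lam, curve = loo_cv_select_lambda(X, y, fixed, lambda_grid,
                                      standardize=standardize)
    model = fit_penalized_logistic(X, y, fixed, lam, standardize=standardize,
                                   fixed_names=fixed_names)
    model.cv_curve = curve
    return model


@dataclass
class ClassificationScoreResult:
    """Per-sample scores plus summary classification metrics."""

    scores: pd.Series
    predicted: pd.Series
    truth: pd.Series | None
    threshold: float
    sensitivity: float | None = None
    specificity: float | None = None
    roc: pd.DataFrame | None = None
    auc: float | None = None
    group_means: pd.Series | None = None


def classify_and_score(
    model: FittedClassifier,
    table: ConcentrationTable,
    *,
    threshold: float = 0.5,
    truth: pd.Series | None = None,
    linear: bool = False,
) -> ClassificationScoreResult:
    """Score a held-out cohort with a trained model.

    Features are standardized with the *training* means and SDs; the
    experiment covariate of an unseen cohort is taken at the training
    reference level (zero indicator).  The score is the predicted
    probability of the colonized class (``linear=True`` returns the linear
    predictor instead); lower scores are more germfree-like.  When truth
    labels are available (or derivable from the group annotation),
    sensitivity, specificity, ROC and AUC are reported along with per-group
    mean scores for ranking treatments.
    """
    missing = [f for f in model.feature_names
               if f not in table.values.columns]
    if missing:
        raise KeyError(f"missing feature columns: {missing}")
    X = table.values[model.feature_names]
    if X.isna().any().any() or (X <= 0).any().any():
        raise ValueError("features must be complete and positive")
    eta = model.linear_predictor(np.log2(X.to_numpy(dtype=float)), None)
    scores = pd.Series(eta if linear else _sigmoid(eta),
                       index=table.values.index, name="score")
    predicted = (scores > (0.0 if linear else threshold)).astype(int)
    group_means = scores.groupby(
        table.sample_meta["group"].values).mean().sort_values()
    result = ClassificationScoreResult(
        scores=scores, predicted=predicted, truth=truth,
        threshold=threshold, group_means=group_means,
    )
    if truth is not None:
        sens, spec, roc, area = roc_sens_spec(
            scores.to_numpy(), np.asarray(truth, dtype=int),
            threshold=0.0 if linear else threshold)
        result.sensitivity, result.specificity = sens, spec
        result.roc, result.auc = roc, area
    return result


def roc_sens_spec(
    scores: np.ndarray,
    truth: np.ndarray,
    threshold: float = 0.5,
) -> tuple[float, float, pd.DataFrame, float]:
    """Sensitivity/specificity at ``threshold`` plus the full ROC and AUC.

    Sensitivity is the true-positive rate of the colonized class (truth 1);
    specificity the true-negative rate for germfree/treated (truth 0).  The
    ROC sweeps all unique score thresholds; AUC is the trapezoidal area.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if len(np.unique(truth)) < 2:
        raise ValueError("both classes must be present")
    pred = scores > threshold
    tp = int(((pred == 1) & (truth == 1)).sum())
    fn = int(((pred == 0) & (truth == 1)).sum())
    tn = int(((pred == 0) & (truth == 0)).sum())
    fp = int(((pred == 1) & (truth == 0)).sum())
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    fpr, tpr, thresholds = roc_curve(truth, scores)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return sensitivity, specificity, roc, float(auc(fpr, tpr))
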