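"""Ridge-penalized logistic classification of post-MI outcome with
leave-one-out cross-validation and AUC.

The classifier maximizes the penalized log-likelihood

    l(b0, b) = sum_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ] - lambda ||b||^2

with p_i = sigmoid(b0 + x_i . b); the intercept b0 is unpenalized.  The
default ridge value lambda = 1e-8 keeps the optimum finite on separable
data while leaving the fit essentially unregularized.  Panels are scored
by leave-one-out cross-validation: each sample receives the predicted
probability of *poor* outcome from a model trained on the other n - 1, and
the pooled out-of-fold scores are summarized by the AUC (Mann-Whitney
formulation; ties count one half).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .expression import GOOD, POOR, ExpressionDataset, module_mean_profile

__all__ = [
    "FeaturePanel",
    "ClassifierConfig",
    "PanelEvaluation",
    "ConvergenceError",
    "standardize",
    "fit_ridge_logistic",
    "predict_proba",
    "auc",
    "panel_matrix",
    "loocv_evaluate",
]


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the last iterate."""

    def __init__(self, message, intercept, coef):
        super().__init__(message)
        self.intercept = intercept
        self.coef = coef


@dataclass(frozen=True)
class FeaturePanel:
    """An ordered list of classifier inputs.

    Each feature is ``("gene", gene_id)`` — one gene's expression row — or
    ``("module-mean", module_id)`` — the per-sample mean profile of a
    module's genes.
    """

    name: str
    features: tuple

    def __post_init__(self):
        feats = tuple((str(kind), key) for kind, key in self.features)
        object.__setattr__(self, "features", feats)
        if not feats:
            raise ValueError("panel must have at least one feature")
        if len(set(feats)) != len(feats):
            raise ValueError("duplicate features in panel")
        bad = {k for k, _ in feats} - {"gene", "module-mean"}
        if bad:
            raise ValueError(f"unknown feature kinds: {sorted(bad)}")


@dataclass
class ClassifierConfig:
    """Ridge-logistic settings.

    ``ridge_lambda`` is the L2 penalty on non-intercept coefficients
    (default 1e-8); ``scaler_scope`` chooses whether standardization
    parameters come from each training fold (``"fold"``, leakage-free) or
    from the whole dataset (``"global"``).
    """

    ridge_lambda: float = 1e-8
    standardize: bool = True
    scaler_scope: str = "fold"
    max_iter: int = 200
    tol: float = 1e-8

    def __post_init__(self):
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.scaler_scope not in ("fold", "global"):
            raise ValueError("scaler_scope must be 'fold' or 'global'")


@dataclass
class PanelEvaluation:
    """LOOCV result: per-sample out-of-fold scores and the pooled AUC."""

    panel: FeaturePanel
    oof_scores: pd.Series
    auc: float


def standardize(train: np.ndarray, apply_to: np.ndarray) -> np.ndarray:
    """Center/scale columns of ``apply_to`` by train-column mean and SD.

    Population (ddof=0) standard deviations.  A zero-variance training
    column maps to zeros, with a warning.
    """
    train = np.asarray(train, dtype=float)
    apply_to = np.asarray(apply_to, dtype=float)
    if train.ndim != 2 or apply_to.ndim != 2 or train.shape[1] != apply_to.shape[1]:
        raise ValueError("train and apply_to must be 2-D with matching column counts")
    if train.shape[0] < 2:
        raise ValueError("need >= 2 training rows to standardize")
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    out = apply_to - mu
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} constant column(s) standardized to zeros",
            stacklevel=2,
        )
        out[:, zero] = 0.0
    out[:, ~zero] = out[:, ~zero] / sd[~zero]
    return out


def _penalized_nll(beta: np.ndarray, X1: np.ndarray, y: np.ndarray, lam: float) -> float:
    eta = X1 @ beta
    # log(1 + exp(eta)) - y*eta, numerically stable
    ll = np.sum(np.logaddexp(0.0, eta) - y * eta)
    return ll + lam * float(beta[1:] @ beta[1:])


def fit_ridge_logistic(
    X,
    y,
    ridge_lambda: float = 1e-8,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> tuple[float, np.ndarray]:
    """Fit ridge-penalized logistic regression by damped IRLS (Newton).

    Maximizes the log-likelihood minus ``ridge_lambda * ||coef||^2`` with
    an unpenalized intercept.  Convergence: max absolute parameter change
    below ``tol``.  Raises :class:`ConvergenceError` (carrying the last
    iterate) if ``max_iter`` is exhausted.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least one sample of each class")
    n, p = X.shape
    X1 = np.hstack([np.ones((n, 1)), X])
    beta = np.zeros(p + 1)
    pen = np.full(p + 1, 2.0 * ridge_lambda)
    pen[0] = 0.0  # intercept unpenalized
    obj = _penalized_nll(beta, X1, y, ridge_lambda)
    gtol = 1e-7 * max(1.0, n)
    for _ in range(max_iter):
        eta = X1 @ beta
        mu = expit(eta)
        grad = X1.T @ (y - mu) - pen * beta
        if np.max(np.abs(grad)) < gtol:
            return float(beta[0]), beta[1:].copy()
        # Weight floor and a tiny Hessian ridge keep the Newton system
        # solvable when probabilities saturate (near-separable data with a
        # vanishing penalty); neither changes the optimum, only the step.
        w = np.clip(mu * (1.0 - mu), 1e-9, None)
        hess = (X1 * w[:, None]).T @ X1 + np.diag(pen) + 1e-9 * np.eye(p + 1)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # Backtracking line search on the penalized negative log-likelihood.
        t = 1.0
        new_beta, new_obj = beta, obj
        for _ in range(60):
            cand = beta + t * step
            cand_obj = _penalized_nll(cand, X1, y, ridge_lambda)
            if cand_obj <= obj:
                new_beta, new_obj = cand, cand_obj
                break
            t /= 2.0
        delta = np.max(np.abs(new_beta - beta))
        beta, obj = new_beta, new_obj
        if delta < tol:
            return float(beta[0]), beta[1:].copy()
    raise ConvergenceError(
        f"IRLS did not converge within {max_iter} iterations",
        float(beta[0]), beta[1:].copy(),
    )


def predict_proba(intercept: float, coef: np.ndarray, X) -> np.ndarray:
    """Predicted probability of the positive (poor-outcome) class."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return expit(intercept + X @ np.asarray(coef, dtype=float))


def auc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney formulation.

    Fraction of (positive, negative) pairs with score_pos > score_neg,
    ties counting 0.5.  Labels are 0/1; both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def panel_matrix(
    ds: ExpressionDataset,
    panel: FeaturePanel,
    module_genes: dict | None = None,
) -> pd.DataFrame:
    """Samples x features design matrix for a panel.

    ``module_genes`` maps module ids to gene lists and is required when the
    panel contains module-mean features.
    """
    cols = {}
    for kind, key in panel.features:
        if kind == "gene":
            if key not in ds.matrix.index:
                raise ValueError(f"panel gene {key!r} absent from the dataset")
            cols[f"gene:{key}"] = ds.matrix.loc[key]
        else:
            if module_genes is None or key not in module_genes:
                raise ValueError(f"module {key!r} gene list not provided")
            cols[f"module-mean:{key}"] = module_mean_profile(ds, module_genes[key])
    return pd.DataFrame(cols, index=ds.samples)


def _binary_labels(ds: ExpressionDataset) -> np.ndarray:
    return (ds.labels == POOR).to_numpy().astype(float)


def fit_panel(
    ds: ExpressionDataset,
    panel: FeaturePanel,
    cfg: ClassifierConfig,
    module_genes: dict | None = None,
):
    """Fit the panel classifier on a whole dataset.

    Returns ``(intercept, coef, scaler)`` where ``scaler`` is the (mean,
    sd) pair used for standardization (None if cfg.standardize is False).
    Use with :func:`score_panel` for train-on-A / score-on-B designs, e.g.
    fitting on microarray data and scoring an independent qPCR cohort.
    """
    X = panel_matrix(ds, panel, module_genes).to_numpy()
    y = _binary_labels(ds)
    scaler = None
    if cfg.standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        scaler = (mu, sd)
        X = standardize(X, X)
    b0, b = fit_ridge_logistic(X, y, cfg.ridge_lambda, cfg.max_iter, cfg.tol)
    return b0, b, scaler


def score_panel(
    model,
    ds: ExpressionDataset,
    panel: FeaturePanel,
    module_genes: dict | None = None,
) -> pd.Series:
    """Score a dataset with a model returned by :func:`fit_panel`."""
    b0, b, scaler = model
    X = panel_matrix(ds, panel, module_genes).to_numpy()
    if scaler is not None:
        mu, sd = scaler
        X = (X - mu) / np.where(sd == 0, 1.0, sd)
        X[:, sd == 0] = 0.0
    return pd.Series(predict_proba(b0, b, X), index=ds.samples)


def loocv_evaluate(
    ds: ExpressionDataset,
    panel: FeaturePanel,
    cfg: ClassifierConfig | None = None,
    module_genes: dict | None = None,
) -> PanelEvaluation:
    """Leave-one-out cross-validated evaluation of a feature panel.

    For each sample, the classifier is trained on the remaining n - 1
    samples (standardizing with fold or global scope per the config) and
    the held-out sample is scored with its predicted probability of poor
    outcome; the pooled out-of-fold scores give the AUC.  A training fold
    missing one class is an error.
    """
    if cfg is None:
        cfg = ClassifierConfig()
    Xdf = panel_matrix(ds, panel, module_genes)
    X = Xdf.to_numpy()
    y = _binary_labels(ds)
    n = len(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    global_X = standardize(X, X) if (cfg.standardize and cfg.scaler_scope == "global") else None
    scores = np.empty(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-column warnings inside folds
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            y_tr = y[mask]
            if len(np.unique(y_tr)) < 2:
                raise ValueError(f"training fold for sample {Xdf.index[i]!r} lacks one class")
            if global_X is not None:
                X_tr, X_te = global_X[mask], global_X[[i]]
            elif cfg.standardize:
                X_tr = standardize(X[mask], X[mask])
                X_te = standardize(X[mask], X[[i]])
            else:
                X_tr, X_te = X[mask], X[[i]]
            b0, b = fit_ridge_logistic(X_tr, y_tr, cfg.ridge_lambda, cfg.max_iter, cfg.tol)
            scores[i] = predict_proba(b0, b, X_te)[0]
    oof = pd.Series(scores, index=Xdf.index)
    return PanelEvaluation(panel=panel, oof_scores=oof, auc=auc(scores, y))
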