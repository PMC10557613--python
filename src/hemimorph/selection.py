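"""Forward binary logistic regression with Nagelkerke pseudo-R².

The multivariate stage: starting from an intercept-only model, candidates
(region-measure values) are entered one at a time.  At each step the
candidate with the smallest entry p-value (likelihood-ratio chi-square with
1 df against the current model; a score-test option is provided) is added if
its p is below ``entry_alpha`` (default .05) **and** the Nagelkerke R²
improves by at least ``min_r2_change`` (default .001); otherwise selection
stops.  The recorded path lists predictors in entry order with per-step
entry p and cumulative R².

The base fitter is a Newton/IRLS maximum-likelihood solver with an iteration
cap; complete or quasi-complete separation — a real risk with n as small as
13 patients against 51 controls — is detected from diverging coefficients
and flagged on the path rather than silently reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin

_ETA_CAP = 30.0  # linear predictors beyond this are numerically 0/1


@dataclass(frozen=True)
class LogisticFit:
    coef: np.ndarray  # includes intercept (first)
    loglik: float
    converged: bool
    separated: bool
    n_iter: int


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    eta = np.clip(eta, -_ETA_CAP, _ETA_CAP)
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def fit_logistic(y, X, max_iter: int = 100, tol: float = 1e-10) -> LogisticFit:
    """Maximum-likelihood logistic regression by iteratively reweighted LS.

    ``X`` must include its intercept column; ``y`` is 0/1 with both classes
    present.  Returns coefficients, the converged log-likelihood, and flags
    for non-convergence and (quasi-)separation.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (include the intercept column)")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    n, k = X.shape
    beta = np.zeros(k)
    ll_old = _loglik(y, X @ beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -_ETA_CAP, _ETA_CAP)
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        ll_new = _loglik(y, X @ beta_new)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if abs(ll_new - ll_old) < tol and step < 1e-6:
            converged = True
            ll_old = ll_new
            break
        ll_old = ll_new
    eta = X @ beta
    # separation: fitted log-odds pinned at the cap for some subjects, or
    # coefficients still drifting at the iteration cap
    separated = bool(np.max(np.abs(eta)) >= _ETA_CAP - 1e-6) or (
        not converged and np.max(np.abs(beta)) > 10.0
    )
    return LogisticFit(coef=beta, loglik=ll_old, converged=converged,
                       separated=separated, n_iter=it)


def nagelkerke_r2(ll_null: float, ll_model: float, n: int) -> float:
    """Nagelkerke's rescaled likelihood-ratio pseudo-R², in [0, 1]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if ll_model < ll_null - 1e-6:
        raise ValueError("ll_model < ll_null: not a maximum-likelihood fit")
    ll_model = max(ll_model, ll_null)
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - ll_model) / n)
    denom = 1.0 - np.exp(2.0 * ll_null / n)
    if denom <= 0:
        return 0.0
    return float(min(cox_snell / denom, 1.0))


def _score_test_p(y, X_current, beta_current, x_new) -> float:
    """Rao score test for adding one column to a fitted logistic model."""
    eta = np.clip(X_current @ beta_current, -_ETA_CAP, _ETA_CAP)
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    u = float(x_new @ (y - mu))
    xw = X_current * w[:, None]
    a = float(x_new @ (w * x_new))
    b = X_current.T @ (w * x_new)
    try:
        v = a - float(b @ np.linalg.solve(X_current.T @ xw, b))
    except np.linalg.LinAlgError:
        return 1.0
    if v <= 0:
        return 1.0
    return float(stats.chi2.sf(u * u / v, df=1))


class ForwardLogisticSelector(ClassifierMixin, BaseEstimator):
    """Forward-selected logistic classifier over named candidate columns.

    Parameters
    ----------
    entry_alpha : entry threshold on the per-candidate test p-value (.05).
    min_r2_change : minimum Nagelkerke R² gain to keep entering (.001).
    entry_test : 'lr' (likelihood ratio, default) or 'score'.
    max_steps : optional cap on the number of predictors entered.

    Attributes
    ----------
    path_ : DataFrame with columns step, predictor, entry_p, r2_cumulative, separated.
    selected_ : list of entered predictor names (possibly empty).
    coef_, intercept_ : final-model parameters over the selected predictors.
    r2_ : final cumulative Nagelkerke R².
    """

    def __init__(
        self,
        entry_alpha: float = 0.05,
        min_r2_change: float = 0.001,
        entry_test: str = "lr",
        max_steps: int | None = None,
    ):
        self.entry_alpha = entry_alpha
        self.min_r2_change = min_r2_change
        self.entry_test = entry_test
        self.max_steps = max_steps

    def fit(self, X, y):
        if self.entry_test not in ("lr", "score"):
            raise ValueError("entry_test must be 'lr' or 'score'")
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            X = X.to_numpy(float)
        else:
            X = np.asarray(X, dtype=float)
            names = [f"x{j}" for j in range(X.shape[1])]
        y = np.asarray(y)
        self.classes_, y01 = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError("y must be binary")
        y01 = y01.astype(float)
        n = len(y01)
        selected: list[int] = []
        cur_X = np.ones((n, 1))
        cur_fit = fit_logistic(y01, cur_X)
        ll_null = cur_fit.loglik
        r2_cur = 0.0
        steps = []
        max_steps = self.max_steps if self.max_steps is not None else X.shape[1]
        while len(selected) < max_steps:
            best = None  # (p, -r2_gain, name, j, fit)
            for j in range(X.shape[1]):
                if j in selected:
                    continue
                cand_X = np.column_stack([cur_X, X[:, j]])
                if np.linalg.matrix_rank(cand_X) < cand_X.shape[1]:
                    continue  # collinear with the current model
                fit = fit_logistic(y01, cand_X)
                lr = max(0.0, 2.0 * (fit.loglik - cur_fit.loglik))
                if self.entry_test == "lr":
                    p = float(stats.chi2.sf(lr, df=1))
                else:
                    p = _score_test_p(y01, cur_X, cur_fit.coef, X[:, j])
                r2_new = nagelkerke_r2(ll_null, fit.loglik, n)
                key = (p, -(r2_new - r2_cur), names[j])
                if best is None or key < best[0]:
                    best = (key, j, fit, p, r2_new)
            if best is None:
                break
            key, j, fit, p, r2_new = best
            if p >= self.entry_alpha or (r2_new - r2_cur) < self.min_r2_change:
                break
            selected.append(j)
            cur_X = np.column_stack([cur_X, X[:, j]])
            cur_fit = fit
            r2_cur = r2_new
            steps.append(
                dict(step=len(selected), predictor=names[j], entry_p=p,
                     r2_cumulative=r2_cur, separated=fit.separated)
            )
            if fit.separated:
                break  # R² is saturated; further entries are meaningless
        self.path_ = pd.DataFrame(
            steps, columns=["step", "predictor", "entry_p", "r2_cumulative", "separated"]
        )
        self.selected_ = [names[j] for j in selected]
        self.selected_idx_ = list(selected)
        self.intercept_ = float(cur_fit.coef[0])
        self.coef_ = np.asarray(cur_fit.coef[1:], dtype=float)
        self.r2_ = r2_cur
        self.ll_ = cur_fit.loglik
        self.separated_ = bool(cur_fit.separated)
        return self

    def decision_function(self, X):
        if isinstance(X, pd.DataFrame):
            X = X[self.selected_].to_numpy(float) if self.selected_ else np.empty((len(X), 0))
        else:
            X = np.asarray(X, dtype=float)[:, self.selected_idx_]
        return self.intercept_ + X @ self.coef_

    def predict_proba(self, X):
        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


def forward_select(
    y,
    candidates: pd.DataFrame,
    entry_alpha: float = 0.05,
    min_r2_change: float = 0.001,
    entry_test: str = "lr",
) -> pd.DataFrame:
    """Functional wrapper: returns the selection path as a DataFrame."""
    sel = ForwardLogisticSelector(
        entry_alpha=entry_alpha, min_r2_change=min_r2_change, entry_test=entry_test
    ).fit(candidates, y)
    return sel.path_
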