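"""L1-penalized logistic feature selection over repeated cross-validation.

Importance of a feature = number of (repeat, fold) fits in which its LASSO
coefficient is non-zero, out of ``n_repeats * n_folds`` (100 by default).
Within each outer training fold, features are standardized on that fold only
and the penalty is chosen from a log-spaced grid below the smallest penalty
that zeroes every coefficient, by inner cross-validated deviance.

The path is solved by accelerated proximal gradient descent (FISTA) with
soft-thresholding, which yields exact zeros and is deterministic; all grid
penalties are solved simultaneously, which keeps 100 repeated-CV fits fast.
The binary outcome is modelled with penalized logistic regression (binomial
deviance); a linear-LASSO variant on the 0/1 label is available behind
``family='gaussian'`` for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LassoCV
from sklearn.model_selection import StratifiedKFold

LABEL_COLUMN = "label"

_NONZERO_TOL = 1e-10


def split_table(table: pd.DataFrame):
    """(X, y) from a feature table holding a 'label' column."""
    if LABEL_COLUMN not in table.columns:
        raise ValueError(f"feature table must contain a {LABEL_COLUMN!r} column")
    y = table[LABEL_COLUMN].to_numpy()
    if np.isnan(y.astype(float)).any():
        raise ValueError("missing labels are not allowed")
    y = y.astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes 0 and 1")
    X = table.drop(columns=[LABEL_COLUMN])
    return X, y


@dataclass
class ImportanceCounts:
    """Non-zero-coefficient counts over all repeated-CV fits."""

    counts: pd.Series
    mean_abs_coef: pd.Series
    n_fits: int
    penalties: List[float]
    seed: int
    constant_features: List[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"count": self.counts,
                             "mean_abs_coef": self.mean_abs_coef})


def _lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int,
                 decades: float) -> np.ndarray:
    """Descending log-spaced penalties below the all-zero penalty for
    standardized X (largest first)."""
    n = X.shape[0]
    ybar = y.mean()
    lam_max = np.abs(X.T @ (y - ybar)).max() / n
    lam_max = max(lam_max, 1e-8)
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, n_lambda)


def l1_logistic_path(X: np.ndarray, y: np.ndarray, lams: np.ndarray,
                     max_iter: int = 200, tol: float = 1e-6,
                     init: Optional[Tuple[np.ndarray, np.ndarray]] = None
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """Solve min (1/n) binomial deviance + lam * ||w||_1 for every penalty.

    Returns (W, b) with W of shape (p, len(lams)); the intercept is not
    penalized. FISTA with constant step 1/L (L = smax(X_aug)^2 / (4n)) and
    gradient-based adaptive restart; soft-thresholding yields exact zeros.
    """
    n, p = X.shape
    Xa = np.hstack([X, np.ones((n, 1))])
    L = np.linalg.norm(Xa, 2) ** 2 / (4.0 * n)
    step = 1.0 / L
    nl = len(lams)
    lam_mat = np.vstack([np.tile(lams, (p, 1)), np.zeros((1, nl))])
    if init is not None:
        theta = np.vstack([init[0], init[1][None, :]]).copy()
    else:
        theta = np.zeros((p + 1, nl))
    z = theta.copy()
    s = np.ones(nl)
    yv = y.astype(float)[:, None]
    for _ in range(max_iter):
        grad = Xa.T @ (expit(Xa @ z) - yv) / n
        w = z - step * grad
        theta_new = np.sign(w) * np.maximum(np.abs(w) - step * lam_mat, 0.0)
        move = theta_new - theta
        # restart momentum where it points against the descent direction
        restart = ((z - theta_new) * move).sum(axis=0) > 0
        s = np.where(restart, 1.0, s)
        s_new = (1.0 + np.sqrt(1.0 + 4.0 * s * s)) / 2.0
        z = theta_new + ((s - 1.0) / s_new) * move
        delta = np.abs(move).max()
        theta = theta_new
        s = s_new
        if delta < tol:
            break
    return theta[:p, :], theta[p, :]


def _deviance(W: np.ndarray, b: np.ndarray, X: np.ndarray,
              y: np.ndarray) -> np.ndarray:
    """Mean binomial deviance per penalty column."""
    prob = expit(X @ W + b)
    prob = np.clip(prob, 1e-12, 1 - 1e-12)
    yv = y.astype(float)[:, None]
    return -(yv * np.log(prob) + (1 - yv) * np.log(1 - prob)).mean(axis=0)


def _standardize(train: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, mu, sd


def _fit_one_fold(Xtr: np.ndarray, ytr: np.ndarray, n_lambda: int,
                  decades: float, inner_folds: int, rs: int
                  ) -> Tuple[np.ndarray, float]:
    """Standardize, pick the penalty by inner-CV deviance, refit on the full
    training fold; returns (coefficients, chosen penalty)."""
    Xs, _, _ = _standardize(Xtr)
    lams = _lambda_grid(Xs, ytr, n_lambda, decades)
    inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=rs)
    dev = np.zeros(len(lams))
    warm = None
    for itr, ival in inner.split(Xs, ytr):
        Xi, mu, sd = _standardize(Xtr[itr])
        # validation data standardized with inner-train parameters
        Xv = (Xtr[ival] - mu) / sd
        W, b = l1_logistic_path(Xi, ytr[itr], lams, init=warm)
        warm = (W, b)
        dev += _deviance(W, b, Xv, ytr[ival])
    best = int(np.argmin(dev))  # descending grid: ties go to the sparser fit
    W, _ = l1_logistic_path(Xs, ytr, lams, init=warm)
    return W[:, best], float(lams[best])


def lasso_importance(
    table: pd.DataFrame,
    n_folds: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
    n_lambda: int = 50,
    lambda_decades: float = 4.0,
    inner_folds: int = 5,
    family: str = "binomial",
) -> ImportanceCounts:
    """Count non-zero LASSO coefficients over ``n_repeats`` stratified
    ``n_folds``-fold partitions (default 100 fits)."""
    if family not in ("binomial", "gaussian"):
        raise ValueError("family must be 'binomial' or 'gaussian'")
    X_df, y = split_table(table)

    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if min(n_pos, n_neg) < n_folds:
        raise ValueError(
            f"stratified {n_folds}-fold CV needs >= {n_folds} cases per class "
            f"(got {n_pos}/{n_neg}); use a larger cohort or fewer folds"
        )

    constant = [c for c in X_df.columns if X_df[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant feature columns excluded from selection: {constant}")
    active_cols = [c for c in X_df.columns if c not in constant]
    X = X_df[active_cols].to_numpy(dtype=float)

    counts = np.zeros(len(active_cols))
    abs_coef = np.zeros(len(active_cols))
    penalties: List[float] = []
    n_fits = 0

    for r in range(n_repeats):
        rs = seed + r
        outer = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rs)
        for train_idx, _ in outer.split(X, y):
            Xtr = X[train_idx]
            ytr = y[train_idx]
            if family == "binomial":
                coef, lam = _fit_one_fold(Xtr, ytr, n_lambda, lambda_decades,
                                          inner_folds, rs)
            else:
                Xs, _, _ = _standardize(Xtr)
                lams = _lambda_grid(Xs, ytr, n_lambda, lambda_decades)
                reg = LassoCV(alphas=lams, cv=inner_folds, random_state=rs,
                              max_iter=5000)
                reg.fit(Xs, ytr)
                coef, lam = reg.coef_, float(reg.alpha_)
            penalties.append(lam)
            nz = np.abs(coef) > _NONZERO_TOL
            counts[nz] += 1
            abs_coef += np.abs(coef)
            n_fits += 1

    counts_s = pd.Series(0.0, index=X_df.columns)
    mean_abs = pd.Series(0.0, index=X_df.columns)
    counts_s[active_cols] = counts
    mean_abs[active_cols] = abs_coef / n_fits
    return ImportanceCounts(
        counts=counts_s.astype(int), mean_abs_coef=mean_abs,
        n_fits=n_fits, penalties=penalties, seed=seed,
        constant_features=constant,
    )


def select_top(counts: ImportanceCounts, k: int = 10) -> List[str]:
    """Top-``k`` features by count; ties broken by mean |coefficient|, then name."""
    n_features = len(counts.counts)
    if k > n_features:
        raise ValueError(f"k={k} exceeds the {n_features} available features")
    order = pd.DataFrame({
        "count": counts.counts,
        "mean_abs_coef": counts.mean_abs_coef,
        "name": counts.counts.index,
    }).sort_values(["count", "mean_abs_coef", "name"],
                   ascending=[False, False, True], kind="mergesort")
    return list(order["name"].iloc[:k])


@dataclass
class ScoreModel:
    """Linear radiomics score: intercept + sum(coef * standardized feature)."""

    features: List[str]
    coefficients: np.ndarray
    intercept: float
    means: np.ndarray
    scales: np.ndarray
    penalty: float

    def to_dict(self) -> dict:
        return {
            "features": list(self.features),
            "coefficients": list(map(float, self.coefficients)),
            "intercept": float(self.intercept),
            "means": list(map(float, self.means)),
            "scales": list(map(float, self.scales)),
            "penalty": float(self.penalty),
        }


def fit_score_model(table: pd.DataFrame, selected: Sequence[str],
                    counts: Optional[ImportanceCounts] = None,
                    penalty: Optional[float] = None) -> ScoreModel:
    """Full-data L1 logistic refit on the selected features.

    The penalty defaults to the median of the penalties chosen across the
    repeated-CV fits; standardization parameters come from the full data and
    are stored with the model.
    """
    X_df, y = split_table(table)
    missing = [f for f in selected if f not in X_df.columns]
    if missing:
        raise ValueError(f"selected features absent from table: {missing}")
    if penalty is None:
        if counts is None or not counts.penalties:
            raise ValueError("provide either a penalty or ImportanceCounts")
        penalty = float(np.median(counts.penalties))
    X = X_df[list(selected)].to_numpy(dtype=float)
    Xs, mu, sd = _standardize(X)
    W, b = l1_logistic_path(Xs, y, np.array([penalty]), max_iter=5000, tol=1e-9)
    return ScoreModel(features=list(selected), coefficients=W[:, 0],
                      intercept=float(b[0]), means=mu, scales=sd,
                      penalty=penalty)


def radiomics_score(features: Union[Mapping[str, float], pd.Series, pd.DataFrame],
                    model: ScoreModel) -> Union[float, np.ndarray]:
    """intercept + sum coefficient * standardized feature value.

    Accepts a single feature mapping/Series (returns a float) or a DataFrame
    of cases (returns an array). A missing feature raises an error naming it.
    """
    if isinstance(features, pd.DataFrame):
        for f in model.features:
            if f not in features.columns:
                raise KeyError(f"missing feature value for {f!r}")
        X = features[model.features].to_numpy(dtype=float)
        if np.isnan(X).any():
            bad = [f for f in model.features
                   if np.isnan(features[f].to_numpy(dtype=float)).any()]
            raise ValueError(f"missing feature value for {bad}")
        Xs = (X - model.means) / model.scales
        return model.intercept + Xs @ model.coefficients
    vals = []
    for f in model.features:
        try:
            v = features[f]
        except KeyError as exc:
            raise KeyError(f"missing feature value for {f!r}") from exc
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"missing feature value for {f!r}")
        vals.append(float(v))
    xs = (np.asarray(vals) - model.means) / model.scales
    return float(model.intercept + xs @ model.coefficients)
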