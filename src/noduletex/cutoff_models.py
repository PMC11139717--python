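"""Youden cutoffs, binarization, univariate and stepwise logistic models, ROC/AUC.

Conventions: candidate thresholds are midpoints of adjacent sorted unique
values plus +/- infinity, evaluated in both directions ('greater' means
strictly above the threshold is positive; 'less-or-equal' is inclusive).
Inference is Wald throughout; separation in a 2x2 table falls back to a
Haldane (add 0.5) corrected estimate, flagged in the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from . import _delong

DIRECTION_GREATER = "greater"
DIRECTION_LE = "less-or-equal"


@dataclass(frozen=True)
class CutoffRule:
    feature: str
    threshold: float
    direction: str
    youden_j: float
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        if self.direction not in (DIRECTION_GREATER, DIRECTION_LE):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not -1.0 <= self.youden_j <= 1.0:
            raise ValueError("youden_j must lie in [-1, 1]")


def _sens_spec(pred: np.ndarray, labels: np.ndarray) -> Tuple[float, float]:
    pos = labels == 1
    sens = pred[pos].mean() if pos.any() else np.nan
    spec = (~pred[~pos]).mean() if (~pos).any() else np.nan
    return float(sens), float(spec)


def _apply_rule(values: np.ndarray, threshold: float, direction: str) -> np.ndarray:
    if direction == DIRECTION_GREATER:
        return values > threshold
    return values <= threshold


def youden_cutoff(values: Sequence[float], labels: Sequence[int],
                  feature: str = "") -> CutoffRule:
    """Rule maximizing J = sensitivity + specificity - 1 over all candidate
    thresholds and both directions; ties broken toward higher sensitivity,
    then smaller |threshold|."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.isnan(values).any():
        raise ValueError("missing feature values are not allowed")
    if not ((labels == 1).any() and (labels == 0).any()):
        raise ValueError("both classes must be present")
    uniq = np.unique(values)
    if uniq.size < 2:
        raise ValueError("no discriminating cutoff: feature is constant")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate([[-np.inf], mids, [np.inf]])

    best = None
    for direction in (DIRECTION_GREATER, DIRECTION_LE):
        for thr in candidates:
            pred = _apply_rule(values, thr, direction)
            sens, spec = _sens_spec(pred, labels)
            j = sens + spec - 1.0
            key = (j, sens, -abs(thr))
            if best is None or key > best[0]:
                best = (key, thr, direction, j, sens, spec)
    _, thr, direction, j, sens, spec = best
    return CutoffRule(feature=feature, threshold=float(thr), direction=direction,
                      youden_j=float(j), sensitivity=sens, specificity=spec)


def binarize(values: Sequence[float], rule: CutoffRule) -> np.ndarray:
    """Score 1 iff the value lies on the rule's positive side.

    'greater' is strict at the threshold; 'less-or-equal' is inclusive.
    """
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValueError(f"missing value for feature {rule.feature!r}")
    out = _apply_rule(values, rule.threshold, rule.direction).astype(int)
    if out.min() == out.max():
        warnings.warn(f"binarized scores for {rule.feature!r} are constant")
    return out


@dataclass
class LogisticFitResult:
    """Wald summary of a fitted logistic model plus its ROC performance."""

    terms: pd.DataFrame          # index term; coef, odds_ratio, ci_low, ci_high, p
    included: List[str]
    auc: float
    auc_ci: Tuple[float, float]
    method: str = "wald"
    flags: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "terms": self.terms.reset_index().rename(
                columns={"index": "term"}).to_dict(orient="records"),
            "included": list(self.included),
            "auc": float(self.auc),
            "auc_ci": [float(self.auc_ci[0]), float(self.auc_ci[1])],
            "method": self.method,
            "flags": list(self.flags),
        }


def _wald_terms(res, names: Sequence[str], level: float = 0.95) -> pd.DataFrame:
    z = norm.ppf(0.5 + level / 2.0)
    rows = []
    for name in names:
        b = float(res.params[name])
        try:
            se = float(res.bse[name])
            p = float(res.pvalues[name])
        except Exception:  # singular Hessian under separation
            se, p = np.nan, np.nan
        rows.append({
            "coef": b,
            "odds_ratio": float(np.exp(b)),
            "ci_low": float(np.exp(b - z * se)),
            "ci_high": float(np.exp(b + z * se)),
            "p": p,
        })
    return pd.DataFrame(rows, index=list(names))


def _fit_logit(X: pd.DataFrame, y: np.ndarray):
    design = sm.add_constant(X.astype(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, design)
        model.raise_on_perfect_prediction = False
        try:
            return model.fit(disp=0, maxiter=200)
        except Exception:  # Newton fails under separation; bfgs still yields llf
            return model.fit(disp=0, maxiter=500, method="bfgs")


#: |coefficient| beyond which a Wald p-value is considered separation-degenerate
_SEPARATION_COEF = 10.0


def _term_pvalue(X: pd.DataFrame, y: np.ndarray, term: str, res) -> Tuple[float, bool]:
    """Wald p for ``term``; falls back to a drop-one likelihood-ratio test when
    the estimate is separation-degenerate (Hauck-Donner: huge coef, huge SE)."""
    from scipy.stats import chi2 as chi2_dist

    try:
        p = float(res.pvalues[term])
    except Exception:
        p = np.nan
    if abs(float(res.params[term])) <= _SEPARATION_COEF and np.isfinite(p):
        return p, False
    others = [c for c in X.columns if c != term]
    if others:
        red = _fit_logit(X[others], y)
        ll0 = red.llf
    else:
        p1 = np.clip(y.mean(), 1e-12, 1 - 1e-12)
        ll0 = float((y * np.log(p1) + (1 - y) * np.log(1 - p1)).sum())
    stat = max(0.0, 2.0 * (res.llf - ll0))
    return float(chi2_dist.sf(stat, df=1)), True


def univariate_logistic(scores: Sequence[int], labels: Sequence[int],
                        name: str = "x", level: float = 0.95) -> LogisticFitResult:
    """Single-predictor ML logistic fit with Wald CI and p.

    For a binary predictor the odds ratio equals the 2x2 cross-product ratio;
    a zero cell triggers a Haldane (add 0.5) fallback, flagged as 'separation'.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.unique(x).size < 2:
        raise ValueError("predictor is constant")
    flags: List[str] = []
    binary = set(np.unique(x)) <= {0.0, 1.0}
    if binary:
        a = float(((x == 1) & (y == 1)).sum())  # exposed, case
        b = float(((x == 1) & (y == 0)).sum())
        c = float(((x == 0) & (y == 1)).sum())
        d = float(((x == 0) & (y == 0)).sum())
        if min(a, b, c, d) == 0:
            flags.append("separation")
            a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            coef = np.log(a2 * d2 / (b2 * c2))
            se = np.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
            z = norm.ppf(0.5 + level / 2.0)
            terms = pd.DataFrame({
                "coef": [coef],
                "odds_ratio": [np.exp(coef)],
                "ci_low": [np.exp(coef - z * se)],
                "ci_high": [np.exp(coef + z * se)],
                "p": [float(2 * norm.sf(abs(coef / se)))],
            }, index=[name])
            auc, ci = _delong.auc_ci(x, y, level)
            return LogisticFitResult(terms=terms, included=[name], auc=auc,
                                     auc_ci=ci, method="wald-haldane", flags=flags)
    res = _fit_logit(pd.DataFrame({name: x}), y)
    terms = _wald_terms(res, [name], level)
    auc, ci = _delong.auc_ci(np.asarray(res.predict()), y, level)
    return LogisticFitResult(terms=terms, included=[name], auc=auc, auc_ci=ci,
                             flags=flags)


def stepwise_logistic(binaries: pd.DataFrame, labels: Sequence[int],
                      p_enter: float = 0.05, p_remove: float = 0.1,
                      level: float = 0.95, max_steps: int = 100
                      ) -> LogisticFitResult:
    """Forward-entry / backward-removal logistic regression on Wald p-values.

    Candidates are considered in column order; entry picks the smallest p
    below ``p_enter``; after each entry any included term with p above
    ``p_remove`` is dropped (largest first). Deterministic for a fixed input.
    Perfectly collinear candidates never enter (rank guard).
    """
    y = np.asarray(labels, dtype=int)
    if binaries.shape[1] < 1:
        raise ValueError("at least one candidate predictor required")
    included: List[str] = []
    flags: List[str] = []

    def _rank_ok(cols: List[str]) -> bool:
        mat = np.column_stack([np.ones(len(y))] +
                              [binaries[c].to_numpy(dtype=float) for c in cols])
        return np.linalg.matrix_rank(mat) == mat.shape[1]

    for _ in range(max_steps):
        changed = False
        # entry
        best_p, best_c = None, None
        for c in binaries.columns:
            if c in included or not _rank_ok(included + [c]):
                continue
            cols = included + [c]
            try:
                res = _fit_logit(binaries[cols], y)
                p, degenerate = _term_pvalue(binaries[cols], y, c, res)
            except Exception:
                continue
            if degenerate and "separation" not in flags:
                flags.append("separation")
            if np.isnan(p):
                continue
            if best_p is None or p < best_p:
                best_p, best_c = p, c
        if best_c is not None and best_p <= p_enter:
            included.append(best_c)
            changed = True
        # removal
        while included:
            res = _fit_logit(binaries[included], y)
            pvals = {c: _term_pvalue(binaries[included], y, c, res)[0]
                     for c in included}
            worst = max(pvals, key=lambda c: pvals[c])
            if pvals[worst] > p_remove:
                included.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break

    if not included:
        flags.append("intercept-only")
        p1 = float(y.mean())
        terms = pd.DataFrame(columns=["coef", "odds_ratio", "ci_low", "ci_high", "p"])
        return LogisticFitResult(terms=terms, included=[], auc=0.5,
                                 auc_ci=(0.5, 0.5), flags=flags)
    res = _fit_logit(binaries[included], y)
    terms = _wald_terms(res, included, level)
    auc, ci = _delong.auc_ci(np.asarray(res.predict()), y, level)
    return LogisticFitResult(terms=terms, included=included, auc=auc,
                             auc_ci=ci, flags=flags)


def roc_auc(scores: Sequence[float], labels: Sequence[int],
            level: float = 0.95, method: str = "delong"
            ) -> Tuple[float, Tuple[float, float]]:
    """Empirical rank-based AUC (ties count one-half) with a 95% CI.

    ``method`` is 'delong' (default) or 'hanley' (Hanley-McNeil SE).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if method == "delong":
        return _delong.auc_ci(scores, labels, level)
    if method == "hanley":
        auc, _, _ = _delong.auc_components(scores, labels)
        m = int((labels == 1).sum())
        n = int((labels == 0).sum())
        q1 = auc / (2 - auc)
        q2 = 2 * auc**2 / (1 + auc)
        var = (auc * (1 - auc) + (m - 1) * (q1 - auc**2)
               + (n - 1) * (q2 - auc**2)) / (m * n)
        z = norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(max(var, 0.0))
        return auc, (max(0.0, auc - half), min(1.0, auc + half))
    raise ValueError(f"unknown CI method {method!r}")


def cutoff_table(features: pd.DataFrame, labels: Sequence[int],
                 selected: Sequence[str]) -> pd.DataFrame:
    """Per-feature cutoff report: rule, per-binary-group n and mean +/- SD."""
    y = np.asarray(labels, dtype=int)
    rows = []
    for name in selected:
        vals = features[name].to_numpy(dtype=float)
        rule = youden_cutoff(vals, y, feature=name)
        scored = binarize(vals, rule)
        rows.append({
            "feature": name,
            "cutoff": rule.threshold,
            "direction": rule.direction,
            "youden_j": rule.youden_j,
            "n_score0": int((scored == 0).sum()),
            "mean_score0": float(vals[scored == 0].mean()) if (scored == 0).any() else np.nan,
            "sd_score0": float(vals[scored == 0].std(ddof=1)) if (scored == 0).sum() > 1 else np.nan,
            "n_score1": int((scored == 1).sum()),
            "mean_score1": float(vals[scored == 1].mean()) if (scored == 1).any() else np.nan,
            "sd_score1": float(vals[scored == 1].std(ddof=1)) if (scored == 1).sum() > 1 else np.nan,
        })
    return pd.DataFrame(rows)
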