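"""Paired reader-study statistics: confusion metrics, McNemar tests,
paired-difference confidence intervals and paired AUC comparison.

Discordance for McNemar is defined on *correctness* (agreement with the
ground truth), since the compared quantities are the accuracy, sensitivity
or specificity of the same cases under two reading conditions. The exact
two-sided binomial test is used when the discordant total is at most 25,
otherwise a continuity-corrected chi-square. Percentages are reported with
the raw integer counts retained alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binomtest, chi2, norm

from . import _delong

EXACT_SWITCH = 25  # exact binomial when b + c <= this


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return 100.0 * self.tp / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return 100.0 * self.tn / denom if denom else float("nan")

    @property
    def ppv(self) -> Optional[float]:
        denom = self.tp + self.fp
        return 100.0 * self.tp / denom if denom else None

    @property
    def npv(self) -> Optional[float]:
        denom = self.tn + self.fn
        return 100.0 * self.tn / denom if denom else None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "ppv": self.ppv, "npv": self.npv,
        }


def confusion_metrics(pred: Sequence[int], truth: Sequence[int]) -> ConfusionMetrics:
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth lengths differ")
    if not ((truth == 1).any() and (truth == 0).any()):
        raise ValueError("truth must contain both classes")
    return ConfusionMetrics(
        tp=int(((pred == 1) & (truth == 1)).sum()),
        fp=int(((pred == 1) & (truth == 0)).sum()),
        fn=int(((pred == 0) & (truth == 1)).sum()),
        tn=int(((pred == 0) & (truth == 0)).sum()),
    )


def predictions_from_rates(sensitivity: float, specificity: float,
                           n_pos: int, n_neg: int
                           ) -> Tuple[np.ndarray, np.ndarray]:
    """(truth, prediction) vectors realizing printed sensitivity/specificity
    proportions as integer counts (rounded)."""
    tp = int(round(sensitivity * n_pos))
    tn = int(round(specificity * n_neg))
    if not (0 <= tp <= n_pos and 0 <= tn <= n_neg):
        raise ValueError("rates incompatible with class sizes")
    truth = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
    pred = np.concatenate([
        np.ones(tp, int), np.zeros(n_pos - tp, int),
        np.zeros(tn, int), np.ones(n_neg - tn, int),
    ])
    return truth, pred


def _restrict(truth: np.ndarray, restrict: str) -> np.ndarray:
    if restrict == "all":
        return np.ones_like(truth, dtype=bool)
    if restrict == "positives":
        return truth == 1
    if restrict == "negatives":
        return truth == 0
    raise ValueError(f"unknown restriction {restrict!r}")


@dataclass(frozen=True)
class McNemarResult:
    b: int                      # a correct where b wrong
    c: int                      # a wrong where b correct
    statistic: Optional[float]
    p_value: float
    method: str
    flags: Tuple[str, ...] = ()


def mcnemar(pred_a: Sequence[int], pred_b: Sequence[int], truth: Sequence[int],
            restrict: str = "all") -> McNemarResult:
    """Paired McNemar test on correctness-discordant cases.

    ``restrict`` subsets by truth to compare sensitivities ('positives') or
    specificities ('negatives').
    """
    pred_a = np.asarray(pred_a, dtype=int)
    pred_b = np.asarray(pred_b, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if not (pred_a.shape == pred_b.shape == truth.shape):
        raise ValueError("paired predictions must cover identical cases")
    sel = _restrict(truth, restrict)
    ca = pred_a[sel] == truth[sel]
    cb = pred_b[sel] == truth[sel]
    b = int((ca & ~cb).sum())
    c = int((~ca & cb).sum())
    n = b + c
    if n == 0:
        return McNemarResult(b=b, c=c, statistic=None, p_value=1.0,
                             method="exact-binomial", flags=("no discordance",))
    if n <= EXACT_SWITCH:
        p = binomtest(min(b, c), n, 0.5, alternative="two-sided").pvalue
        return McNemarResult(b=b, c=c, statistic=None, p_value=float(min(1.0, p)),
                             method="exact-binomial")
    stat = (abs(b - c) - 1.0) ** 2 / n
    p = float(chi2.sf(stat, df=1))
    return McNemarResult(b=b, c=c, statistic=float(stat), p_value=p,
                         method="chi2-continuity")


@dataclass(frozen=True)
class PairedDifference:
    metric: str
    value_a: float              # percent
    value_b: float              # percent
    difference: float           # percentage points, b - a
    ci: Tuple[float, float]
    method: str = "wald-paired"


def paired_diff_ci(pred_a: Sequence[int], pred_b: Sequence[int],
                   truth: Sequence[int], metric: str = "accuracy",
                   level: float = 0.95) -> PairedDifference:
    """Difference (condition B minus A) of accuracy/sensitivity/specificity in
    percentage points, with a paired-proportion Wald CI from discordant counts."""
    restrict = {"accuracy": "all", "sensitivity": "positives",
                "specificity": "negatives"}[metric]
    pred_a = np.asarray(pred_a, dtype=int)
    pred_b = np.asarray(pred_b, dtype=int)
    truth = np.asarray(truth, dtype=int)
    sel = _restrict(truth, restrict)
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"no cases in restriction for metric {metric!r}")
    ca = pred_a[sel] == truth[sel]
    cb = pred_b[sel] == truth[sel]
    pa = float(ca.mean())
    pb = float(cb.mean())
    b = int((ca & ~cb).sum())
    c = int((~ca & cb).sum())
    diff = pb - pa
    var = (b + c - (b - c) ** 2 / n) / n**2
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return PairedDifference(metric=metric, value_a=100 * pa, value_b=100 * pb,
                            difference=100 * diff,
                            ci=(100 * (diff - half), 100 * (diff + half)))


def compare_auc_paired(scores_a: Sequence[float], scores_b: Sequence[float],
                       truth: Sequence[int]) -> Tuple[float, float, float]:
    """DeLong paired AUC comparison; returns (auc_a, auc_b, p)."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if not (scores_a.shape == scores_b.shape == truth.shape):
        raise ValueError("paired scores must cover identical cases")
    return _delong.paired_test(scores_a, scores_b, truth)


def reader_report(table: pd.DataFrame, sessions: Sequence[Tuple[str, str]],
                  truth_col: str = "truth") -> pd.DataFrame:
    """Session-comparison report (one row per reader x metric) from a reader
    table with one prediction column per (reader, session).

    ``sessions`` pairs column names (before, after) per reader.
    """
    truth = table[truth_col].to_numpy(dtype=int)
    rows = []
    for col_a, col_b in sessions:
        pred_a = table[col_a].to_numpy(dtype=int)
        pred_b = table[col_b].to_numpy(dtype=int)
        for metric in ("accuracy", "sensitivity", "specificity"):
            restrict = {"accuracy": "all", "sensitivity": "positives",
                        "specificity": "negatives"}[metric]
            diff = paired_diff_ci(pred_a, pred_b, truth, metric)
            mc = mcnemar(pred_a, pred_b, truth, restrict=restrict)
            rows.append({
                "reader": col_a, "metric": metric,
                "before_pct": round(diff.value_a, 1),
                "after_pct": round(diff.value_b, 1),
                "difference_pp": round(diff.difference, 1),
                "ci_low_pp": round(diff.ci[0], 1),
                "ci_high_pp": round(diff.ci[1], 1),
                "p_value": mc.p_value,
                "mcnemar_method": mc.method,
            })
    return pd.DataFrame(rows)
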