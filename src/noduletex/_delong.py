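"""DeLong variance components for empirical AUCs (shared by modelling and
reader evaluation)."""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy.stats import norm, rankdata


def auc_components(scores: np.ndarray, labels: np.ndarray
                   ) -> Tuple[float, np.ndarray, np.ndarray]:
    """Empirical AUC (ties one-half) plus per-positive / per-negative
    structural components V10, V01."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present to compute an AUC")
    all_r = rankdata(np.concatenate([pos, neg]))
    pos_r = rankdata(pos)
    neg_r = rankdata(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return float(auc), v10, v01


def auc_variance(scores: np.ndarray, labels: np.ndarray) -> Tuple[float, float]:
    auc, v10, v01 = auc_components(scores, labels)
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, float(s10 / m + s01 / n)


def auc_ci(scores: np.ndarray, labels: np.ndarray,
           level: float = 0.95) -> Tuple[float, Tuple[float, float]]:
    """AUC with a DeLong Wald confidence interval clipped to [0, 1]."""
    auc, var = auc_variance(scores, labels)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return auc, (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def paired_test(scores_a: np.ndarray, scores_b: np.ndarray,
                labels: np.ndarray) -> Tuple[float, float, float]:
    """Two-sided DeLong test for a difference between paired AUCs.

    Returns (auc_a, auc_b, p). Zero variance with equal AUCs gives p = 1.
    """
    auc_a, v10a, v01a = auc_components(scores_a, labels)
    auc_b, v10b, v01b = auc_components(scores_b, labels)
    m, n = v10a.size, v01a.size
    if m > 1:
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    else:
        s01 = np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2.0 * norm.sf(abs(z)))
    return float(auc_a), float(auc_b), p
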