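"""Independent brute-force oracles, written against the definitions only.

Everything here is deliberately naive (explicit python loops, flood fill,
full enumeration) and shares no code with the package implementation.
"""

from __future__ import annotations

from math import comb
from typing import Dict, List, Sequence, Tuple

import numpy as np

OFFSETS_4 = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]  # 0, 45, 90, 135 degrees


def glcm_oracle(levels: np.ndarray, roi: np.ndarray, ng: int,
                distance: int = 1) -> np.ndarray:
    """Symmetric direction-pooled normalized co-occurrence matrix by pair
    enumeration."""
    counts = np.zeros((ng, ng))
    nrow, ncol = levels.shape
    for dr, dc in [(r * distance, c * distance) for r, c in OFFSETS_4]:
        for r in range(nrow):
            for c in range(ncol):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < nrow and 0 <= c2 < ncol and roi[r, c] and roi[r2, c2]:
                    a, b = levels[r, c] - 1, levels[r2, c2] - 1
                    counts[a, b] += 1
                    counts[b, a] += 1
    total = counts.sum()
    return counts / total


def glrlm_oracle(levels: np.ndarray, roi: np.ndarray, ng: int
                 ) -> Dict[str, np.ndarray]:
    """Run counts per direction by walking every line pixel by pixel."""
    nrow, ncol = levels.shape
    dirs = {"0": (0, 1), "45": (1, -1), "90": (1, 0), "135": (1, 1)}
    out = {}
    for name, (dr, dc) in dirs.items():
        runs: List[Tuple[int, int]] = []
        # starting points: pixels with no predecessor along (dr, dc)
        for r in range(nrow):
            for c in range(ncol):
                pr, pc = r - dr, c - dc
                if 0 <= pr < nrow and 0 <= pc < ncol:
                    continue  # not a line start
                rr, cc = r, c
                cur_level, cur_len = 0, 0
                while 0 <= rr < nrow and 0 <= cc < ncol:
                    if roi[rr, cc] and levels[rr, cc] == cur_level and cur_len > 0:
                        cur_len += 1
                    else:
                        if cur_len > 0:
                            runs.append((cur_level, cur_len))
                        if roi[rr, cc]:
                            cur_level, cur_len = int(levels[rr, cc]), 1
                        else:
                            cur_level, cur_len = 0, 0
                    rr += dr
                    cc += dc
                if cur_len > 0:
                    runs.append((cur_level, cur_len))
        rmax = max((ln for _, ln in runs), default=1)
        mat = np.zeros((ng, rmax))
        for level, length in runs:
            mat[level - 1, length - 1] += 1
        out[name] = mat
    return out


def glszm_oracle(levels: np.ndarray, roi: np.ndarray, ng: int) -> np.ndarray:
    """Zone counts by explicit 8-connected flood fill."""
    nrow, ncol = levels.shape
    seen = np.zeros_like(roi, dtype=bool)
    zones: List[Tuple[int, int]] = []
    for r in range(nrow):
        for c in range(ncol):
            if not roi[r, c] or seen[r, c]:
                continue
            level = levels[r, c]
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        r2, c2 = rr + dr, cc + dc
                        if (0 <= r2 < nrow and 0 <= c2 < ncol and roi[r2, c2]
                                and not seen[r2, c2] and levels[r2, c2] == level):
                            seen[r2, c2] = True
                            stack.append((r2, c2))
            zones.append((int(level), size))
    smax = max((s for _, s in zones), default=1)
    mat = np.zeros((ng, smax))
    for level, s in zones:
        mat[level - 1, s - 1] += 1
    return mat


def ngtdm_oracle(levels: np.ndarray, roi: np.ndarray, ng: int
                 ) -> Tuple[np.ndarray, np.ndarray, int]:
    """(p_i, s_i, N) by explicit neighborhood enumeration."""
    nrow, ncol = levels.shape
    s = np.zeros(ng)
    n_i = np.zeros(ng)
    total = 0
    for r in range(nrow):
        for c in range(ncol):
            if not roi[r, c]:
                continue
            neigh = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < nrow and 0 <= c2 < ncol and roi[r2, c2]:
                        neigh.append(levels[r2, c2])
            if not neigh:
                continue
            total += 1
            lvl = int(levels[r, c])
            n_i[lvl - 1] += 1
            s[lvl - 1] += abs(lvl - sum(neigh) / len(neigh))
    return (n_i / total if total else n_i), s, total


def youden_oracle(values: Sequence[float], labels: Sequence[int]
                  ) -> Tuple[float, float, str]:
    """(best J, threshold, direction) by exhaustive search over every distinct
    threshold (all observed values and midpoints) and both directions."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    uniq = np.unique(values)
    cands = list(uniq) + list((uniq[:-1] + uniq[1:]) / 2) + [-np.inf, np.inf]
    best = (-2.0, np.nan, "")
    for thr in cands:
        for direction in ("greater", "less-or-equal"):
            pred = values > thr if direction == "greater" else values <= thr
            sens = pred[labels == 1].mean()
            spec = (~pred[labels == 0]).mean()
            j = sens + spec - 1.0
            if j > best[0]:
                best = (float(j), float(thr), direction)
    return best


def mcnemar_exact_oracle(b: int, c: int) -> float:
    """Exact two-sided binomial p for b/c discordant pairs at p = 1/2."""
    n = b + c
    if n == 0:
        return 1.0
    k = min(b, c)
    tail = sum(comb(n, i) for i in range(k + 1)) / 2**n
    return min(1.0, 2.0 * tail)


def auc_oracle(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Empirical AUC by direct pair comparison, ties one-half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
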