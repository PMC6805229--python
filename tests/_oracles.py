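"""Independent brute-force oracles used by the test suite.

Each function re-derives a quantity from first principles (explicit
formula evaluation, exhaustive enumeration, exact combinatorics) and is
kept free of any package import so it cannot share a code path with the
implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def zero_adjusted_braycurtis(x, y, dummy: float) -> float:
    """Direct evaluation of sum|xi-yi| / (sum(xi+yi) + 2*dummy)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    num = float(np.abs(x - y).sum())
    den = float((x + y).sum()) + 2.0 * dummy
    return num / den


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the literal step-up rule."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def fisher_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by full hypergeometric enumeration.

    Probabilities computed with exact integer combinatorics; the
    two-sided p sums every table (same margins) whose probability does
    not exceed the observed table's (minimum-likelihood rule).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def prob(k: int) -> float:
        return math.comb(r1, k) * math.comb(r2, c1 - k) / denom

    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    p_obs = prob(a)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = prob(k)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(total, 1.0)


def maxss_exhaustive(observed, predicted) -> float:
    """Exhaustive search over every candidate threshold (all midpoints
    of distinct predictions, one value below the minimum, the maximum),
    keeping the smallest threshold among maximizers of sens + spec
    under the strict 'present iff predicted > t' rule."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    u = np.unique(predicted)
    candidates = [u[0] - 1.0]
    candidates += [0.5 * (u[i] + u[i + 1]) for i in range(len(u) - 1)]
    candidates += [u[-1]]
    n_pos = observed.sum()
    n_neg = len(observed) - n_pos
    best_t, best_ss = None, -np.inf
    for t in candidates:
        pos = predicted > t
        ss = (pos & (observed == 1)).sum() / n_pos \
            + (~pos & (observed == 0)).sum() / n_neg
        if ss > best_ss + 1e-12:
            best_ss, best_t = ss, t
    return float(best_t)


def auc_pair_count(y, score) -> float:
    """AUC as the exhaustive concordance count over all (+,-) pairs,
    ties counting one half."""
    y = np.asarray(y, dtype=float)
    score = np.asarray(score, dtype=float)
    pos = score[y == 1]
    neg = score[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def pca_eigh(X: np.ndarray):
    """Principal axes of X by direct eigendecomposition of its
    covariance matrix; returns (coordinates, pct variance per axis)."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (len(X) - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    return Xc @ v, 100.0 * w / w.sum()
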