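"""Independent reference implementations used only to cross-check the package.

Each oracle takes a deliberately different computational route from the code
it verifies: the PLS oracle uses closed-form SVD steps instead of the NIPALS
iteration, the hypergeometric oracle enumerates subsets instead of using a
distribution function, and the variance oracle is a literal two-pass sum.
"""

from itertools import combinations

import numpy as np


def svd_pls(X, y, A):
    """PLS1 via SVD of the covariance vector at each deflation step.

    At each step the weight vector is the dominant left singular vector of
    the p x 1 matrix X'y; scores/loadings/deflation use the closed-form
    expressions directly.  Returns (W, T, P) for comparison up to column
    sign.
    """
    X = np.asarray(X, float).copy()
    y = np.asarray(y, float).copy()
    X = X - X.mean(axis=0)
    y = y - y.mean()
    n, p = X.shape
    W = np.zeros((p, A))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    for a in range(A):
        M = (X.T @ y).reshape(-1, 1)
        u_svd, _, _ = np.linalg.svd(M, full_matrices=False)
        w = u_svd[:, 0]
        t = X @ w
        tt = float(t @ t)
        p_a = X.T @ t / tt
        r_a = float(y @ t) / tt
        X = X - np.outer(t, p_a)
        y = y - t * r_a
        W[:, a], T[:, a], P[:, a] = w, t, p_a
    return W, T, P


def hypergeom_tail_enumeration(N, m, n, k):
    """P(X >= k) by exhaustive enumeration of all n-subsets of an N-universe."""
    universe = list(range(N))
    pathway = set(range(m))
    total = 0
    hits = 0
    for draw in combinations(universe, n):
        total += 1
        if len(pathway & set(draw)) >= k:
            hits += 1
    return hits / total


def two_pass_sd(values, ddof=1):
    """Literal two-pass sample standard deviation."""
    v = list(float(x) for x in values)
    mean = sum(v) / len(v)
    ss = sum((x - mean) ** 2 for x in v)
    return (ss / (len(v) - ddof)) ** 0.5


def lorentzian_interval_area(center, fwhm, lo, hi):
    """Closed-form integral of a unit-area Lorentzian over [lo, hi]."""
    gamma = fwhm / 2.0
    return (np.arctan((hi - center) / gamma) - np.arctan((lo - center) / gamma)) / np.pi


def auc_by_pair_counting(y_true, decision):
    """AUC as the concordant-pair fraction with half-credit for ties."""
    pos = [d for t, d in zip(y_true, decision) if t == 1]
    neg = [d for t, d in zip(y_true, decision) if t == -1]
    score = 0.0
    for a in pos:
        for b in neg:
            score += 1.0 if a > b else (0.5 if a == b else 0.0)
    return score / (len(pos) * len(neg))
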