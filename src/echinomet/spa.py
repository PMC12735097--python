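"""Subwindow Permutation Analysis (SPA) variable selection.

SPA populates N Monte-Carlo PLS-LDA sub-models, each trained on a random
stratified subset of samples (fraction ``ratio``) and Q randomly drawn
variables, with the latent-variable count optimized by internal K-fold CV.
Each sub-model's held-out misclassification rate is the "normal" prediction
error for every variable it contains; permuting one variable's values across
the held-out samples (trained model fixed) yields that variable's "permuted"
error.  Per variable, the normal and permuted error samples are compared by
a one-sided rank-sum test (permuted stochastically greater); the Conditional
Synergistic Score is COSS = -log10(p) with p floored at 1/(N+1), and
variables with COSS above the threshold (default 2, i.e. p < 0.01) are
selected.  DMEAN and DSD are the differences of means and standard
deviations (permuted minus normal), whose plane separates informative
(DMEAN > 0) from uninformative variables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .preprocess import FeatureMatrix, apply_scaling, scale
from .plslda import fit_discriminant, fit_nipals_pls, stratified_folds


@dataclass(frozen=True)
class SPAConfig:
    N: int = 1000  # Monte-Carlo iterations
    Q: int = 15  # variables per sub-model
    K: int = 3  # internal CV folds
    ratio: float = 0.7  # calibration fraction
    scaling: str = "pareto"
    coss_threshold: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.ratio < 1.0):
            raise ValueError("ratio must be in (0, 1)")
        if self.N < 100:
            raise ValueError("N must be >= 100")
        if self.Q < 1 or self.K < 2:
            raise ValueError("Q >= 1 and K >= 2 required")


@dataclass
class SPAResult:
    n_normal: np.ndarray  # per-bin count of normal errors collected
    n_permuted: np.ndarray
    dmean: np.ndarray  # mean(permuted) - mean(normal)
    dsd: np.ndarray  # sd(permuted) - sd(normal)
    p: np.ndarray
    coss: np.ndarray
    selected: np.ndarray  # indices with coss > threshold, descending coss
    never_sampled: np.ndarray  # flagged variables that entered no sub-model
    config: SPAConfig


def coss_from_p(p: float, n_iterations: int | None = None) -> float:
    """Conditional Synergistic Score: COSS = -log10(p).

    When ``n_iterations`` is given, p is floored at 1/(N+1) (the resolution
    of an N-iteration Monte-Carlo permutation scheme) so the score stays
    finite; p = 0.01 maps to exactly 2, the conventional significance
    cut-off.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be in [0, 1]")
    if n_iterations is not None:
        p = min(1.0, max(p, 1.0 / (n_iterations + 1.0)))
    elif p == 0.0:
        raise ValueError("p = 0 needs an n_iterations floor")
    return float(-np.log10(p))


# --- rank-sum p-value -------------------------------------------------------

def _midrank_u(normal: np.ndarray, permuted: np.ndarray) -> float:
    """Mann-Whitney U of the permuted sample (ties counted half)."""
    m = len(permuted)
    ranks = rankdata(np.concatenate([permuted, normal]))
    return float(np.sum(ranks[:m]) - m * (m + 1) / 2.0)


def rank_sum_p(normal, permuted, method: str = "auto") -> float:
    """One-sided Mann-Whitney p for 'permuted stochastically greater than normal'.

    Exact by enumeration of all C(n+m, m) group assignments when both samples
    have at most 8 values (valid under ties); tie-corrected normal
    approximation with continuity correction otherwise.  ``method`` forces
    one branch ("exact"/"approx") for cross-checking.
    """
    if method not in ("auto", "exact", "approx"):
        raise ValueError("method must be auto, exact or approx")
    a = np.asarray(normal, float)
    b = np.asarray(permuted, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n, m = a.size, b.size
    u_obs = _midrank_u(a, b)
    if method == "exact" or (method == "auto" and n <= 8 and m <= 8):
        combined = np.concatenate([b, a])
        ranks = rankdata(combined)
        total = 0
        hits = 0
        offset = m * (m + 1) / 2.0
        for idx in itertools.combinations(range(n + m), m):
            u = float(np.sum(ranks[list(idx)]) - offset)
            total += 1
            if u >= u_obs - 1e-12:
                hits += 1
        return hits / total
    # tie-corrected normal approximation
    N = n + m
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (N * (N - 1))
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (u_obs - n * m / 2.0 - 0.5) / np.sqrt(var)
    return float(norm.sf(z))


# --- sub-model machinery ----------------------------------------------------

def _stratified_calibration(y: np.ndarray, ratio: float, rng: np.random.Generator):
    cal = []
    for cls in (1, -1):
        idx = np.nonzero(y == cls)[0]
        k = int(np.ceil(ratio * idx.size))
        cal.append(rng.choice(idx, size=k, replace=False))
    cal = np.sort(np.concatenate(cal))
    test = np.setdiff1d(np.arange(y.size), cal)
    return cal, test


def _choose_lv(Xc: np.ndarray, yc: np.ndarray, K: int, a_max: int,
               scaling: str, rng: np.random.Generator) -> int:
    """Internal K-fold CV over 1..a_max components; smallest-A tie-break."""
    errors = np.zeros(a_max)
    counts = 0
    for te in stratified_folds(yc, K, rng):
        tr = np.setdiff1d(np.arange(yc.size), te)
        a_lim = min(a_max, tr.size - 1)
        sm = scale(Xc[tr], scaling)
        model = fit_nipals_pls(sm, yc[tr], a_lim, strict=False)
        a_lim = model.A  # may truncate on vanishing residuals
        Xte = apply_scaling(Xc[te], sm)
        for a in range(1, a_max + 1):
            aa = min(a, a_lim)
            Wa, Pa, ra = model.W[:, :aa], model.P[:, :aa], model.r[:aa]
            w_star = Wa @ np.linalg.inv(Pa.T @ Wa)
            bnd = fit_discriminant(model.T[:, :aa], yc[tr])
            pred = bnd.classify(Xte @ w_star)
            errors[a - 1] += np.sum(pred != yc[te])
        counts += te.size
    cv_err = errors / counts
    return int(np.argmin(cv_err)) + 1  # argmin takes the first (smallest A) on ties


def run_spa(fm: FeatureMatrix, config: SPAConfig | None = None) -> SPAResult:
    """Run subwindow permutation analysis on a (normalized) feature matrix."""
    config = config or SPAConfig()
    X, y = fm.data, fm.labels
    n, p = X.shape
    if config.Q > p:
        raise ValueError("Q exceeds the number of bins")
    if not ({-1, 1} <= set(np.unique(y))):
        raise ValueError("both classes required")
    rng = np.random.default_rng(config.seed)

    normal_errors: list[list[float]] = [[] for _ in range(p)]
    permuted_errors: list[list[float]] = [[] for _ in range(p)]

    for _ in range(config.N):
        cal, test = _stratified_calibration(y, config.ratio, rng)
        variables = rng.choice(p, size=config.Q, replace=False)
        Xc, Xt = X[np.ix_(cal, variables)], X[np.ix_(test, variables)]
        yc, yt = y[cal], y[test]

        a_max = max(1, min(config.Q, cal.size - config.K))
        a_best = _choose_lv(Xc, yc, config.K, a_max, config.scaling, rng)

        sm = scale(Xc, config.scaling)
        model = fit_nipals_pls(sm, yc, min(a_best, cal.size - 1), strict=False)
        bnd = fit_discriminant(model.T, yc)
        w_star = model.w_star
        Xts = apply_scaling(Xt, sm)
        e0 = float(np.mean(bnd.classify(Xts @ w_star) != yt))

        for col in range(config.Q):
            Xp = Xts.copy()
            Xp[:, col] = Xp[rng.permutation(Xp.shape[0]), col]
            e1 = float(np.mean(bnd.classify(Xp @ w_star) != yt))
            j = int(variables[col])
            normal_errors[j].append(e0)
            permuted_errors[j].append(e1)

    floor = 1.0 / (config.N + 1.0)
    n_norm = np.array([len(v) for v in normal_errors])
    n_perm = np.array([len(v) for v in permuted_errors])
    never = n_norm == 0
    dmean = np.zeros(p)
    dsd = np.zeros(p)
    pvals = np.ones(p)
    for j in range(p):
        if never[j]:
            continue
        a = np.array(normal_errors[j])
        b = np.array(permuted_errors[j])
        dmean[j] = float(b.mean() - a.mean())
        sd_a = float(a.std(ddof=1)) if a.size > 1 else 0.0
        sd_b = float(b.std(ddof=1)) if b.size > 1 else 0.0
        dsd[j] = sd_b - sd_a
        pvals[j] = min(1.0, max(rank_sum_p(a, b), floor))
    coss = np.array([coss_from_p(v) for v in pvals])
    coss[never] = 0.0
    sel = select_variables_from_arrays(coss, config.coss_threshold)
    return SPAResult(
        n_normal=n_norm, n_permuted=n_perm, dmean=dmean, dsd=dsd,
        p=pvals, coss=coss, selected=sel, never_sampled=never, config=config,
    )


def select_variables_from_arrays(coss: np.ndarray, threshold: float) -> np.ndarray:
    idx = np.nonzero(coss > threshold)[0]
    return idx[np.argsort(-coss[idx], kind="stable")]


def select_variables(res: SPAResult, threshold: float | None = None) -> np.ndarray:
    """Indices with COSS strictly greater than threshold, descending COSS."""
    thr = res.config.coss_threshold if threshold is None else threshold
    return select_variables_from_arrays(res.coss, thr)
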