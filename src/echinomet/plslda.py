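"""NIPALS PLS regression on class labels with an LDA rule in score space.

The spectral matrix X is decomposed as X = T*P' and the centered class
vector y (+1/-1) as y = T*r'; the discriminant boundary is a two-class LDA
with pooled covariance fitted to the scores, so the decision value is affine
in the latent variables (c'*t + c0 = 0 defines the boundary).  Diagnostics
are Wold VIP scores and Kvalheim-style target-projection loadings; model
quality is assessed by stratified repeated cross-validation (error,
per-class sensitivity/specificity, midrank ROC AUC) and a label-permutation
test on the AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, rankdata

from .preprocess import FeatureMatrix, ScaledMatrix, apply_scaling, scale


@dataclass
class PLSModel:
    A: int
    W: np.ndarray  # bins x A, unit-norm weight columns
    T: np.ndarray  # samples x A scores
    P: np.ndarray  # bins x A x-loadings
    r: np.ndarray  # A-vector of y-loadings
    U: np.ndarray  # samples x A y-scores
    q: np.ndarray  # y-loading scalars (PLS1: ones)
    r2x_cum: np.ndarray
    r2y_cum: np.ndarray
    y_mean: float
    pretreatment: ScaledMatrix | None = None
    X_: np.ndarray = field(default=None, repr=False)  # pretreated training matrix

    @property
    def w_star(self) -> np.ndarray:
        """Weights W* = W (P'W)^-1 mapping pretreated X directly to scores."""
        return self.W @ np.linalg.inv(self.P.T @ self.W)

    @property
    def b(self) -> np.ndarray:
        """Regression vector: y_hat = Xs @ b + y_mean."""
        return self.w_star @ self.r

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        Xs = apply_scaling(X_new, self.pretreatment) if self.pretreatment is not None else np.asarray(X_new, float)
        return Xs @ self.w_star

    def predict_y(self, X_new: np.ndarray) -> np.ndarray:
        Xs = apply_scaling(X_new, self.pretreatment) if self.pretreatment is not None else np.asarray(X_new, float)
        return Xs @ self.b + self.y_mean


@dataclass
class DiscriminantBoundary:
    coefficients: np.ndarray  # c1..cA
    intercept: float  # c0
    class_map: dict
    boundary_2d: tuple[float, float, float] | None = None  # (c1, c2, c0) on LV1/LV2

    def decision(self, T: np.ndarray) -> np.ndarray:
        return np.asarray(T, float) @ self.coefficients + self.intercept

    def classify(self, T: np.ndarray) -> np.ndarray:
        return np.where(self.decision(T) > 0, 1, -1)


@dataclass
class CVMetrics:
    error: float
    sensitivity: float
    specificity: float
    auc: float
    cv_scores: np.ndarray  # pooled held-out decision values
    cv_truth: np.ndarray
    folds: int
    repeats: int
    seed: int


@dataclass
class DiagnosticProfile:
    vip: np.ndarray
    tp_loadings: np.ndarray
    selected: np.ndarray  # bin indices with vip above threshold
    vip_threshold: float


def fit_nipals_pls(
    X: ScaledMatrix | np.ndarray,
    y,
    A: int,
    *,
    tol: float = 1e-12,
    max_iter: int = 500,
    strict: bool = True,
) -> PLSModel:
    """Fit an A-component PLS1 model by NIPALS with deflation.

    Per component: iterate w = X'u/||X'u||, t = X w, until t stabilizes
    (immediate for a single y); then p = X't/(t't), r_a = y't/(t't) and
    deflation X <- X - t p', y <- y - t r_a.

    With ``strict=False`` the model is truncated (instead of raising) when
    the X or y residual vanishes before reaching A components.
    """
    pre = X if isinstance(X, ScaledMatrix) else None
    Xw = (X.data if pre is not None else np.asarray(X, float)).copy()
    X0 = Xw.copy()
    y = np.asarray(y, float).copy()
    if len(np.unique(y)) < 2:
        raise ValueError("y must take two values")
    n, p = Xw.shape
    if not (1 <= A <= min(n - 1, p)):
        raise ValueError(f"A={A} exceeds the rank-permitting limit min(n-1, p)={min(n - 1, p)}")
    ssx0 = float(np.sum(Xw**2))
    if ssx0 == 0:
        raise ValueError("zero-variance X")
    y_mean = float(y.mean())
    yw = y - y_mean
    ssy0 = float(np.sum(yw**2))

    W = np.zeros((p, A))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    U = np.zeros((n, A))
    r = np.zeros(A)
    q = np.ones(A)
    r2x = np.zeros(A)
    r2y = np.zeros(A)
    a_done = 0
    for a in range(A):
        u = yw.copy()
        if float(u @ u) <= tol * max(ssy0, 1e-300):
            if strict:
                raise ValueError(f"y residual vanished before component {a + 1}; lower A")
            break
        t_old = None
        degenerate = False
        for _ in range(max_iter):
            w = Xw.T @ u
            nw = float(np.linalg.norm(w))
            if nw <= tol:
                if strict:
                    raise ValueError(f"X residual vanished before component {a + 1}; lower A")
                degenerate = True
                break
            w /= nw
            t = Xw @ w
            c = float(yw @ t) / float(t @ t)
            u = yw * c  # single-y inner relation; converges on first pass
            if t_old is not None and np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
                break
            t_old = t
        if degenerate:
            break
        tt = float(t @ t)
        p_a = Xw.T @ t / tt
        r_a = float(yw @ t) / tt
        Xw -= np.outer(t, p_a)
        W[:, a], T[:, a], P[:, a], U[:, a], r[a] = w, t, p_a, u, r_a
        yw = yw - t * r_a
        r2x[a] = 1.0 - float(np.sum(Xw**2)) / ssx0
        r2y[a] = 1.0 - float(np.sum(yw**2)) / ssy0
        a_done = a + 1

    if a_done < A:  # truncated (strict=False)
        W, T, P, U = W[:, :a_done], T[:, :a_done], P[:, :a_done], U[:, :a_done]
        r, q, r2x, r2y = r[:a_done], q[:a_done], r2x[:a_done], r2y[:a_done]

    return PLSModel(
        A=a_done, W=W, T=T, P=P, r=r, U=U, q=q,
        r2x_cum=r2x, r2y_cum=r2y, y_mean=y_mean,
        pretreatment=pre, X_=X0,
    )


def vip(model: PLSModel) -> np.ndarray:
    """Wold VIP: VIP_j = sqrt(p * sum_a SSY_a w_ja^2 / sum_a SSY_a); sum VIP^2 = p."""
    p = model.W.shape[0]
    ssy = model.r**2 * np.einsum("ia,ia->a", model.T, model.T)  # y-variance per component
    wnorm2 = model.W**2 / np.maximum(np.sum(model.W**2, axis=0), 1e-300)
    return np.sqrt(p * (wnorm2 @ ssy) / float(np.sum(ssy)))


def tp_loadings(model: PLSModel) -> np.ndarray:
    """Target-projection loadings: X projected onto the normalized regression vector."""
    b = model.b
    nb = float(np.linalg.norm(b))
    if nb == 0:
        raise ValueError("zero regression vector")
    t_tp = model.X_ @ (b / nb)
    return model.X_.T @ t_tp / float(t_tp @ t_tp)


def diagnostics(model: PLSModel, vip_threshold: float = 1.0) -> DiagnosticProfile:
    v = vip(model)
    return DiagnosticProfile(
        vip=v,
        tp_loadings=tp_loadings(model),
        selected=np.nonzero(v > vip_threshold)[0],
        vip_threshold=vip_threshold,
    )


# --- LDA in score space -----------------------------------------------------

def fit_discriminant(
    T: np.ndarray,
    labels,
    class_names: tuple[str, str] = ("A_lixula", "P_lividus"),
) -> DiscriminantBoundary:
    """Two-class LDA with pooled covariance on the PLS scores.

    Returns c, c0 with sign(c't + c0) the predicted class; also the boundary
    restricted to the first two latent variables for plotting.  A singular
    pooled covariance is ridge-regularized by 1e-8 * trace/A on the diagonal.
    """
    T = np.atleast_2d(np.asarray(T, float))
    y = np.asarray(labels, int)
    if not ({-1, 1} <= set(np.unique(y))):
        raise ValueError("both classes required")

    def _lda(Ts: np.ndarray) -> tuple[np.ndarray, float]:
        pos, neg = Ts[y == 1], Ts[y == -1]
        mu_p, mu_n = pos.mean(axis=0), neg.mean(axis=0)
        n_p, n_n = len(pos), len(neg)
        S = ((pos - mu_p).T @ (pos - mu_p) + (neg - mu_n).T @ (neg - mu_n)) / (n_p + n_n - 2)
        S = np.atleast_2d(S)
        cond = np.linalg.cond(S)
        if not np.isfinite(cond) or cond > 1e12:
            S = S + (1e-8 * np.trace(S) / S.shape[0] + 1e-300) * np.eye(S.shape[0])
        c = np.linalg.solve(S, mu_p - mu_n)
        c0 = -0.5 * float(c @ (mu_p + mu_n)) + float(np.log(n_p / n_n))
        return c, c0

    c, c0 = _lda(T)
    b2 = None
    if T.shape[1] >= 2:
        c2, c02 = _lda(T[:, :2])
        b2 = (float(c2[0]), float(c2[1]), float(c02))
    return DiscriminantBoundary(
        coefficients=c,
        intercept=c0,
        class_map={1: class_names[0], -1: class_names[1]},
        boundary_2d=b2,
    )


# --- performance ------------------------------------------------------------

def roc_auc(y_true, decision) -> float:
    """Midrank (tie-aware trapezoidal) ROC AUC for +1/-1 truth."""
    y = np.asarray(y_true, int)
    d = np.asarray(decision, float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = rankdata(d)  # midranks
    return float((np.sum(ranks[y == 1]) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def stratified_folds(labels, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Index partition with each class spread as evenly as possible over folds."""
    y = np.asarray(labels, int)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in (1, -1):
        idx = np.nonzero(y == cls)[0]
        rng.shuffle(idx)
        for k, i in enumerate(idx):
            folds[k % n_folds].append(int(i))
    out = [np.sort(np.array(f, int)) for f in folds]
    if any(len(f) == 0 for f in out):
        raise ValueError("fold without samples; reduce n_folds")
    return out


def _fit_fold(X_tr, y_tr, X_te, A, method):
    sm = scale(X_tr, method)
    model = fit_nipals_pls(sm, y_tr, A)
    bnd = fit_discriminant(model.T, y_tr)
    return bnd.decision(model.transform(X_te))


def cross_validate(
    fm: FeatureMatrix,
    A: int = 3,
    folds: int = 5,
    repeats: int = 20,
    method: str = "centre",
    seed: int = 0,
) -> CVMetrics:
    """Stratified repeated K-fold CV with pretreatment re-estimated per fold.

    Held-out LDA decision values are pooled over all repeats; error,
    per-class sensitivity/specificity use the sign rule, AUC is midrank.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X, y = fm.data, fm.labels
    rng = np.random.default_rng(seed)
    dec_pool, truth_pool = [], []
    for _ in range(repeats):
        for te in stratified_folds(y, folds, rng):
            tr = np.setdiff1d(np.arange(len(y)), te)
            if len(np.unique(y[tr])) < 2:
                raise ValueError("training fold lost a class")
            a_eff = min(A, len(tr) - 1, X.shape[1])
            dec = _fit_fold(X[tr], y[tr], X[te], a_eff, method)
            dec_pool.append(dec)
            truth_pool.append(y[te])
    dec = np.concatenate(dec_pool)
    truth = np.concatenate(truth_pool)
    pred = np.where(dec > 0, 1, -1)
    err = float(np.mean(pred != truth))
    sens = float(np.mean(pred[truth == 1] == 1))
    spec = float(np.mean(pred[truth == -1] == -1))
    return CVMetrics(
        error=err, sensitivity=sens, specificity=spec,
        auc=roc_auc(truth, dec), cv_scores=dec, cv_truth=truth,
        folds=folds, repeats=repeats, seed=seed,
    )


def permutation_test(
    fm: FeatureMatrix,
    A: int = 3,
    n_perm: int = 199,
    folds: int = 5,
    method: str = "centre",
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Label-permutation test on the cross-validated AUC.

    Returns (p, observed_auc, permuted_aucs) with the add-one estimator
    p = (1 + #{perm AUC >= observed}) / (n_perm + 1).  Observed and permuted
    AUCs use the identical single-repeat CV procedure.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    obs = cross_validate(fm, A, folds, repeats=1, method=method,
                         seed=int(rng.integers(2**31))).auc
    perm_aucs = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = rng.permutation(fm.labels)
        fm_p = FeatureMatrix(fm.data, y_perm, list(fm.bin_edges), list(fm.sample_ids))
        perm_aucs[i] = cross_validate(fm_p, A, folds, repeats=1, method=method,
                                      seed=int(rng.integers(2**31))).auc
    p = (1.0 + float(np.sum(perm_aucs >= obs))) / (n_perm + 1.0)
    return p, obs, perm_aucs


def confidence_ellipse(T2: np.ndarray, level: float = 0.95):
    """95%-style Gaussian ellipse for a 2-D score cloud.

    Semi-axes are sqrt(eigenvalue * chi2.ppf(level, df=2)); the angle is the
    orientation of the major axis in degrees.
    """
    T2 = np.asarray(T2, float)
    if T2.ndim != 2 or T2.shape[1] != 2:
        raise ValueError("T2 must be n x 2")
    if T2.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    center = T2.mean(axis=0)
    cov = np.cov(T2, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    if np.any(evals <= 0):
        raise ValueError("degenerate covariance")
    k = chi2.ppf(level, df=2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    angle = float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])))
    return {
        "center": center,
        "semi_axes": np.sqrt(evals * k),
        "angle_deg": angle,
        "chi2_scale": float(k),
    }
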