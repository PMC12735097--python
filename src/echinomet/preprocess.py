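"""Spectra to feature matrix: binning, exclusions, normalization, scaling.

Bins are half-open ppm intervals [hi, lo), sorted descending; a bin's value
is the trapezoidal integral of the spectrum over the interval.  Exclusion
windows (residual water, TSP) drop whole bins.  Row normalization is by
total area; column pretreatments are mean centering, Pareto scaling
((x - mean)/sqrt(sd)) and autoscaling, with sample (ddof=1) standard
deviations throughout.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .synthetic import DEFAULT_EXCLUSIONS, Spectrum

SCALING_METHODS = ("centre", "pareto", "auto", "none")


@dataclass
class FeatureMatrix:
    """Samples x bins matrix with +1/-1 class labels and bin ppm ranges."""

    data: np.ndarray
    labels: np.ndarray
    bin_edges: list[tuple[float, float]]  # (ppm_hi, ppm_lo), descending, [hi, lo)
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("feature matrix contains non-finite values")
        if self.data.shape[0] != self.labels.size or self.data.shape[0] != len(self.sample_ids):
            raise ValueError("rows, labels and sample_ids must agree")
        if self.data.shape[1] != len(self.bin_edges):
            raise ValueError("columns and bin_edges must agree")
        his = np.array([e[0] for e in self.bin_edges])
        los = np.array([e[1] for e in self.bin_edges])
        if np.any(los >= his):
            raise ValueError("each bin must satisfy hi > lo")
        if np.any(his[1:] > los[:-1] + 1e-12):
            raise ValueError("bins must be non-overlapping and descending")
        if not (set(np.unique(self.labels)) <= {-1, 0, 1}):
            raise ValueError("labels must be +1/-1 (0 = unassigned)")

    @property
    def bin_centers(self) -> np.ndarray:
        return np.array([(hi + lo) / 2.0 for hi, lo in self.bin_edges])

    def copy_with(self, data: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(data, self.labels.copy(), list(self.bin_edges), list(self.sample_ids))


@dataclass
class ScaledMatrix:
    """Column-pretreated matrix with the statistics needed to invert it."""

    data: np.ndarray
    column_means: np.ndarray
    column_scales: np.ndarray
    method: str
    zero_variance: np.ndarray = field(default=None)  # flagged sd == 0 columns

    def inverse(self) -> np.ndarray:
        return self.data * self.column_scales + self.column_means


def _cum_integral(spectrum: Spectrum):
    """Cumulative trapezoid on the ascending axis, as an interpolator."""
    ppm_asc = spectrum.ppm[::-1]
    y_asc = spectrum.intensity[::-1]
    cum = np.concatenate([[0.0], cumulative_trapezoid(y_asc, ppm_asc)])
    return ppm_asc, cum


def _interval_integral(ppm_asc, cum, lo: float, hi: float) -> float:
    lo = max(lo, float(ppm_asc[0]))
    hi = min(hi, float(ppm_asc[-1]))
    if hi <= lo:
        return 0.0
    c_lo, c_hi = np.interp([lo, hi], ppm_asc, cum)
    return float(c_hi - c_lo)


def bin_spectra(
    spectra: Sequence[Spectrum],
    bin_width_ppm: float = 0.01,
    exclusions: Sequence[tuple[float, float]] = DEFAULT_EXCLUSIONS,
    *,
    labels: Sequence[int] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Integrate each spectrum over uniform descending bins.

    All spectra must share one axis.  Bins start at the axis maximum and
    descend in steps of ``bin_width_ppm``; an incomplete final bin is
    dropped, as is any bin overlapping an exclusion window.
    """
    if not spectra:
        raise ValueError("no spectra")
    axis = spectra[0].ppm
    for s in spectra[1:]:
        if s.ppm.shape != axis.shape or not np.allclose(s.ppm, axis):
            raise ValueError("spectra must share a common ppm axis")
    resolution = float(np.max(np.abs(np.diff(axis))))
    if bin_width_ppm <= resolution:
        raise ValueError("bin width must exceed the axis resolution")

    hi_axis, lo_axis = float(axis[0]), float(axis[-1])
    n_bins = int(np.floor((hi_axis - lo_axis) / bin_width_ppm + 1e-9))
    edges = []
    for i in range(n_bins):
        b_hi = hi_axis - i * bin_width_ppm
        b_lo = b_hi - bin_width_ppm
        if any(b_hi > min(e) and b_lo < max(e) for e in exclusions):
            continue
        edges.append((b_hi, b_lo))
    if not edges:
        raise ValueError("no bins remain after exclusions")

    data = np.empty((len(spectra), len(edges)))
    for r, s in enumerate(spectra):
        ppm_asc, cum = _cum_integral(s)
        for c, (b_hi, b_lo) in enumerate(edges):
            data[r, c] = _interval_integral(ppm_asc, cum, b_lo, b_hi)

    n = len(spectra)
    labels = np.asarray(labels, int) if labels is not None else np.zeros(n, int)
    ids = list(sample_ids) if sample_ids is not None else [f"S{i+1:03d}" for i in range(n)]
    return FeatureMatrix(data, labels, edges, ids)


def normalize_total_area(fm: FeatureMatrix) -> FeatureMatrix:
    """Scale each row to unit sum."""
    totals = fm.data.sum(axis=1)
    if np.any(totals <= 0):
        bad = [fm.sample_ids[i] for i in np.nonzero(totals <= 0)[0]]
        raise ValueError(f"non-positive row total for samples {bad}")
    return fm.copy_with(fm.data / totals[:, None])


def normalize_pqn(fm: FeatureMatrix) -> FeatureMatrix:
    """Probabilistic quotient normalization against the cohort median profile."""
    fm = normalize_total_area(fm)
    ref = np.median(fm.data, axis=0)
    keep = ref > 0
    quotients = np.median(fm.data[:, keep] / ref[keep], axis=1)
    return fm.copy_with(fm.data / quotients[:, None])


def scale(fm: FeatureMatrix | np.ndarray, method: str = "centre") -> ScaledMatrix:
    """Column pretreatment: centre, pareto, auto or none (sample sd, ddof=1)."""
    if method not in SCALING_METHODS:
        raise ValueError(f"unknown scaling method {method!r}; pick from {SCALING_METHODS}")
    X = fm.data if isinstance(fm, FeatureMatrix) else np.asarray(fm, dtype=float)
    if X.shape[0] < 2 and method != "none":
        raise ValueError("scaling needs at least 2 samples")
    if method == "none":
        means = np.zeros(X.shape[1])
        scales = np.ones(X.shape[1])
        zero = np.zeros(X.shape[1], bool)
    else:
        means = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        zero = sd == 0
        if method == "centre":
            scales = np.ones_like(sd)
        elif method == "auto":
            scales = np.where(zero, 1.0, sd)
        else:  # pareto
            scales = np.where(zero, 1.0, np.sqrt(sd))
    return ScaledMatrix((X - means) / scales, means, scales, method, zero)


def apply_scaling(X: np.ndarray, sm: ScaledMatrix) -> np.ndarray:
    """Apply a previously estimated pretreatment to new samples."""
    return (np.asarray(X, float) - sm.column_means) / sm.column_scales


def integrate_window(spectrum: Spectrum, window: tuple[float, float]) -> float:
    """Trapezoidal integral of the total-area-normalized spectrum over a window."""
    lo, hi = sorted(float(w) for w in window)
    ppm_asc, cum = _cum_integral(spectrum)
    if hi <= ppm_asc[0] or lo >= ppm_asc[-1]:
        raise ValueError(f"window ({lo}, {hi}) does not overlap the ppm axis")
    total = float(cum[-1])
    if total <= 0:
        raise ValueError("spectrum has non-positive total area")
    return _interval_integral(ppm_asc, cum, lo, hi) / total


def align_to_median(spectra: Sequence[Spectrum], max_shift_ppm: float = 0.05) -> list[Spectrum]:
    """Global shift correction by cross-correlation to the cohort median (optional)."""
    stack = np.vstack([s.intensity for s in spectra])
    ref = np.median(stack, axis=0)
    step = abs(float(spectra[0].ppm[1] - spectra[0].ppm[0]))
    max_lag = int(round(max_shift_ppm / step))
    out = []
    for s in spectra:
        lags = range(-max_lag, max_lag + 1)
        scores = [np.dot(np.roll(s.intensity, k), ref) for k in lags]
        k = list(lags)[int(np.argmax(scores))]
        out.append(Spectrum(ppm=s.ppm.copy(), intensity=np.roll(s.intensity, k)))
    return out


def write_feature_matrix(path, fm: FeatureMatrix, class_names=("A_lixula", "P_lividus")) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "class"] + [f"{hi:.4f}_{lo:.4f}" for hi, lo in fm.bin_edges])
        for i, sid in enumerate(fm.sample_ids):
            cls = class_names[0] if fm.labels[i] > 0 else class_names[1]
            w.writerow([sid, cls] + [repr(float(v)) for v in fm.data[i]])


def read_feature_matrix(path, class_names=("A_lixula", "P_lividus")) -> FeatureMatrix:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    edges = []
    for token in rows[0][2:]:
        hi, lo = token.split("_")
        edges.append((float(hi), float(lo)))
    ids, labels, data = [], [], []
    for row in rows[1:]:
        ids.append(row[0])
        labels.append(1 if row[1] == class_names[0] else -1)
        data.append([float(x) for x in row[2:]])
    return FeatureMatrix(np.array(data), np.array(labels, int), edges, ids)
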