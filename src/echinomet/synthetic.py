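"""Synthetic two-class cohorts of 1D 1H NMR-like gonadal spectra.

Generates spectra that emulate HR-MAS CPMG profiles of sea-urchin gonads from
two species (*Arbacia lixula* and *Paracentrotus lividus*), with a known
ground-truth panel of discriminant metabolites.  Peaks are rendered as
Lorentzian lines on a descending ppm axis; class differences are injected as
symmetric log2 fold-changes on species-biased metabolites, on top of
per-sample biological variability, additive Gaussian noise, a smooth
polynomial baseline and a small per-spectrum chemical-shift jitter.

Chemical shifts are configuration data compiled from standard reference
values (HMDB-style singlet positions); they parameterise the simulator and
carry no claim about any particular measured dataset.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

A_LIXULA = "A_lixula"
P_LIVIDUS = "P_lividus"
SHARED = "shared"

#: default exclusion windows (ppm): residual water and the TSP reference
DEFAULT_EXCLUSIONS: tuple[tuple[float, float], ...] = ((4.7, 5.0), (-0.05, 0.05))

DEFAULT_LINEWIDTH_PPM = 0.003


@dataclass(frozen=True)
class MetaboliteTemplate:
    """One metabolite: named Lorentzian lines plus its species bias."""

    name: str
    kegg_id: str
    peaks: tuple[tuple[float, float, float], ...]  # (center_ppm, rel_area, fwhm_ppm)
    species_bias: str  # A_lixula | P_lividus | shared

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError(f"{self.name}: at least one peak required")
        if self.species_bias not in (A_LIXULA, P_LIVIDUS, SHARED):
            raise ValueError(f"{self.name}: bad species_bias {self.species_bias!r}")
        for c, a, w in self.peaks:
            if not (0.0 <= c <= 10.0):
                raise ValueError(f"{self.name}: peak center {c} outside [0, 10] ppm")
            if a <= 0 or w <= 0:
                raise ValueError(f"{self.name}: non-positive area/width")
        total = sum(a for _, a, _ in self.peaks)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: relative areas sum to {total}, not 1")


@dataclass(frozen=True)
class CohortConfig:
    """Simulation conditions for one two-class cohort."""

    n_per_class: int = 12
    ppm_axis: tuple[float, float, int] = (0.0, 10.0, 16384)
    log2_effect: float = 2.0
    biological_cv: float = 0.15
    noise_sd: float = 0.3
    baseline_amplitude: float = 0.5
    shift_jitter_sd_ppm: float = 0.002
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_per_class < 3:
            raise ValueError("n_per_class must be >= 3")
        if self.noise_sd < 0 or self.shift_jitter_sd_ppm < 0:
            raise ValueError("noise_sd and shift_jitter_sd_ppm must be >= 0")
        lo, hi, n = self.ppm_axis
        if n < 64:
            raise ValueError("degenerate ppm axis: n_points must be >= 64")
        if hi <= lo:
            raise ValueError("ppm_axis must satisfy max > min")


@dataclass
class Spectrum:
    """One 1D spectrum: strictly descending ppm axis plus intensities."""

    ppm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D and equal length")
        if not np.all(np.diff(self.ppm) < 0):
            raise ValueError("ppm axis must be strictly descending")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")


@dataclass
class CohortTruth:
    """Ground truth bookkeeping for a simulated cohort."""

    labels: np.ndarray  # +1 = A. lixula, -1 = P. lividus
    enriched_in_A: set[str]
    enriched_in_B: set[str]
    true_bins: set[int]
    #: per-sample, per-metabolite concentrations actually rendered
    concentrations: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.enriched_in_A & self.enriched_in_B:
            raise ValueError("enriched sets must be disjoint")


# --- metabolite library -----------------------------------------------------
#
# Panels follow the study design: osmolytes/methylamines/organic acids and
# nucleoside derivatives elevated in A. lixula; amino acids and
# methylotrophy-linked compounds elevated in P. lividus; shared background
# metabolites including a broad fatty-acid envelope.

def _load_shift_table() -> list[dict]:
    path = resources.files("echinomet.data") / "chemical_shifts.tsv"
    rows = []
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append(row)
    return rows


def build_metabolite_library() -> list[MetaboliteTemplate]:
    """Load the packaged chemical-shift fixture as metabolite templates.

    Returns at least 18 templates covering both species panels plus shared
    metabolites (kynurenine, fatty-acid envelope, common background
    compounds); relative peak areas are normalized to sum to 1 per
    metabolite.
    """
    templates = []
    for row in _load_shift_table():
        peaks = []
        for token in row["peaks"].split(";"):
            c, a, w = (float(x) for x in token.split(":"))
            peaks.append((c, a, w))
        total = sum(a for _, a, _ in peaks)
        peaks = tuple((c, a / total, w) for c, a, w in peaks)
        templates.append(
            MetaboliteTemplate(
                name=row["name"],
                kegg_id=row["kegg_id"],
                peaks=peaks,
                species_bias=row["species_bias"],
            )
        )
    return templates


#: the seven headline discriminant metabolites of the SPA selection
SPA_HEADLINE_METABOLITES = (
    "betaine", "sarcosine", "glycine", "malonate", "taurine",
    "formaldehyde", "lysine",
)


def spa_benchmark_library(
    biased: Sequence[str] = SPA_HEADLINE_METABOLITES,
) -> list[MetaboliteTemplate]:
    """Reduced-panel library for scaled-down SPA experiments.

    Only the named metabolites keep a species bias (rendered as a single
    line at their main resonance); all other metabolites become shared
    background.  Paired with ~0.05-ppm bins and N = 200 Monte-Carlo
    iterations this preserves the two quantities that govern SPA power at
    full scale (N = 1000, ~0.01-ppm bins): the expected number of error
    samples per variable (N*Q/bins ~ 15) and the density of informative
    variables among the bins (~3%).
    """
    out = []
    for m in build_metabolite_library():
        if m.name in biased:
            c, _, w = max(m.peaks, key=lambda pk: pk[1])
            out.append(MetaboliteTemplate(m.name, m.kegg_id, ((c, 1.0, w),), m.species_bias))
        else:
            out.append(MetaboliteTemplate(m.name, m.kegg_id, m.peaks, SHARED))
    return out


# --- simulation -------------------------------------------------------------

def _lorentzian(ppm: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    gamma = fwhm / 2.0
    return gamma / ((ppm - center) ** 2 + gamma**2)


def _ascending_area(ppm_desc: np.ndarray, y: np.ndarray) -> float:
    return float(np.trapezoid(y[::-1], ppm_desc[::-1]))


def true_bin_indices(
    library: Sequence[MetaboliteTemplate],
    bin_edges: Sequence[tuple[float, float]],
) -> set[int]:
    """Bins [hi, lo) whose interval contains a peak center of a biased metabolite."""
    out: set[int] = set()
    for i, (hi, lo) in enumerate(bin_edges):
        for m in library:
            if m.species_bias == SHARED:
                continue
            if any(lo < c <= hi for c, _, _ in m.peaks):
                out.add(i)
    return out


def _default_bin_edges(
    config: CohortConfig,
    bin_width_ppm: float,
    exclusions: Sequence[tuple[float, float]],
) -> list[tuple[float, float]]:
    # mirrors preprocess.bin_spectra edge construction; kept tiny on purpose
    lo, hi, _ = config.ppm_axis
    n_bins = int(np.floor((hi - lo) / bin_width_ppm + 1e-9))
    edges = []
    for i in range(n_bins):
        b_hi = hi - i * bin_width_ppm
        b_lo = b_hi - bin_width_ppm
        if any(b_hi > min(e) and b_lo < max(e) for e in exclusions):
            continue
        edges.append((b_hi, b_lo))
    return edges


def simulate_cohort(
    config: CohortConfig | None = None,
    library: Sequence[MetaboliteTemplate] | None = None,
    *,
    bin_width_ppm: float = 0.01,
    exclusions: Sequence[tuple[float, float]] = DEFAULT_EXCLUSIONS,
) -> tuple[list[Spectrum], CohortTruth]:
    """Simulate a two-class cohort of 2*n_per_class spectra.

    Species-biased metabolites are scaled symmetrically in log space,
    2**(+log2_effect/2) in the enriched class and 2**(-log2_effect/2) in the
    other, so class geometric means straddle the shared baseline
    concentration of 1.  Each rendered line is area-normalized on the finite
    axis so that, at zero noise and baseline, the trapezoidal area of the
    spectrum equals the sum of concentration-weighted template areas exactly.

    ``true_bins`` in the returned truth is computed for the given
    ``bin_width_ppm`` / ``exclusions`` scheme (defaults match
    :func:`echinomet.preprocess.bin_spectra`).
    """
    config = config or CohortConfig()
    library = list(library) if library is not None else build_metabolite_library()

    lo, hi, n_points = config.ppm_axis
    ppm = np.linspace(hi, lo, n_points)  # descending
    n = 2 * config.n_per_class
    labels = np.concatenate(
        [np.ones(config.n_per_class, int), -np.ones(config.n_per_class, int)]
    )

    # log-normal biological variability with the requested CV
    sigma = float(np.sqrt(np.log1p(config.biological_cv**2)))
    half = config.log2_effect / 2.0

    spectra: list[Spectrum] = []
    conc_store = {m.name: np.zeros(n) for m in library}
    for i in range(n):
        rng = np.random.default_rng([config.seed, i])
        cls = labels[i]
        jitter = rng.normal(0.0, config.shift_jitter_sd_ppm) if config.shift_jitter_sd_ppm else 0.0
        intensity = np.zeros(n_points)
        for m in library:
            if m.species_bias == A_LIXULA:
                log2fc = half * cls
            elif m.species_bias == P_LIVIDUS:
                log2fc = -half * cls
            else:
                log2fc = 0.0
            conc = 2.0**log2fc * float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))
            conc_store[m.name][i] = conc
            for center, rel_area, fwhm in m.peaks:
                shape = _lorentzian(ppm, center + jitter, fwhm)
                area = _ascending_area(ppm, shape)
                intensity += (conc * rel_area / area) * shape
        if config.baseline_amplitude > 0:
            x = np.linspace(-1.0, 1.0, n_points)
            coefs = rng.normal(0.0, 1.0, 4) * np.array([1.0, 0.5, 0.25, 0.125])
            base = np.polynomial.chebyshev.chebval(x, coefs)
            base = config.baseline_amplitude * (base - base.min())
            intensity += base
        if config.noise_sd > 0:
            intensity += rng.normal(0.0, config.noise_sd, n_points)
        spectra.append(Spectrum(ppm=ppm.copy(), intensity=intensity))

    edges = _default_bin_edges(config, bin_width_ppm, exclusions)
    truth = CohortTruth(
        labels=labels,
        enriched_in_A={m.name for m in library if m.species_bias == A_LIXULA},
        enriched_in_B={m.name for m in library if m.species_bias == P_LIVIDUS},
        true_bins=true_bin_indices(library, edges) if config.log2_effect != 0 else set(),
        concentrations=conc_store,
    )
    if config.log2_effect != 0 and not truth.true_bins:
        raise RuntimeError("no true bins despite nonzero effect; check bin scheme")
    return spectra, truth


# --- export -----------------------------------------------------------------

def write_cohort_csv(path, spectra: Sequence[Spectrum], truth: CohortTruth) -> None:
    """Wide CSV: sample_id, class, then intensities at header-declared ppm."""
    ppm = spectra[0].ppm
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "class"] + [f"{p:.6f}" for p in ppm])
        for i, s in enumerate(spectra):
            cls = A_LIXULA if truth.labels[i] > 0 else P_LIVIDUS
            w.writerow([f"S{i+1:03d}", cls] + [repr(float(v)) for v in s.intensity])


def write_spectrum_csv(path, spectrum: Spectrum) -> None:
    """Two-column ppm,intensity CSV for one sample."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["ppm", "intensity"])
        for p, v in zip(spectrum.ppm, spectrum.intensity):
            w.writerow([repr(float(p)), repr(float(v))])


def write_truth_json(path, truth: CohortTruth) -> None:
    payload = {
        "labels": truth.labels.tolist(),
        "enriched_in_A": sorted(truth.enriched_in_A),
        "enriched_in_B": sorted(truth.enriched_in_B),
        "true_bins": sorted(truth.true_bins),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def read_cohort_csv(path) -> tuple[list[Spectrum], np.ndarray, list[str]]:
    """Read a wide cohort CSV back into spectra, +1/-1 labels and sample ids."""
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    ppm = np.array([float(x) for x in rows[0][2:]])
    spectra, labels, ids = [], [], []
    for row in rows[1:]:
        ids.append(row[0])
        labels.append(1 if row[1] == A_LIXULA else -1)
        spectra.append(Spectrum(ppm=ppm.copy(), intensity=np.array([float(x) for x in row[2:]])))
    return spectra, np.array(labels, int), ids
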