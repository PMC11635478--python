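"""Copy-number conversion and per-subpopulation content statistics.

The single-fluorophore calibration fits a Gaussian to the intensity
histogram of isolated labelled antibodies; its peak position mu1 is the
"single-unit signal" used to convert per-particle integrated intensity to
a real-valued molecule count (count = intensity / mu1).  An alternative
histogram-deconvolution route models the measured intensity density as a
mixture sum_n w_n N(n mu1, n sigma1^2) and recovers the copy-number weights
w_n by non-negative least squares.  The module also provides the pairwise
intensity correlations, the sqrt-intensity size proxy, the normalized
between-subpopulation intensity variance, the capture mass balance, Welch
group comparisons, and the acquisition-geometry arithmetic.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .subpopulations import CHANNELS, SUBPOPULATION_LABELS, POSITIVITY_OF_LABEL

log = logging.getLogger(__name__)

__all__ = [
    "CalibrationModel",
    "CopyNumberDistribution",
    "CaptureInputs",
    "fit_single_fluorophore",
    "counts_by_ratio",
    "counts_by_deconvolution",
    "pairwise_correlation",
    "size_proxy",
    "normalized_variance",
    "captured_fraction",
    "compare_groups",
    "significance_stars",
    "physical_length",
    "plan_acquisition",
    "subpopulation_summary",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Single-fluorophore-unit intensity distribution N(mu1, sigma1^2)."""

    unit_mu_adu: float
    unit_sigma_adu: float
    n_calibration_spots: int
    fit_quality: float  # R^2 of the Gaussian histogram fit

    def __post_init__(self) -> None:
        if self.unit_mu_adu <= 0:
            raise ValueError("unit_mu_adu must be positive")
        if self.unit_sigma_adu < 0:
            raise ValueError("unit_sigma_adu must be non-negative")


@dataclass
class CopyNumberDistribution:
    """Discrete weights over integer copy numbers 1..n_max (sum to one)."""

    weights: np.ndarray  # weights[k] is the weight of copy number k+1
    n_max: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.n_max,) or (w < 0).any():
            raise ValueError("weights must be n_max non-negative reals")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1 within 1e-9")
        self.weights = w

    @property
    def mean_count(self) -> float:
        return float(np.arange(1, self.n_max + 1) @ self.weights)


@dataclass(frozen=True)
class CaptureInputs:
    surface_density_per_um2: float
    chip_area_mm2: float
    bulk_concentration_per_ml: float
    incubated_volume_ml: float

    def __post_init__(self) -> None:
        if self.surface_density_per_um2 < 0:
            raise ValueError("surface density must be non-negative")
        if min(self.chip_area_mm2, self.bulk_concentration_per_ml, self.incubated_volume_ml) <= 0:
            raise ValueError("chip area, bulk concentration and volume must be positive")


def _gauss(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_single_fluorophore(intensities: Sequence[float], min_spots: int = 100) -> CalibrationModel:
    """Fit a Gaussian to the single-antibody intensity histogram.

    Histogram bins follow the Freedman-Diaconis rule; the fit is restricted
    to a window around the dominant mode so that dimer contamination at
    roughly twice the monomer intensity does not bias the peak.  The fit is
    refused when the recovered peak is indistinguishable from zero
    (mu1 <= 2 sigma1).
    """
    arr = np.asarray(intensities, dtype=float)
    if arr.size < min_spots:
        raise ValueError(f"need at least {min_spots} calibration intensities, got {arr.size}")
    if arr.std() == 0.0:
        return CalibrationModel(float(arr[0]), 0.0, int(arr.size), 1.0)

    counts, edges = np.histogram(arr, bins="fd")
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = float(centers[np.argmax(counts)])

    mu, sigma = peak, max(peak / 4.0, float(np.diff(edges).mean()))
    for _ in range(2):  # refit once with a window informed by the first pass
        lo, hi = mu - 2.5 * sigma, mu + 2.5 * sigma
        sel = (centers >= lo) & (centers <= hi)
        if sel.sum() < 4:
            half = 2 * float(np.diff(edges).mean())
            sel = (centers >= mu - 4 * half) & (centers <= mu + 4 * half)
        x, y = centers[sel], counts[sel].astype(float)
        try:
            popt, _ = optimize.curve_fit(
                _gauss, x, y, p0=(y.max(), mu, sigma),
                bounds=((0.0, 0.0, 1e-9), (np.inf, np.inf, np.inf)), maxfev=10000,
            )
        except RuntimeError as err:
            raise ValueError(f"Gaussian calibration fit did not converge: {err}") from err
        _, mu, sigma = float(popt[0]), float(popt[1]), float(popt[2])

    resid = y - _gauss(x, *popt)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0

    if mu <= 2.0 * sigma:
        raise ValueError(
            f"calibration peak mu1={mu:.1f} indistinguishable from zero (sigma1={sigma:.1f})"
        )
    return CalibrationModel(mu, sigma, int(arr.size), r2)


def counts_by_ratio(
    intensities: Sequence[float], calibration: CalibrationModel
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Real-valued copy counts by intensity ratio, plus their histogram.

    count_i = intensity_i / mu1; the histogram is the intensity histogram
    with a rescaled abscissa (shape preserved).  Returns (counts,
    (bin_counts, bin_edges)).
    """
    if calibration.unit_mu_adu == 0:
        raise ValueError("calibration mu1 must be non-zero")
    arr = np.asarray(intensities, dtype=float)
    counts = arr / calibration.unit_mu_adu
    hist = np.histogram(counts, bins="fd") if counts.size > 1 else np.histogram(counts, bins=1)
    return counts, hist


def counts_by_deconvolution(
    intensities: Sequence[float],
    calibration: CalibrationModel,
    n_max: int = 100,
    min_samples: int = 500,
    ridge: float = 1e-6,
) -> CopyNumberDistribution:
    """Copy-number weights by NNLS deconvolution of the intensity histogram.

    The measured intensity density is modelled as
    ``sum_n w_n N(n mu1, n sigma1^2)`` (the n-fold convolution of the
    Gaussian single-unit signal, in closed form).  Weights are estimated by
    non-negative least squares on the binned histogram with a heavily
    weighted sum-to-one constraint and a small ridge for conditioning, then
    renormalized exactly.
    """
    arr = np.asarray(intensities, dtype=float)
    if arr.size < min_samples:
        raise ValueError(f"need at least {min_samples} intensities, got {arr.size}")
    mu, sig = calibration.unit_mu_adu, calibration.unit_sigma_adu
    if sig > 0.5 * mu:
        warnings.warn(
            "deconvolution is ill-conditioned (sigma1 > mu1/2); weights are unreliable"
        )
    sig = max(sig, 1e-9)

    width = mu / 4.0
    hi = float(arr.max()) + 3.0 * sig * math.sqrt(n_max)
    edges = np.arange(0.0, hi + width, width)
    counts, _ = np.histogram(arr, bins=edges)
    target = counts / counts.sum()

    ns = np.arange(1, n_max + 1)
    # column n: probability a draw from N(n mu, n sigma^2) lands in each bin
    z = (edges[:, None] - ns[None, :] * mu) / (sig * np.sqrt(ns)[None, :])
    cdf = stats.norm.cdf(z)
    design = np.diff(cdf, axis=0)

    lam = 10.0  # weight of the sum-to-one row relative to unit histogram mass
    a = np.vstack([design, lam * np.ones((1, n_max)), math.sqrt(ridge) * np.eye(n_max)])
    b = np.concatenate([target, [lam], np.zeros(n_max)])
    w, _ = optimize.nnls(a, b)
    total = w.sum()
    if total <= 0:
        raise ValueError("deconvolution produced an empty solution")
    return CopyNumberDistribution(weights=w / total, n_max=n_max)


def pairwise_correlation(
    particles: pd.DataFrame,
    label: str,
    marker_a: str,
    marker_b: str,
    min_particles: int = 30,
) -> tuple[float, pd.DataFrame]:
    """Pearson correlation of two markers' intensities within one subpopulation.

    Operates on a particle table (see ``particles_to_dataframe``); only
    particles of the given label positive for both markers enter.  Returns
    (r, paired intensity table); r is NaN with a warning when either vector
    is constant.
    """
    sel = (
        (particles["label"] == label)
        & particles[f"positive_{marker_a}"]
        & particles[f"positive_{marker_b}"]
    )
    if "flags" in particles:
        sel &= ~particles["flags"].fillna("").str.contains("edge|aggregate")
    table = particles.loc[sel, [f"intensity_{marker_a}", f"intensity_{marker_b}"]].copy()
    if len(table) < min_particles:
        raise ValueError(
            f"need at least {min_particles} particles carrying both markers, got {len(table)}"
        )
    a = table.iloc[:, 0].to_numpy()
    b = table.iloc[:, 1].to_numpy()
    if a.std() == 0.0 or b.std() == 0.0:
        warnings.warn("constant intensity vector: correlation undefined")
        return float("nan"), table
    r = float(np.corrcoef(a, b)[0, 1])
    return r, table


def size_proxy(coe_intensity) -> np.ndarray | float:
    """Relative particle diameter: sqrt of the COE integrated intensity.

    The membrane-dye signal scales with lipid surface area (diameter^2),
    so its square root is linear in diameter up to a constant.
    """
    arr = np.asarray(coe_intensity, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative intensity")
    out = np.sqrt(arr)
    return float(out) if np.isscalar(coe_intensity) or out.ndim == 0 else out


def normalized_variance(label_means: Sequence[float]) -> float:
    """Between-subpopulation dispersion of one marker's mean intensity.

    Each subpopulation mean is normalized by the grand mean across
    subpopulations; the population variance of the normalized values is
    returned.  Scale-invariant by construction.
    """
    arr = np.asarray(label_means, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two subpopulations carrying the marker")
    grand = arr.mean()
    if grand == 0:
        raise ValueError("grand mean is zero")
    return float(np.var(arr / grand))


def captured_fraction(inputs: CaptureInputs) -> float:
    """Fraction of bulk particles immobilized on the chip.

    f = (surface density x chip area) / (bulk concentration x incubated
    volume), with the mm^2 -> um^2 conversion handled internally.  Values
    above one violate mass balance and trigger a warning.
    """
    surface_count = inputs.surface_density_per_um2 * inputs.chip_area_mm2 * 1e6
    bulk_count = inputs.bulk_concentration_per_ml * inputs.incubated_volume_ml
    if bulk_count == 0:
        raise ValueError("zero bulk particle count")
    f = surface_count / bulk_count
    if f > 1.0:
        warnings.warn(f"captured fraction {f:.3g} > 1 violates mass balance")
    return f


def compare_groups(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Welch two-sample t-test on trial-level summary values.

    Returns (t, two-sided p).  Identical constant samples give (0, 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if min(a.size, b.size) < 2:
        raise ValueError("need at least two trials per group")
    if min(a.size, b.size) < 3:
        warnings.warn("fewer than three trials in a group; test poorly powered")
    if a.std() == 0.0 and b.std() == 0.0:
        return (0.0, 1.0) if a.mean() == b.mean() else (math.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def physical_length(pixels: float, pixel_size_um: float) -> float:
    """Convert a pixel count to micrometres."""
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    return pixels * pixel_size_um


def plan_acquisition(chip_area_mm2: float, fov_um: tuple[float, float]) -> int:
    """Number of fields of view needed to tile a chip."""
    if chip_area_mm2 <= 0 or min(fov_um) <= 0:
        raise ValueError("areas must be positive")
    field_mm2 = fov_um[0] * fov_um[1] * 1e-6
    return int(math.ceil(chip_area_mm2 / field_mm2 - 1e-9))


def subpopulation_summary(
    particles: pd.DataFrame,
    calibration: Optional[CalibrationModel] = None,
) -> pd.DataFrame:
    """Per-subpopulation content table.

    For each of the seven labels: particle count and, for each marker the
    label carries, the mean integrated intensity among its particles;
    mean CD63 copy count when a calibration is supplied.  Edge- and
    aggregate-flagged particles are excluded.
    """
    df = particles
    if "flags" in df:
        df = df[~df["flags"].fillna("").str.contains("edge|aggregate")]
    rows = []
    for label in SUBPOPULATION_LABELS:
        sub = df[df["label"] == label]
        row: dict = {"label": label, "n_particles": int(len(sub))}
        pos = dict(zip(CHANNELS, POSITIVITY_OF_LABEL[label]))
        for c in CHANNELS:
            row[f"mean_intensity_{c}"] = (
                float(sub[f"intensity_{c}"].mean()) if pos[c] and len(sub) else float("nan")
            )
        if calibration is not None and pos["CD63"] and len(sub):
            row["mean_cd63_count"] = float(
                (sub["intensity_CD63"] / calibration.unit_mu_adu).mean()
            )
        else:
            row["mean_cd63_count"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
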