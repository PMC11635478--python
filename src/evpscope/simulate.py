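"""Synthetic TIRF scene generator with per-particle ground truth.

Emulates high-density arrays of surface-anchored sEVPs imaged by TIRF
microscopy: each particle is a diffraction-limited emitter rendered as an
isotropic 2-D Gaussian (the PSF approximation), with per-channel
intensities drawn from a seven-category subpopulation mixture.  COE and
CFSE intensities are log-normal and may be correlated through a latent
Gaussian copula; the CD63 channel emits the sum of ``k`` independent
single-fluorophore units (truncated-normal), where ``k`` is the particle's
true antibody copy number.  Pixels are corrupted by a multiplicative
illumination gain field, Poisson shot noise on (signal + camera offset),
and additive Gaussian read noise — an EM-CCD-like model:

    pixel = gain(x, y) * Poisson(signal + offset) + N(0, read_sd)

All randomness flows from a single integer seed through one
``numpy.random.Generator``; identical parameters and seed give
bit-identical images and truth tables.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field, asdict
from typing import Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtr

from .fields import FieldImage
from .subpopulations import COE, CFSE, CD63, SUBPOPULATION_LABELS, POSITIVITY_OF_LABEL

__all__ = [
    "MarkerModel",
    "SceneParams",
    "SceneTruth",
    "generate_scene",
    "generate_calibration_field",
    "sample_intensity_pairs",
    "background_noise_sd",
    "intensity_for_peak_snr",
    "write_scene",
]

#: Representative mid-range subpopulation mixture (order = SUBPOPULATION_LABELS).
DEFAULT_CATEGORY_PROBS: tuple[float, ...] = (0.10, 0.15, 0.05, 0.12, 0.08, 0.28, 0.22)


@dataclass(frozen=True)
class MarkerModel:
    """Log-normal intensity model: median (ADU) and geometric SD (>= 1)."""

    median_adu: float = 800.0
    gsd: float = 1.5

    def __post_init__(self) -> None:
        if self.median_adu <= 0:
            raise ValueError("median_adu must be positive")
        if self.gsd < 1.0:
            raise ValueError("geometric SD must be >= 1")

    @property
    def log_sd(self) -> float:
        return math.log(self.gsd)


@dataclass
class SceneParams:
    """Parameters of one synthetic field of view.

    ``field_size_px`` is (nx, ny) = (columns, rows); coordinates follow the
    package convention x = column, y = row, 0-based.
    """

    field_size_px: Tuple[int, int] = (400, 400)
    pixel_size_um: float = 0.25
    particle_density_per_um2: float = 0.05
    category_probs: Tuple[float, ...] = DEFAULT_CATEGORY_PROBS
    psf_sigma_px: float = 1.0
    coe_model: MarkerModel = field(default_factory=MarkerModel)
    cfse_model: MarkerModel = field(default_factory=MarkerModel)
    cd63_copy_mean: float = 10.0          # zero-truncated Poisson mean for CD63+ particles
    unit_intensity_mu: float = 400.0      # single-fluorophore-unit Gaussian mu1 (ADU)
    unit_intensity_sigma: float = 80.0    # sigma1 (ADU)
    marker_correlation: float = 0.7       # target Pearson r between COE and CFSE intensities
    illumination_gradient: Tuple[float, float] = (0.85, 1.15)  # linear gain ramp along x
    background_offset_adu: float = 100.0
    read_noise_sd_adu: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        nx, ny = self.field_size_px
        if nx < 1 or ny < 1:
            raise ValueError("field_size_px must be positive")
        if self.pixel_size_um <= 0 or self.psf_sigma_px <= 0:
            raise ValueError("pixel_size_um and psf_sigma_px must be positive")
        if self.particle_density_per_um2 < 0:
            raise ValueError("particle density must be non-negative")
        probs = np.asarray(self.category_probs, dtype=float)
        if probs.shape != (7,) or (probs < 0).any():
            raise ValueError("category_probs must be 7 non-negative reals")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("category_probs must sum to 1 within 1e-9")
        if self.cd63_copy_mean <= 0 or self.unit_intensity_mu <= 0:
            raise ValueError("copy mean and unit intensity must be positive")
        if self.unit_intensity_sigma < 0:
            raise ValueError("unit_intensity_sigma must be non-negative")
        if self.background_offset_adu < 0 or self.read_noise_sd_adu < 0:
            raise ValueError("noise parameters must be non-negative")
        if not -1.0 < self.marker_correlation < 1.0:
            raise ValueError("marker_correlation must lie in (-1, 1)")
        gmin, gmax = self.illumination_gradient
        if gmin <= 0 or gmax <= 0:
            raise ValueError("illumination gains must be positive")

    @property
    def field_area_um2(self) -> float:
        nx, ny = self.field_size_px
        return nx * ny * self.pixel_size_um**2

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneParams":
        d = dict(d)
        for key in ("coe_model", "cfse_model"):
            if isinstance(d.get(key), dict):
                d[key] = MarkerModel(**d[key])
        for key in ("field_size_px", "illumination_gradient", "category_probs"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SceneTruth:
    """Ground truth for one synthetic field.

    ``particles`` columns: x_px, y_px (sub-pixel), category, copies_cd63,
    intensity_COE / intensity_CFSE / intensity_CD63 (true emitted integrated
    intensity, ADU, before gain and noise), near_edge (within one PSF sigma
    of the border; still rendered, but the detector excludes an edge margin).
    """

    particles: pd.DataFrame
    params: SceneParams

    def save(self, directory: str | os.PathLike, stem: str = "truth") -> str:
        os.makedirs(directory, exist_ok=True)
        path = os.path.join(str(directory), f"{stem}.csv")
        self.particles.to_csv(path, index=False)
        with open(os.path.join(str(directory), f"{stem}_params.yaml"), "w") as fh:
            yaml.safe_dump(self.params.to_dict(), fh, sort_keys=True)
        return path


_TRUTH_COLUMNS = [
    "x_px", "y_px", "category", "copies_cd63",
    "intensity_COE", "intensity_CFSE", "intensity_CD63", "near_edge",
]


def background_noise_sd(params: SceneParams) -> float:
    """Per-pixel noise SD on empty background at unit illumination gain."""
    return math.sqrt(params.background_offset_adu + params.read_noise_sd_adu**2)


def intensity_for_peak_snr(peak_snr: float, params: SceneParams) -> float:
    """Integrated intensity giving the requested peak SNR for this PSF/noise."""
    return peak_snr * background_noise_sd(params) * 2.0 * math.pi * params.psf_sigma_px**2


def _latent_rho(r: float, s1: float, s2: float) -> float:
    """Latent Gaussian correlation whose bivariate-lognormal Pearson r is ``r``.

    From Pearson(r) = (exp(rho*s1*s2) - 1) / sqrt((e^{s1^2}-1)(e^{s2^2}-1)).
    Degenerates gracefully when either log-SD is zero.
    """
    if s1 == 0.0 or s2 == 0.0:
        return r
    arg = 1.0 + r * math.sqrt(math.expm1(s1**2) * math.expm1(s2**2))
    if arg <= 0:
        raise ValueError("requested marker_correlation is below the attainable minimum")
    rho = math.log(arg) / (s1 * s2)
    if abs(rho) > 1.0:
        warnings.warn("requested marker correlation not attainable; clipping latent rho")
        rho = max(-1.0, min(1.0, rho))
    return rho


def sample_intensity_pairs(
    coe_model: MarkerModel,
    cfse_model: MarkerModel,
    r: float,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n correlated (COE, CFSE) intensity pairs from the scene's copula model."""
    rho = _latent_rho(r, coe_model.log_sd, cfse_model.log_sd)
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + math.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n)
    a = coe_model.median_adu * np.exp(coe_model.log_sd * z1)
    b = cfse_model.median_adu * np.exp(cfse_model.log_sd * z2)
    return a, b


def _zero_truncated_poisson(lam: float, n: int, rng: np.random.Generator) -> np.ndarray:
    out = rng.poisson(lam, size=n)
    while True:
        zero = out == 0
        if not zero.any():
            return out
        out[zero] = rng.poisson(lam, size=int(zero.sum()))


def _truncated_normal(mu: float, sigma: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """N(mu, sigma) truncated at 0, by rejection (cheap when mu >> sigma)."""
    if sigma == 0.0:
        return np.full(n, float(mu))
    out = rng.normal(mu, sigma, size=n)
    while True:
        neg = out < 0
        if not neg.any():
            return out
        out[neg] = rng.normal(mu, sigma, size=int(neg.sum()))


def _render_spots(
    shape: tuple[int, int],
    xs: np.ndarray,
    ys: np.ndarray,
    intensities: np.ndarray,
    sigma: float,
) -> np.ndarray:
    """Add 2-D Gaussians (exact pixel-integrated, via the error function).

    Each spot's integral over the plane equals its intensity; the rendered
    window spans +-6 sigma, so >99.99% of the flux lands on the grid for
    interior spots.
    """
    ny, nx = shape
    img = np.zeros(shape, dtype=float)
    r = int(math.ceil(6.0 * sigma))
    for x, y, inten in zip(xs, ys, intensities):
        if inten <= 0:
            continue
        cx = int(math.floor(x))
        cy = int(math.floor(y))
        x0, x1 = max(0, cx - r), min(nx, cx + r + 1)
        y0, y1 = max(0, cy - r), min(ny, cy + r + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        # pixel i covers [i, i+1); integrate the Gaussian over each pixel
        ex = ndtr((np.arange(x0, x1 + 1) - x) / sigma)
        ey = ndtr((np.arange(y0, y1 + 1) - y) / sigma)
        img[y0:y1, x0:x1] += inten * np.outer(np.diff(ey), np.diff(ex))
    return img


def _gain_field(shape: tuple[int, int], gradient: tuple[float, float]) -> np.ndarray:
    ny, nx = shape
    gmin, gmax = gradient
    ramp = np.full(nx, gmin) if nx == 1 else gmin + (gmax - gmin) * np.arange(nx) / (nx - 1)
    return np.broadcast_to(ramp, (ny, nx)).copy()


def _apply_camera(
    signal: np.ndarray, gain: np.ndarray, params: SceneParams, rng: np.random.Generator
) -> np.ndarray:
    shot = rng.poisson(np.clip(signal + params.background_offset_adu, 0, None)).astype(float)
    read = rng.normal(0.0, params.read_noise_sd_adu, size=signal.shape) if params.read_noise_sd_adu > 0 else 0.0
    return gain * shot + read


def generate_scene(params: SceneParams) -> tuple[FieldImage, SceneTruth]:
    """Generate a three-channel field and its ground truth.

    The particle count is Poisson(density x field area); categories are
    drawn from ``category_probs``; a particle's channel intensity is zero
    exactly when its category says the marker is absent.  A crowding
    warning fires when the expected nearest-neighbour spacing falls below
    two PSF sigmas.
    """
    rng = np.random.default_rng(params.seed)
    nx, ny = params.field_size_px

    density_px = params.particle_density_per_um2 * params.pixel_size_um**2
    if density_px > 0:
        expected_nn = 0.5 / math.sqrt(density_px)
        if expected_nn < 2.0 * params.psf_sigma_px:
            warnings.warn(
                f"crowded scene: expected nearest-neighbour spacing {expected_nn:.2f} px "
                f"< 2 x psf_sigma ({2 * params.psf_sigma_px:.2f} px)"
            )

    n = int(rng.poisson(params.particle_density_per_um2 * params.field_area_um2))
    xs = rng.uniform(0.0, nx, size=n)
    ys = rng.uniform(0.0, ny, size=n)
    cat_idx = rng.choice(7, size=n, p=np.asarray(params.category_probs, dtype=float))
    labels = np.asarray(SUBPOPULATION_LABELS)[cat_idx]
    pos = np.asarray([POSITIVITY_OF_LABEL[l] for l in labels], dtype=bool).reshape(n, 3)

    coe_i = np.zeros(n)
    cfse_i = np.zeros(n)
    # correlated latent copula draws for every particle; intensity applied
    # only where the category carries the marker
    a, b = sample_intensity_pairs(
        params.coe_model, params.cfse_model, params.marker_correlation, n, rng
    )
    coe_i[pos[:, 0]] = a[pos[:, 0]]
    cfse_i[pos[:, 1]] = b[pos[:, 1]]

    copies = np.zeros(n, dtype=int)
    cd63_i = np.zeros(n)
    n_cd63 = int(pos[:, 2].sum())
    if n_cd63:
        k = _zero_truncated_poisson(params.cd63_copy_mean, n_cd63, rng)
        draws = _truncated_normal(
            params.unit_intensity_mu, params.unit_intensity_sigma, int(k.sum()), rng
        )
        starts = np.concatenate(([0], np.cumsum(k)[:-1]))
        sums = np.add.reduceat(draws, starts) if k.sum() else np.zeros(n_cd63)
        copies[pos[:, 2]] = k
        cd63_i[pos[:, 2]] = sums

    gain = _gain_field((ny, nx), params.illumination_gradient)
    channels = {}
    for label, inten in ((COE, coe_i), (CFSE, cfse_i), (CD63, cd63_i)):
        signal = _render_spots((ny, nx), xs, ys, inten, params.psf_sigma_px)
        channels[label] = _apply_camera(signal, gain, params, rng)

    margin = params.psf_sigma_px
    near_edge = (
        (xs < margin) | (xs > nx - margin) | (ys < margin) | (ys > ny - margin)
    )
    truth = pd.DataFrame(
        {
            "x_px": xs,
            "y_px": ys,
            "category": labels,
            "copies_cd63": copies,
            "intensity_COE": coe_i,
            "intensity_CFSE": cfse_i,
            "intensity_CD63": cd63_i,
            "near_edge": near_edge,
        },
        columns=_TRUTH_COLUMNS,
    )
    image = FieldImage(channels=channels, pixel_size_um=params.pixel_size_um,
                       field_id=f"scene{params.seed}")
    return image, SceneTruth(particles=truth, params=params)


def generate_calibration_field(
    unit_mu: float,
    unit_sigma: float,
    density_per_um2: float,
    field_size_px: tuple[int, int] = (400, 400),
    pixel_size_um: float = 0.25,
    psf_sigma_px: float = 1.0,
    background_offset_adu: float = 100.0,
    read_noise_sd_adu: float = 3.0,
    illumination_gradient: tuple[float, float] = (1.0, 1.0),
    channel: str = CD63,
    seed: int = 0,
) -> tuple[FieldImage, SceneTruth]:
    """Single-channel field of isolated single fluorophore-labelled antibodies.

    Each spot's true integrated intensity is one draw from N(mu1, sigma1)
    truncated at zero — the calibration target for single-molecule intensity
    fitting.  Densities at which spots would not be isolated (expected
    nearest-neighbour distance <= 6 PSF sigma) are rejected.
    """
    if unit_mu <= 0 or unit_sigma < 0:
        raise ValueError("unit_mu must be positive and unit_sigma non-negative")
    density_px = density_per_um2 * pixel_size_um**2
    if density_px > 0 and 0.5 / math.sqrt(density_px) <= 6.0 * psf_sigma_px:
        raise ValueError("calibration density too high: spots would not be isolated")

    params = SceneParams(
        field_size_px=tuple(field_size_px),
        pixel_size_um=pixel_size_um,
        particle_density_per_um2=density_per_um2,
        psf_sigma_px=psf_sigma_px,
        unit_intensity_mu=unit_mu,
        unit_intensity_sigma=unit_sigma,
        illumination_gradient=tuple(illumination_gradient),
        background_offset_adu=background_offset_adu,
        read_noise_sd_adu=read_noise_sd_adu,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    nx, ny = params.field_size_px
    n = int(rng.poisson(density_per_um2 * params.field_area_um2))
    xs = rng.uniform(0.0, nx, size=n)
    ys = rng.uniform(0.0, ny, size=n)
    inten = _truncated_normal(unit_mu, unit_sigma, n, rng)

    gain = _gain_field((ny, nx), params.illumination_gradient)
    signal = _render_spots((ny, nx), xs, ys, inten, psf_sigma_px)
    img = _apply_camera(signal, gain, params, rng)

    margin = psf_sigma_px
    truth = pd.DataFrame(
        {
            "x_px": xs,
            "y_px": ys,
            "category": np.full(n, "calibration"),
            "copies_cd63": np.ones(n, dtype=int),
            "intensity_COE": np.zeros(n),
            "intensity_CFSE": np.zeros(n),
            "intensity_CD63": inten,
            "near_edge": (xs < margin) | (xs > nx - margin) | (ys < margin) | (ys > ny - margin),
        },
        columns=_TRUTH_COLUMNS,
    )
    image = FieldImage(channels={channel: img}, pixel_size_um=pixel_size_um,
                       field_id=f"calibration{seed}")
    return image, SceneTruth(particles=truth, params=params)


def write_scene(image: FieldImage, truth: SceneTruth, directory: str | os.PathLike) -> dict:
    """Persist a scene: per-channel TIFFs, truth CSV and a YAML parameter file."""
    paths = image.save(directory)
    truth_path = truth.save(directory, stem=f"{image.field_id}_truth")
    return {"channels": paths, "truth": truth_path}
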