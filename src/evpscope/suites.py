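"""Validation suites: canonical synthetic benchmarks for every pipeline stage.

Each function generates its own scenes from a seed, runs the package
end-to-end, and returns plain-number metrics.  The conditions (field sizes,
densities, intensity scales) are the package's reference benchmarks and are
documented in the methods note; tests and the acceptance script both call
these functions so the measured quantities are defined in exactly one
place.
"""

from __future__ import annotations

import hashlib
import math
import os
from typing import Sequence

import numpy as np
import pandas as pd

from .colocalize import composite_detect, particles_to_dataframe, venn_fractions
from .detect import DetectionParams, band_filter, detect_spots, flag_aggregates, segment_strings
from .evaluate import interior_truth, label_accuracy, precision_recall
from .preprocess import preprocess_field
from .quantify import CalibrationModel, counts_by_deconvolution, counts_by_ratio, fit_single_fluorophore
from .simulate import (
    MarkerModel,
    SceneParams,
    generate_calibration_field,
    generate_scene,
    intensity_for_peak_snr,
    sample_intensity_pairs,
)
from .subpopulations import SUBPOPULATION_LABELS

#: scoring radius for matching detections to ground truth (px)
MATCH_RADIUS_PX = 3.0
#: truth margin excluded from scoring, matching the detector's edge margin
SCORE_MARGIN_PX = 5.0

__all__ = [
    "detection_suite",
    "mixture_scene",
    "categorization_suite",
    "copy_number_suite",
    "deconvolution_suite",
    "correlation_from_particles",
    "null_correlation_suite",
    "welch_type1_suite",
    "determinism_suite",
]


def _single_channel_spots(channel_img: np.ndarray, params: DetectionParams, channel: str):
    spots = detect_spots(band_filter(channel_img, params.kernel_size_px), channel_img,
                         params, channel)
    spots = segment_strings(spots, channel_img, params)
    return flag_aggregates(spots, params)


def detection_suite(
    n_fields: int = 100,
    peak_snr: float = 5.0,
    density_per_um2: float = 0.02,
    field_size_px: tuple[int, int] = (300, 300),
    k_sd: float = 3.5,
    seed: int = 0,
) -> dict:
    """Single-channel detection benchmark: pooled precision and recall.

    Fields carry membrane-dye-only particles of fixed intensity at the
    requested peak SNR under flat illumination; scoring is greedy
    one-to-one matching within 3 px, excluding a 5 px border.
    """
    params = DetectionParams(k_sd=k_sd)
    tp = n_det = n_true = 0
    for i in range(n_fields):
        base = SceneParams(field_size_px=field_size_px, pixel_size_um=0.25,
                           particle_density_per_um2=density_per_um2, seed=seed + i)
        intensity = intensity_for_peak_snr(peak_snr, base)
        p = SceneParams(
            field_size_px=field_size_px,
            particle_density_per_um2=density_per_um2,
            category_probs=(0, 0, 0, 1, 0, 0, 0),  # membrane dye only
            coe_model=MarkerModel(intensity, 1.0),
            illumination_gradient=(1.0, 1.0),
            seed=seed + i,
        )
        image, truth = generate_scene(p)
        channel = preprocess_field(image).channels["COE"]
        spots = _single_channel_spots(channel, params, "COE")
        xy = np.array([[s.x_px, s.y_px] for s in spots if not s.excluded])
        inter = interior_truth(truth.particles, channel.shape, SCORE_MARGIN_PX)
        _, _, matched = precision_recall(xy, inter[["x_px", "y_px"]].to_numpy(),
                                         MATCH_RADIUS_PX)
        tp += matched
        n_det += 0 if xy.size == 0 else len(xy)
        n_true += len(inter)
    return {
        "precision": tp / n_det if n_det else 1.0,
        "recall": tp / n_true if n_true else 1.0,
        "n_fields": n_fields,
        "n_true": n_true,
    }


def mixture_scene(
    seed: int,
    n_target: int = 2000,
    density_per_um2: float = 0.005,
    median_peak_snr: float = 20.0,
    gsd: float = 1.3,
    marker_correlation: float = 0.8,
    cd63_copy_mean: float = 10.0,
) -> SceneParams:
    """Study conditions for the seven-category mixture benchmarks.

    Sized so the expected particle count is ``n_target``; marker medians
    sit at peak SNR 20 with a narrow spread, keeping effectively every
    particle above peak SNR 8.
    """
    area_um2 = n_target / density_per_um2
    side = int(round(math.sqrt(area_um2) / 0.25))
    base = SceneParams(field_size_px=(side, side), pixel_size_um=0.25,
                       particle_density_per_um2=density_per_um2, seed=seed)
    median = intensity_for_peak_snr(median_peak_snr, base)
    return SceneParams(
        field_size_px=(side, side),
        particle_density_per_um2=density_per_um2,
        coe_model=MarkerModel(median, gsd),
        cfse_model=MarkerModel(median, gsd),
        cd63_copy_mean=cd63_copy_mean,
        marker_correlation=marker_correlation,
        seed=seed,
    )


#: composite-mode detection settings for composition estimates: the upper
#: end of the conventional 3-4 SD threshold range suppresses noise-born
#: false particles that would bias subpopulation fractions
COMPOSITION_PARAMS = DetectionParams(k_sd=4.0)


def categorization_suite(n_rois: int = 10, seed: int = 0, **scene_kwargs) -> dict:
    """Run the composite pipeline on ``n_rois`` mixture ROIs.

    Returns the pooled 7-way label accuracy, the Venn fractions with their
    deviation from the generator probabilities in binomial-SE units, and
    the per-ROI particle tables.
    """
    rois = []
    correct = matched = 0
    probs = None
    for i in range(n_rois):
        params = mixture_scene(seed=seed + i, **scene_kwargs)
        probs = params.category_probs
        image, truth = generate_scene(params)
        pre = preprocess_field(image)
        particles = composite_detect(pre, COMPOSITION_PARAMS)
        particles = [p for p in particles if not p.excluded]
        rois.append(particles)
        df = particles_to_dataframe(particles)
        inter = interior_truth(truth.particles, pre.shape, SCORE_MARGIN_PX)
        acc, n = label_accuracy(df, inter, MATCH_RADIUS_PX)
        correct += acc * n
        matched += n
    venn = venn_fractions(rois)
    total = venn["n_particles"]
    deviations = {}
    for label, p_true in zip(SUBPOPULATION_LABELS, probs):
        se = math.sqrt(p_true * (1 - p_true) / total)
        obs = venn["fractions"][label]["fraction"]
        deviations[label] = {"observed": obs, "expected": p_true,
                             "se_units": (obs - p_true) / se if se > 0 else 0.0}
    return {
        "label_accuracy": correct / matched if matched else 0.0,
        "n_matched": matched,
        "venn": venn,
        "deviations": deviations,
        "max_abs_se_units": max(abs(d["se_units"]) for d in deviations.values()),
        "rois": rois,
    }


def fit_calibration(
    seed: int = 0,
    unit_mu: float = 400.0,
    unit_sigma: float = 80.0,
    n_fields: int = 2,
    field_size_px: tuple[int, int] = (1200, 1200),
    density_per_um2: float = 0.004,
) -> CalibrationModel:
    """Image single antibodies and fit the single-unit intensity peak."""
    params = DetectionParams()
    intensities: list[float] = []
    for i in range(n_fields):
        image, _ = generate_calibration_field(
            unit_mu, unit_sigma, density_per_um2,
            field_size_px=field_size_px, seed=seed + i,
        )
        channel = preprocess_field(image).channels["CD63"]
        spots = _single_channel_spots(channel, params, "CD63")
        intensities.extend(s.integrated_intensity_adu for s in spots if not s.excluded)
    return fit_single_fluorophore(intensities)


def copy_number_suite(rois: Sequence, calibration: CalibrationModel,
                      copy_mean: float = 10.0) -> dict:
    """Recover the mean CD63 copy number of triple-positive sEVs by ratio."""
    intensities = np.array([
        p.intensity["CD63"] for roi in rois for p in roi
        if p.label == "sEV CFSE+CD63+"
    ])
    counts, _ = counts_by_ratio(intensities, calibration)
    return {
        "mean_count": float(counts.mean()),
        "true_mean": copy_mean,
        "n_particles": int(intensities.size),
        "relative_error": abs(float(counts.mean()) - copy_mean) / copy_mean,
    }


def deconvolution_suite(
    seed: int = 0,
    unit_mu: float = 1000.0,
    unit_sigma: float = 150.0,
    weights: dict[int, float] | None = None,
    n_draws: int = 10_000,
    n_max: int = 10,
) -> dict:
    """Known-mixture weight recovery by NNLS histogram deconvolution."""
    weights = weights or {2: 0.5, 5: 0.5}
    rng = np.random.default_rng(seed)
    ns = rng.choice(list(weights), size=n_draws, p=list(weights.values()))
    draws = rng.normal(ns * unit_mu, np.sqrt(ns) * unit_sigma)
    cal = CalibrationModel(unit_mu, unit_sigma, 1000, 1.0)
    dist = counts_by_deconvolution(draws, cal, n_max=n_max)
    true_w = np.zeros(n_max)
    for n, w in weights.items():
        true_w[n - 1] = w
    tv = 0.5 * float(np.abs(dist.weights - true_w).sum())
    return {"tv_distance": tv, "mean_count": dist.mean_count,
            "true_mean": float(sum(n * w for n, w in weights.items()))}


def correlation_from_particles(rois: Sequence, marker_a: str = "COE",
                               marker_b: str = "CFSE") -> dict:
    """Pearson r between two markers on particles carrying both."""
    from .quantify import pairwise_correlation

    df = particles_to_dataframe([p for roi in rois for p in roi])
    # pool the two CFSE+ sEV labels (both carry COE and CFSE)
    sub = df[df[f"positive_{marker_a}"] & df[f"positive_{marker_b}"]].copy()
    sub["label"] = "pooled"
    r, table = pairwise_correlation(sub, "pooled", marker_a, marker_b)
    return {"r": r, "n": len(table)}


def correlation_parameter_recovery(seed: int = 0, n: int = 2000, r: float = 0.8) -> dict:
    """Recover the generator's intensity correlation from sampled pairs.

    Draws ``n`` (COE, CFSE) intensity pairs from the scene copula model and
    estimates Pearson r with :func:`evpscope.quantify.pairwise_correlation`.
    This checks the copula parameterization itself; the companion
    end-to-end number (:func:`correlation_from_particles`) is additionally
    attenuated by photometric noise (see the methods note).
    """
    from .quantify import pairwise_correlation

    model = MarkerModel(800.0, 1.5)
    rng = np.random.default_rng(seed)
    a, b = sample_intensity_pairs(model, model, r, n, rng)
    df = pd.DataFrame({
        "label": "pooled", "flags": "",
        "positive_COE": True, "positive_CFSE": True,
        "intensity_COE": a, "intensity_CFSE": b,
    })
    r_hat, table = pairwise_correlation(df, "pooled", "COE", "CFSE")
    return {"r": r_hat, "true_r": r, "n": len(table)}


def null_correlation_suite(n_seeds: int = 100, n: int = 2000, seed: int = 0) -> dict:
    """|r| of independent log-normal intensities across seeds."""
    model = MarkerModel(800.0, 1.5)
    rs = []
    for i in range(n_seeds):
        rng = np.random.default_rng(seed + i)
        a, _ = sample_intensity_pairs(model, model, 0.0, n, rng)
        b, _ = sample_intensity_pairs(model, model, 0.0, n, rng)
        rs.append(float(np.corrcoef(a, b)[0, 1]))
    rs = np.array(rs)
    return {"frac_below_0.05": float((np.abs(rs) < 0.05).mean()),
            "max_abs_r": float(np.abs(rs).max())}


def welch_type1_suite(n_reps: int = 10_000, n_per_group: int = 5, seed: int = 0,
                      alpha: float = 0.05) -> dict:
    """Type-I error of the Welch test under the null, vectorized."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n_reps, n_per_group))
    b = rng.normal(size=(n_reps, n_per_group))
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    return {"type1_rate": float((p < alpha).mean()), "n_reps": n_reps}


def determinism_suite(workdir: str, seed: int = 0) -> dict:
    """Simulate, analyze twice with the same config, compare output hashes."""
    from .pipeline import PipelineConfig, run_pipeline
    from .simulate import write_scene

    params = mixture_scene(seed=seed, n_target=300)
    image, truth = generate_scene(params)
    scene_dir = os.path.join(workdir, "scene")
    paths = write_scene(image, truth, scene_dir)

    digests = []
    for run in ("a", "b"):
        out = os.path.join(workdir, f"run_{run}")
        config = PipelineConfig(
            fields=[{"field_id": image.field_id, "channels": dict(paths["channels"])}],
            pixel_size_um=params.pixel_size_um,
            output_dir=out,
            seed=seed,
        )
        results = run_pipeline(config)
        with open(results["particles_path"], "rb") as fh:
            digests.append(hashlib.sha256(fh.read()).hexdigest())
    return {"identical": digests[0] == digests[1], "sha256": digests[0]}
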