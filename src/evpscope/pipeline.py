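"""End-to-end pipeline: preprocess -> detect -> colocalize -> categorize -> quantify.

A :class:`PipelineConfig` describes one run: the per-field channel TIFFs,
the preprocessing and detection parameters, the colocalization mode, an
optional calibration source and capture metadata, and an output directory.
``run_pipeline`` executes every field, pools them as ROIs, and writes the
particle table (CSV), the subpopulation fractions (JSON), the summary
table (CSV) and a run log.  Every output table carries the config hash in
its header metadata; identical config + inputs give identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .colocalize import (
    Particle,
    composite_detect,
    match_spots,
    particles_to_dataframe,
    venn_fractions,
)
from .detect import DetectionParams, band_filter, detect_spots, flag_aggregates, segment_strings
from .fields import FieldImage
from .preprocess import PreprocessParams, preprocess_field
from .quantify import (
    CalibrationModel,
    CaptureInputs,
    captured_fraction,
    fit_single_fluorophore,
    subpopulation_summary,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "calibration_from_image"]


@dataclass
class PipelineConfig:
    """Round-trippable description of one analysis run."""

    fields: List[Dict]  # [{"field_id": str, "channels": {label: tif path}}, ...]
    pixel_size_um: float = 0.25
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    coloc_mode: str = "composite"  # or "match"
    max_match_dist_px: float = 2.0
    calibration_file: Optional[str] = None  # CSV with an intensity_adu column
    calibration_image: Optional[str] = None  # single-antibody TIFF
    capture: Optional[CaptureInputs] = None
    output_dir: str = "evpscope_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fields:
            raise ValueError("config needs at least one field")
        if self.coloc_mode not in ("composite", "match"):
            raise ValueError("coloc_mode must be 'composite' or 'match'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("preprocess"), dict):
            d["preprocess"] = PreprocessParams(**d["preprocess"])
        if isinstance(d.get("detection"), dict):
            d["detection"] = DetectionParams(**d["detection"])
        if isinstance(d.get("capture"), dict):
            d["capture"] = CaptureInputs(**d["capture"])
        return cls(**d)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @property
    def config_hash(self) -> str:
        """Hash of the analysis parameters (the output location is run metadata)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        canonical = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def calibration_from_image(
    path: str | os.PathLike,
    pixel_size_um: float,
    preprocess_params: PreprocessParams | None = None,
    detection_params: DetectionParams | None = None,
    channel: str = "CD63",
) -> CalibrationModel:
    """Detect isolated single antibodies in a calibration image and fit mu1."""
    field_img = FieldImage.load({channel: path}, pixel_size_um, field_id="calibration")
    pre = preprocess_field(field_img, preprocess_params)
    params = detection_params or DetectionParams()
    img = pre.channels[channel]
    spots = detect_spots(band_filter(img, params.kernel_size_px), img, params, channel)
    spots = flag_aggregates(segment_strings(spots, img, params), params)
    intensities = [s.integrated_intensity_adu for s in spots if not s.excluded]
    return fit_single_fluorophore(intensities)


def _write_table(df: pd.DataFrame, path: str, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# evpscope={__version__} config_hash={config_hash}\n")
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.6g")


def analyze_field(field_img: FieldImage, config: PipelineConfig) -> List[Particle]:
    """Preprocess one field and return its colocalized particles."""
    pre = preprocess_field(field_img, config.preprocess)
    if config.coloc_mode == "composite":
        return composite_detect(pre, config.detection)
    spots_by_channel = {}
    for c, img in pre.channels.items():
        spots = detect_spots(
            band_filter(img, config.detection.kernel_size_px), img, config.detection, c
        )
        spots = flag_aggregates(segment_strings(spots, img, config.detection), config.detection)
        spots_by_channel[c] = spots
    return match_spots(spots_by_channel, config.max_match_dist_px, field_id=field_img.field_id)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis described by ``config``.

    Returns a result bundle with the particle table, per-ROI particles,
    Venn fractions, summary table and the paths of everything written.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    log_path = os.path.join(config.output_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("evpscope")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        log.info("evpscope %s config_hash=%s", __version__, config.config_hash)
        log.info("config: %s", json.dumps(config.to_dict(), default=str, sort_keys=True))

        rois: List[List[Particle]] = []
        for entry in config.fields:
            field_img = FieldImage.load(
                entry["channels"], config.pixel_size_um, field_id=entry.get("field_id", "field")
            )
            particles = analyze_field(field_img, config)
            if not particles:
                log.warning("field %s: no particles detected", field_img.field_id)
            rois.append(particles)

        all_particles = [p for roi in rois for p in roi]
        table = particles_to_dataframe(all_particles)

        calibration = None
        if config.calibration_file:
            cal_df = pd.read_csv(config.calibration_file, comment="#")
            calibration = fit_single_fluorophore(cal_df["intensity_adu"].to_numpy())
        elif config.calibration_image:
            calibration = calibration_from_image(
                config.calibration_image, config.pixel_size_um,
                config.preprocess, config.detection,
            )
        if calibration:
            log.info(
                "calibration: mu1=%.2f sigma1=%.2f n=%d R2=%.3f",
                calibration.unit_mu_adu, calibration.unit_sigma_adu,
                calibration.n_calibration_spots, calibration.fit_quality,
            )

        results: dict = {"particles": table, "rois": rois, "calibration": calibration}
        particles_path = os.path.join(config.output_dir, "particles.csv")
        _write_table(table, particles_path, config.config_hash)
        results["particles_path"] = particles_path

        if any(not p.excluded for p in all_particles):
            venn = venn_fractions(rois)
            venn["config_hash"] = config.config_hash
            venn_path = os.path.join(config.output_dir, "venn.json")
            with open(venn_path, "w") as fh:
                json.dump(venn, fh, indent=2, sort_keys=True)
            summary = subpopulation_summary(table, calibration)
            summary_path = os.path.join(config.output_dir, "summary.csv")
            _write_table(summary, summary_path, config.config_hash)
            results.update(
                {"venn": venn, "venn_path": venn_path,
                 "summary": summary, "summary_path": summary_path}
            )
        else:
            log.warning("empty detection result: no venn/summary written")

        if config.capture is not None:
            results["captured_fraction"] = captured_fraction(config.capture)
            log.info("captured_fraction=%.4g", results["captured_fraction"])

        return results
    finally:
        root.removeHandler(handler)
        handler.close()
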