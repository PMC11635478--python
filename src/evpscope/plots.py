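"""Diagnostic plots: intensity scatters, subpopulation fractions, count histograms."""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .subpopulations import SUBPOPULATION_LABELS


def scatter_intensity(
    particles: pd.DataFrame, label: str, marker_a: str, marker_b: str, path: str
) -> str:
    sel = (
        (particles["label"] == label)
        & particles[f"positive_{marker_a}"]
        & particles[f"positive_{marker_b}"]
    )
    sub = particles.loc[sel]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(sub[f"intensity_{marker_a}"], sub[f"intensity_{marker_b}"], s=4, alpha=0.4)
    ax.set_xlabel(f"{marker_a} integrated intensity (ADU)")
    ax.set_ylabel(f"{marker_b} integrated intensity (ADU)")
    ax.set_title(f"{label} (n={len(sub)})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def fraction_bars(venn: dict, path: str) -> str:
    labels = list(SUBPOPULATION_LABELS)
    fracs = [venn["fractions"][l]["fraction"] for l in labels]
    ses = [venn["fractions"][l]["se"] for l in labels]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(range(7), fracs, yerr=np.nan_to_num(ses), capsize=3,
           color=["#2c7fb8"] * 4 + ["#d95f02"] * 3)
    ax.set_xticks(range(7))
    ax.set_xticklabels(labels, rotation=30, ha="right", fontsize=8)
    ax.set_ylabel("fraction of particles")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def count_histogram(counts: np.ndarray, path: str, xlabel: str = "CD63 count per particle") -> str:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(counts, bins="fd", color="#756bb1")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("particles")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
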