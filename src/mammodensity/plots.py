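"""Figure exports: agreement scatter, Bland-Altman, category box plots,
and the four-panel per-image segmentation overview."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .agreement import BlandAltman

_BIRADS_BANDS = ((0, 25), (25, 50), (50, 75), (75, 100))
_BAND_COLORS = ("#c6dbef", "#9ecae1", "#6baed6", "#3182bd")


def scatter_agreement(algorithm, reference, path: str | Path) -> Path:
    """Algorithm (x) vs reference (y) with identity and least-squares
    lines."""
    alg = np.asarray(algorithm, dtype=float)
    ref = np.asarray(reference, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(alg, ref, s=12, color="black", alpha=0.6)
    lim = (0, 100)
    ax.plot(lim, lim, color="tab:blue", label="identity")
    slope, intercept = np.polyfit(alg, ref, 1)
    xs = np.linspace(*lim, 2)
    ax.plot(xs, slope * xs + intercept, color="tab:red",
            label="least squares")
    ax.set_xlim(lim), ax.set_ylim(lim)
    ax.set_xlabel("algorithm percent density")
    ax.set_ylabel("reference standard percent density")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def bland_altman_plot(result: BlandAltman, path: str | Path) -> Path:
    """Difference (reference minus algorithm) vs pair mean, with bias band
    and limit lines."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(result.means, result.differences, s=12, color="black",
               alpha=0.6)
    ax.axhline(0.0, color="gray", lw=0.8)
    ax.axhline(result.bias, color="orange", lw=2,
               label=f"bias = {result.bias:+.2f}%")
    for limit in (result.loa_low, result.loa_high):
        ax.axhline(limit, color="tab:red", ls="--", lw=1)
    ax.set_xlabel("mean of reference and algorithm (%)")
    ax.set_ylabel("reference - algorithm (%)")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def category_boxplot(reference, algorithm_categories, path: str | Path) -> Path:
    """Reference-density box-and-whisker per algorithm BI-RADS category,
    over shaded category bands."""
    ref = np.asarray(reference, dtype=float)
    cats = np.asarray(algorithm_categories, dtype=int)
    fig, ax = plt.subplots(figsize=(6, 4))
    for (lo, hi), color in zip(_BIRADS_BANDS, _BAND_COLORS):
        ax.axhspan(lo, hi, color=color, alpha=0.35, lw=0)
    data = [ref[cats == c] for c in (1, 2, 3, 4)]
    positions = [c for c, d in zip((1, 2, 3, 4), data) if d.size]
    ax.boxplot([d for d in data if d.size], positions=positions, widths=0.5)
    ax.set_xticks([1, 2, 3, 4])
    ax.set_xlim(0.5, 4.5), ax.set_ylim(0, 100)
    ax.set_xlabel("algorithm BI-RADS density category")
    ax.set_ylabel("reference standard percent density")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def four_panel(image, masks, dense, path: str | Path) -> Path:
    """Per-image overview: original, envelope-masked image, dense-pixel
    overlay, binary ROI map."""
    pixels = np.asarray(image.pixels, dtype=float)
    envelope = np.asarray(masks.envelope_mask, dtype=bool)
    fig, axes = plt.subplots(1, 4, figsize=(12, 4))
    axes[0].imshow(pixels, cmap="gray")
    axes[0].set_title("original")
    masked = np.where(envelope, pixels, 0.0)
    axes[1].imshow(masked, cmap="gray")
    axes[1].set_title("breast envelope")
    rgb = np.stack([pixels] * 3, axis=-1) / max(pixels.max(), 1.0)
    rgb[np.asarray(dense, dtype=bool)] = (1.0, 0.0, 0.0)
    axes[2].imshow(rgb)
    axes[2].set_title("dense tissue")
    axes[3].imshow(envelope, cmap="gray")
    axes[3].set_title("ROI map")
    for ax in axes:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
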