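"""Spectrum plotting (peak-annotated k-mer coverage histogram)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .spectrum import KmerHistogram


def plot_spectrum(
    hist: KmerHistogram,
    path,
    error_cutoff: int | None = None,
    lambda_het: float | None = None,
    c_hom: float | None = None,
    repeat_cutoff: float | None = None,
    max_depth: int | None = None,
) -> None:
    """Draw the distinct-k-mer histogram with the fitted landmarks.

    The x range defaults to ~1.5x the repeat cutoff so the error limb,
    both coverage peaks and the onset of the repeat tail are visible.
    """
    depths, counts = hist.arrays()
    if max_depth is None:
        top = repeat_cutoff * 1.5 if repeat_cutoff else (c_hom or max(depths)) * 4
        max_depth = int(top)
    keep = depths <= max_depth
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(depths[keep], counts[keep], lw=1.2, color="#1f77b4")
    marks = [
        (error_cutoff, "error cutoff", "#999999"),
        (lambda_het, "het peak", "#d62728"),
        (c_hom, "hom peak", "#2ca02c"),
        (repeat_cutoff, "repeat cutoff", "#9467bd"),
    ]
    for x, label, color in marks:
        if x is not None:
            ax.axvline(x, ls="--", lw=1, color=color, label=f"{label} ({x:g}x)")
    ax.set_xlabel(f"{hist.k}-mer depth (x)")
    ax.set_ylabel("distinct k-mers")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
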