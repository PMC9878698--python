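"""Diagnostic plots: QQ (genomic control) and Manhattan views of a scan."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .association import AssociationResult, qq_coordinates

__all__ = ["qq_plot", "manhattan_plot"]


def qq_plot(pvals, ax=None, label=None):
    """Expected vs observed -log10 p with the y = x reference line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    coords = qq_coordinates(pvals)
    ax.plot(coords["expected"], coords["observed"], ".", ms=3, label=label)
    lim = max(coords["expected"].max(), coords["observed"].max())
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    if label:
        ax.legend(frameon=False)
    return ax


def manhattan_plot(result: AssociationResult, threshold_nlp: float = 4.5, ax=None):
    """Per-SNP -log10 p along the genome with the calling threshold."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    chroms = np.asarray(result.chrom)
    nlp = result.neg_log10_p
    offset = 0
    for i, ch in enumerate(dict.fromkeys(chroms)):
        sel = chroms == ch
        x = offset + (result.pos[sel] - result.pos[sel].min())
        ax.plot(x, nlp[sel], ".", ms=2, color=f"C{i % 2}")
        offset = x.max() + 1
    ax.axhline(threshold_nlp, color="r", lw=0.8, ls="--")
    ax.set_xlabel("genome position")
    ax.set_ylabel("$-\\log_{10} p$")
    ax.set_title(f"{result.model} scan, $\\lambda_{{GC}}$ = {result.lambda_gc:.2f}")
    return ax
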