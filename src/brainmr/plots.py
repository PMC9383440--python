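"""Diagnostic plots (Manhattan, QQ, MR ladder, pattern scatter).

Figures are created without pyplot so plotting works headless; every
function accepts an existing Axes or returns a fresh Figure's Axes.
"""

from __future__ import annotations

import numpy as np


def _new_axes():
    from matplotlib.figure import Figure

    fig = Figure(figsize=(7, 4))
    return fig.add_subplot(111)


def manhattan(res, ax=None, alpha: float = 5e-8):
    """Manhattan plot of a GWAS result with the genome-wide line."""
    ax = ax or _new_axes()
    tab = res.table
    p = tab["p"].to_numpy(float)
    ok = np.isfinite(p)
    ax.scatter(tab["pos"][ok], -np.log10(p[ok]), s=4, c="steelblue")
    ax.axhline(-np.log10(alpha), color="gray", lw=1)
    ax.set_xlabel("position")
    ax.set_ylabel("-log10 p")
    ax.set_title(f"GWAS of {res.trait}")
    return ax


def qq_plot(res, ax=None):
    """Observed vs expected -log10 p with the inflation factor annotated."""
    from .association import genomic_inflation

    ax = ax or _new_axes()
    p = res.table["p"].to_numpy(float)
    p = np.sort(p[np.isfinite(p)])
    exp = -np.log10((np.arange(1, p.size + 1) - 0.5) / p.size)
    ax.scatter(exp, -np.log10(p), s=4, c="steelblue")
    lim = max(exp.max(), -np.log10(p.min()))
    ax.plot([0, lim], [0, lim], color="gray", lw=1)
    lam = genomic_inflation(res)["lambda_gc"]
    ax.annotate(f"lambda_GC = {lam:.3f}", xy=(0.05, 0.9), xycoords="axes fraction")
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    return ax


def mr_ladder(report, ax=None, alpha: float = 0.05):
    """-log10 outcome p per removal threshold, one bar group per direction."""
    ax = ax or _new_axes()
    width = 0.02
    for off, (direction, color) in enumerate(
        (("X->Y", "firebrick"), ("Y->X", "steelblue"))
    ):
        rows = report.direction_rows(direction)
        ax.bar(
            rows["t"] + (off - 0.5) * width,
            -np.log10(rows["p_outcome"]),
            width=width,
            color=color,
            label=direction,
        )
    ax.axhline(-np.log10(alpha), color="gray", lw=1)
    ax.set_xlabel("pleiotropy removal threshold")
    ax.set_ylabel("-log10 one-tailed p (instrument vs outcome)")
    ax.legend()
    ax.set_title(f"{report.x} <-> {report.y}: verdict {report.verdict}")
    return ax


def pattern_scatter(pattern_a, pattern_b, ax=None):
    """Region-wise scatter of two association patterns."""
    from .patterns import pattern_correlation

    ax = ax or _new_axes()
    va, vb = pattern_a.vector, pattern_b.vector
    ax.scatter(va, vb, s=10, c="mediumpurple")
    r = pattern_correlation(pattern_a, pattern_b)
    ax.set_xlabel(pattern_a.phenotype)
    ax.set_ylabel(pattern_b.phenotype)
    ax.set_title(f"pattern similarity r = {r:.4f}")
    return ax
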