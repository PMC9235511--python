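"""Basic diagnostic plots: Manhattan, QQ and ROC."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["manhattan_plot", "qq_plot", "roc_plot"]


def manhattan_plot(site_table: pd.DataFrame, fdr: float = 0.05, path=None):
    """-log10 p by genomic position, colored per chromosome."""
    df = site_table.copy()
    df["chr_num"] = pd.to_numeric(df["chr"], errors="coerce")
    df = df.dropna(subset=["chr_num"]).sort_values(["chr_num", "pos"])
    fig, ax = plt.subplots(figsize=(9, 3))
    offset, ticks = 0, []
    for i, (c, block) in enumerate(df.groupby("chr_num", sort=True)):
        x = offset + np.arange(len(block))
        ax.scatter(x, -np.log10(block["p"]), s=3,
                   color="steelblue" if i % 2 else "slategray")
        ticks.append((offset + len(block) / 2, int(c)))
        offset += len(block)
    sig = df[df["q"] < fdr]
    if len(sig):
        thr_p = sig["p"].max()
        ax.axhline(-np.log10(thr_p), color="red", lw=0.8)
    ax.set_xticks([t for t, _ in ticks])
    ax.set_xticklabels([str(c) for _, c in ticks], fontsize=6)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} p$")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def qq_plot(p, lam: float | None = None, path=None):
    """Observed vs expected -log10 p under the uniform null."""
    p = np.sort(np.asarray(p, float))
    n = len(p)
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(expected, -np.log10(p), s=3, color="steelblue")
    lim = max(expected.max(), -np.log10(p[0]))
    ax.plot([0, lim], [0, lim], color="red", lw=0.8)
    ax.set_xlabel(r"expected $-\log_{10} p$")
    ax.set_ylabel(r"observed $-\log_{10} p$")
    if lam is not None:
        ax.annotate(f"$\\lambda$ = {lam:.2f}", xy=(0.05, 0.9),
                    xycoords="axes fraction")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def roc_plot(roc, path=None):
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(roc.fpr, roc.tpr, color="steelblue")
    ax.plot([0, 1], [0, 1], color="gray", lw=0.8, ls="--")
    ax.annotate(f"AUC = {roc.auc:.2f}", xy=(0.55, 0.1), xycoords="axes fraction")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
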