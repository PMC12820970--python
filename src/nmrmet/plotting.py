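"""Figure helpers: score plots, VIP-colored loadings, validation plots."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = [
    "plot_scores",
    "plot_loading_weights",
    "plot_true_vs_permuted",
    "plot_roc_band",
]

GROUP_COLORS = {"SC": "tab:green", "HF": "tab:red"}


def _hotelling_ellipse(ax, t1, t2, alpha=0.95, **kw):
    """95% Hotelling T²-style confidence ellipse of a 2-D score cloud."""
    from scipy import stats

    n = t1.size
    cov = np.cov(np.vstack([t1, t2]))
    vals, vecs = np.linalg.eigh(cov)
    f = stats.f.ppf(alpha, 2, n - 2) * 2 * (n - 1) / (n - 2)
    theta = np.linspace(0, 2 * np.pi, 200)
    circle = np.vstack([np.cos(theta), np.sin(theta)])
    ellipse = vecs @ (np.sqrt(vals[:, None] * f) * circle)
    ax.plot(t1.mean() + ellipse[0], t2.mean() + ellipse[1], **kw)


def plot_scores(scores: np.ndarray, groups, path=None, title=""):
    """2-D score scatter with 95% confidence ellipse, colored by diet group."""
    fig, ax = plt.subplots(figsize=(5, 4))
    groups = np.asarray(groups)
    for g in np.unique(groups):
        sel = groups == g
        ax.scatter(scores[sel, 0], scores[sel, 1],
                   color=GROUP_COLORS.get(g, "gray"), label=str(g))
    if scores.shape[0] > 3:
        _hotelling_ellipse(ax, scores[:, 0], scores[:, 1],
                           color="gray", lw=1, ls="--")
    ax.set_xlabel("LV1 / PC1")
    ax.set_ylabel("LV2 / PC2")
    ax.legend()
    ax.set_title(title)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_loading_weights(lw, path=None, title=""):
    """LV1 back-scaled loading profile vs ppm, colored by VIP."""
    fig, ax = plt.subplots(figsize=(8, 3))
    ppm = np.asarray(lw.index, dtype=float)
    sc = ax.scatter(ppm, lw["w1_sd"], c=lw["vip"], cmap="coolwarm", s=4)
    fig.colorbar(sc, ax=ax, label="VIP")
    ax.invert_xaxis()
    ax.set_xlabel("δ (ppm)")
    ax.set_ylabel("w1 × SD")
    ax.set_title(title)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_true_vs_permuted(mccv_report, path=None, title=""):
    """Q² distributions of true-label and label-permuted MCCV runs."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(mccv_report.q2_distribution, bins=30, alpha=0.6, label="true classes")
    ax.hist(mccv_report.null_q2_distribution, bins=30, alpha=0.6,
            label="permuted classes")
    ax.set_xlabel("Q² (withheld)")
    ax.set_ylabel("iterations")
    ax.legend()
    ax.set_title(title)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_roc_band(auroc_report, path=None, title=""):
    """Per-fold AUROCs with the 95% CI and the permutation null band."""
    fig, ax = plt.subplots(figsize=(5, 4))
    k = auroc_report.fold_aurocs.size
    ax.scatter(np.arange(1, k + 1), auroc_report.fold_aurocs, label="fold AUROC")
    lo, hi = auroc_report.ci95
    ax.axhspan(lo, hi, color="tab:blue", alpha=0.2, label="95% CI")
    if auroc_report.null_aurocs.size:
        lo_n, hi_n = np.quantile(auroc_report.null_aurocs, [0.025, 0.975])
        ax.axhspan(lo_n, hi_n, color="gray", alpha=0.2, label="null band")
    ax.set_ylim(0, 1.05)
    ax.set_xlabel("fold")
    ax.set_ylabel("AUROC")
    ax.legend()
    ax.set_title(title)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
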