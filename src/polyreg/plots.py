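"""Evaluation figures: Bland-Altman, regression scatter, overlay/difference maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .losses_metrics import AgreementStats, RegressionReport

__all__ = ["bland_altman_plot", "regression_scatter_plot", "report_figures",
           "overlay_difference_figure"]


def bland_altman_plot(stats: AgreementStats, path, title: str = "") -> None:
    """Scatter of paired differences vs paired means with limits of agreement."""
    if stats.means is None or stats.diffs is None:
        raise ValueError("AgreementStats carries no paired data to plot")
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(stats.means, stats.diffs, s=6, alpha=0.5)
    ax.axhline(stats.mean_difference, color="k", lw=1,
               label=f"mean {stats.mean_difference:.3g}")
    for lim in (stats.lower_limit, stats.upper_limit):
        ax.axhline(lim, color="r", lw=1, ls="--")
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference")
    if title:
        ax.set_title(f"{title}  (R={stats.pearson_r:.3f})", fontsize=9)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=110)
    plt.close(fig)


def regression_scatter_plot(pred: np.ndarray, target: np.ndarray, path,
                            title: str = "") -> None:
    """Predicted vs target scatter with the identity line."""
    pred = np.asarray(pred).ravel()
    target = np.asarray(target).ravel()
    fig, ax = plt.subplots(figsize=(3.5, 3.5))
    ax.scatter(target, pred, s=5, alpha=0.4)
    lo, hi = min(target.min(), pred.min()), max(target.max(), pred.max())
    ax.plot([lo, hi], [lo, hi], "k--", lw=1)
    ax.set_xlabel("target")
    ax.set_ylabel("predicted")
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=110)
    plt.close(fig)


def report_figures(report: RegressionReport, pred_norm: np.ndarray,
                   target_norm: np.ndarray, out_dir) -> list[Path]:
    """Write per-parameter Bland-Altman plots and the pooled scatter."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, stats in report.per_parameter.items():
        p = out / f"bland_altman_{name}.png"
        bland_altman_plot(stats, p, title=name)
        written.append(p)
    p = out / "regression_pooled.png"
    regression_scatter_plot(pred_norm, target_norm, p,
                            title=f"pooled R={report.pooled_r:.4f}")
    written.append(p)
    return written


def overlay_difference_figure(fixed: np.ndarray, other: np.ndarray, path,
                              labels: tuple[str, str] = ("fixed", "other")) -> None:
    """Checkerboard-free qualitative view: overlay plus absolute-difference map."""
    def gray(a):
        a = np.asarray(a, dtype=float)
        return a.mean(axis=-1) if a.ndim == 3 else a

    gf, go = gray(fixed), gray(other)
    overlay = np.zeros(gf.shape + (3,))
    overlay[..., 0] = gf / max(gf.max(), 1)
    overlay[..., 1] = go / max(go.max(), 1)
    diff = np.abs(gf - go)
    fig, axes = plt.subplots(1, 2, figsize=(7, 3.2))
    axes[0].imshow(overlay)
    axes[0].set_title(f"overlay: {labels[0]} (red) vs {labels[1]} (green)", fontsize=8)
    im = axes[1].imshow(diff, cmap="inferno")
    axes[1].set_title("absolute difference", fontsize=8)
    fig.colorbar(im, ax=axes[1], fraction=0.046)
    for ax in axes:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=110)
    plt.close(fig)
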