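"""Report figures: PRD scatter, association heatmaps, MIA precision curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .eval_resemblance import AssociationMatrix, PRDCurve
from .eval_utility_privacy import MIAResult


def plot_prd(curves: dict[str, PRDCurve], path: str) -> None:
    """PRD curves (recall on x, precision on y), one per labelled fold/run."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for label, curve in curves.items():
        ax.plot(curve.betas, curve.alphas, label=label, lw=1.2)
    ax.set_xlabel(r"recall $\beta$")
    ax.set_ylabel(r"precision $\alpha$")
    ax.set_xlim(0, 1.02)
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_association_heatmap(assoc: AssociationMatrix, path: str, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    m = np.ma.masked_invalid(assoc.matrix)
    im = ax.imshow(m, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(assoc.variables)))
    ax.set_yticks(range(len(assoc.variables)))
    ax.set_xticklabels(assoc.variables, rotation=90, fontsize=6)
    ax.set_yticklabels(assoc.variables, fontsize=6)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_mia_curves(results: dict[str, MIAResult], path: str) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, res in results.items():
        ax.plot(res.known_fractions, res.precisions, marker="o", label=label)
    ax.set_xlabel("fraction of training data known to adversary")
    ax.set_ylabel("attack precision")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
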