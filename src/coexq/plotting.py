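"""Expression-profile figures (grouped TPM bars per sample per gene)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .expression_io import ExpressionMatrix

__all__ = ["render_profiles"]


def render_profiles(
    matrix: ExpressionMatrix,
    genes: Sequence[str],
    path: str | Path,
) -> Path:
    """Grouped bar chart of TPM per sample for the given genes.

    The output format follows the file extension (png, pdf, svg).
    Figures are a convenience layer for eyeballing profiles; all
    quantitative output is tabular.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene list is empty")
    unknown = [g for g in genes if g not in matrix.data.index]
    if unknown:
        raise KeyError(f"unknown gene(s): {', '.join(unknown)}")

    path = Path(path)
    samples = matrix.sample_labels
    x = np.arange(len(samples))
    width = 0.8 / len(genes)

    fig, ax = plt.subplots(figsize=(max(6.0, 0.9 * len(samples)), 4.0))
    for i, gene in enumerate(genes):
        ax.bar(
            x + (i - (len(genes) - 1) / 2) * width,
            matrix.data.loc[gene].to_numpy(),
            width,
            label=gene,
        )
    ax.set_xticks(x)
    ax.set_xticklabels(samples, rotation=45, ha="right")
    ax.set_ylabel("Expression (TPM)")
    ax.legend(frameon=False, fontsize="small")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
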