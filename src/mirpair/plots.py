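"""Per-pair scatter plots of log2 intensities with a regression line."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io import ExpressionMatrix, SampleSheet


def pair_scatter(
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    sheet: SampleSheet,
    mrna_id: str,
    mirna_id: str,
    path,
) -> None:
    """Scatter of one pair's log2 intensities, groups distinguished,
    with the least-squares regression line."""
    x = mirna.row(mirna_id)
    y = mrna.row(mrna_id)
    mask_r, mask_nr = sheet.masks_for(mrna.sample_ids)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x[mask_r], y[mask_r], marker="o", label="R", color="tab:blue")
    ax.scatter(x[mask_nr], y[mask_nr], marker="^", label="NR", color="tab:red")
    slope, intercept = np.polyfit(x, y, 1)
    grid = np.linspace(x.min(), x.max(), 50)
    ax.plot(grid, slope * grid + intercept, color="black", linewidth=1)
    ax.set_xlabel(f"{mirna_id} (log2 intensity)")
    ax.set_ylabel(f"{mrna_id} (log2 intensity)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
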