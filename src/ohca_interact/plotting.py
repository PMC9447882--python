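"""Rendering of counterfactual heatmaps.

The convention for these figures: a diverging color scale clipped
symmetrically (default +/-6%, so the two ends of the spectrum mean "6%
increase/decrease in predicted CPC 1/2"), the unadjusted (0, 0) cell
outlined with a square box, axes labeled in delta minutes.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from matplotlib.patches import Rectangle

from .counterfactual import HeatmapGrid

__all__ = ["render_heatmap"]

_AXIS_LABELS = {
    "age_years": "age delta (years)",
    "call_to_contact": "call-to-contact delta (min)",
    "contact_to_arrival": "contact-to-hospital-arrival delta (min)",
    "contact_to_first_defib": "contact-to-first-defibrillation delta (min)",
    "contact_to_first_drug": "contact-to-first-drug delta (min)",
}


def render_heatmap(grid: HeatmapGrid, path, color_limit_percent: float = 6.0,
                   title: str | None = None) -> None:
    """Write the grid as a deterministic SVG (or PNG, by file suffix).

    Cells beyond +/-``color_limit_percent`` render at the clipped extremes.
    Rendering is a pure function of (grid, limit, title): metadata that
    would vary between runs (dates, hash salts) is pinned.
    """
    with plt.rc_context({"svg.hashsalt": "ohca-interact", "svg.fonttype": "none"}):
        fig, ax = plt.subplots(figsize=(6.0, 4.8))
        im = ax.imshow(
            grid.values,
            origin="lower",
            aspect="auto",
            cmap="coolwarm",
            vmin=-color_limit_percent,
            vmax=color_limit_percent,
        )
        ax.set_xticks(range(len(grid.deltas_b)), [f"{d:g}" for d in grid.deltas_b])
        ax.set_yticks(range(len(grid.deltas_a)), [f"{d:g}" for d in grid.deltas_a])
        ax.set_xlabel(_AXIS_LABELS.get(grid.factor_b, grid.factor_b))
        ax.set_ylabel(_AXIS_LABELS.get(grid.factor_a, grid.factor_a))
        i0 = grid.deltas_a.index(0.0)
        j0 = grid.deltas_b.index(0.0)
        ax.add_patch(Rectangle((j0 - 0.5, i0 - 0.5), 1.0, 1.0,
                               fill=False, edgecolor="black", linewidth=2.0))
        cbar = fig.colorbar(im, ax=ax)
        cbar.set_label("change in predicted CPC 1/2 (%)")
        ax.set_title(title or f"{grid.factor_a} x {grid.factor_b} "
                              f"(baseline {grid.baseline:.4g}, {grid.summary_mode})")
        fig.tight_layout()
        fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
        plt.close(fig)
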