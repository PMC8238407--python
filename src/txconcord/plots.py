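"""Three-set Venn figure for one cutoff of a concordance report.

Drawn directly with matplotlib circle patches and count annotations; region
areas are not proportional to counts (layout is fixed, labels carry the
numbers)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Circle

__all__ = ["venn3_figure"]

# fixed layout: circle centers and the 7 exclusive-region label anchors
_CENTERS = [(-0.45, 0.3), (0.45, 0.3), (0.0, -0.48)]
_RADIUS = 0.85
_COLORS = ["#1b9e77", "#d95f02", "#7570b3"]
_REGION_XY = {
    (0,): (-0.85, 0.55),
    (1,): (0.85, 0.55),
    (2,): (0.0, -0.95),
    (0, 1): (0.0, 0.6),
    (0, 2): (-0.5, -0.35),
    (1, 2): (0.5, -0.35),
    (0, 1, 2): (0.0, 0.05),
}


def venn3_figure(
    labels: list[str],
    regions: dict[str, int],
    path: str | Path,
    title: str = "",
) -> Path:
    """Render a 3-set Venn diagram with per-region counts.

    ``regions`` maps ``"&"``-joined label subsets (as written in the JSON
    report) to gene counts.
    """
    if len(labels) != 3:
        raise ValueError(f"3-set plots only, got {len(labels)} labels")

    fig, ax = plt.subplots(figsize=(5, 5))
    for (cx, cy), color in zip(_CENTERS, _COLORS):
        ax.add_patch(Circle((cx, cy), _RADIUS, alpha=0.3, facecolor=color, edgecolor="black"))
    for idxs, (x, y) in _REGION_XY.items():
        key = "&".join(labels[i] for i in idxs)
        ax.text(x, y, str(regions.get(key, 0)), ha="center", va="center", fontsize=12)
    set_label_xy = [(-1.15, 1.15), (1.15, 1.15), (0.0, -1.55)]
    for lab, (x, y), color in zip(labels, set_label_xy, _COLORS):
        ax.text(x, y, lab, ha="center", va="center", fontsize=11, color=color)
    ax.set_xlim(-1.8, 1.8)
    ax.set_ylim(-1.9, 1.7)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    path = Path(path)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path
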