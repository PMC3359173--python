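"""Elongation-onset (transition-zone) landmark estimation.

Along a root cell file, cell lengths stay roughly constant through the
meristem and then rise steeply in the elongation zone. The landmark is
located geometrically on the cell-number vs cell-length series: draw the
chord from the first to the last data point and pick the interior point
with the largest perpendicular distance to it — the 'break point' at the
base of the rising curve. Distances are computed in raw data units; no
smoothing is applied to the series first.

The cumulative-length variant (positions instead of cell numbers on the
abscissa) is provided but not the default: the horizontal stretching
introduced by long distal cells flattens the curve and makes the corner
less consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .walls import CellFile

logger = logging.getLogger("cellfiler")

__all__ = ["TSZEstimate", "find_break_point", "estimate_tsz", "plot_break_point"]

MODES = ("cell_number", "cumulative_length")


@dataclass(frozen=True)
class TSZEstimate:
    """Break-point landmark of a cell file.

    cell_index : 1-based index of the break-point cell counted from the
        profile start.
    distance_um : arc distance from the profile start to the proximal
        boundary of that cell.
    mode : abscissa used ('cell_number' or 'cumulative_length').
    """

    cell_index: int
    distance_um: float
    mode: str = "cell_number"


def find_break_point(
    xs: np.ndarray, ys: np.ndarray, normalize: bool = False
) -> int:
    """Index (1-based) of the point with maximum perpendicular distance to
    the first-to-last chord.

    Distances are unsigned and computed in raw data units; set
    ``normalize`` to min-max scale both axes to [0, 1] first. Only interior
    points are considered; ties break toward the smallest index.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.ndim != 1 or xs.shape != ys.shape:
        raise ValueError("xs and ys must be equal-length 1-D arrays")
    if len(xs) < 3:
        raise ValueError(f"need >= 3 points to find a break point, got {len(xs)}")
    if np.any(np.diff(xs) <= 0):
        raise ValueError("xs must be strictly increasing")
    if normalize:
        xs = (xs - xs[0]) / (xs[-1] - xs[0])
        span = ys.max() - ys.min()
        ys = (ys - ys.min()) / span if span > 0 else np.zeros_like(ys)
    dx = xs[-1] - xs[0]
    dy = ys[-1] - ys[0]
    norm = np.hypot(dx, dy)
    # unsigned distance of each interior point to the chord
    d = np.abs(dx * (ys[1:-1] - ys[0]) - dy * (xs[1:-1] - xs[0])) / norm
    return int(np.argmax(d)) + 2  # 0-based argmax over the interior -> 1-based index


def estimate_tsz(
    cellfile: CellFile, mode: str = "cell_number", normalize: bool = False
) -> TSZEstimate:
    """Estimate the onset of rapid elongation from a cell file.

    ``cell_number`` mode (default) uses (cell number, length) pairs;
    ``cumulative_length`` uses (start position, length). A logged warning —
    not an error — is emitted when the file lacks two substantially
    elongated cells (>= ~4x the typical meristem length, taken as the
    median of the first quartile of cells), since the corner is then poorly
    defined.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    L = np.asarray(cellfile.lengths_um, dtype=float)
    n = len(L)
    if n < 3:
        raise ValueError(f"need >= 3 cells to estimate the landmark, got {n}")
    q = max(1, n // 4)
    meristem_len = float(np.median(L[:q]))
    if int(np.sum(L >= 4.0 * meristem_len)) < 2:
        logger.warning(
            "fewer than two cells reach 4x the meristem length (%.3g um); "
            "the profile may not extend far enough into the elongation zone",
            meristem_len,
        )
    if mode == "cell_number":
        xs = np.arange(1, n + 1, dtype=float)
    else:
        xs = np.asarray(cellfile.starts_um, dtype=float)
    idx = find_break_point(xs, L, normalize=normalize)
    return TSZEstimate(
        cell_index=idx,
        distance_um=float(cellfile.starts_um[idx - 1]),
        mode=mode,
    )


def plot_break_point(
    cellfile: CellFile,
    tsz: TSZEstimate,
    path: Optional[str | Path] = None,
):
    """Plot cell length against cell number with the chord and the break
    point marked; save to ``path`` when given, else return the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    L = np.asarray(cellfile.lengths_um, dtype=float)
    n = len(L)
    xs = np.arange(1, n + 1)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(xs, L, "o-", ms=4, lw=1, label="cell length")
    ax.plot([1, n], [L[0], L[-1]], "--", color="gray", label="chord")
    ax.plot(
        tsz.cell_index, L[tsz.cell_index - 1], "r^", ms=10,
        label=f"break point (cell {tsz.cell_index})",
    )
    ax.set_xlabel("cell number from profile start")
    ax.set_ylabel("cell length (µm)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
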