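"""Williams Index: computer-vs-expert agreement on landmark locations.

Given landmark estimates for the same set of images from an automatic
method ("rater 0", the computer) and n >= 2 human experts, the Williams
Index I' is the ratio of the average computer-to-expert agreement to the
average inter-expert agreement:

    I' = [ (1/n) Σ_j 1/D_{0,j} ] / [ (2 / (n (n-1))) Σ_{j<j'} 1/D_{j,j'} ]

where D_{a,b} is the disagreement between raters a and b — here the mean
absolute difference of their estimates across images. I' >= 1 means the
computer agrees with the experts at least as well as the experts agree
with one another.

The index is undefined when any pairwise disagreement is zero (a
reciprocal blows up), e.g. when the computer column duplicates an expert.
No confidence interval is computed by default; an optional
jackknife-over-images interval is available as an extension.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RaterPanel",
    "DisagreementMatrix",
    "pairwise_disagreement",
    "williams_index",
    "williams_jackknife_ci",
    "panel_study",
    "read_panel_csv",
]


@dataclass(frozen=True)
class RaterPanel:
    """Landmark estimates: rows = images, column 0 = computer, 1..n = experts."""

    estimates: np.ndarray  # shape (n_images, 1 + n_experts)
    metric: str = "distance_um"  # distance_um | cell_count
    rater_names: Optional[tuple] = None

    def __post_init__(self) -> None:
        est = np.asarray(self.estimates, dtype=float)
        if est.ndim != 2 or est.shape[1] < 3:
            raise ValueError(
                "panel needs a 2-D table with the computer plus >= 2 expert columns"
            )
        if not np.all(np.isfinite(est)):
            raise ValueError("panel contains missing or non-finite estimates")
        object.__setattr__(self, "estimates", est)

    @property
    def n_experts(self) -> int:
        return self.estimates.shape[1] - 1

    @property
    def n_images(self) -> int:
        return self.estimates.shape[0]


@dataclass(frozen=True)
class DisagreementMatrix:
    """Disagreements entering I': computer-to-expert and expert pairs."""

    D0: np.ndarray     # D_{0,j}, j = 1..n
    Dpair: np.ndarray  # D_{j,j'} for j < j', row-major upper triangle

    @property
    def n_experts(self) -> int:
        return len(self.D0)


def pairwise_disagreement(panel: RaterPanel) -> DisagreementMatrix:
    """Mean absolute difference between every pair of raters.

    Raises if any pairwise disagreement is exactly zero, since the Williams
    Index takes reciprocals of every D.
    """
    est = panel.estimates
    n = panel.n_experts
    D0 = np.array(
        [np.mean(np.abs(est[:, 0] - est[:, j])) for j in range(1, n + 1)]
    )
    Dpair = np.array(
        [
            np.mean(np.abs(est[:, j] - est[:, jp]))
            for j in range(1, n + 1)
            for jp in range(j + 1, n + 1)
        ]
    )
    if np.any(D0 == 0) or np.any(Dpair == 0):
        raise ValueError(
            "a pair of raters agrees exactly on every image (D = 0); "
            "the Williams Index is undefined"
        )
    return DisagreementMatrix(D0=D0, Dpair=Dpair)


def williams_index(matrix: DisagreementMatrix) -> float:
    """Evaluate I' from a disagreement matrix (all entries must be > 0)."""
    D0 = np.asarray(matrix.D0, dtype=float)
    Dpair = np.asarray(matrix.Dpair, dtype=float)
    if np.any(D0 <= 0) or np.any(Dpair <= 0):
        raise ValueError("all disagreements must be strictly positive")
    n = len(D0)
    if len(Dpair) != n * (n - 1) // 2:
        raise ValueError(
            f"expected {n * (n - 1) // 2} expert-pair entries for {n} experts, "
            f"got {len(Dpair)}"
        )
    # the (2 / (n (n-1))) Σ prefactor is exactly the mean over the n(n-1)/2 pairs
    num = np.mean(1.0 / D0)
    den = np.mean(1.0 / Dpair)
    return float(num / den)


def williams_index_from_panel(panel: RaterPanel) -> float:
    return williams_index(pairwise_disagreement(panel))


def williams_jackknife_ci(
    panel: RaterPanel, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Jackknife-over-images (I', lower, upper) confidence interval.

    An extension beyond the plain index: leave one image out at a time,
    recompute I', and form a normal-theory interval from the jackknife
    variance.
    """
    from scipy import stats

    full = williams_index_from_panel(panel)
    m = panel.n_images
    if m < 3:
        raise ValueError("jackknife CI needs >= 3 images")
    loo = np.array(
        [
            williams_index_from_panel(
                RaterPanel(
                    estimates=np.delete(panel.estimates, i, axis=0),
                    metric=panel.metric,
                )
            )
            for i in range(m)
        ]
    )
    pseudo = m * full - (m - 1) * loo
    se = pseudo.std(ddof=1) / np.sqrt(m)
    z = stats.norm.ppf(1 - alpha / 2)
    return full, full - z * se, full + z * se


def panel_study(
    truth: Sequence[float],
    expert_noise_sd: float,
    n_experts: int,
    computer_values: Sequence[float],
    seed: int,
) -> float:
    """I' for a simulated rater panel.

    Experts report the true landmark plus independent Gaussian noise with
    the given standard deviation; the computer reports
    ``computer_values``. A synthetic surrogate for an expert-annotation
    study when no expert panel is available.
    """
    truth = np.asarray(truth, dtype=float)
    computer = np.asarray(computer_values, dtype=float)
    if truth.shape != computer.shape:
        raise ValueError("truth and computer_values must have equal length")
    rng = np.random.default_rng(seed)
    experts = truth[:, None] + rng.normal(
        0.0, expert_noise_sd, size=(len(truth), n_experts)
    )
    panel = RaterPanel(estimates=np.column_stack([computer, experts]))
    return williams_index_from_panel(panel)


def read_panel_csv(path: str | Path, metric: str = "distance_um") -> RaterPanel:
    """Read a rater panel CSV: first column image id, then a ``computer``
    column, then one column per expert."""
    df = pd.read_csv(path)
    if df.shape[1] < 4:
        raise ValueError(
            "panel CSV needs an image-id column, a 'computer' column and >= 2 experts"
        )
    cols = list(df.columns[1:])
    lowered = [c.lower() for c in cols]
    if "computer" in lowered:
        comp = cols[lowered.index("computer")]
        order = [comp] + [c for c in cols if c != comp]
    else:
        order = cols  # first rater column is taken as the computer
    est = df[order].to_numpy(dtype=float)
    return RaterPanel(estimates=est, metric=metric, rater_names=tuple(order))
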