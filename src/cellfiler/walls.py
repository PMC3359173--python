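"""Cell-wall detection on 1-D intensity profiles and cell segmentation.

Walls of adjacent cells appear as bright ridges crossing the profile line.
A profile sample is a raw wall candidate when it dominates a fixed-size
window centered on it: its intensity must reach the window maximum
(excluding itself), exceed the window minimum times a *stringency* factor,
and clear an absolute intensity floor that guards against false positives
in low-signal regions. Runs of consecutive candidates (flat-topped ridges)
merge into a single wall at their intensity-weighted centroid, giving
sub-sample localization; near-coincident walls within half a window are
collapsed onto the stronger peak.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np

from .profile import IntensityProfile, SampledPath

logger = logging.getLogger("cellfiler")

__all__ = [
    "DetectorParams",
    "Wall",
    "WallSet",
    "CellFile",
    "detect_wall_candidates",
    "detect_walls",
    "add_manual_walls",
    "segment_cells",
]


@dataclass(frozen=True)
class DetectorParams:
    """Tunable parameters of the windowed wall detector.

    window : odd number of samples (>= 3) examined around each candidate.
    stringency : multiplier (>= 1) applied to the in-window minimum; the
        candidate must exceed ``i_min * stringency``. Higher values demand
        more prominent peaks.
    min_intensity : absolute floor, in raw intensity units, expected of a
        cell wall.
    """

    window: int = 9
    stringency: float = 1.5
    min_intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be an odd integer >= 3, got {self.window}")
        if self.stringency < 1:
            raise ValueError(f"stringency must be >= 1, got {self.stringency}")
        if self.min_intensity < 0:
            raise ValueError(f"min_intensity must be >= 0, got {self.min_intensity}")


@dataclass(frozen=True)
class Wall:
    """A wall boundary on the sampled profile."""

    sample_index: float   # fractional sample position on the profile
    s_um: float           # arc distance from the profile start
    x: float = math.nan   # image coordinates, when a path is available
    y: float = math.nan
    source: str = "auto"  # auto | manual
    peak_intensity: float = math.nan


@dataclass(frozen=True)
class WallSet:
    """Ordered wall boundaries along one profile."""

    walls: tuple
    pixel_size_um: float
    step_um: float  # profile sampling step in μm

    def __post_init__(self) -> None:
        s = np.array([w.s_um for w in self.walls], dtype=float)
        if len(s) > 1 and np.any(np.diff(s) <= 0):
            raise ValueError("wall positions must be strictly increasing")
        object.__setattr__(self, "walls", tuple(self.walls))

    def __len__(self) -> int:
        return len(self.walls)

    @property
    def s_um(self) -> np.ndarray:
        return np.array([w.s_um for w in self.walls], dtype=float)


@dataclass(frozen=True)
class CellFile:
    """Ordered per-cell lengths along a profile, with cumulative starts."""

    lengths_um: np.ndarray
    starts_um: np.ndarray

    def __post_init__(self) -> None:
        L = np.asarray(self.lengths_um, dtype=float)
        S = np.asarray(self.starts_um, dtype=float)
        if L.shape != S.shape:
            raise ValueError("lengths_um and starts_um must have equal length")
        if L.size and L.min() <= 0:
            raise ValueError("all cell lengths must be > 0")
        if L.size > 1 and not np.allclose(S[1:], S[:-1] + L[:-1]):
            raise ValueError("starts_um must accumulate the preceding lengths")
        object.__setattr__(self, "lengths_um", L)
        object.__setattr__(self, "starts_um", S)

    @property
    def n_cells(self) -> int:
        return len(self.lengths_um)


def detect_wall_candidates(
    intensity: np.ndarray, params: DetectorParams
) -> np.ndarray:
    """Boolean mask of raw (pre-merge) wall candidates.

    Sample t is a candidate iff, within the window of ``params.window``
    samples centered on t (truncated at the profile ends, t itself
    excluded), its intensity v satisfies v >= i_max, v >= i_min *
    stringency and v >= min_intensity.
    """
    v = np.asarray(intensity, dtype=float)
    n = len(v)
    if n <= params.window:
        raise ValueError(
            f"profile of {n} samples is not longer than the {params.window}-sample window"
        )
    h = params.window // 2
    pad_max = np.concatenate([np.full(h, -np.inf), v, np.full(h, -np.inf)])
    pad_min = np.concatenate([np.full(h, np.inf), v, np.full(h, np.inf)])
    win_max = np.lib.stride_tricks.sliding_window_view(pad_max, params.window).copy()
    win_min = np.lib.stride_tricks.sliding_window_view(pad_min, params.window).copy()
    win_max[:, h] = -np.inf  # exclude the center sample
    win_min[:, h] = np.inf
    i_max = win_max.max(axis=1)
    i_min = win_min.min(axis=1)
    return (v >= i_max) & (v >= i_min * params.stringency) & (v >= params.min_intensity)


def _merge_candidate_runs(v: np.ndarray, mask: np.ndarray) -> list[tuple[float, float]]:
    """(fractional index, peak intensity) per maximal run of candidates."""
    walls: list[tuple[float, float]] = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return walls
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    for run in np.split(idx, splits):
        weights = v[run]
        total = weights.sum()
        center = float(run.mean()) if total == 0 else float((run * weights).sum() / total)
        walls.append((center, float(weights.max())))
    return walls


def _merge_close(
    walls: list[tuple[float, float]], min_sep: float
) -> list[tuple[float, float]]:
    """Collapse walls closer than ``min_sep`` samples, keeping the stronger.

    Gaps within 1e-6 samples of the threshold count as separated, so that
    float drift in the centroid cannot flip an exact-threshold gap.
    """
    merged: list[tuple[float, float]] = []
    for w in walls:
        if merged and w[0] - merged[-1][0] < min_sep - 1e-6:
            if w[1] > merged[-1][1]:
                merged[-1] = w
        else:
            merged.append(w)
    return merged


def detect_walls(
    profile: IntensityProfile,
    params: DetectorParams = DetectorParams(),
    path: Optional[SampledPath] = None,
) -> WallSet:
    """Detect cell walls on an intensity profile.

    Raw candidates from :func:`detect_wall_candidates` are merged per
    maximal run (intensity-weighted centroid); walls closer than
    ``ceil(window / 2)`` samples are collapsed onto the higher peak.
    Supplying the sampled ``path`` fills in image coordinates per wall.
    """
    v = np.asarray(profile.intensity, dtype=float)
    mask = detect_wall_candidates(v, params)
    raw = _merge_candidate_runs(v, mask)
    min_sep = math.ceil(params.window / 2)
    kept = _merge_close(raw, min_sep)
    step_um = profile.step_um
    walls = []
    for center, peak in kept:
        x, y = path.point_at(center) if path is not None else (math.nan, math.nan)
        walls.append(
            Wall(
                sample_index=center,
                s_um=center * step_um,
                x=x,
                y=y,
                source="auto",
                peak_intensity=peak,
            )
        )
    return WallSet(walls=tuple(walls), pixel_size_um=profile.pixel_size_um, step_um=step_um)


def add_manual_walls(
    wallset: WallSet,
    positions_um: Sequence[float],
    path: Optional[SampledPath] = None,
) -> WallSet:
    """Insert user-specified wall positions (μm) into a wall set.

    Stands in for the interactive wall-painting step of a GUI workflow:
    walls the detector missed in low-contrast regions are declared
    explicitly and merged, tagged ``source="manual"``. Positions within one
    sampling step of an existing wall are rejected with a warning.
    """
    step_um = wallset.step_um
    if path is not None:
        extent_um = float(path.arc_length_px[-1]) * wallset.pixel_size_um
    else:
        extent_um = math.inf
    walls = list(wallset.walls)
    existing = [w.s_um for w in walls]
    for pos in positions_um:
        pos = float(pos)
        if pos < 0 or pos > extent_um:
            raise ValueError(
                f"manual wall at {pos} um lies outside the profile [0, {extent_um:.3f}] um"
            )
        if any(abs(pos - s) < step_um for s in existing):
            logger.warning(
                "manual wall at %.3f um duplicates an existing wall; skipped", pos
            )
            continue
        frac = pos / step_um
        x, y = path.point_at(frac) if path is not None else (math.nan, math.nan)
        walls.append(Wall(sample_index=frac, s_um=pos, x=x, y=y, source="manual"))
        existing.append(pos)
    walls.sort(key=lambda w: w.s_um)
    return WallSet(walls=tuple(walls), pixel_size_um=wallset.pixel_size_um, step_um=step_um)


def segment_cells(
    wallset: WallSet,
    profile: Optional[IntensityProfile] = None,
    include_start_as_wall: bool = True,
) -> CellFile:
    """Segment the profile into cells between consecutive wall boundaries.

    With ``include_start_as_wall`` (the default) the profile start — placed
    by the user on the originating boundary of the file, e.g. the cortex and
    endodermis initial — counts as boundary 0 unless a detected wall already
    sits within half a sampling step of it.
    """
    bounds = list(wallset.s_um)
    if include_start_as_wall and (not bounds or bounds[0] > 0.5 * wallset.step_um):
        bounds.insert(0, 0.0)
    if len(bounds) < 2:
        raise ValueError(
            f"{len(bounds)} boundary(ies) found; at least 2 are needed to form a cell"
        )
    b = np.asarray(bounds, dtype=float)
    lengths = np.diff(b)
    return CellFile(lengths_um=lengths, starts_um=b[:-1])
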