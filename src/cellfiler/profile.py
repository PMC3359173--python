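"""Arc-length-uniform spline sampling of image intensity.

A smooth interpolating spline is fitted through the user's polyline anchors
and resampled at uniform arc-length steps; image intensity is then read off
the resampled path by bilinear interpolation, yielding a 1-D intensity
profile indexed by physical distance from the profile start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import map_coordinates

from .io import CalibratedImage, Polyline

__all__ = ["SampledPath", "IntensityProfile", "fit_spline", "sample_intensity"]

# dense subdivisions per unit chord length used for arc-length inversion
_DENSE_PER_PX = 16


@dataclass(frozen=True)
class SampledPath:
    """Spline path resampled at uniform arc-length spacing (pixels)."""

    points: np.ndarray        # (n, 2) sample coordinates (x, y)
    step_px: float            # nominal spacing between consecutive samples
    arc_length_px: np.ndarray  # cumulative arc length per sample, starts at 0
    total_length_px: float = float("nan")  # full arc length of the fitted curve

    def point_at(self, frac_index: float) -> tuple[float, float]:
        """Linearly interpolated (x, y) at a fractional sample index."""
        i = float(frac_index)
        lo = int(np.clip(np.floor(i), 0, len(self.points) - 2))
        t = i - lo
        p = (1.0 - t) * self.points[lo] + t * self.points[lo + 1]
        return float(p[0]), float(p[1])


@dataclass(frozen=True)
class IntensityProfile:
    """Intensities sampled along a path, positioned in μm from its start."""

    s_um: np.ndarray
    intensity: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        s = np.asarray(self.s_um, dtype=float)
        v = np.asarray(self.intensity, dtype=float)
        if s.shape != v.shape or s.ndim != 1:
            raise ValueError("s_um and intensity must be equal-length 1-D arrays")
        if s[0] != 0 or np.any(np.diff(s) <= 0):
            raise ValueError("s_um must increase strictly from 0")
        object.__setattr__(self, "s_um", s)
        object.__setattr__(self, "intensity", v)

    def __len__(self) -> int:
        return len(self.s_um)

    @property
    def step_um(self) -> float:
        return float(self.s_um[1] - self.s_um[0])


def _spline_curve(anchors: np.ndarray):
    """(evaluate, t_knots) for the chord-length-parameterized interpolating
    curve: a natural cubic spline, or the straight segment for 2 anchors."""
    chords = np.linalg.norm(np.diff(anchors, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(chords)])
    if len(anchors) == 2:
        def evaluate(tt):
            frac = np.asarray(tt) / t[-1]
            return anchors[0] + frac[:, None] * (anchors[1] - anchors[0])
        return evaluate, t
    spl = CubicSpline(t, anchors, bc_type="natural", axis=0)
    return spl, t


def fit_spline(polyline: Polyline, step_px: float = 1.0) -> SampledPath:
    """Fit a smooth spline through the anchors and resample it at uniform
    arc-length steps.

    The spline interpolates every anchor (chord-length parameterization,
    natural end conditions). Resampling inverts the numeric arc length so
    that consecutive samples are ``step_px`` apart along the curve; the
    first sample sits on the first anchor and the last within ``step_px``
    of the last anchor.
    """
    if step_px <= 0:
        raise ValueError(f"step_px must be > 0, got {step_px}")
    anchors = np.asarray(polyline.anchors, dtype=float)
    evaluate, t = _spline_curve(anchors)
    # numeric arc length on a dense parameter grid (anchor knots included)
    n_dense = max(int(np.ceil(t[-1] * _DENSE_PER_PX)), 2 * len(anchors)) + 1
    tt = np.union1d(np.linspace(0.0, t[-1], n_dense), t)
    dense = evaluate(tt)
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    s_dense = np.concatenate([[0.0], np.cumsum(seg)])
    total = s_dense[-1]
    n_steps = int(np.floor(total / step_px + 1e-9))
    s_targets = np.arange(n_steps + 1) * step_px
    # invert arc length to curve parameter, then evaluate the curve itself
    # so every sample lies on the spline, not on a polyline approximation
    t_targets = np.interp(s_targets, s_dense, tt)
    pts = evaluate(t_targets)
    return SampledPath(
        points=np.asarray(pts, dtype=float),
        step_px=float(step_px),
        arc_length_px=s_targets,
        total_length_px=float(total),
    )


def sample_intensity(image: CalibratedImage, path: SampledPath) -> IntensityProfile:
    """Bilinear intensity sampling of the image at each path point."""
    pts = np.asarray(path.points, dtype=float)
    h, w = image.shape
    # pixel centers span [0, w-1] x [0, h-1]; outside that bilinear support
    # the sample would extrapolate
    bad = (
        (pts[:, 0] < 0) | (pts[:, 0] > w - 1) | (pts[:, 1] < 0) | (pts[:, 1] > h - 1)
    )
    if np.any(bad):
        i = int(np.argmax(bad))
        raise ValueError(
            f"path sample {i} at (x={pts[i, 0]:.3f}, y={pts[i, 1]:.3f}) lies "
            f"outside the {w}x{h} image"
        )
    vals = map_coordinates(
        image.pixels, [pts[:, 1], pts[:, 0]], order=1, mode="nearest"
    )
    return IntensityProfile(
        s_um=np.asarray(path.arc_length_px) * image.pixel_size_um,
        intensity=vals,
        pixel_size_um=image.pixel_size_um,
    )
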