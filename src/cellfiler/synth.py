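"""Synthetic cell-file images and length series with known ground truth.

Emulates what the wall detector sees in a confocal image of a root cell
file: a dark, noisy background crossed by bright ridges (the stained cell
walls) at known positions along a straight or gently curved file axis.
Cell lengths are roughly constant in the meristem, then grow geometrically
through a transition until they reach ``elongation_factor`` times the
meristem length (~15x in Arabidopsis roots), giving every stage of the
pipeline — profile sampling, wall detection, segmentation, break-point
estimation — a known answer to recover. The ground-truth landmark index
attached to each length series is the last cell before rapid elongation
(cell ``n_meristem``): the geometric break-point rule targets the
change-point just before the rise, so that is the cell a correct detector
should name.

Length heterogeneity is multiplicative lognormal (lengths are positive and
the scatter scales with the mean); ridges are 1-D Gaussians in arc-length
distance to the nearest wall plane, constant across the file's width.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import tifffile

from .io import CalibratedImage, Polyline, write_polyline

__all__ = [
    "SyntheticSpec",
    "generate_length_series",
    "render_cell_file_image",
    "make_fixture_suite",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic cell file.

    n_meristem : cells before the elongation onset.
    L_m : mean meristem cell length (μm).
    elongation_factor : final/initial length ratio reached after the ramp.
    ramp_cells : cells over which elongation completes (geometric ramp).
    n_elongated : fully elongated cells appended after the ramp.
    noise_cv : coefficient of variation of multiplicative length noise.
    wall_sigma_px : Gaussian ridge half-width (pixels).
    wall_amp : ridge peak intensity (raw units).
    bg_noise_sd : additive background noise sd (raw units).
    pixel_size_um : calibration (μm per pixel).
    seed : RNG seed; fixed seed means identical output.
    """

    n_meristem: int = 30
    L_m: float = 8.0
    elongation_factor: float = 15.0
    ramp_cells: int = 6
    n_elongated: int = 3
    noise_cv: float = 0.1
    wall_sigma_px: float = 1.5
    wall_amp: float = 1000.0
    bg_noise_sd: float = 10.0
    pixel_size_um: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_meristem, self.ramp_cells, self.n_elongated) < 1:
            raise ValueError("cell counts must be positive")
        if min(self.L_m, self.wall_sigma_px, self.wall_amp, self.pixel_size_um) <= 0:
            raise ValueError("lengths, ridge width/amplitude and calibration must be > 0")
        if self.elongation_factor <= 1:
            raise ValueError("elongation_factor must exceed 1")
        if self.noise_cv < 0 or self.bg_noise_sd < 0:
            raise ValueError("noise levels must be >= 0")


def generate_length_series(spec: SyntheticSpec) -> tuple[np.ndarray, int]:
    """Cell lengths (μm) along the file and the true transition index.

    Meristem cells have mean length ``L_m``; ramp cell r (r = 1..ramp_cells)
    has mean ``L_m * elongation_factor**(r / ramp_cells)``; the remaining
    cells stay at ``L_m * elongation_factor``. Multiplicative lognormal
    noise with the requested CV is applied to every cell. The true
    landmark index is ``n_meristem`` (1-based: the last cell before
    elongation begins, i.e. the break-point cell).
    """
    means = np.concatenate(
        [
            np.full(spec.n_meristem, spec.L_m),
            spec.L_m
            * spec.elongation_factor
            ** (np.arange(1, spec.ramp_cells + 1) / spec.ramp_cells),
            np.full(spec.n_elongated, spec.L_m * spec.elongation_factor),
        ]
    )
    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        sigma2 = np.log1p(spec.noise_cv**2)
        # lognormal factor with mean exactly 1 and CV = noise_cv
        factors = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=len(means))
        lengths = means * factors
    else:
        lengths = means.copy()
    return lengths, spec.n_meristem


_MARGIN_PX = 10
_HALFWIDTH_PX = 12  # half-width of the rendered file band
_ANCHOR_EVERY_PX = 25.0


def render_cell_file_image(
    lengths_um: np.ndarray,
    spec: SyntheticSpec,
    orientation: str = "straight",
) -> tuple[CalibratedImage, np.ndarray, Polyline]:
    """Render a cell file as a calibrated image with ground truth.

    Returns the image, the arc-length wall positions (μm, wall 0 at 0) and
    a polyline along the file axis whose start coincides with wall 0 (the
    polyline overshoots the last wall by a few ridge widths so the final
    wall is interior to the sampled profile).
    """
    if orientation not in ("straight", "arc"):
        raise ValueError(f"orientation must be 'straight' or 'arc', got {orientation!r}")
    lengths_um = np.asarray(lengths_um, dtype=float)
    wall_s_um = np.concatenate([[0.0], np.cumsum(lengths_um)])
    wall_s_px = wall_s_um / spec.pixel_size_um
    total_px = wall_s_px[-1]
    tail_px = max(6.0 * spec.wall_sigma_px, 5.0)
    rng = np.random.default_rng(spec.seed + 1)

    if orientation == "straight":
        w = int(np.ceil(total_px + tail_px)) + 2 * _MARGIN_PX
        h = 2 * (_HALFWIDTH_PX + _MARGIN_PX)
        if w < 3 or h < 3:
            raise ValueError("image too small for the requested cell file")
        x0, cy = float(_MARGIN_PX), h / 2.0 - 0.5
        xs = np.arange(w, dtype=float)
        s_px = xs - x0
        d_wall = np.min(np.abs(s_px[:, None] - wall_s_px[None, :]), axis=1)
        ridge = spec.wall_amp * np.exp(-(d_wall**2) / (2.0 * spec.wall_sigma_px**2))
        in_file = (s_px >= -tail_px) & (s_px <= total_px + tail_px)
        ys = np.arange(h, dtype=float)
        band = np.abs(ys - cy) <= _HALFWIDTH_PX
        img = band[:, None] * (ridge * in_file)[None, :]
        # polyline along the axis, anchored at wall 0
        s_end = min(total_px + tail_px - 1.0, w - 1 - x0)
        anchors = np.column_stack(
            [x0 + np.array([0.0, s_end]), np.array([cy, cy])]
        )
    else:
        arc_px = total_px + tail_px
        theta_span = 1.0  # radians; a gentle bend
        R = arc_px / theta_span
        cx, cy = float(_MARGIN_PX), R + _MARGIN_PX + _HALFWIDTH_PX
        # axis point at arc length s: (cx + R sin(s/R), cy - R cos(s/R))
        w = int(np.ceil(cx + (R + _HALFWIDTH_PX) * np.sin(theta_span))) + _MARGIN_PX
        h = int(np.ceil(cy - (R - _HALFWIDTH_PX) * np.cos(theta_span))) + _MARGIN_PX
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        r = np.hypot(xx - cx, yy - cy)
        theta = np.arctan2(xx - cx, cy - yy)  # 0 at the top, increasing with s
        s_px = r * theta  # arc-length distance to the radial wall planes
        band = np.abs(r - R) <= _HALFWIDTH_PX
        sel = band & (s_px >= -tail_px) & (s_px <= total_px + tail_px) & (theta >= -0.05)
        img = np.zeros((h, w), dtype=float)
        s_sel = s_px[sel]
        d_wall = np.min(np.abs(s_sel[:, None] - wall_s_px[None, :]), axis=1)
        img[sel] = spec.wall_amp * np.exp(-(d_wall**2) / (2.0 * spec.wall_sigma_px**2))
        s_end = total_px + tail_px - 1.0
        s_anchor = np.append(
            np.arange(0.0, s_end, _ANCHOR_EVERY_PX), s_end
        )
        anchors = np.column_stack(
            [cx + R * np.sin(s_anchor / R), cy - R * np.cos(s_anchor / R)]
        )

    if spec.bg_noise_sd > 0:
        img = img + rng.normal(0.0, spec.bg_noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 65535)
    image = CalibratedImage(
        pixels=img, pixel_size_um=spec.pixel_size_um, bit_depth=16, source_path=""
    )
    return image, wall_s_um, Polyline(anchors=anchors)


def _write_tiff(image: CalibratedImage, path: Path) -> None:
    px_per_um = 1.0 / image.pixel_size_um
    tifffile.imwrite(
        path,
        image.pixels.astype(np.uint16),
        resolution=(px_per_um, px_per_um),
        resolutionunit=1,
    )


_FIXTURE_CASES = (
    # name, orientation, overrides
    ("clean_straight", "straight", dict(noise_cv=0.0, bg_noise_sd=0.0)),
    ("clean_curved", "arc", dict(noise_cv=0.0, bg_noise_sd=0.0)),
    ("noisy_straight", "straight", dict(noise_cv=0.1, bg_noise_sd=10.0)),
    ("noisy_curved", "arc", dict(noise_cv=0.1, bg_noise_sd=10.0)),
    ("coarse_pixel", "straight", dict(noise_cv=0.0, bg_noise_sd=0.0, pixel_size_um=1.0)),
    ("short_meristem", "straight", dict(noise_cv=0.0, bg_noise_sd=0.0, n_meristem=12)),
)


def make_fixture_suite(out_dir: str | Path, seed: int = 0, **overrides) -> dict:
    """Write a standard set of ground-truthed test images.

    Each case has a TIFF image, a JSON polyline and a JSON ground-truth
    file (lengths, wall positions, true transition index, parameters); a
    ``truncated_clean_straight`` variant drops the last two cells of its
    parent series to emulate a profile line stopped short of the
    elongation zone. Returns (and writes) the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": int(seed), "cases": {}}

    def emit(name: str, lengths, true_idx: int, spec: SyntheticSpec, orientation: str):
        image, wall_s_um, poly = render_cell_file_image(lengths, spec, orientation)
        img_path = out_dir / f"{name}.tif"
        poly_path = out_dir / f"{name}.polyline.json"
        gt_path = out_dir / f"{name}.truth.json"
        _write_tiff(image, img_path)
        write_polyline(poly, poly_path)
        truth = {
            "lengths_um": [float(v) for v in lengths],
            "wall_s_um": [float(v) for v in wall_s_um],
            "true_tsz_index": int(true_idx),
            "orientation": orientation,
            "spec": asdict(spec),
        }
        with open(gt_path, "w", encoding="utf-8") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
        manifest["cases"][name] = {
            "image": img_path.name,
            "polyline": poly_path.name,
            "truth": gt_path.name,
            "orientation": orientation,
        }

    for i, (name, orientation, case_overrides) in enumerate(_FIXTURE_CASES):
        spec = SyntheticSpec(seed=seed + i, **{**case_overrides, **overrides})
        lengths, true_idx = generate_length_series(spec)
        emit(name, lengths, true_idx, spec, orientation)

    # truncated variant: the clean_straight series minus its last two cells
    parent_spec = SyntheticSpec(seed=seed + 0, **{**_FIXTURE_CASES[0][2], **overrides})
    lengths, true_idx = generate_length_series(parent_spec)
    emit("truncated_clean_straight", lengths[:-2], true_idx, parent_spec, "straight")

    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
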