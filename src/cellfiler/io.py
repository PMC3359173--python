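"""Calibrated image and region-of-interest I/O.

Reads single-channel TIFF/PNG images with a micrometre-per-pixel
calibration, polyline regions of interest (JSON dialect or ImageJ ``.roi``
segmented/polyline files), and writes measurement CSVs, landmark JSON
sidecars and annotated RGB overlays.

Coordinate convention: continuous, 0-based pixel-center coordinates
(x rightward, y downward, origin at the center of the top-left pixel).
ImageJ ``.roi`` integer vertices are taken to lie on pixel centers and are
imported unchanged under this convention.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio

logger = logging.getLogger("cellfiler")

__all__ = [
    "CalibratedImage",
    "Polyline",
    "read_image",
    "read_polyline",
    "write_polyline",
    "write_measurements",
    "read_measurements",
    "write_overlay",
]


@dataclass(frozen=True)
class CalibratedImage:
    """A 2-D grayscale image with a physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        2-D array of non-negative intensities in raw units.
    pixel_size_um : float
        Micrometres per pixel; square pixels are assumed.
    bit_depth : int
        8 or 16; bounds the admissible intensity range.
    source_path : str
        Provenance of the pixel data (may be empty for in-memory images).
    """

    pixels: np.ndarray
    pixel_size_um: float
    bit_depth: int = 16
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D grayscale image, got shape {px.shape}")
        if not np.isfinite(self.pixel_size_um) or self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if px.size and (px.min() < 0 or px.max() > 2 ** self.bit_depth - 1):
            raise ValueError(
                f"intensities outside [0, {2 ** self.bit_depth - 1}] for "
                f"bit_depth={self.bit_depth}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class Polyline:
    """An ordered open polyline in pixel coordinates (>= 2 anchors)."""

    anchors: np.ndarray  # shape (n, 2), columns (x, y)

    def __post_init__(self) -> None:
        a = np.asarray(self.anchors, dtype=float)
        if a.ndim != 2 or a.shape[1] != 2 or a.shape[0] < 2:
            raise ValueError("a polyline needs >= 2 (x, y) anchors")
        if np.any(np.all(np.diff(a, axis=0) == 0.0, axis=1)):
            raise ValueError("consecutive polyline anchors must not coincide")
        object.__setattr__(self, "anchors", a)

    def __len__(self) -> int:
        return len(self.anchors)


def _tiff_pixel_size(path: Path) -> Optional[float]:
    """Pixel size in μm from TIFF resolution tags, if resolvable."""
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        tags = page.tags
        if "XResolution" not in tags:
            return None
        num, den = tags["XResolution"].value
        if num == 0 or den == 0:
            return None
        px_per_unit = num / den  # pixels per resolution unit
        unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else 1
        unit = int(unit)
        # RESUNIT: 1 none (assume μm, the convention tifffile/ImageJ use for
        # micron-calibrated scientific TIFFs), 2 inch, 3 cm.
        if unit == 2:
            um_per_unit = 25400.0
        elif unit == 3:
            um_per_unit = 10000.0
        else:
            um_per_unit = 1.0
        if "YResolution" in tags:
            ynum, yden = tags["YResolution"].value
            if yden != 0 and ynum != 0 and not np.isclose(ynum / yden, px_per_unit, rtol=1e-6):
                raise ValueError(
                    f"anisotropic pixel calibration in {path} "
                    f"(XResolution != YResolution); square pixels are required"
                )
        return um_per_unit / px_per_unit


def read_image(
    path: str | Path,
    pixel_size_um: Optional[float] = None,
    channel: Optional[int] = None,
) -> CalibratedImage:
    """Read a TIFF or PNG image as a calibrated grayscale plane.

    Calibration precedence: explicit ``pixel_size_um`` argument, then TIFF
    resolution metadata, then a default of 1.0 μm/px with a logged warning.
    Multi-channel images require an explicit ``channel``.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"image not found: {path}")
    suffix = path.suffix.lower()
    meta_px: Optional[float] = None
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        meta_px = _tiff_pixel_size(path)
    elif suffix == ".png":
        arr = np.asarray(iio.imread(path))
    else:
        raise ValueError(f"unsupported image format: {path.suffix!r} (TIFF or PNG)")

    arr = np.asarray(arr)
    if arr.ndim == 3:
        # channel axis: smallest axis of a 3-D stack
        ch_axis = int(np.argmin(arr.shape))
        n_ch = arr.shape[ch_axis]
        if channel is None:
            raise ValueError(
                f"{path} has {n_ch} channels; an explicit channel index is required"
            )
        if not 0 <= channel < n_ch:
            raise IndexError(f"channel {channel} out of range for {n_ch} channels")
        arr = np.take(arr, channel, axis=ch_axis)
    elif arr.ndim != 2:
        raise ValueError(f"cannot interpret image of shape {arr.shape}")

    if pixel_size_um is not None:
        if pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")
        px_um = float(pixel_size_um)
    elif meta_px is not None:
        px_um = float(meta_px)
        logger.info("calibration %.6g um/px taken from TIFF metadata of %s", px_um, path)
    else:
        px_um = 1.0
        logger.warning(
            "no calibration for %s; defaulting to 1.0 um/px", path
        )

    bit_depth = 8 if arr.dtype == np.uint8 else 16
    return CalibratedImage(
        pixels=arr.astype(float),
        pixel_size_um=px_um,
        bit_depth=bit_depth,
        source_path=str(path),
    )


# --- ImageJ .roi polyline support -------------------------------------------
# Byte layout per ImageJ's RoiDecoder: big-endian, magic "Iout", roi type at
# offset 6 (polyline = 6, freeline = 7; a "segmented line" saves as type 6),
# top/left/bottom/right int16 at 8..14, n coordinates at 16, optional
# SUB_PIXEL_RESOLUTION flag (bit 7 of options at offset 50) with float
# coordinates at offset 64; otherwise int16 x then y relative to (left, top).

_ROI_POLYLINE_TYPES = {6, 7}  # polyline, freehand line
_ROI_SUBPIXEL = 1 << 7


def _read_imagej_roi(data: bytes) -> np.ndarray:
    if len(data) < 64 or data[:4] != b"Iout":
        raise ValueError("not an ImageJ .roi file (missing 'Iout' magic)")
    roi_type = data[6]
    if roi_type not in _ROI_POLYLINE_TYPES:
        raise ValueError(
            f"unsupported ROI type {roi_type}; only polyline/segmented-line "
            "ROIs can define a profile"
        )
    top, left = struct.unpack(">hh", data[8:12])
    (n,) = struct.unpack(">h", data[16:18])
    if n < 2:
        raise ValueError(f"polyline ROI has {n} anchors; >= 2 required")
    (options,) = struct.unpack(">h", data[50:52])
    if options & _ROI_SUBPIXEL:
        off = 64 + 4 * n  # float block follows the int16 block
        xs = np.frombuffer(data, dtype=">f4", count=n, offset=off)
        ys = np.frombuffer(data, dtype=">f4", count=n, offset=off + 4 * n)
        return np.column_stack([xs.astype(float), ys.astype(float)])
    xs = np.frombuffer(data, dtype=">i2", count=n, offset=64).astype(float) + left
    ys = np.frombuffer(data, dtype=">i2", count=n, offset=64 + 2 * n).astype(float) + top
    return np.column_stack([xs, ys])


def read_polyline(path: str | Path) -> Polyline:
    """Read a polyline from a JSON anchor list or an ImageJ ``.roi`` file.

    The JSON dialect is ``{"anchors": [[x, y], ...]}`` in 0-based pixel
    coordinates; ``.roi`` files must hold a polyline/segmented-line ROI.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"polyline file not found: {path}")
    if path.suffix.lower() == ".roi":
        return Polyline(anchors=_read_imagej_roi(path.read_bytes()))
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    anchors = doc["anchors"] if isinstance(doc, dict) else doc
    return Polyline(anchors=np.asarray(anchors, dtype=float))


def write_polyline(polyline: Polyline, path: str | Path) -> None:
    """Write a polyline as the JSON anchor-list dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"anchors": polyline.anchors.tolist()}, fh, indent=1)
        fh.write("\n")


def write_measurements(cellfile, tsz=None, path: str | Path = "measurements.csv") -> None:
    """Write per-cell measurements as CSV, with a JSON landmark sidecar.

    The CSV has columns ``cell_index`` (1-based), ``start_um``, ``end_um``,
    ``length_um``. When a break-point estimate is given, a ``<path>.tsz.json``
    sidecar records the landmark both as a cell count and as a distance from
    the profile start.
    """
    path = Path(path)
    n = cellfile.n_cells
    starts = np.asarray(cellfile.starts_um, dtype=float)
    lengths = np.asarray(cellfile.lengths_um, dtype=float)
    df = pd.DataFrame(
        {
            "cell_index": np.arange(1, n + 1, dtype=int),
            "start_um": starts,
            "end_um": starts + lengths,
            "length_um": lengths,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")
    if tsz is not None:
        sidecar = path.with_suffix(path.suffix + ".tsz.json")
        with open(sidecar, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "tsz_cell_index": int(tsz.cell_index),
                    "tsz_distance_um": float(tsz.distance_um),
                    "mode": tsz.mode,
                },
                fh,
                indent=1,
            )
            fh.write("\n")


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a measurement CSV written by :func:`write_measurements`."""
    return pd.read_csv(path)


def _draw_disc(rgb: np.ndarray, x: float, y: float, radius: int, color) -> None:
    h, w = rgb.shape[:2]
    xi, yi = int(round(x)), int(round(y))
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            if dx * dx + dy * dy <= radius * radius:
                yy, xx = yi + dy, xi + dx
                if 0 <= yy < h and 0 <= xx < w:
                    rgb[yy, xx] = color


_PROFILE_COLOR = (60, 120, 255)
_WALL_COLOR = (255, 40, 40)
_TSZ_COLOR = (255, 255, 255)


def write_overlay(
    image: CalibratedImage,
    path_samples,
    walls,
    tsz=None,
    path: str | Path = "overlay.png",
) -> None:
    """Write an RGB PNG of the image with the profile line, wall markers and
    (if given) a distinct marker at the break-point wall."""
    px = image.pixels
    lo, hi = float(px.min()), float(px.max())
    scale = 255.0 / (hi - lo) if hi > lo else 0.0
    gray = ((px - lo) * scale).astype(np.uint8)
    rgb = np.stack([gray] * 3, axis=-1)

    pts = np.asarray(path_samples.points, dtype=float)
    for x, y in pts:
        _draw_disc(rgb, x, y, 0, _PROFILE_COLOR)
    for wall in walls.walls:
        _draw_disc(rgb, wall.x, wall.y, 2, _WALL_COLOR)
    if tsz is not None:
        s = np.asarray(path_samples.arc_length_px, dtype=float) * image.pixel_size_um
        i = int(np.argmin(np.abs(s - tsz.distance_um)))
        _draw_disc(rgb, pts[i, 0], pts[i, 1], 4, _TSZ_COLOR)
    iio.imwrite(Path(path), rgb)
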