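"""Image and region-of-interest handling for ultrasound still frames.

Lesions on endoscopic-ultrasound stills are delineated as free-hand polygons.
All texture analysis runs on the largest axis-aligned rectangular sub-image
that fits inside the polygon, so that every case contributes a gap-free raster
of comparable geometry.

Conventions
-----------
* Images are 2-D ``uint8`` arrays indexed ``[row, col]``, intensities 0-255.
* Coordinates are 0-based ``(row, col)``; rectangles are half-open
  ``[r0, r1) x [c0, c1)``.
* A pixel belongs to the ROI when its center ``(row, col)`` lies inside or on
  the polygon boundary (even-odd rule; boundary pixels count).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from PIL import Image
from shapely.geometry import Polygon as _ShapelyPolygon

#: Smallest sub-image edge accepted for analysis (a 3-level dyadic wavelet
#: decomposition needs at least 8 pixels per axis).
MIN_SUBIMAGE = 8


class RoiError(ValueError):
    """Raised for invalid ROI polygons or ROIs too small to analyse."""


def as_gray_image(pixels: np.ndarray) -> np.ndarray:
    """Validate and return a 2-D uint8 grayscale raster."""
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError(f"grayscale image must be 2-D, got shape {arr.shape}")
    if arr.size and (arr.min() < 0 or arr.max() > 255):
        raise ValueError("intensities must lie in [0, 255]")
    return arr.astype(np.uint8)


@dataclass(frozen=True)
class RoiPolygon:
    """Closed lesion boundary given as ordered ``(row, col)`` vertices."""

    vertices: np.ndarray  # (n, 2) float array

    def __post_init__(self) -> None:
        verts = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise RoiError("an ROI polygon needs at least 3 (row, col) vertices")
        poly = _ShapelyPolygon(verts)
        if not poly.is_valid:
            raise RoiError("ROI polygon is self-intersecting or degenerate")
        object.__setattr__(self, "vertices", verts)

    def as_shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)


@dataclass(frozen=True)
class SubImage:
    """Axis-aligned rectangular crop of a parent image.

    ``origin`` is the (row, col) of the crop's top-left pixel in the parent.
    """

    pixels: np.ndarray
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", as_gray_image(self.pixels))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class QuantizedImage:
    """Grey-level-reduced raster: bin indices in ``[0, levels)``."""

    pixels: np.ndarray
    levels: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.int64)
        if self.levels < 2:
            raise ValueError("need at least 2 grey levels")
        if arr.size and (arr.min() < 0 or arr.max() >= self.levels):
            raise ValueError("bin indices out of range")
        object.__setattr__(self, "pixels", arr)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale still image (BMP or PNG).

    RGB files are accepted only when the three channels are identical (a
    grayscale image saved in a color container); a genuine color overlay is
    rejected rather than silently flattened.
    """
    with Image.open(path) as im:
        if im.mode == "L":
            return as_gray_image(np.asarray(im))
        if im.mode in ("RGB", "RGBA"):
            arr = np.asarray(im.convert("RGB"))
            if not (np.array_equal(arr[..., 0], arr[..., 1])
                    and np.array_equal(arr[..., 0], arr[..., 2])):
                raise ValueError(
                    f"{path}: RGB channels differ; not a grayscale image")
            return as_gray_image(arr[..., 0])
        if im.mode in ("I", "I;16", "P", "1"):
            conv = im.convert("L")
            return as_gray_image(np.asarray(conv))
        raise ValueError(f"{path}: unsupported image mode {im.mode!r}")


def save_image(pixels: np.ndarray, path: str | Path) -> None:
    """Write a grayscale raster as 8-bit BMP/PNG (format from the suffix)."""
    Image.fromarray(as_gray_image(pixels), mode="L").save(path)


def read_roi(path: str | Path, image: np.ndarray) -> RoiPolygon:
    """Parse an ROI vertex file and validate it against the image bounds.

    The file holds one ``row,col`` vertex per line; blank lines and ``#``
    comments are ignored. Vertices outside the image raise rather than being
    clipped.
    """
    image = as_gray_image(image)
    verts: list[tuple[float, float]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(";", ",").split(",")
        if len(parts) != 2:
            raise RoiError(f"{path}:{lineno}: expected 'row,col', got {raw!r}")
        verts.append((float(parts[0]), float(parts[1])))
    poly = RoiPolygon(np.array(verts))
    h, w = image.shape
    rows, cols = poly.vertices[:, 0], poly.vertices[:, 1]
    if rows.min() < 0 or cols.min() < 0 or rows.max() > h - 1 or cols.max() > w - 1:
        raise RoiError(f"{path}: vertex outside the {h}x{w} image")
    return poly


def full_frame_roi(image: np.ndarray) -> RoiPolygon:
    """Rectangular ROI covering the whole frame (synthetic cohorts)."""
    h, w = as_gray_image(image).shape
    return RoiPolygon(np.array([(0, 0), (0, w - 1), (h - 1, w - 1), (h - 1, 0)],
                               dtype=float))


# ---------------------------------------------------------------------------
# Rasterization and largest-rectangle extraction
# ---------------------------------------------------------------------------

def rasterize_roi(roi: RoiPolygon, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside/on the polygon."""
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    geom = roi.as_shapely()
    # shapely works in (x, y); feed (row, col) consistently with the vertices
    inside = shapely.intersects_xy(geom, rr.ravel().astype(float),
                                   cc.ravel().astype(float))
    return inside.reshape(h, w)


def largest_rectangle(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Maximum-area axis-aligned all-True rectangle ``(r0, c0, height, width)``.

    Ties are broken deterministically: larger height first, then smaller
    origin row, then smaller origin column. Uses the per-row histogram /
    monotone-stack dynamic programme, which enumerates every maximal
    rectangle once at its bottom row.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    best: tuple[int, int, int, int] | None = None
    best_key = (-1, -1, 0, 0)
    heights = np.zeros(w, dtype=np.int64)
    for r in range(h):
        heights = np.where(mask[r], heights + 1, 0)
        # monotone stack of (start_col, bar_height); each pop yields the
        # maximal-width rectangle of that bar's height ending before col c
        stack: list[tuple[int, int]] = []
        for c in range(w + 1):
            cur = int(heights[c]) if c < w else 0
            start = c
            while stack and stack[-1][1] > cur:
                idx, hh = stack.pop()
                width = c - idx
                r0, c0 = r - hh + 1, idx
                key = (hh * width, hh, -r0, -c0)
                if key > best_key:
                    best_key = key
                    best = (r0, c0, hh, width)
                start = idx
            if cur > 0 and (not stack or stack[-1][1] < cur):
                stack.append((start, cur))
    if best is None:
        return (0, 0, 0, 0)
    return best


def extract_subimage(image: np.ndarray, roi: RoiPolygon) -> SubImage:
    """Crop the largest axis-aligned rectangle fully inside the ROI.

    Raises :class:`RoiError` when no 8x8 rectangle fits (ROI too small).
    """
    image = as_gray_image(image)
    mask = rasterize_roi(roi, image.shape)
    r0, c0, hh, ww = largest_rectangle(mask)
    if hh < MIN_SUBIMAGE or ww < MIN_SUBIMAGE:
        raise RoiError(
            f"ROI too small: largest inscribed rectangle is {hh}x{ww}, "
            f"need at least {MIN_SUBIMAGE}x{MIN_SUBIMAGE}")
    return SubImage(image[r0:r0 + hh, c0:c0 + ww], origin=(r0, c0))


def quantize(sub: SubImage | np.ndarray, levels: int = 64) -> QuantizedImage:
    """Min-max linear grey-level binning over the sub-image's own range.

    Equal-width bins; the maximum intensity maps to bin ``levels - 1`` and a
    constant image maps everywhere to bin 0.
    """
    if levels < 2:
        raise ValueError("need at least 2 grey levels")
    pixels = sub.pixels if isinstance(sub, SubImage) else as_gray_image(sub)
    lo, hi = int(pixels.min()), int(pixels.max())
    if hi == lo:
        return QuantizedImage(np.zeros(pixels.shape, dtype=np.int64), levels)
    bins = ((pixels.astype(np.float64) - lo) / (hi - lo) * levels).astype(np.int64)
    return QuantizedImage(np.minimum(bins, levels - 1), levels)
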