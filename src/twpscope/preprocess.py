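"""Loading, mosaicking, masking and contrast enhancement of filter images.

A :class:`FilterImage` couples an 8-bit RGB raster with its physical pixel
size and an optional exclusion mask marking regions to ignore (the
programmatic analogue of covering organic debris in white before analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "FilterImage",
    "load_image",
    "save_image",
    "assemble_mosaic",
    "apply_exclusion",
    "enhance",
]

_WHITE = np.array([255, 255, 255], dtype=np.uint8)


@dataclass
class FilterImage:
    """RGB filter raster with physical scale.

    Parameters
    ----------
    rgb
        H x W x 3 uint8 raster.
    pixel_size_um
        Physical edge length of one pixel in micrometres (> 0).
    exclusion_mask
        Optional H x W boolean raster; True marks pixels excluded from
        particle detection.
    """

    rgb: np.ndarray
    pixel_size_um: float
    exclusion_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 RGB raster, got shape {self.rgb.shape}")
        if self.rgb.dtype != np.uint8:
            raise ValueError(f"expected 8-bit raster, got dtype {self.rgb.dtype}")
        if not (self.pixel_size_um is not None and self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be a positive number")
        if self.exclusion_mask is not None:
            self.exclusion_mask = np.asarray(self.exclusion_mask, dtype=bool)
            if self.exclusion_mask.shape != self.rgb.shape[:2]:
                raise ValueError("exclusion_mask shape must match the raster")

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]

    def copy(self) -> "FilterImage":
        return FilterImage(
            self.rgb.copy(),
            self.pixel_size_um,
            None if self.exclusion_mask is None else self.exclusion_mask.copy(),
        )


def load_image(path: str | Path, pixel_size_um: float | None = None) -> FilterImage:
    """Load a TIFF or PNG filter image.

    The pixel size comes from the ``pixel_size_um`` argument or, for TIFF,
    from the resolution tags written by :func:`save_image`; the argument
    wins. A missing pixel size is an error, never a silent default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta_px: float | None = None
    if path.suffix.lower() in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            rgb = page.asarray()
            tags = page.tags
            if "XResolution" in tags and "ResolutionUnit" in tags:
                num, den = tags["XResolution"].value
                unit = tags["ResolutionUnit"].value
                if num > 0:
                    per_px = den / num  # unit length per pixel
                    if unit == tifffile.RESUNIT.CENTIMETER:
                        meta_px = per_px * 1e4
                    elif unit == tifffile.RESUNIT.INCH:
                        meta_px = per_px * 2.54e4
    else:
        rgb = iio.imread(path)
    if rgb.ndim == 3 and rgb.shape[2] == 4:  # tolerate opaque alpha
        if np.all(rgb[..., 3] == 255):
            rgb = rgb[..., :3]
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"{path.name}: expected an 8-bit RGB image, got shape {rgb.shape}")
    if rgb.dtype != np.uint8:
        raise ValueError(f"{path.name}: expected an 8-bit image, got dtype {rgb.dtype}")
    px = pixel_size_um if pixel_size_um is not None else meta_px
    if px is None:
        raise ValueError(
            f"{path.name}: pixel size not given and not present in image metadata"
        )
    return FilterImage(rgb, float(px))


def save_image(image: FilterImage, path: str | Path) -> Path:
    """Write as lossless TIFF (with resolution tags) or PNG, by extension."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        px_cm = 1e4 / image.pixel_size_um  # pixels per centimetre
        tifffile.imwrite(
            path,
            image.rgb,
            photometric="rgb",
            resolution=(px_cm, px_cm),
            resolutionunit=tifffile.RESUNIT.CENTIMETER,
        )
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, image.rgb)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    return path


def assemble_mosaic(tiles: list[FilterImage], grid: tuple[int, int]) -> FilterImage:
    """Abut tiles row-major into a ``rows x cols`` mosaic, no blending."""
    rows, cols = grid
    if rows * cols != len(tiles):
        raise ValueError(f"grid {rows}x{cols} does not match {len(tiles)} tiles")
    px = tiles[0].pixel_size_um
    if any(t.pixel_size_um != px for t in tiles):
        raise ValueError("all tiles must share the same pixel size")
    grid_rows = []
    for r in range(rows):
        row_tiles = tiles[r * cols : (r + 1) * cols]
        h = row_tiles[0].rgb.shape[0]
        if any(t.rgb.shape[0] != h for t in row_tiles):
            raise ValueError("tiles within a mosaic row must share their height")
        grid_rows.append(np.concatenate([t.rgb for t in row_tiles], axis=1))
    w = grid_rows[0].shape[1]
    if any(g.shape[1] != w for g in grid_rows):
        raise ValueError("mosaic rows must share their total width")
    mosaic = np.concatenate(grid_rows, axis=0)
    masks = [t.exclusion_mask for t in tiles]
    mask = None
    if any(m is not None for m in masks):
        full = [
            m if m is not None else np.zeros(t.rgb.shape[:2], bool)
            for m, t in zip(masks, tiles)
        ]
        mask = np.concatenate(
            [
                np.concatenate(full[r * cols : (r + 1) * cols], axis=1)
                for r in range(rows)
            ],
            axis=0,
        )
    return FilterImage(mosaic, px, mask)


def _regions_to_mask(shape: tuple[int, int], regions) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for r0, r1, c0, c1 in regions:
        mask[r0:r1, c0:c1] = True
    return mask


def apply_exclusion(image: FilterImage, mask_or_regions) -> FilterImage:
    """Paint excluded pixels pure white and record them in the exclusion mask.

    ``mask_or_regions`` is either a boolean H x W raster or an iterable of
    ``(row0, row1, col0, col1)`` rectangles. Exclusion is absorbing: no
    particle may later be detected on an excluded pixel.
    """
    if isinstance(mask_or_regions, np.ndarray):
        mask = mask_or_regions.astype(bool)
        if mask.shape != image.shape:
            raise ValueError("exclusion mask shape must match the image")
    else:
        mask = _regions_to_mask(image.shape, mask_or_regions)
    out = image.copy()
    out.rgb[mask] = _WHITE
    if out.exclusion_mask is None:
        out.exclusion_mask = mask.copy()
    else:
        out.exclusion_mask |= mask
    return out


def enhance(
    image: FilterImage, exposure_gain: float = 1.5, black_level: int = 30
) -> FilterImage:
    """Stretch contrast: ``v -> clip(gain * (v - black_level), 0, 255)``.

    Pushes dark (particle) pixels to 0 and the pale bluish filter background
    toward white; monotone per channel, identity at gain 1 / level 0.
    """
    if exposure_gain < 1:
        raise ValueError("exposure_gain must be >= 1")
    if not (0 <= black_level < 255):
        raise ValueError("black_level must be in [0, 255)")
    mapped = np.clip(
        exposure_gain * (image.rgb.astype(np.float32) - black_level), 0, 255
    ).astype(np.uint8)
    out = FilterImage(mapped, image.pixel_size_um, image.exclusion_mask)
    if out.exclusion_mask is not None:
        out.rgb[out.exclusion_mask] = _WHITE
    return out
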