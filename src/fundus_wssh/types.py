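"""Shared container types carried between pipeline stages.

The universal carrier is :class:`RasterImage` — an ``H x W (x C)`` pixel array
with a declared value range and color space.  Coordinates throughout the
package are 0-based ``(row, col)`` with the origin at the top-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import (
    InvalidColorSpaceError,
    InvalidParameterError,
    OutOfRangeError,
    ShapeError,
)

COLOR_SPACES = ("RGB", "LAB", "GRAY")


@dataclass
class RasterImage:
    """An image plus the metadata the pipeline needs to interpret it.

    Parameters
    ----------
    pixels
        ``H x W`` (grayscale) or ``H x W x C`` array.  Stored as float64
        internally so intermediate stages do not quantize; I/O converts to
        8-bit at the boundary.
    value_range
        Declared inclusive bounds of valid pixel values, default ``(0, 255)``.
    color_space
        One of ``"RGB"``, ``"LAB"``, ``"GRAY"``.
    """

    pixels: np.ndarray
    value_range: tuple[float, float] = (0.0, 255.0)
    color_space: str = "RGB"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.color_space not in COLOR_SPACES:
            raise InvalidColorSpaceError(
                f"unknown color space {self.color_space!r}; expected one of {COLOR_SPACES}"
            )
        if self.color_space == "GRAY":
            if self.pixels.ndim == 3 and self.pixels.shape[2] == 1:
                self.pixels = self.pixels[:, :, 0]
            if self.pixels.ndim != 2:
                raise ShapeError("GRAY images must be H x W (single channel)")
        else:
            if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
                raise ShapeError(f"{self.color_space} images must be H x W x 3")
        h, w = self.pixels.shape[:2]
        if h < 3 or w < 3:
            raise ShapeError(f"images must be at least 3 x 3, got {h} x {w}")
        lo, hi = self.value_range
        if lo >= hi:
            raise InvalidParameterError("value_range must be (low, high) with low < high")
        # LAB a/b channels are signed; only enforce the range for RGB/GRAY.
        if self.color_space != "LAB":
            if self.pixels.min() < lo - 1e-9 or self.pixels.max() > hi + 1e-9:
                raise OutOfRangeError(
                    f"pixel values [{self.pixels.min()}, {self.pixels.max()}] "
                    f"outside declared range {self.value_range}"
                )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def copy_with(self, pixels: np.ndarray, color_space: Optional[str] = None) -> "RasterImage":
        return RasterImage(
            pixels=pixels,
            value_range=self.value_range,
            color_space=self.color_space if color_space is None else color_space,
        )

    def to_uint8(self) -> np.ndarray:
        lo, hi = self.value_range
        scaled = (self.pixels - lo) * (255.0 / (hi - lo))
        return np.clip(np.rint(scaled), 0, 255).astype(np.uint8)


def as_raster(image, color_space: str = "RGB") -> RasterImage:
    """Coerce an ndarray (or pass through a RasterImage) to :class:`RasterImage`."""
    if isinstance(image, RasterImage):
        return image
    arr = np.asarray(image)
    if arr.ndim == 2:
        color_space = "GRAY"
    return RasterImage(pixels=arr.astype(np.float64), color_space=color_space)


@dataclass
class HistogramDensity:
    """A normalized gray-level histogram: ``density[i] = n_i / n``."""

    levels: int
    density: np.ndarray

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=np.float64)
        if self.density.shape != (self.levels,):
            raise ShapeError("density length must equal the level count")
        if (self.density < 0).any():
            raise InvalidParameterError("density values must be non-negative")
        if abs(self.density.sum() - 1.0) > 1e-9:
            raise InvalidParameterError("density must sum to 1 within 1e-9")


@dataclass
class ODCircle:
    """A detected optic-disc circle.

    ``center_a`` is the column coordinate, ``center_b`` the row coordinate
    (matching the ``x = a + r cos(theta), y = b + r sin(theta)``
    parametrization); both are 0-based pixel indices.
    """

    center_a: float
    center_b: float
    radius_r: float
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.radius_r <= 0:
            raise InvalidParameterError("radius_r must be positive")

    def contains(self, rows: np.ndarray, cols: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """Disc membership (x-a)^2 + (y-b)^2 <= (r+margin)^2 — boundary included."""
        return (cols - self.center_a) ** 2 + (rows - self.center_b) ** 2 <= (
            self.radius_r + margin
        ) ** 2

    def mask(self, shape: tuple[int, int], margin: float = 0.0) -> np.ndarray:
        rows, cols = np.ogrid[: shape[0], : shape[1]]
        return self.contains(rows, cols, margin=margin)

    def to_dict(self) -> dict:
        return {
            "a": float(self.center_a),
            "b": float(self.center_b),
            "r": float(self.radius_r),
            "score": float(self.score),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ODCircle":
        return cls(center_a=d["a"], center_b=d["b"], radius_r=d["r"], score=d.get("score", 0.0))


@dataclass
class BinaryMask:
    """A strictly binary H x W mask with the threshold that produced it."""

    bits: np.ndarray
    threshold_used: float = float("nan")

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits)
        if self.bits.ndim != 2:
            raise ShapeError("mask must be 2-D")
        uniq = np.unique(self.bits)
        if not np.all(np.isin(uniq, [0, 1])):
            raise InvalidParameterError("mask values must be strictly 0/1")
        self.bits = self.bits.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.bits.shape

    def as_bool(self) -> np.ndarray:
        return self.bits.astype(bool)


@dataclass
class StructuringElement:
    """A flat or grayscale structuring element for morphology.

    ``offsets`` is the boolean support; ``values`` holds ``b(x)`` for the
    grayscale case (zeros for a flat element).
    """

    shape: str = "disk"
    size: int = 3
    offsets: np.ndarray = field(default=None)  # type: ignore[assignment]
    values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.offsets is None:
            self.offsets = footprint(self.shape, self.size)
        self.offsets = np.asarray(self.offsets, dtype=bool)
        if self.values is None:
            self.values = np.zeros(self.offsets.shape, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.offsets.shape:
            raise ShapeError("values and offsets must share a shape")
        if not self.offsets.any():
            raise InvalidParameterError("structuring element support must be non-empty")
        center = tuple(s // 2 for s in self.offsets.shape)
        if not self.offsets[center]:
            raise InvalidParameterError("structuring element must contain the origin")


def footprint(shape: str, size: int) -> np.ndarray:
    """Boolean support for a named structuring element.

    ``size`` is the radius for a disk and the side length for a square.
    """
    if size < 1:
        raise InvalidParameterError("structuring element size must be >= 1")
    if shape == "disk":
        r = size
        y, x = np.ogrid[-r : r + 1, -r : r + 1]
        return (x * x + y * y) <= r * r
    if shape == "square":
        if size % 2 == 0:
            raise InvalidParameterError("square element side must be odd")
        return np.ones((size, size), dtype=bool)
    raise InvalidParameterError(f"unknown element shape {shape!r}")
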