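"""Fundus preprocessing: median denoising, LAB/CLAHE contrast enhancement,
gamma correction and the Kirsch compass edge map.

The stage order is fixed: median -> CLAHE -> gamma -> (optional) Kirsch on the
grayscale conversion.  All 3x3 neighborhood operators replicate the edge row /
column at the border.

CLAHE is implemented directly on an integer-quantized L channel (per-tile
histogram, clip + uniform redistribution of the excess, CDF mapping
``m(i) = (L-1) * cdf(i)``, bilinear interpolation between tile mappings).  With
a single tile and a clip limit above the tile pixel count it reduces exactly
to plain histogram equalization of the channel, which is the property the test
suite pins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color as skcolor

from .errors import InvalidColorSpaceError, InvalidParameterError, OutOfRangeError
from .types import HistogramDensity, RasterImage, as_raster

__all__ = [
    "PreprocessConfig",
    "median_denoise",
    "clahe_enhance",
    "clahe_channel",
    "gamma_correct",
    "normalized_histogram",
    "kirsch_edge_map",
    "KIRSCH_KERNELS",
    "run_preprocess",
]

GAMMA_DENOMINATOR = 155.0  # printed constant of the gamma mapping; not 255


@dataclass
class PreprocessConfig:
    """Configuration of the preprocessing chain.

    Parameters
    ----------
    median_kernel
        Odd window side of the median filter, >= 3.
    clahe_clip_limit
        Contrast limit as a multiple of the uniform histogram height
        (OpenCV-style; 2.0 is mild clipping).
    clahe_tile_grid
        ``(rows, cols)`` of the CLAHE tile grid.
    gamma_g
        Luminance exponent ``g`` of ``I' = 255 * (I / 155)^(1/g)``; ``g > 1``
        lightens the image.
    apply_kirsch
        Whether the final stage converts to grayscale and applies the Kirsch
        edge operator.
    """

    median_kernel: int = 3
    clahe_clip_limit: float = 2.0
    clahe_tile_grid: tuple[int, int] = (8, 8)
    gamma_g: float = 1.2
    apply_kirsch: bool = False

    def __post_init__(self) -> None:
        if self.median_kernel < 3 or self.median_kernel % 2 == 0:
            raise InvalidParameterError("median_kernel must be odd and >= 3")
        if self.clahe_clip_limit <= 0:
            raise InvalidParameterError("clahe_clip_limit must be positive")
        if self.gamma_g <= 0:
            raise InvalidParameterError("gamma_g must be positive")
        r, c = self.clahe_tile_grid
        if r < 1 or c < 1:
            raise InvalidParameterError("clahe_tile_grid entries must be >= 1")


def median_denoise(image, kernel: int = 3) -> RasterImage:
    """Median-filter every channel with a ``kernel x kernel`` window.

    The border is handled by edge replication; shape and declared value range
    are preserved.
    """
    img = as_raster(image)
    if kernel % 2 == 0 or kernel < 3:
        raise InvalidParameterError(f"median kernel must be odd and >= 3, got {kernel}")
    if kernel > min(img.height, img.width):
        raise InvalidParameterError(
            f"median kernel {kernel} exceeds image size {img.height}x{img.width}"
        )
    if img.pixels.ndim == 2:
        out = ndimage.median_filter(img.pixels, size=kernel, mode="nearest")
    else:
        out = np.stack(
            [
                ndimage.median_filter(img.pixels[:, :, c], size=kernel, mode="nearest")
                for c in range(img.pixels.shape[2])
            ],
            axis=2,
        )
    return img.copy_with(out)


def _clip_histogram(hist: np.ndarray, clip_limit: float, n_pixels: int) -> np.ndarray:
    """Clip a tile histogram and redistribute the excess uniformly."""
    nbins = hist.size
    limit = max(clip_limit * n_pixels / nbins, 1.0)
    clipped = np.minimum(hist, limit)
    excess = hist.sum() - clipped.sum()
    return clipped + excess / nbins


def clahe_channel(
    channel: np.ndarray,
    clip_limit: float = 2.0,
    tile_grid: tuple[int, int] = (8, 8),
    nbins: int = 256,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of one integer channel.

    ``channel`` must hold integers in ``[0, nbins)``.  Returns float values in
    ``[0, nbins - 1]`` (round to requantize).  Tile mappings are
    ``m(i) = (nbins - 1) * cdf(i)`` from the clipped histogram; pixel values
    are bilinearly interpolated between the mappings of the four surrounding
    tile centers (clamped at the border).
    """
    ch = np.asarray(channel)
    if ch.ndim != 2:
        raise InvalidParameterError("clahe_channel expects a 2-D channel")
    if ch.min() < 0 or ch.max() >= nbins:
        raise OutOfRangeError(f"channel values must lie in [0, {nbins})")
    ch = ch.astype(np.intp)
    h, w = ch.shape
    tr, tc = tile_grid
    tr, tc = min(tr, h), min(tc, w)

    row_edges = np.linspace(0, h, tr + 1).astype(int)
    col_edges = np.linspace(0, w, tc + 1).astype(int)
    mappings = np.empty((tr, tc, nbins), dtype=np.float64)
    centers_r = np.empty(tr)
    centers_c = np.empty(tc)
    for i in range(tr):
        r0, r1 = row_edges[i], row_edges[i + 1]
        centers_r[i] = (r0 + r1 - 1) / 2.0
        for j in range(tc):
            c0, c1 = col_edges[j], col_edges[j + 1]
            if i == 0:
                centers_c[j] = (c0 + c1 - 1) / 2.0
            tile = ch[r0:r1, c0:c1]
            hist = np.bincount(tile.ravel(), minlength=nbins).astype(np.float64)
            hist = _clip_histogram(hist, clip_limit, tile.size)
            cdf = np.cumsum(hist) / hist.sum()
            mappings[i, j] = (nbins - 1) * cdf

    if tr == 1 and tc == 1:
        return mappings[0, 0][ch]

    # Bilinear interpolation between tile-center mappings, clamped outside.
    rows = np.arange(h, dtype=np.float64)
    cols = np.arange(w, dtype=np.float64)
    i1 = np.clip(np.searchsorted(centers_r, rows), 0, tr - 1)
    i0 = np.clip(i1 - 1, 0, tr - 1)
    j1 = np.clip(np.searchsorted(centers_c, cols), 0, tc - 1)
    j0 = np.clip(j1 - 1, 0, tc - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        wr = np.where(
            i1 > i0,
            (rows - centers_r[i0]) / (centers_r[i1] - centers_r[i0]),
            0.0,
        )
        wc = np.where(
            j1 > j0,
            (cols - centers_c[j0]) / (centers_c[j1] - centers_c[j0]),
            0.0,
        )
    wr = np.clip(wr, 0.0, 1.0)[:, None]
    wc = np.clip(wc, 0.0, 1.0)[None, :]

    def gather(ii, jj):
        return mappings[ii[:, None], jj[None, :], ch]

    out = (
        (1 - wr) * (1 - wc) * gather(i0, j0)
        + (1 - wr) * wc * gather(i0, j1)
        + wr * (1 - wc) * gather(i1, j0)
        + wr * wc * gather(i1, j1)
    )
    return out


def clahe_lab(
    image: RasterImage,
    clip_limit: float = 2.0,
    tile_grid: tuple[int, int] = (8, 8),
) -> tuple[np.ndarray, np.ndarray]:
    """CLAHE on the L channel of the LAB conversion.

    Returns ``(lab_before, lab_after)``; the a/b channels of the two arrays
    are identical by construction.
    """
    lab = skcolor.rgb2lab(image.pixels / image.value_range[1])
    l_quant = np.clip(np.rint(lab[:, :, 0] * 255.0 / 100.0), 0, 255).astype(int)
    l_eq = clahe_channel(l_quant, clip_limit=clip_limit, tile_grid=tile_grid)
    lab_after = lab.copy()
    lab_after[:, :, 0] = l_eq * (100.0 / 255.0)
    return lab, lab_after


def clahe_enhance(
    image,
    clip_limit: float = 2.0,
    tile_grid: tuple[int, int] = (8, 8),
) -> RasterImage:
    """Enhance contrast by CLAHE on the LAB lightness channel only.

    The image is converted RGB -> LAB, CLAHE is applied to L, the untouched
    a/b channels are merged back and the result converted to RGB within the
    declared value range.
    """
    img = as_raster(image)
    if img.color_space != "RGB":
        raise InvalidColorSpaceError("clahe_enhance requires an RGB image")
    _, lab_after = clahe_lab(img, clip_limit=clip_limit, tile_grid=tile_grid)
    rgb = skcolor.lab2rgb(lab_after) * img.value_range[1]
    return img.copy_with(np.clip(rgb, *img.value_range))


def gamma_correct(image, g: float) -> RasterImage:
    """Pointwise gamma mapping ``I' = 255 * (I / 155)^(1/g)``, clipped to range.

    The denominator is 155, so inputs above 155 saturate at the range maximum.
    The mapping is monotone non-decreasing for every ``g > 0``.
    """
    img = as_raster(image)
    if g <= 0:
        raise InvalidParameterError(f"gamma g must be positive, got {g}")
    if img.pixels.min() < 0:
        raise InvalidParameterError("gamma_correct requires non-negative pixel values")
    out = 255.0 * (img.pixels / GAMMA_DENOMINATOR) ** (1.0 / g)
    return img.copy_with(np.clip(out, *img.value_range))


def normalized_histogram(image, levels: int = 256) -> HistogramDensity:
    """Normalized gray-level histogram ``p(i) = n_i / n`` over ``levels`` bins.

    Accepts a grayscale :class:`RasterImage` or any 2-D array (a histogram
    has no neighborhood, so the 3x3 minimum of the windowed operators does
    not apply).
    """
    if isinstance(image, RasterImage):
        if image.color_space != "GRAY":
            raise InvalidColorSpaceError("normalized_histogram requires a grayscale image")
        vals = image.pixels
    else:
        vals = np.asarray(image, dtype=np.float64)
        if vals.ndim != 2:
            raise InvalidColorSpaceError("normalized_histogram requires a 2-D grayscale array")
    if vals.min() < 0 or vals.max() >= levels:
        raise OutOfRangeError(f"pixel values must lie in [0, {levels})")
    counts = np.bincount(vals.astype(np.intp).ravel(), minlength=levels).astype(np.float64)
    return HistogramDensity(levels=levels, density=counts / vals.size)


def _kirsch_kernels() -> np.ndarray:
    # the N mask plus its 45-degree turn; 90-degree rotations give all 8 compass directions
    base = np.array([[5, 5, 5], [-3, 0, -3], [-3, -3, -3]], dtype=np.float64)
    diag = np.array([[5, 5, -3], [5, 0, -3], [-3, -3, -3]], dtype=np.float64)
    kernels = []
    k, d = base, diag
    for _ in range(4):
        kernels.append(k)
        kernels.append(d)
        k = np.rot90(k)
        d = np.rot90(d)
    return np.stack(kernels)


KIRSCH_KERNELS = _kirsch_kernels()


def kirsch_edge_map(image, rescale: bool = True) -> RasterImage:
    """Maximum response over the eight 3x3 Kirsch compass kernels.

    Each kernel has the +-5 / -+3 pattern and zero coefficient sum, so a flat
    image maps to zero everywhere.  The border replicates the edge pixels.
    With ``rescale=True`` the response is min-max scaled into the declared
    value range; ``rescale=False`` returns the raw maximum response (always
    >= 0 because the kernel family sums to zero pointwise).
    """
    img = as_raster(image)
    if img.color_space != "GRAY":
        raise InvalidColorSpaceError("kirsch_edge_map requires a grayscale image")
    responses = np.stack(
        [ndimage.correlate(img.pixels, k, mode="nearest") for k in KIRSCH_KERNELS]
    )
    out = responses.max(axis=0)
    if rescale:
        peak = out.max()
        if peak > 0:
            out = out * (img.value_range[1] / peak)
        return img.copy_with(out, color_space="GRAY")
    return RasterImage(
        pixels=out,
        value_range=(0.0, max(float(out.max()), img.value_range[1])),
        color_space="GRAY",
    )


def to_gray_luminance(image: RasterImage) -> RasterImage:
    # local import to avoid a cycle: od_removal owns the luminance conversion
    from .od_removal import to_luminance

    return to_luminance(image)


def run_preprocess(image, config: PreprocessConfig | None = None, return_stages: bool = False):
    """Run the full chain median -> CLAHE -> gamma -> (optional) Kirsch.

    With ``return_stages=True`` also returns an ordered dict of per-stage
    intermediates for a side-by-side panel.
    """
    img = as_raster(image)
    cfg = config or PreprocessConfig()
    stages: dict[str, RasterImage] = {"input": img}
    try:
        img = median_denoise(img, kernel=cfg.median_kernel)
        stages["median"] = img
    except Exception as exc:  # annotate with the failing stage
        raise type(exc)(f"[median] {exc}") from exc
    try:
        img = clahe_enhance(img, clip_limit=cfg.clahe_clip_limit, tile_grid=cfg.clahe_tile_grid)
        stages["clahe"] = img
    except Exception as exc:
        raise type(exc)(f"[clahe] {exc}") from exc
    try:
        img = gamma_correct(img, g=cfg.gamma_g)
        stages["gamma"] = img
    except Exception as exc:
        raise type(exc)(f"[gamma] {exc}") from exc
    if cfg.apply_kirsch:
        try:
            img = kirsch_edge_map(to_gray_luminance(img))
            stages["kirsch"] = img
        except Exception as exc:
            raise type(exc)(f"[kirsch] {exc}") from exc
    if return_stages:
        return img, stages
    return img
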