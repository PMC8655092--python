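"""Weakly Supervised Sensitive Heatmap (WSSH) localization.

A class-sensitive heat map is the class-weighted sum of the final-layer
feature maps, ``H_c(x, y) = sum_n w_n^c f_n(x, y)`` — a class activation map.
The WSSH variant additionally combines the global-region weight with each
quadrant-region weight, ``I_cj(x, y) = sum_k (w_{k1}^c / 4 + w_{kj}^c)
f_k(x, y)`` for regions j = 2..5, and takes the elementwise maximum over the
four region maps as the combined saliency, so evidence from any quadrant's
weights stays visible.

Lesion regions of interest come from basic thresholding of the (upsampled)
heat map at a fraction of its maximum, with connected components as boxes and
optional suppression of everything inside the optic-disc mask — the step that
removes exudate false positives at the disc.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .cnn_head import ClassWeights, FeatureMaps, PooledUnits
from .errors import (
    InvalidParameterError,
    InvalidROIError,
    ShapeError,
    UndefinedGroundTruthError,
)
from .types import BinaryMask, RasterImage, as_raster

__all__ = [
    "HeatMap",
    "ClassScore",
    "LesionROI",
    "class_heatmap",
    "wssh_heatmap",
    "wssh_region_maps",
    "wssh_score",
    "region_score",
    "upsample_heatmap",
    "heatmap_to_roi",
    "warp_roi",
    "pointing_game",
]

EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass
class HeatMap:
    """Class-sensitive saliency values for one class."""

    values: np.ndarray
    class_id: object = None
    upsampled: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ShapeError("heat map must be 2-D")
        if not np.isfinite(self.values).all():
            raise InvalidParameterError("heat map values must be finite")


@dataclass
class ClassScore:
    """A pre-softmax class score, from the region (``S_c``) or WSSH reading."""

    s_c: float
    variant: str = "region"

    def __post_init__(self) -> None:
        if not np.isfinite(self.s_c):
            raise InvalidParameterError("class score must be finite")


@dataclass
class LesionROI:
    """A thresholded heat-map component as a bounding box.

    ``bbox`` is ``(row_min, col_min, row_max, col_max)``, half-open and
    0-based in full-image coordinates; ``peak`` the location of the component
    maximum and ``score`` its heat value.
    """

    bbox: tuple[int, int, int, int]
    peak: tuple[int, int]
    score: float

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.bbox
        if not (r0 < r1 and c0 < c1):
            raise InvalidROIError(f"degenerate bbox {self.bbox}")
        pr, pc = self.peak
        if not (r0 <= pr < r1 and c0 <= pc < c1):
            raise InvalidROIError(f"peak {self.peak} outside bbox {self.bbox}")

    def to_dict(self) -> dict:
        return {
            "bbox": [int(v) for v in self.bbox],
            "peak": [int(v) for v in self.peak],
            "score": float(self.score),
        }


def _maps_and_weights(features, weights: ClassWeights, c) -> tuple[np.ndarray, int]:
    fm = features if isinstance(features, FeatureMaps) else FeatureMaps(np.asarray(features))
    if fm.n != weights.n_maps:
        raise ShapeError(
            f"feature maps ({fm.n}) and class weights ({weights.n_maps}) disagree on map count"
        )
    return fm.maps, weights.class_index(c)


def class_heatmap(features, weights: ClassWeights, c) -> HeatMap:
    """Plain class activation map ``H_c = sum_n w_n^c f_n`` (global weights)."""
    maps, ci = _maps_and_weights(features, weights, c)
    w_global = weights.weights[ci, :, 0]
    return HeatMap(values=np.tensordot(w_global, maps, axes=(0, 0)), class_id=c)


def wssh_region_maps(features, weights: ClassWeights, c) -> list[HeatMap]:
    """The four per-region maps ``I_c2 .. I_c5``.

    ``I_cj = sum_k (w_{k1}^c / 4 + w_{kj}^c) f_k`` for quadrant regions
    j = 2..5 (weight columns 1..4).
    """
    maps, ci = _maps_and_weights(features, weights, c)
    w = weights.weights[ci]
    if w.shape[1] < 2:
        raise InvalidParameterError("region weights for regions 1 and 2 are required")
    out = []
    for j in range(1, w.shape[1]):
        coeff = w[:, 0] / 4.0 + w[:, j]
        out.append(HeatMap(values=np.tensordot(coeff, maps, axes=(0, 0)), class_id=c))
    return out


def wssh_heatmap(features, weights: ClassWeights, c) -> HeatMap:
    """Combined WSSH saliency: the elementwise maximum over ``I_c2 .. I_c5``."""
    region_maps = wssh_region_maps(features, weights, c)
    combined = np.maximum.reduce([m.values for m in region_maps])
    return HeatMap(values=combined, class_id=c)


def wssh_score(features, weights: ClassWeights, c) -> ClassScore:
    """``S_c(WSSH) = (1/N_1) sum_x sum_y sum_n W_n^c A^n_{x,y}``.

    Algebraically this is the spatial mean of :func:`class_heatmap` (no bias
    term exists to exclude), which the test suite pins as the CAM identity.
    """
    maps, ci = _maps_and_weights(features, weights, c)
    n1 = maps.shape[1] * maps.shape[2]
    total = float(np.einsum("n,nxy->", weights.weights[ci, :, 0], maps))
    return ClassScore(s_c=total / n1, variant="wssh")


def region_score(pooled: PooledUnits, weights: ClassWeights, c) -> ClassScore:
    """``S_c = sum_n w_{n1}^c A_n1 + sum_n w_{n2}^c A_n2 + ...`` over all regions."""
    ci = weights.class_index(c)
    units = pooled.as_matrix()  # (n_maps, 5)
    if units.shape[0] != weights.n_maps:
        raise ShapeError("pooled units and class weights disagree on map count")
    return ClassScore(s_c=float((weights.weights[ci] * units).sum()), variant="region")


def upsample_heatmap(heat: HeatMap, target: tuple[int, int]) -> HeatMap:
    """Bilinear upsampling to ``target = (H, W)`` with corner alignment.

    Source grid points map exactly onto the output (order preserving), so the
    argmax of the output lies in the pre-image cell of the source argmax.
    """
    th, tw = target
    sh, sw = heat.values.shape
    if th < sh or tw < sw:
        raise InvalidParameterError(
            f"target {target} smaller than source {heat.values.shape}"
        )
    rows = np.linspace(0.0, sh - 1.0, th)
    cols = np.linspace(0.0, sw - 1.0, tw)
    grid = np.meshgrid(rows, cols, indexing="ij")
    up = ndimage.map_coordinates(heat.values, grid, order=1, mode="nearest")
    return HeatMap(values=heat.values, class_id=heat.class_id, upsampled=up)


def heatmap_to_roi(
    heat: HeatMap,
    frac: float = 0.2,
    od_mask: Optional[BinaryMask] = None,
    clip_negative: bool = False,
) -> list[LesionROI]:
    """Threshold the heat map into lesion bounding boxes.

    Binarizes at ``frac * max(heat)``, removes all pixels inside ``od_mask``,
    and returns one :class:`LesionROI` per 8-connected component, sorted by
    descending peak heat (ties by row-major peak position).  When an
    ``od_mask`` is given the disc is a hard exclusion zone for boxes: a
    component whose bounding box cannot be drawn without covering disc
    pixels is discarded as a disc-adjacent false positive, so no returned
    box ever intersects the disc.  Returns an empty list when everything
    falls below the threshold or inside the disc.
    """
    if not 0 < frac < 1:
        raise InvalidParameterError(f"frac must lie in (0, 1), got {frac}")
    values = heat.upsampled if heat.upsampled is not None else heat.values
    values = np.asarray(values, dtype=np.float64)
    if clip_negative:
        values = np.maximum(values, 0.0)
    if od_mask is not None:
        if od_mask.shape != values.shape:
            raise ShapeError(
                f"od_mask shape {od_mask.shape} != heat shape {values.shape}; "
                "upsample the heat map first"
            )
    peak_val = values.max()
    if peak_val <= 0:
        return []
    binary = values >= frac * peak_val
    if od_mask is not None:
        binary &= ~od_mask.as_bool()
    if not binary.any():
        return []
    labels, n_comp = ndimage.label(binary, structure=EIGHT_CONN)
    rois: list[LesionROI] = []
    for comp_id, comp in enumerate(ndimage.find_objects(labels), start=1):
        if od_mask is not None and od_mask.as_bool()[comp].any():
            continue  # bounding box would cover disc pixels
        region = labels[comp] == comp_id
        vals = np.where(region, values[comp], -np.inf)
        flat = int(np.argmax(vals))  # row-major first maximum
        pr, pc = np.unravel_index(flat, vals.shape)
        rois.append(
            LesionROI(
                bbox=(comp[0].start, comp[1].start, comp[0].stop, comp[1].stop),
                peak=(comp[0].start + int(pr), comp[1].start + int(pc)),
                score=float(vals[pr, pc]),
            )
        )
    rois.sort(key=lambda r: (-r.score, r.peak[0], r.peak[1]))
    return rois


def warp_roi(image, roi: LesionROI, out_size: tuple[int, int]) -> RasterImage:
    """Warping operator ``W_p``: crop the ROI box and bilinearly resize.

    Resizing uses corner-aligned bilinear sampling, so a same-size warp is
    exactly the crop.
    """
    img = as_raster(image)
    r0, c0, r1, c1 = roi.bbox
    if r0 < 0 or c0 < 0 or r1 > img.height or c1 > img.width:
        raise InvalidROIError(f"roi {roi.bbox} outside image {img.height}x{img.width}")
    crop = img.pixels[r0:r1, c0:c1]
    oh, ow = out_size
    if oh < 1 or ow < 1:
        raise InvalidParameterError("out_size must be positive")
    ch, cw = crop.shape[:2]
    rows = np.linspace(0.0, ch - 1.0, oh)
    cols = np.linspace(0.0, cw - 1.0, ow)
    grid = np.meshgrid(rows, cols, indexing="ij")
    if crop.ndim == 2:
        out = ndimage.map_coordinates(crop, grid, order=1, mode="nearest")
    else:
        out = np.stack(
            [
                ndimage.map_coordinates(crop[:, :, ch_i], grid, order=1, mode="nearest")
                for ch_i in range(crop.shape[2])
            ],
            axis=2,
        )
    return img.copy_with(out)


def pointing_game(heat: HeatMap, lesion_mask: BinaryMask) -> bool:
    """Hit iff the heat maximum falls inside the ground-truth lesion mask.

    Ties at the maximum resolve row-major (first maximum in C order).
    """
    values = heat.upsampled if heat.upsampled is not None else heat.values
    values = np.asarray(values, dtype=np.float64)
    if values.shape != lesion_mask.shape:
        raise ShapeError(
            f"heat shape {values.shape} != mask shape {lesion_mask.shape}; upsample first"
        )
    if not lesion_mask.bits.any():
        raise UndefinedGroundTruthError("lesion mask is empty; pointing game undefined")
    r, c = np.unravel_index(int(np.argmax(values)), values.shape)
    return bool(lesion_mask.bits[r, c])
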