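"""scikit-learn style estimators composing the pipeline stages.

``FundusPreprocessor`` and ``OpticDiscRemover`` are stateless transformers
(fit is a no-op, like ``Binarizer``); ``WSSHClassifier`` is a fit/predict
classifier whose fitted class weights double as the localization weights.
They compose with ``sklearn.pipeline.Pipeline`` on image batches shaped
``(n_samples, H, W, C)``.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import od_removal as odr
from . import preprocess as pp
from .cnn_head import TrainConfig, train_classifier
from .errors import NoDiscFoundError
from .types import BinaryMask, ODCircle, RasterImage, as_raster
from .wssh import (
    HeatMap,
    LesionROI,
    class_heatmap,
    heatmap_to_roi,
    upsample_heatmap,
    wssh_heatmap,
)

__all__ = ["FundusPreprocessor", "OpticDiscRemover", "WSSHClassifier"]


def _iter_images(X) -> list[RasterImage]:
    if isinstance(X, RasterImage):
        return [X]
    if isinstance(X, np.ndarray) and X.ndim == 4:
        return [as_raster(x) for x in X]
    return [as_raster(x) for x in X]


def _stack(images: Sequence[RasterImage]) -> np.ndarray:
    return np.stack([img.pixels for img in images])


class FundusPreprocessor(TransformerMixin, BaseEstimator):
    """Median denoising, LAB-space CLAHE and gamma correction per image.

    A stateless transformer: ``fit`` only records the input count.  With
    ``apply_kirsch=True`` the output is the single-channel Kirsch edge map of
    the enhanced image instead of the RGB image.
    """

    def __init__(
        self,
        median_kernel: int = 3,
        clahe_clip_limit: float = 2.0,
        clahe_tile_grid: tuple[int, int] = (8, 8),
        gamma_g: float = 1.2,
        apply_kirsch: bool = False,
    ):
        self.median_kernel = median_kernel
        self.clahe_clip_limit = clahe_clip_limit
        self.clahe_tile_grid = clahe_tile_grid
        self.gamma_g = gamma_g
        self.apply_kirsch = apply_kirsch

    def _config(self) -> pp.PreprocessConfig:
        return pp.PreprocessConfig(
            median_kernel=self.median_kernel,
            clahe_clip_limit=self.clahe_clip_limit,
            clahe_tile_grid=tuple(self.clahe_tile_grid),
            gamma_g=self.gamma_g,
            apply_kirsch=self.apply_kirsch,
        )

    def fit(self, X, y=None):
        self._config()  # validate parameters
        self.n_features_in_ = len(_iter_images(X))
        return self

    def transform(self, X) -> np.ndarray:
        cfg = self._config()
        out = [pp.run_preprocess(img, cfg) for img in _iter_images(X)]
        return _stack(out)


class OpticDiscRemover(TransformerMixin, BaseEstimator):
    """Detect and excise the optic disc from each image.

    Stateless per sample; after ``transform`` the detected circles and masks
    of the last batch are available as ``circles_`` and ``masks_`` (``None``
    entries where no disc was found and ``on_missing='keep'``).
    """

    def __init__(
        self,
        margin: float = 2.0,
        fill: str = "black",
        rmin_frac: float = 0.03,
        rmax_frac: float = 0.15,
        blur_sigma: float = 2.0,
        score_floor: float = 0.30,
        on_missing: str = "raise",  # or 'keep' (pass image through unchanged)
    ):
        self.margin = margin
        self.fill = fill
        self.rmin_frac = rmin_frac
        self.rmax_frac = rmax_frac
        self.blur_sigma = blur_sigma
        self.score_floor = score_floor
        self.on_missing = on_missing

    def fit(self, X, y=None):
        self.n_features_in_ = len(_iter_images(X))
        return self

    def transform(self, X) -> np.ndarray:
        images = _iter_images(X)
        out, circles, masks = [], [], []
        for img in images:
            m = min(img.height, img.width)
            try:
                circle = odr.detect_od(
                    img,
                    radius_range=(self.rmin_frac * m, self.rmax_frac * m),
                    blur_sigma=self.blur_sigma,
                    score_floor=self.score_floor,
                )
            except NoDiscFoundError:
                if self.on_missing == "raise":
                    raise
                out.append(img)
                circles.append(None)
                masks.append(None)
                continue
            removed, mask = odr.remove_od(img, circle, margin=self.margin, fill=self.fill)
            out.append(removed)
            circles.append(circle)
            masks.append(mask)
        self.circles_ = circles
        self.masks_ = masks
        return _stack(out)


class WSSHClassifier(ClassifierMixin, BaseEstimator):
    """DR-grade classifier with a weakly supervised localization head.

    ``fit`` trains the bundled small conv backbone with a region-pooled
    linear class layer (momentum SGD, plateau learning-rate schedule);
    the fitted per-class region weights are reused, without any box
    annotations, to build class-sensitive heat maps and lesion boxes.
    """

    def __init__(
        self,
        epochs: int = 12,
        batch_size: int = 32,
        momentum: float = 0.9,
        weight_decay: float = 0.0001,
        lr_scale: float = 1.0,
        channels: tuple[int, ...] = (8, 16, 32),
        freeze_backbone: bool = False,
        use_lrn: bool = False,
        thresh_frac: float = 0.2,
        use_wssh_map: bool = True,
        random_state: int = 0,
    ):
        self.epochs = epochs
        self.batch_size = batch_size
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.lr_scale = lr_scale
        self.channels = channels
        self.freeze_backbone = freeze_backbone
        self.use_lrn = use_lrn
        self.thresh_frac = thresh_frac
        self.use_wssh_map = use_wssh_map
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        cfg = TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            momentum=self.momentum,
            weight_decay=self.weight_decay,
            lr_scale=self.lr_scale,
            seed=self.random_state,
            channels=tuple(self.channels),
            freeze_backbone=self.freeze_backbone,
            use_lrn=self.use_lrn,
        )
        self.model_ = train_classifier(X, y, cfg)
        self.classes_ = np.asarray(self.model_.classes)
        self.class_weights_ = self.model_.class_weights
        self.loss_history_ = list(self.model_.loss_history)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(np.asarray(X, dtype=np.float64))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict(np.asarray(X, dtype=np.float64))

    def heatmap(self, image, target_class=None, upsample: bool = True) -> HeatMap:
        """Class-sensitive heat map for one image (WSSH or plain CAM)."""
        check_is_fitted(self, "model_")
        img = as_raster(image)
        feats = self.model_.feature_maps(img.pixels[None])[0]
        if target_class is None:
            probs = self.model_.predict_proba(img.pixels[None])[0]
            target_class = self.model_.classes[int(probs.argmax())]
        build = wssh_heatmap if self.use_wssh_map else class_heatmap
        heat = build(feats, self.class_weights_, target_class)
        if upsample:
            heat = upsample_heatmap(heat, (img.height, img.width))
        return heat

    def localize(
        self,
        image,
        target_class=None,
        od_mask: Optional[BinaryMask] = None,
        od_circle: Optional[ODCircle] = None,
    ) -> list[LesionROI]:
        """Lesion bounding boxes for one image, with optional OD suppression."""
        img = as_raster(image)
        heat = self.heatmap(img, target_class=target_class, upsample=True)
        if od_mask is None and od_circle is not None:
            od_mask = BinaryMask(
                bits=od_circle.mask((img.height, img.width)).astype(np.uint8)
            )
        return heatmap_to_roi(heat, frac=self.thresh_frac, od_mask=od_mask)
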