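"""Image and configuration I/O shared by the CLI and the library."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import numpy as np
import yaml
from PIL import Image, UnidentifiedImageError

from .errors import ImageIOError, PipelineConfigError
from .preprocess import PreprocessConfig
from .synthetic import GeneratorConfig
from .types import RasterImage

logger = logging.getLogger("fundus_wssh")

__all__ = [
    "read_image",
    "write_image",
    "heat_to_uint8",
    "PipelineConfig",
    "ODRemovalConfig",
    "WSSHConfig",
    "TrainSection",
]

SUPPORTED_SUFFIXES = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}


def read_image(path) -> RasterImage:
    """Decode a PNG/JPEG/TIFF file to an 8-bit-range :class:`RasterImage`.

    16-bit TIFF input is rescaled to 0-255 with a logged warning.  PNG
    round-trips through :func:`write_image` are bit-identical.
    """
    p = Path(path)
    if not p.exists():
        raise ImageIOError(f"image file not found: {p}")
    if p.suffix.lower() not in SUPPORTED_SUFFIXES:
        raise ImageIOError(f"unsupported image format {p.suffix!r} for {p}")
    try:
        with Image.open(p) as im:
            arr = np.asarray(im)
    except (UnidentifiedImageError, OSError) as exc:
        raise ImageIOError(f"cannot decode image {p}: {exc}") from exc
    if arr.dtype == np.uint16:
        logger.warning("16-bit image %s rescaled to 0-255", p)
        arr = (arr.astype(np.float64) / 65535.0) * 255.0
    elif arr.dtype == bool:
        arr = arr.astype(np.float64) * 255.0
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    space = "GRAY" if arr.ndim == 2 else "RGB"
    return RasterImage(pixels=np.clip(arr, 0, 255), color_space=space)


def write_image(image: RasterImage, path) -> None:
    """Write an image as 8-bit PNG (or JPEG/TIFF by suffix)."""
    p = Path(path)
    if p.suffix.lower() not in SUPPORTED_SUFFIXES:
        raise ImageIOError(f"unsupported output format {p.suffix!r} for {p}")
    p.parent.mkdir(parents=True, exist_ok=True)
    try:
        Image.fromarray(image.to_uint8()).save(p)
    except OSError as exc:
        raise ImageIOError(f"cannot write image {p}: {exc}") from exc


def heat_to_uint8(values: np.ndarray) -> np.ndarray:
    """Min-max scale a heat map to 0-255 for PNG export (flat map -> zeros)."""
    v = np.asarray(values, dtype=np.float64)
    span = v.max() - v.min()
    if span <= 0:
        return np.zeros(v.shape, dtype=np.uint8)
    return np.clip(np.rint((v - v.min()) * (255.0 / span)), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ODRemovalConfig:
    margin: float = 2.0
    fill: str = "black"
    rmin_frac: float = 0.03
    rmax_frac: float = 0.15
    blur_sigma: float = 2.0
    score_floor: float = 0.30


@dataclass
class WSSHConfig:
    thresh_frac: float = 0.2
    clip_negative: bool = False
    use_wssh_map: bool = True  # combined region maps; False = plain CAM


@dataclass
class TrainSection:
    epochs: int = 60
    batch_size: int = 32
    momentum: float = 0.9
    weight_decay: float = 0.0001
    lr_scale: float = 1.0
    channels: tuple = (8, 16, 32)
    freeze_backbone: bool = False
    use_lrn: bool = False


@dataclass
class PipelineConfig:
    """Nested configuration for the full preprocessing-to-localization chain.

    Round-trips losslessly through YAML; unknown keys are rejected with the
    offending dotted path named.
    """

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    od_removal: ODRemovalConfig = field(default_factory=ODRemovalConfig)
    training: TrainSection = field(default_factory=TrainSection)
    wssh: WSSHConfig = field(default_factory=WSSHConfig)
    synth: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _build_dataclass(cls, data, path="")

    def to_dict(self) -> dict:
        return _as_plain(dataclasses.asdict(self))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise PipelineConfigError(f"config root in {path} must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _as_plain(obj):
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _build_dataclass(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise PipelineConfigError(f"section {path or '<root>'} must be a mapping")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        where = f"{path}.{sorted(unknown)[0]}" if path else sorted(unknown)[0]
        raise PipelineConfigError(f"unknown configuration key: {where}")
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        sub_path = f"{path}.{name}" if path else name
        if is_dataclass(f.type) or (isinstance(f.type, type) and is_dataclass(f.type)):
            kwargs[name] = _build_dataclass(f.type, value, sub_path)
        elif isinstance(value, dict):
            # nested dataclass declared via default_factory
            factory = f.default_factory  # type: ignore[attr-defined]
            if factory is not dataclasses.MISSING and is_dataclass(factory):
                kwargs[name] = _build_dataclass(factory, value, sub_path)
            else:
                raise PipelineConfigError(f"unexpected mapping at {sub_path}")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise PipelineConfigError(f"invalid configuration in section {path or '<root>'}: {exc}")
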