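"""Deterministic synthetic fundus generator with exact ground truth.

Renders the structures the pipeline assumes: a dark field with a reddish
circular retina, a bright yellowish optic disc (OD), dark branching vessels,
sharp-edged bright exudate blobs whose color is drawn from the OD's intensity
range (deliberately reproducing the exudate/OD confusion the pipeline
addresses), and dark-red hemorrhage dots.  Lesion counts grow with the
disease grade (0 = none .. 4 = proliferative); grade 0 renders no lesions.

Every image is driven by one seed, split into independent per-structure
streams, so toggling lesions does not reshuffle the OD position.  The
returned masks are exact: they mark precisely the stamped pixels.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError
from .types import BinaryMask, ODCircle, RasterImage

__all__ = [
    "GeneratorConfig",
    "SyntheticGroundTruth",
    "generate_fundus",
    "generate_dataset",
]

# lesion counts per grade 0..4; non-decreasing by construction
DEFAULT_EXUDATE_COUNTS = (0, 2, 4, 7, 10)
DEFAULT_HEMORRHAGE_COUNTS = (0, 1, 3, 5, 8)


@dataclass
class GeneratorConfig:
    """Rendering parameters of the synthetic fundus field.

    Radii of the OD scale with the image (a fundus disc occupies a fixed
    fraction of the field of view); lesion radii are in pixels, so lesions
    stay localizable at the 64 px training resolution.
    """

    image_size: int = 256
    od_radius_frac: tuple[float, float] = (0.06, 0.10)
    exudate_counts: tuple[int, ...] = DEFAULT_EXUDATE_COUNTS
    hemorrhage_counts: tuple[int, ...] = DEFAULT_HEMORRHAGE_COUNTS
    exudate_radius: tuple[float, float] = (3.0, 6.0)
    hemorrhage_radius: tuple[float, float] = (2.0, 4.0)
    vessel_count: tuple[int, int] = (2, 4)
    noise_sigma: float = 2.0
    od_contrast_margin: float = 40.0  # required mean OD-vs-background luminance gap
    class_probs: tuple[float, ...] = (0.3, 0.2, 0.2, 0.15, 0.15)

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise InvalidParameterError("image_size must be >= 32")
        if abs(sum(self.class_probs) - 1.0) > 1e-9 or any(p < 0 for p in self.class_probs):
            raise InvalidParameterError("class_probs must be non-negative and sum to 1")
        for counts in (self.exudate_counts, self.hemorrhage_counts):
            if len(counts) != 5 or any(
                counts[i] > counts[i + 1] for i in range(4)
            ):
                raise InvalidParameterError("lesion counts must be non-decreasing over grades 0..4")
        lo, hi = self.od_radius_frac
        if not 0 < lo <= hi < 0.5:
            raise InvalidParameterError("od_radius_frac must satisfy 0 < lo <= hi < 0.5")


@dataclass
class SyntheticGroundTruth:
    """Exact per-image ground truth: the rendering's own bookkeeping."""

    od_circle: ODCircle
    exudate_mask: BinaryMask
    hemorrhage_mask: BinaryMask
    vessel_mask: BinaryMask
    grade: int
    seed: int

    def lesion_mask(self) -> BinaryMask:
        """Union of exudate and hemorrhage masks."""
        return BinaryMask(bits=(self.exudate_mask.bits | self.hemorrhage_mask.bits))


def _stamp_disc(
    image: np.ndarray, mask: np.ndarray, center: tuple[float, float], radius: float,
    color: np.ndarray,
) -> None:
    """Draw a filled disc (sharp edge) and record it in the mask."""
    h, w = mask.shape
    rows, cols = np.ogrid[:h, :w]
    inside = (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2
    image[inside] = color
    mask |= inside


def _stamp_bezier(
    image: np.ndarray, mask: np.ndarray, p0, p1, p2, width: float, color: np.ndarray
) -> None:
    """Rasterize a quadratic Bezier curve as stacked discs of ``width`` radius."""
    length = np.hypot(*(np.asarray(p2) - np.asarray(p0)))
    t = np.linspace(0.0, 1.0, max(int(3 * length), 8))[:, None]
    pts = (1 - t) ** 2 * np.asarray(p0) + 2 * (1 - t) * t * np.asarray(p1) + t**2 * np.asarray(p2)
    h, w = mask.shape
    rows, cols = np.ogrid[:h, :w]
    hit = np.zeros_like(mask)
    for pr, pc in pts:
        hit |= (rows - pr) ** 2 + (cols - pc) ** 2 <= width**2
    image[hit] = color
    mask |= hit


def generate_fundus(
    seed: int, grade: int, config: GeneratorConfig | None = None
) -> tuple[RasterImage, SyntheticGroundTruth]:
    """Render one synthetic fundus image with its exact ground truth.

    Deterministic in ``(seed, grade, config)``.  The RNG is split into
    independent streams per structure (field, OD, vessels, exudates,
    hemorrhages, noise) keyed on the seed.
    """
    cfg = config or GeneratorConfig()
    if grade not in (0, 1, 2, 3, 4):
        raise InvalidParameterError(f"grade must be in 0..4, got {grade}")
    s = cfg.image_size
    streams = [np.random.default_rng(ss) for ss in np.random.SeedSequence(seed).spawn(6)]
    rng_field, rng_od, rng_vessel, rng_exu, rng_hem, rng_noise = streams

    rows, cols = np.ogrid[:s, :s]
    cy = cx = (s - 1) / 2.0
    field_r = 0.47 * s
    dist = np.sqrt((rows - cy) ** 2 + (cols - cx) ** 2)
    in_field = dist <= field_r

    img = np.zeros((s, s, 3), dtype=np.float64)
    base = np.array([170.0, 80.0, 50.0]) + rng_field.normal(0, 5, size=3)
    shading = 1.0 - 0.35 * (dist / field_r) ** 2
    img[in_field] = base[None, :] * shading[in_field][:, None]

    # optic disc: bright yellowish disc at a seeded eccentric position
    od_r = rng_od.uniform(*cfg.od_radius_frac) * s
    od_dist = rng_od.uniform(0.15, 0.30) * s
    od_angle = rng_od.uniform(0, 2 * np.pi)
    od_row = cy + od_dist * np.sin(od_angle)
    od_col = cx + od_dist * np.cos(od_angle)
    od_color = np.array([235.0, 215.0, 150.0]) + rng_od.normal(0, 4, size=3)
    od_mask = np.zeros((s, s), dtype=bool)
    _stamp_disc(img, od_mask, (od_row, od_col), od_r, np.clip(od_color, 0, 255))
    circle = ODCircle(center_a=float(od_col), center_b=float(od_row), radius_r=float(od_r))

    # vessels: dark quadratic Bezier branches radiating from the OD
    vessel_mask = np.zeros((s, s), dtype=bool)
    n_vessels = int(rng_vessel.integers(cfg.vessel_count[0], cfg.vessel_count[1] + 1))
    vessel_color = np.array([70.0, 25.0, 20.0])
    for _ in range(n_vessels):
        ang = rng_vessel.uniform(0, 2 * np.pi)
        end_r = rng_vessel.uniform(0.7, 0.95) * field_r
        p2 = (cy + end_r * np.sin(ang), cx + end_r * np.cos(ang))
        mid_ang = ang + rng_vessel.uniform(-0.6, 0.6)
        p1 = (cy + 0.5 * end_r * np.sin(mid_ang), cx + 0.5 * end_r * np.cos(mid_ang))
        width = rng_vessel.uniform(1.0, max(1.5, s / 128.0))
        _stamp_bezier(img, vessel_mask, (od_row, od_col), p1, p2, width, vessel_color)

    def _place_lesions(rng, count, radius_range, colors, forbid_od: bool, avoid_mask=None):
        mask = np.zeros((s, s), dtype=bool)
        placed = 0
        tries = 0
        grid_r, grid_c = np.ogrid[:s, :s]
        while placed < count and tries < 200 * max(count, 1):
            tries += 1
            r = rng.uniform(*radius_range)
            ang = rng.uniform(0, 2 * np.pi)
            d = rng.uniform(0, 0.85 * field_r - r)
            lr, lc = cy + d * np.sin(ang), cx + d * np.cos(ang)
            if forbid_od:
                # keep exudates clear of the OD so the ground truth is unambiguous
                if np.hypot(lr - od_row, lc - od_col) < od_r + r + 2.0:
                    continue
            elif np.hypot(lr - od_row, lc - od_col) < od_r + r:
                continue
            if avoid_mask is not None:
                blob = (grid_r - lr) ** 2 + (grid_c - lc) ** 2 <= r**2
                if (blob & avoid_mask).any():
                    continue
            color = colors(rng)
            _stamp_disc(img, mask, (lr, lc), r, color)
            placed += 1
        return mask

    if grade == 0:
        exu_mask = np.zeros((s, s), dtype=bool)
        hem_mask = np.zeros((s, s), dtype=bool)
    else:
        # exudate color drawn from the OD's own intensity range
        exu_mask = _place_lesions(
            rng_exu,
            cfg.exudate_counts[grade],
            cfg.exudate_radius,
            lambda r: np.clip(od_color + r.normal(0, 6, size=3), 0, 255),
            forbid_od=True,
        )
        hem_mask = _place_lesions(
            rng_hem,
            cfg.hemorrhage_counts[grade],
            cfg.hemorrhage_radius,
            lambda r: np.clip(np.array([85.0, 20.0, 20.0]) + r.normal(0, 4, size=3), 0, 255),
            forbid_od=False,
            avoid_mask=exu_mask,  # dark dots must not overwrite bright exudates
        )

    if cfg.noise_sigma > 0:
        img = img + rng_noise.normal(0, cfg.noise_sigma, size=img.shape)
    img = np.clip(img, 0, 255)

    truth = SyntheticGroundTruth(
        od_circle=circle,
        exudate_mask=BinaryMask(bits=exu_mask.astype(np.uint8)),
        hemorrhage_mask=BinaryMask(bits=hem_mask.astype(np.uint8)),
        vessel_mask=BinaryMask(bits=vessel_mask.astype(np.uint8)),
        grade=grade,
        seed=seed,
    )
    return RasterImage(pixels=img, color_space="RGB"), truth


def generate_dataset(
    n: int,
    config: GeneratorConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
):
    """Generate ``n`` images with grades drawn from ``config.class_probs``.

    Without ``out_dir`` returns ``(images, truths, grades)`` in memory.  With
    ``out_dir`` additionally writes ``img_*.png``, a ``labels.csv``
    (filename, grade) compatible with training, per-image ground-truth JSON
    under ``truth/`` and the masks as PNGs.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    grades = rng.choice(5, size=n, p=np.asarray(cfg.class_probs, dtype=np.float64))
    image_seeds = rng.integers(0, 2**31, size=n)

    images, truths = [], []
    for g, s in zip(grades, image_seeds):
        img, truth = generate_fundus(int(s), int(g), cfg)
        images.append(img)
        truths.append(truth)

    if out_dir is not None:
        from .io_utils import write_image  # local import: io depends on types only

        out = Path(out_dir)
        truth_dir = out / "truth"
        truth_dir.mkdir(parents=True, exist_ok=True)
        with open(out / "labels.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["filename", "grade"])
            for i, (img, truth) in enumerate(zip(images, truths)):
                name = f"img_{i:04d}.png"
                write_image(img, out / name)
                writer.writerow([name, truth.grade])
                for mask_name, mask in (
                    ("exudate", truth.exudate_mask),
                    ("hemorrhage", truth.hemorrhage_mask),
                    ("vessel", truth.vessel_mask),
                ):
                    write_image(
                        RasterImage(mask.bits * 255.0, color_space="GRAY"),
                        truth_dir / f"img_{i:04d}_{mask_name}.png",
                    )
                with open(truth_dir / f"img_{i:04d}.json", "w") as jf:
                    json.dump(
                        {
                            "od_circle": truth.od_circle.to_dict(),
                            "grade": int(truth.grade),
                            "seed": int(truth.seed),
                            "masks": {
                                m: f"truth/img_{i:04d}_{m}.png"
                                for m in ("exudate", "hemorrhage", "vessel")
                            },
                        },
                        jf,
                        indent=2,
                    )
    return images, truths, [int(g) for g in grades]
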