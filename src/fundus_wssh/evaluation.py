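"""End-to-end study harnesses: seeded synthetic training and evaluation.

These functions wire the full chain together at desk scale — generate a
seeded synthetic cohort, excise the optic disc, train the region-pool
classifier, and score weak localization with the pointing game — and are what
both the test suite and the reproduction script run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cnn_head import TrainConfig, TrainedModel, train_classifier
from .errors import InvalidParameterError
from .od_removal import remove_od
from .synthetic import GeneratorConfig, generate_fundus
from .wssh import pointing_game, upsample_heatmap, wssh_heatmap

__all__ = [
    "make_lesion_cohort",
    "LocalizationStudy",
    "run_localization_study",
]


def make_lesion_cohort(
    n: int,
    seed: int,
    image_size: int = 64,
    lesion_fraction: float = 0.5,
    remove_disc: bool = True,
    config: GeneratorConfig | None = None,
):
    """Generate a lesion-present vs healthy cohort with the disc excised.

    Labels are binary: 0 for grade-0 images, 1 for any lesion grade (drawn
    uniformly from 1..4).  With ``remove_disc`` the generator's own circle is
    cut (fill black, 2 px margin) — the study isolates the localization
    question from disc-detection errors, which are measured separately.

    Returns ``(images, labels, truths)`` with images ``(n, S, S, 3)``.
    """
    if n < 2:
        raise InvalidParameterError("cohort needs n >= 2")
    cfg = config or GeneratorConfig(image_size=image_size)
    rng = np.random.default_rng(seed)
    n_lesion = int(round(n * lesion_fraction))
    grades = np.concatenate(
        [np.zeros(n - n_lesion, dtype=int), rng.integers(1, 5, size=n_lesion)]
    )
    rng.shuffle(grades)
    seeds = rng.integers(0, 2**31, size=n)
    images, labels, truths = [], [], []
    for g, s in zip(grades, seeds):
        img, truth = generate_fundus(int(s), int(g), cfg)
        if remove_disc:
            img, _ = remove_od(img, truth.od_circle, margin=2.0, fill="black")
        images.append(img.pixels)
        labels.append(int(g > 0))
        truths.append(truth)
    return np.stack(images), np.asarray(labels), truths


@dataclass
class LocalizationStudy:
    """Results of one seeded train-and-point study."""

    model: TrainedModel
    hits: int
    total: int
    train_accuracy: float
    test_accuracy: float
    first_epoch_loss: float
    final_epoch_loss: float

    @property
    def hit_rate(self) -> float:
        return self.hits / self.total if self.total else float("nan")


def run_localization_study(
    seed: int,
    n_train: int = 400,
    n_test: int = 100,
    image_size: int = 64,
    epochs: int = 12,
    suppress_od: bool = True,
    config: GeneratorConfig | None = None,
) -> LocalizationStudy:
    """Train on a seeded cohort and run the pointing game on held-out lesions.

    The test cohort is all-lesion (grades 1..4); a hit means the maximum of
    the upsampled WSSH heat map for the lesion class falls inside the union
    of the true exudate and hemorrhage masks.  With ``suppress_od`` the true
    disc mask is zeroed in the heat map first (the images already have the
    disc excised; suppression additionally guards the rim).
    """
    x_train, y_train, _ = make_lesion_cohort(
        n_train, seed, image_size=image_size, config=config
    )
    x_test, _, truths_test = make_lesion_cohort(
        n_test, seed + 1, image_size=image_size, lesion_fraction=1.0, config=config
    )
    model = train_classifier(
        x_train, y_train, TrainConfig(epochs=epochs, seed=seed)
    )
    train_acc = float((model.predict(x_train) == y_train).mean())
    test_acc = float((model.predict(x_test) == 1).mean())

    hits = total = 0
    feats = model.feature_maps(x_test)
    for f, truth in zip(feats, truths_test):
        lesions = truth.lesion_mask()
        if not lesions.bits.any():
            continue
        heat = wssh_heatmap(f, model.class_weights, 1)
        heat = upsample_heatmap(heat, lesions.shape)
        if suppress_od:
            od = truth.od_circle.mask(lesions.shape, margin=2.0)
            vals = heat.upsampled.copy()
            vals[od] = vals.min()
            heat.upsampled = vals
        hits += int(pointing_game(heat, lesions))
        total += 1
    return LocalizationStudy(
        model=model,
        hits=hits,
        total=total,
        train_accuracy=train_acc,
        test_accuracy=test_acc,
        first_epoch_loss=model.loss_history[0],
        final_epoch_loss=model.loss_history[-1],
    )
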