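# fundus-wssh

Weakly supervised lesion localization for diabetic-retinopathy (DR) fundus
photographs. The package implements a four-stage pipeline:

1. **Preprocessing** — median denoising, contrast-limited adaptive histogram
   equalization (CLAHE) on the LAB lightness channel, the gamma mapping
   `I' = 255 · (I/155)^(1/g)`, and optionally the eight-direction Kirsch
   compass edge operator.
2. **Optic-disc removal** — the optic disc (OD) shares the bright yellowish
   intensity of hard exudates, the main source of false lesion detections.
   A classical chain (luminance → automatic between-class-variance
   thresholding → morphological cleanup → circular Hough accumulator with an
   intensity check on the selected circle) finds the disc
   `(x − a)² + (y − b)² = r²` and cuts it out.
3. **Classification** — a small, fully deterministic numpy conv net
   (conv / batch-norm / ReLU / max-pool blocks) ends in a *region pooling*
   layer: each final feature map `f_n(x, y)` is pooled into five units — its
   global average `A_{n1}` plus the four spatial quadrants `A_{n2}..A_{n5}` —
   and a linear class layer `S_c = Σ_n Σ_j w_{nj}^c A_{nj}` feeds the softmax
   `P_c = e^{S_c} / Σ e^{S_c}`. Training is SGD with momentum 0.9, weight
   decay 1e-4 and a plateau learning-rate schedule
   (0.1 → 0.01 → 0.001 → 0.0001 at epochs 25/37/45).
4. **WSSH localization** — with no box annotations, the fitted class weights
   are reused as localization weights. The class-sensitive heat map is
   `H_c(x, y) = Σ_n w_n^c f_n(x, y)`; the Weakly Supervised Sensitive
   Heatmap combines the global and quadrant weights,
   `I_cj(x, y) = Σ_k (w_{k1}^c / 4 + w_{kj}^c) f_k(x, y)` for j = 2..5, and
   takes their elementwise maximum. Thresholding at a fraction of the heat
   maximum yields lesion bounding boxes; boxes that would cover the removed
   disc are suppressed. The score identity
   `S_c(WSSH) = (1/N_1) Σ_{x,y,n} w_n^c f_n(x,y) = mean H_c` ties the
   classifier to the localizer exactly.

A deterministic synthetic-fundus generator (dark circular field, bright OD,
vessels, exudate blobs drawn from the OD's own color range, hemorrhage dots,
grade-dependent lesion counts, exact ground-truth masks) makes the whole
pipeline testable without any external dataset.

The package is for computer-vision researchers and engineers prototyping
weakly supervised retinal-lesion localization; it is not a clinical tool.

## Worked example

```python
import numpy as np
from fundus_wssh import (
    generate_fundus, detect_od, remove_od, WSSHClassifier, BinaryMask,
)
from fundus_wssh.evaluation import make_lesion_cohort

# seeded synthetic cohort, optic disc already excised, labels 0=healthy 1=lesion
X, y, truths = make_lesion_cohort(120, seed=1, image_size=64)

clf = WSSHClassifier(epochs=12, random_state=1).fit(X, y)
print("train accuracy:", (clf.predict(X) == y).mean())

img, truth = generate_fundus(seed=123, grade=3)   # a fresh 256 px fundus
circle = detect_od(img)
print("detected OD:", circle.to_dict())
print("true OD:    ", truth.od_circle.to_dict())
```

Output from this exact session:

```
train accuracy: 1.0
detected OD: {'a': 92.0, 'b': 159.0, 'r': 22.0, 'score': 0.8213854295317184}
true OD:     {'a': 92.19413862219557, 'b': 158.77654482762262, 'r': 21.02262459931275, 'score': 0.0}
```

The printed circle is the detector's estimate: column `a`, row `b`, radius
`r` in pixels, and its combined vote-times-brightness score (the truth
record carries no score). On this image the center is recovered to within a
quarter pixel and the radius to about 5%.

Lesion boxes with disc suppression:

```python
od_mask = BinaryMask(truth.od_circle.mask(img.pixels.shape[:2]).astype("uint8"))
rois = clf.localize(img.pixels, target_class=1, od_mask=od_mask)
```

Each returned ROI is `{"bbox": [r0, c0, r1, c1], "peak": [r, c], "score": v}`
(0-based, half-open); no box ever intersects the disc mask.

## Command line

```bash
fundus-wssh synth --n 400 --size 256 --out data/          # synthetic dataset
fundus-wssh preprocess IN.png OUT.png --gamma 1.2
fundus-wssh remove-od IN.png OUT.png --circle-out circle.json
fundus-wssh train data/labels.csv --images data --epochs 60 --out model.npz
fundus-wssh localize IN.png --model model.npz --roi-out roi.json
fundus-wssh run IMG1.png IMG2.png --model model.npz --out results/
```

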