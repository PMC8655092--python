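# Methods

## The problem and the model

Hard exudates — sharp-edged, yellowish lipid deposits — are the earliest
reliably visible lesion of diabetic retinopathy, and they share their color
with the optic disc (OD). A classifier trained only on image-level DR grades
can still localize lesions: the linear layer that maps pooled final-layer
activations to class scores assigns each feature map a per-class weight, and
re-applying those weights *spatially* turns the feature maps into a
class-sensitive heat map. This package implements that weakly supervised
chain, with the disc removed (or suppressed in heat-map space) so that
exudate evidence is never confused with the disc.

### Heat maps and the score identity

With final-layer activations `f_n(x, y)` and per-class weights `w_nj^c`
(region j = 1 the whole map, j = 2..5 the four spatial quadrants):

- plain class activation map: `H_c(x, y) = Σ_n w_{n1}^c f_n(x, y)`;
- region maps: `I_cj(x, y) = Σ_k (w_{k1}^c/4 + w_{kj}^c) f_k(x, y)`,
  j = 2..5. The divisor 4 mirrors the four sub-regions: each quadrant unit
  accounts for a quarter of the global average, so the global weight enters
  each region map at quarter strength;
- combined saliency: the elementwise maximum over `I_c2..I_c5`. The
  combination rule is a design choice of this package; the maximum keeps
  evidence visible whichever quadrant's weights carry it. The four region
  maps are also exposed individually.
- score: `S_c(WSSH) = (1/N_1) Σ_x Σ_y Σ_n w_{n1}^c f_n(x, y)`, which equals
  the spatial mean of `H_c` exactly (the class layer has no bias), so the
  localizer explains precisely the quantity the classifier scored. The test
  suite checks this identity on a thousand random draws at 1e-6 relative
  tolerance.

Boxes come from "basic thresholding": binarize the (bilinearly upsampled,
corner-aligned) heat map at `frac · max`, default `frac = 0.2` — the common
choice in the class-activation-mapping literature — take 8-connected
components, one box per component, sorted by descending peak with row-major
tie-break. Heat maps are not ReLU-clipped before thresholding by default
(`clip_negative` exists). When an OD mask is supplied, its pixels are zeroed
first and any component whose bounding box would still cover disc pixels is
discarded as a disc-adjacent false positive; this makes "no returned box
intersects the disc" a hard guarantee rather than a tendency.

## Preprocessing

Stage order is median → CLAHE → gamma → (optional) Kirsch; all 3×3
neighborhood operators replicate edge pixels at the border (no dark halos).

- **Median filter**: default 3×3, the smallest edge-preserving window.
- **CLAHE** runs on an integer-quantized L channel of the LAB conversion
  only; a and b are untouched. Defaults: clip limit 2.0 (as a multiple of
  the uniform histogram height), 8×8 tiles — common fundus-enhancement
  practice. The implementation is the standard tile algorithm (clip,
  redistribute excess uniformly, map by `m(i) = (L−1)·cdf(i)`, interpolate
  mappings bilinearly between tile centers) written directly so that the
  single-tile unclipped case reduces *exactly* to plain histogram
  equalization — a reduction the test suite pins against a from-scratch
  CDF oracle.
- **Gamma** is `I' = 255·(I/155)^(1/g)` with the denominator 155 kept as
  specified and a clamp at the range maximum: inputs above 155 saturate.
  Default `g = 1.2`, a mild lightening that helps expose the OD rim in dark
  images; the mapping is monotone for every `g > 0`.
- **Kirsch** uses the canonical eight ±5/∓3 compass kernels (coefficients
  sum to zero, so flat regions respond zero; the set is closed under 90°
  rotation). `rescale=False` returns raw responses for oracle comparison;
  by default the map is min-max scaled into the value range.

## Optic-disc detection

The disc is the brightest disc-shaped structure of OD scale. Detection:

1. luminance (BT.601), Gaussian-smoothed (σ = 2);
2. two exhaustive between-class-variance threshold scans (written out
   rather than delegated, so the scan and its tie-break — smallest
   maximizer — are bit-reproducible): the first separates the retinal field
   from the dark surround, the second, restricted to in-field pixels,
   separates bright structures from the retinal background. A single scan
   would split field-versus-surround and call the whole field "bright";
3. morphological closing (disk radius 5) heals vessel segments crossing the
   disc, then opening with a disk of radius `r_min` deletes every bright
   blob smaller than the allowed disc scale — exudates cannot survive it;
4. the Sobel boundary of the cleaned mask votes in a circular Hough
   accumulator (radii `0.03..0.15 · min(H, W)` by default, votes normalized
   by circumference);
5. among candidates within 80% of the best vote, the selected circle is the
   one maximizing `vote · (interior bright fraction − surrounding-ring
   bright fraction)` — an intensity check on the selected circle that
   rejects bright-ring impostors and circles nested inside the disc. Ties
   break to the smaller radius, then row-major center order, so detection
   is fully deterministic.

An image with no bright structure, or whose best vote falls below the floor
(0.25), raises a no-disc-found error rather than returning a guess.

Disc removal fills all pixels with
`(x−a)² + (y−b)² ≤ (r + margin)²` (boundary included), default margin 2 px,
fill black or the median background intensity. Binary opening/closing are
computed on a zero-padded domain and cropped, i.e. they equal the ideal
full-plane operators restricted to the window — this keeps opening
anti-extensive and closing extensive at the border, which the naive
border-as-background composition violates. Grayscale dilation follows the
supremum form `sup_y [f(y) + b(x−y)]` with edge replication.

The adjacent-pixel luminance product `G(i,j) = L(i,j)·L(i,j+1)` is available
behind a flag (`eq4_product`) as a contrast-exaggerating grayscale variant;
the default conversion is the standard weighted sum, which downstream stages
assume.

## Classifier

The backbone is deliberately small — three conv(3×3)/batch-norm/ReLU blocks
(8, 16, 32 channels), max-pooled after the first two blocks only — and is a
plug-in: anything with the same forward/backward/parameters surface can
replace it. Keeping the last block unpooled leaves 16×16 final maps for a
64 px input; heat-map peaks land on the upsampling grid of the final maps,
so halving the stride measurably sharpens localization (coarser 8×8 maps
cost several pointing-game points from quantization alone).

Training protocol: cross-entropy over the softmax (the head implies the
loss), SGD with momentum 0.9, weight decay 1e-4 folded into the gradient as
`λ·w`, batch size 32, learning rate 0.1 with plateau drops to 0.01 / 0.001 /
0.0001 after epochs 25 / 37 / 45 (each change takes effect the epoch after
the milestone; the rate before the first milestone is the first plateau's
value). The standalone `momentum_update` also offers a strict-as-printed
mode in which the scalar penalty value `(λ/2n)Σw²` itself is added to the
velocity; the default uses the penalty's gradient, which is the
dimensionally consistent reading. Batch normalization follows each
convolution and non-linearity; its statistics use the biased `1/n` variance.
Local response normalization (offset 2, scale 1e-4, exponent 0.75,
5-channel neighborhood) is implemented but off by default — modern backbones
omit it. Everything is plain float64 numpy under one seeded generator, so
training is bit-reproducible; no GPU framework is involved.

## Synthetic generator

The generator emulates exactly the structures the pipeline reasons about:

- a reddish retinal field (radius 0.47·size) with radial shading on black;
- a bright yellowish OD, radius 6–10% of the image, center 15–30% of the
  image away from the field center, at a seeded angle;
- 2–4 dark quadratic Bézier vessel branches radiating from the disc (visual
  plausibility only; nothing segments them);
- exudates as sharp-edged discs of 3–6 px whose color is drawn from the
  OD's own color ±6 — deliberately reproducing the disc/exudate confusion —
  kept at least 2 px clear of the disc so localization ground truth is
  unambiguous; lesion radii are fixed in pixels (not a fraction of the
  image) so lesions remain localizable at the 64 px training size;
- hemorrhages as dark-red dots of 2–4 px, never overlapping exudates;
- lesion counts per grade 0..4: exudates (0, 2, 4, 7, 10), hemorrhages
  (0, 1, 3, 5, 8) — zero at grade 0 by construction, non-decreasing in
  grade;
- Gaussian pixel noise σ = 2.

One seed drives six independent substreams (field, OD, vessels, exudates,
hemorrhages, noise), so toggling lesions does not move the disc. Masks mark
exactly the stamped pixels.

What the generator does *not* emulate: camera optics, illumination
gradients beyond radial shading, vessel tortuosity/branching realism,
microaneurysm-vs-hemorrhage distinction, lesion texture, inter-image scale
variation. Passing tests therefore demonstrate that the *mechanism* works
under the stated geometry and contrast assumptions — not clinical
performance on MESSIDOR/APTOS-like data, which would require the full-scale
backbone and real images and is out of scope here.

## Study conditions and numerical choices

- OD recovery study: 50 seeded 256×256 images across all grades; success =
  center error ≤ 5 px and radius error ≤ 10%.
- Suppression study: 100 seeded 64×64 images, heat maps from a seeded
  untrained backbone with random class weights (suppression is a structural
  property of box extraction, not of training); violation = any box
  intersecting the true disc mask.
- Localization study: 400 training images at 64×64 (half healthy, half
  lesion grades 1–4 uniformly), disc excised with the generator's own
  circle so disc-detection error is measured separately, 12 epochs, batch
  32; evaluation on 100 held-out all-lesion images by the pointing game
  (hit = heat argmax inside the union lesion mask, disc suppressed with a
  2 px margin). Twelve epochs at this cohort size sit well inside the
  schedule's first plateau and converge to near-zero training loss; the
  printed 60-epoch protocol remains the default of `TrainConfig`.
- Upsampling and ROI warping use corner-aligned bilinear interpolation
  (`map_coordinates`, order 1): source grid points map exactly, so a
  same-size warp is the identity and heat-map order is preserved at grid
  points.
- Ties everywhere (thresholds, accumulator peaks, pool argmax, ROI order,
  heat argmax) resolve to the first candidate in row-major / smallest-value
  order; this is what makes two runs byte-identical.

## Known limitations

- The intensity-checked Hough detector assumes one dominant bright disc; on
  images with a brighter-than-disc artifact of disc scale it will lock onto
  the artifact (it reports its combined score, so callers can gate on it).
- The numpy backbone is CPU-bound and desk-scale; it is the scaffolding for
  the localization layer, not a competitive DR grader.
- `heatmap_to_roi` discards disc-adjacent components entirely rather than
  re-segmenting them; a lesion hugging the disc rim can be lost from the
  box list (it remains visible in the heat map).
- The five-region pooling uses fixed half-split quadrants; odd map sizes
  make quadrants unequal, and the quadrant/global mean identity then holds
  only approximately.
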