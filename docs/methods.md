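# Methods

## Pipeline model and assumptions

The package scores estrogen-receptor status on RGB histology fields
(nominally 20×, 0.243 µm/pixel) in four stages: distance-transform score-map
regression for cell detection, a weighted-HSV rule for positive/negative
stain classification, a small convolutional classifier for
weak/moderate/strong grading, and Allred scoring of the resulting slide
composition. The method assumes brightfield ER-IHC appearance: negative
nuclei carry a blue/purple hematoxylin counterstain, positive nuclei a brown
DAB reaction product whose darkness increases with expression strength. It
detects *cells*, not segmentation masks: only centroids feed the downstream
stages, so boundary accuracy matters only insofar as it perturbs centroids.

## Cell detection

**Score target.** For annotated centroids, the regression target at pixel
*p* is s(p) = max(0, 1 − d(p)/R), where d(p) is the Euclidean distance to
the nearest centroid and R the nominal cell radius. The linear cone is the
simplest form consistent with a fixed detection threshold: at the default
threshold 0.2 a detected region is the 0.8·R iso-disc around each cell.

**Network.** The default regressor is a same-resolution stack of seven
3×3 conv+ReLU blocks (8 channels) and a linear 3×3 output convolution — 15
layers, receptive field 17 px. A same-resolution stack keeps inference
fully convolutional and exactly translation-equivariant and avoids
upsampling artifacts at cell-scale structures; pooling/upsampling layers
exist in `er_allred.nn` and any architecture can be passed to
`train_detector` via a config list. The receptive field does not span a
whole 2R cone; the net therefore reproduces the cone's peak and inner slope
and underestimates the far skirt, which detection does not use.

**Training.** 64×64 windows centered on each annotated cell plus an equal
number of background windows whose centers lie ≥ R from every centroid;
MSE loss, SGD (momentum 0.9), two-phase learning rate (1e-2 for the first
10 epochs, 1e-4 after), horizontal-flip augmentation, He-scaled zero-mean
Gaussian init. All randomness derives from one integer seed; training is
bit-reproducible single-threaded.

**Extraction.** The predicted map is lightly smoothed (Gaussian,
`smooth_sigma`, default 2 px ≈ R/10 at the synthetic scale) to suppress
regression noise that would otherwise seed duplicate maxima inside one
nucleus; the smoothed map is thresholded at `score_threshold` (0.2), local
maxima with minimum separation R/2 (ties resolved in row-major order) seed
a marker-controlled watershed inside the mask, and regions failing the area
rule are dropped. The area rule defaults to a *minimum* of 240 px²:
removing sub-240 px² fragments discards watershed debris, while a
radius-32 cell covers ~3200 px², so a maximum reading would delete every
true cell; the direction is exposed (`area_is_minimum`) for other
magnifications. Each surviving region reports its score-weighted centroid
(`regionprops` weighted centroid), which recovers the apex of an ideal cone
exactly and is more robust than the mask centroid when the watershed cut is
asymmetric.

## Positive/negative classification

A 32×32 patch is extracted around each centroid (reflection padding at
image borders) and converted to HSV with all channels scaled to 0–255 —
the only scale on which the two decision thresholds (hue 40, value 50) are
simultaneously sensible, with brown at hue ≈ 10–35 and blue at ≈ 140–175.
Weighted hue and value use the weight w(p) = 1 − d(p)/d_max with d(p) the
distance to the patch center and d_max the patch half-diagonal measured
over the full square (so every pixel keeps a strictly positive weight);
the weighting downweights neighbouring cells caught at patch edges. The
hue average is arithmetic, not circular: both stain families sit far from
the 0/255 hue wrap, so circular averaging is unnecessary — a documented
limitation for stains near the wrap point. Decision rule, in order:
wV < 50 → positive; wH ≤ 40 → positive; otherwise negative. The boundary
values (wH exactly 40 positive, wV exactly 50 not dark) are a fixed
convention.

## Weak/moderate/strong classification

Nine weight layers: four pairs of back-to-back padded 3×3 convolutions
(8-8, 12-12, 16-16, 16-16 channels) with 2×2 max-pooling after the first
three pairs, dropout (0.25) before a fully connected softmax over the
three grades. Training uses SGD with the same two-phase schedule
(1e-2/1e-4, switch at epoch 10), batch 32, and flip + random-crop
(28×28, nearest-resized back) + per-channel standardization augmentation.
The default budget of 600 epochs suits slide-scale data; the synthetic
benchmark separates at 15 epochs. Ties in the argmax resolve toward the
stronger class — a deterministic choice that errs toward recommending
treatment. The class posterior is an explicit softmax and sums to 1.

## Allred scoring

Proportion bins use real-valued edges 1/10/33/66 with the half-open
intervals listed in `er_allred.allred`; this is the only edge placement
consistent with every row of the packaged reference table (e.g. 49.47 % →
4, 73.15 % → 5). The intensity score comes from the argmax of the
positive-class proportions, not a weighted average — confirmed by the
reference rows where a strong majority at 0.19 % positivity yields
intensity 3 and a weak numeric maximum yields intensity 1. Scores of 3–8
set the treatment flag. Results with 0 < p < 0.1 % carry a
`low_positivity` flag rather than any score correction: trace positives on
truly negative slides are reported, not silently suppressed.

One row of the packaged table (slide 05459) has class proportions that do
not sum to its ER percentage (a transcription artifact in the source); it
is flagged in the fixture and excluded from exact-reproduction checks,
though its printed scores happen to be reproduced as well because the
proportion score depends only on the ER percentage column.

## Synthetic data

The generator renders elliptical nuclei (major semi-axis uniform 12–20 px,
axis ratio 0.65–1, random rotation) in per-class HSV distributions —
negatives at hue ≈ 155, the three positive grades at hue ≈ 18–22 with
value means 170/110/45 (weak/moderate/strong) — on a warm bright
background (RGB 243/235/224), with per-nucleus and per-pixel HSV jitter
and additive Gaussian sensor noise (sd 3 by default, 8-bit units). Overlap
is controlled by center-distance rejection (1 − d/(r₁+r₂) capped at
`max_overlap_fraction`, default 0.1) with a bounded attempt budget.
Background hue sits in the warm band so that low-saturation noise cannot
flip it across the blue/brown separatrix, keeping the default palette
consistent with the positive/negative thresholds by construction.

What the simulator deliberately omits: Beer–Lambert stain mixing and
deconvolution structure, tissue architecture (glands, stroma, clustered
growth), non-tumor cell types, scanner artifacts beyond Gaussian noise,
and staining-quality variation between slides. Passing synthetic
benchmarks therefore demonstrates the internal consistency of the pipeline
(detection recovers rendered ground truth, classification recovers the
generating palette, scoring maps compositions to the intended scores) —
not clinical-grade performance on real slides, where stain variability and
tumor/stroma discrimination dominate the error budget.

## Benchmark problem sizes

The test suite trains the detector on six 256×256 fields of 25 nuclei
(8 epochs) and the grade classifier on 150 patches per class (15 epochs),
then evaluates on two held-out 448×448 fields totalling 200 nuclei and on
five 512×512 slides composed to span Allred scores {0, 2, 3, 5, 8}. The
score-target radius for these runs is R = 20 px, matching the synthetic
nucleus scale, while `DetectionParams` defaults to the paper-scale
R = 32 px; R is a data property, set once per magnification/cell-size
regime. Both networks train in well under a minute of single-threaded CPU.

## Numerical conventions

Coordinates are 0-based pixels, x = column, y = row, everywhere including
CSV files. Images are 8-bit RGB. All stochastic steps consume
`numpy.random.default_rng(seed)` generators threaded from a single
user-supplied seed; fixed seeds give byte-identical scenes, training
curves, and reports under single-threaded execution. Model archives are
self-describing npz files (architecture config + weights + normalization
constants). Degenerate inputs fail loudly: empty slides are not scorable,
an Allred total of 1 is rejected wherever it could be injected, images
smaller than the receptive field are refused, and malformed annotation
rows report their line number.

## Known limitations

- The weighted hue is non-circular; palettes straddling the hue wrap
  would need a circular mean.
- The detector's receptive field (17 px default) truncates the score
  cone's skirt; detection is unaffected but predicted maps are not
  calibrated proximity estimates far from cells.
- Seam deduplication merges detections within 8 px across tile borders;
  a cell split exactly on a seam into two centroids > 8 px apart can be
  double-counted.
- No tumor/stroma discrimination: every detected nucleus enters the
  denominator of the ER percentage.
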