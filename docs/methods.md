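# Methods

`rcquant` quantifies rotator cuff (RC) muscle degeneration on 2D
sagittal-oblique shoulder CT sections in two stages: (1) a convolutional
network predicts the *premorbid* boundary of each muscle — the
cross-section the muscle occupied before degeneration, inferred from the
surrounding bony anatomy rather than directly visible in the image — and
(2) Hounsfield-unit thresholds classify the tissue inside that boundary
into residual muscle, fat and bone, from which atrophy, fatty
infiltration, secondary bone formation and overall degeneration ratios
are computed.  A STAPLE fusion of multiple human delineations provides
the reference against which automatic segmentations are evaluated.

## Degeneration model

Let S be the premorbid cross-sectional surface of one muscle (pixel
count, convertible to mm² via the pixel spacing).  Thresholding HU > −29
inside S, removing islands (largest 8-connected component) and filling
4-connected holes gives Sa, the outer boundary of the residual/atrophied
muscle; enclosed fat pockets and bone islands therefore count toward Sa.
Within Sa, fatty infiltration Si is the surface below −29 HU and
secondary bone formation So the surface above 166 HU.  The ratios are

    Ra = (S − Sa) / S          atrophy
    Ri = Si / S                fatty infiltration
    Ro = So / S                secondary bone formation
    Rd = Ra + Ri + Ro          overall degeneration

so every ratio is 0 for a fully healthy muscle and Rd = 1 for a
completely degenerated one.  A variant found in parts of the literature
writes Ra = Sa/S and Rd = (Sa + Si + So)/S; that form assigns Rd = 1 to
a *healthy* muscle, contradicting the 0/1 anchors, so it is available
only behind `QuantConfig(printed_formulas=True)`.

Threshold strictness: residual muscle is HU > −29, fat HU < −29, bone
HU > 166, all strict.  A pixel exactly on a threshold belongs to no
tissue class but can still enter Sa through hole filling; on calibrated
integer HU data the boundary set has measure zero.

## Network

The premorbid network is a U-Net-style encoder–decoder with skip
connections, modified to use a *single* convolution (+ batch
normalization + ReLU) after every down- and up-sampling step.  With the
full-resolution configuration — 512×512 input, 4 max-pooling stages, 32
channels after the first convolution, doubling per level — the
bottleneck is a 32×32 representation with 512 channels, and the output
is a single-channel sigmoid probability map at input resolution.
Up-sampling is ×2 bilinear interpolation followed by one convolution;
down-sampling is 2×2 max pooling.  One independent binary network is
trained per muscle per cross-validation fold (4 muscles × 5 folds = 20
networks in the full protocol).

The layers are implemented in a small self-contained numpy engine
(`rcquant.nn`): im2col convolution, batch normalization, max pooling and
bilinear up-sampling with hand-derived backward passes, Adam, and a
per-sample soft-Dice loss (suited to class-imbalanced binary
segmentation).  Everything is float32, CPU-only and deterministic given
the seeds; gradients were verified against finite differences.

Unstated details resolved as follows: loss soft Dice, optimizer Adam
(defaults exposed in `TrainConfig`), ReLU nonlinearities, He-normal
initialization, checkpoint selection by validation Dice on a small
case-level split (default 1 % of cases, at least one case).  Input HU
values are windowed to [−1000, 400] and scaled to [0, 1]; the floor sits
at air so that partial-volume pixels on tissue/background interfaces
keep a graded value — clipping them to the background level measurably
shrinks predicted boundaries and biases the atrophy ratio downward.

## Augmentation and cross-validation

Training sets are expanded tenfold by default: the original is kept as
one of the ten, and nine copies are drawn with a random scale uniform in
±20 % and a random rotation uniform in ±90°, drawn independently and
applied jointly to the image (linear interpolation, background fill at
−1000 HU) and all masks (nearest neighbor).  Augmented items are lazy
and carry provenance (source case, rater, scale, angle).

Cross-validation folds are assigned at the *case* level: all augmented
copies of a case, and all raters' delineations of it, share the case's
fold, so no network is evaluated on a case it saw in any form.  Note one
bookkeeping consequence: 103 cases × 3 raters × 10 = 3090 items per
muscle split five ways equally only at the item level (618 per fold);
case-level folds of 20–21 cases hold 600–630 items.  The package trains
with case-level folds and reports the item-level 618 as the protocol's
fold-size arithmetic.

## STAPLE reference

Multi-rater references use binary STAPLE
(expectation-maximization estimation of the latent true segmentation
with per-rater sensitivity p and specificity q).  Defaults follow the
reference conventions: p = q = 0.99999 initially, scalar foreground
prior equal to the mean foreground fraction across raters, convergence
at max |ΔW| < 1e−6 (cap 100 iterations).  The E-step runs in log space;
the data log-likelihood is recorded per iteration and is non-decreasing.
Computation is restricted to a bounding box around the union of the
rater masks (8 px margin) with outside pixels fixed to background —
otherwise specificity estimates are dominated by arbitrarily large empty
background, which changes q numerically (documented, configurable).
Ties at W = 0.5 binarize to foreground.

## Evaluation

Dice is 2|A∩B|/(|A|+|B|); two empty masks score 1 (agreement on
absence).  The Hausdorff distance is the symmetric variant — the larger
of the two directed maxima of nearest-neighbor Euclidean distances —
over boundary pixels (foreground pixels with a 4-neighbor background),
scaled per axis by the pixel size and reported in mm.  Paired Student
t tests compare automatic-vs-reference Dice with per-case mean
inter-rater Dice; zero-variance differences are flagged as degenerate
rather than producing a spurious statistic.  Agreement between predicted
and reference degeneration ratios is summarized by ordinary least
squares (slope, intercept, R², Pearson r), predicted regressed on
reference.

## Synthetic phantoms

Patient data cannot ship with the package, so every stage is exercised
on synthetic sections that emulate the *structure* of the task: four
star-convex muscle blobs (low-order Fourier perturbations of circles)
arranged around a central high-HU bone structure standing in for the
scapula, on a background at air HU.  Default tissue means are fat −100,
muscle +50, bone +300, background −1000 HU — comfortably separated by
the −29/166 thresholds — with additive Gaussian noise (SD 5 HU) clipped
per tissue class so it can never cross a threshold.

Degeneration is rendered with exact pixel bookkeeping: atrophy removes
exactly round(Ra·S) outermost pixels by uniform radial shrink (the
residual stays star-convex, hence connected) and re-renders them at fat
HU; fatty infiltration and bone formation carve compact pockets of
exactly round(Ri·S) and round(Ro·S) pixels inside the residual muscle,
by default fully enclosed behind a ≥ 1 px muscle wall so hole filling
must recover them (a flag allows boundary-touching pockets).  As a
consequence, quantification with the true premorbid mask reproduces the
generator's recorded measures *exactly* — the round-trip identity that
anchors the test suite.  Simulated raters displace the true boundary
radius with a smooth zero-mean random field whose standard deviation is
set in mm (default 0.5 mm), emulating independent human delineations
while keeping each mask a single connected component.

What the phantoms do not emulate: anatomically realistic shapes,
scanner noise spectra and reconstruction kernels, non-star-convex
muscles, soft-tissue masses, and contested muscle/bone interfaces.
Passing the phantom study therefore demonstrates that the pipeline's
machinery — boundary learning from context, thresholds, STAPLE, fold
hygiene, metrics — is correct and internally consistent; it does not
certify clinical accuracy on patient scans.

## Desk-scale study profile

The full protocol (512×512 inputs, ~100 h of training) is supported in
configuration but not exercised by the test suite.  The default study
profile (`desk_study_config`) scales the same design down: 40 phantom
cases rendered at 128×128 (0.5 mm pixels), 3 simulated raters
(0.5 mm boundary SD), STAPLE references, twofold augmentation (±10 %
scale, ±15° rotation — modest, since muscle identity on a phantom is
positional), and fivefold cross-validation of a 64×64-input, depth-4,
base-8 network per muscle (20 networks), trained 8 epochs with Adam at
lr 5e-3, batch 8.  Sections and rater masks are resampled to 64×64 for
the network; predictions are upscaled back to 128×128
(nearest-neighbor), cleaned (largest component, hole filling) and
quantified at native resolution — the same resample/upscale convention
the full protocol uses between 512 and 1024.

One scale limitation is worth stating: a mild atrophy fraction at this
resolution corresponds to a fat band only 1–2 px wide, so the atrophy
ratio is the most discretization-sensitive of the four; its regression
slope against ground truth sits a few points below the
fatty-infiltration and bone slopes, which are essentially unity.  The
overall degeneration ratio Rd is the profile's headline quantification
check.

## Numerical and degenerate-input conventions

* Largest-component ties break to the lowest label id (deterministic).
* A fully degenerated muscle legitimately yields an empty Sa (Ra = Rd
  = 1); an empty *premorbid* mask is an error (quantification needs S > 0).
* Empty network predictions survive postprocessing as empty masks and
  are flagged in study outputs (`empty_auto_mask`), excluded from
  Dice/Hausdorff records (Hausdorff is undefined for empty masks).
* Masks resample with nearest neighbor everywhere and stay strictly
  {0, 1}; HU images resample linearly without anti-aliasing filters,
  which could otherwise push values across tissue thresholds.
* All randomness flows from explicit seeds through
  `numpy.random.Generator`; cohort generation, augmentation draws,
  fold assignment and training are bit-reproducible on one platform.
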