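# Methods

This note documents the models, parameters and design choices behind
`edcrowd`, in the order the pipeline runs.

## Density-map ground truth

Head-point annotations are turned into an impulse grid (value = head
multiplicity at each annotated pixel, so coincident heads accumulate) and
each head then deposits a truncated 15 × 15 Gaussian kernel with σ = 4 px
centred on its pixel. Literal Gaussian filtering of the impulse grid loses
mass wherever a kernel overhangs the image border, which would break the
defining property that the map's total pixel value equals the head count.
We therefore renormalize each head's in-bounds kernel portion to unit mass,
making mass conservation exact for any annotation set, including corner
heads. Away from borders (heads ≥ 7 px from every edge) this is identical
to plain Gaussian filtering, which the test suite verifies against
`scipy.ndimage` convolution as an independent oracle. Coordinates are
0-based with x = column, y = row; the kernel centre sits on the annotated
pixel.

## The counting network

The MFCNN is fully convolutional, NCHW, float32, built on the package's own
NumPy reverse-mode autodiff engine (conv2d with stride/dilation, ReLU,
sigmoid, nearest-neighbour resize, global average pooling, strip
slice/concat — each op's backward pass is verified against numerical
directional derivatives in the tests).

Architecture, with `base_width` w (default 32) channels throughout:

1. **Input block**: two stride-2 3×3 convolutions reduce each spatial
   dimension to a quarter ("quarter of original size" is read
   per-dimension; a 1/2-per-dimension variant is configurable).
2. **Encoder**: four stages, each a stride-2 downsampling convolution
   followed by `blocks_per_stage[i]` bottleneck residual blocks
   (1×1 reduce to w/2 → 3×3 → 1×1 expand to w, identity shortcut). The
   schedule must be non-decreasing; the default (1, 2, 3, 4) is the
   smallest schedule that deepens with depth. A 128 px input yields
   encoder maps at 32, 16, 8, 4 and 2 px.
3. **Decoder**: the deepest map is repeatedly resized (nearest-neighbour)
   to the next shallower skip's exact size, projected by a 1×1
   convolution, added to the skip and rectified. Resizing to the skip's
   size (rather than a fixed ×2) keeps odd-sized inputs consistent.
4. **Fine-grained regressor**: the quarter-resolution fused map is cut
   into `strip_count` horizontal strips and, independently, vertical
   strips (zero-padded to divisibility, cropped after splicing). Each
   strip passes through a bottleneck block whose parameters are shared
   across strips within a dimension, so the parameter count is independent
   of `strip_count`. The width- and height-enhanced maps are fused by
   addition.
5. **Regression head**: global average pooling followed by a 1×1
   convolution produces a sigmoid channel gate; the gated features pass a
   1×1 convolution to a single-channel quarter-resolution map. No fully
   connected layer anywhere, so arbitrary input sizes ≥ 64 px work without
   rebuilding.
6. **Output**: the coarse map is resized to the input size and refined by
   a 3×3 dilated (rate-2) convolution; a final rectifier enforces
   non-negativity. The predicted count is the map total.

The output pathway (final 1×1 and refine convolutions) is initialized near
zero with a small positive refine bias, so initial count predictions start
near zero and the output rectifier has live gradients; all other weights
are He-normal from the config seed.

## Training

Adam at a fixed learning rate (default 1e-5), batch size 8, 50 epochs by
default. The loss is pixel-wise squared error between predicted and
ground-truth density maps, summed over pixels and averaged over the batch —
the standard objective for density regression (no loss is prescribed by the
measurement design itself). A `val_fraction` split (default 0.2) is carved
off with the training seed; per-epoch training loss and validation
MCE/RMSE are recorded, and the weights of the epoch minimizing validation
MCE are returned. When the validation split rounds to zero, validation
metrics fall back to the training set. Training is bit-reproducible for a
fixed seed on a single device. A capacity smoke test in the suite overfits
20 synthetic 64×64 scenes (counts 0–12) with an 8-channel network for 300
epochs at lr 1e-4 to a training MCE below one person in about a minute on
one CPU core.

## Sampling design

One one-minute video per half hour per area; frames at 0.2 FPS. Sixty
seconds at 0.2 FPS admits 12 grid points, and the design keeps the first
10 (offsets 0–45 s) — the cap is explicit in `SamplingPlan`. Bounded
operating windows include both endpoints on the half-hour grid (8:00–18:00
→ 21 slots; the only convention consistent with 21 videos/day for a
10-hour window), and 24-hour areas use the full 48-point grid. Slot counts
are the arithmetic mean over the slot's frames; count tables store exact
means and round only at report time (half away from zero, configurable).

## Congestion rate

`N_theoretical = area / (π d²)` with d = 1.2 m (Hall's personal distance)
as the default, exposed as a parameter rather than hard-coded;
`R_c = N_actual / N_theoretical`. Mean occupancy for an area is the mean
over its operating-hour slots only (e.g. a 10-hour area has 147 weekly
slots). Time-resolved profiles offer a centred moving-average smoothing
(default window 3 slots) standing in for curve fitting, plus across-area
and across-day views of the same series. Two printing conventions appear
in the surveyed planning table and are both provided: capacities are
truncated at two decimals (its 24.368 → 24.36 cell fixes the convention),
while rates are rounded half away from zero. One printed capacity cell
(Internal medicine and Surgery, 66.78 m² → printed 17.76) is inconsistent
with the formula, which gives 14.76; the package computes from the formula
and does not reproduce that cell.

## Visit-time statistics

T2 = diagnosis − receipt; T1 = dispense − receipt, falling back to
payment when dispensing is absent (dispensing is the later patient-journey
milestone; the preference is a switch). Records missing a needed milestone
or yielding a negative duration are unusable and excluded — missingness is
a state, not an error. Age bands are half-open
([0,1), [1,3), [3,6), [6,12), [12,20), …, [60,∞)), so age 12 belongs to
the adolescent band. Group comparison: t-test for two groups; for more,
one-way ANOVA when every group passes Shapiro–Wilk normality and Levene
homogeneity at α 0.05, else Kruskal–Wallis (the normality/homogeneity
gates need concrete tests; these are the standard choices). Raw p-values
are reported per factor with no multiple-testing correction by default.
Disease-type grouping uses the record's first-listed (primary) diagnosis;
levels with fewer than `min_group_size` observations are dropped from that
factor's test.

## Synthetic data: what it emulates and what it does not

The generator defines the study conditions for all tests:

* **Scenes** are textured grayscale frames with elliptical head blobs
  (radius 4–12 px, random orientation and darkness, mild overlap allowed);
  annotations are exact integer blob centres. Scene count ranges (0–60)
  bracket the surveyed per-slot averages. Blobs are deliberately not
  photorealistic: downstream code exercises counting, not appearance.
* **Profiles** are base + Gaussian bumps on the half-hourly grid, clipped
  at zero, with bounded areas peaking mid-morning and before closing.
* **Frame bundles** draw one Poisson slot count and jitter individual
  frames by at most ±1 person (waiting crowds are treated as stationary);
  empty slots give empty frames.
* **Visit records** follow the surveyed marginal frequencies: age-band
  tallies (66% children), 52/48 sex split, diagnosis counts
  (78.8/20.1/1.1% for 1/2/3), and the 14-category diagnosis distribution
  (54.3% respiratory), with each diagnosis drawn independently so marginal
  category frequencies match their configured probabilities. Durations are
  Gaussian in minutes (T2 ~ N(30, 10); post-diagnosis gap ~ N(60, 20),
  truncated at 2 min) with planted effects expressed in SD units against
  fixed age-standardization constants (mean 18, SD 20 years). The
  missing-milestone mechanism is missing-completely-at-random at the
  surveyed 22.1% rate, blanking either the diagnosis or both payment and
  dispensing milestones.

Passing tests on these data show that the pipeline's arithmetic, selection
logic and error control behave as designed; they do not show that the
network generalizes to real surveillance imagery (occlusion, perspective,
lighting), that real waiting times are Gaussian, or that real missingness
is random. All randomness flows from explicit per-call seeds; no global
state.

## Problem sizes

The test suite and demonstration run at desk scale by design: 64×64
scenes, 8–16-channel networks, 20-scene training sets, a few hundred
epochs at most, 100–200 Monte-Carlo replicates for power and type-I-error
checks, and two-day count tables in the demo. The full-scale survey corpus
(1000 annotated frames, 11,130 images) is not redistributable, so
counting-accuracy claims at that scale are replaced by the property checks
described above.

## Known limitations

* The NumPy engine is single-device and unaccelerated; it is sized for the
  desk-scale experiments above, not for training on real surveillance
  corpora.
* Nearest-neighbour is the only upsampling mode currently implemented.
* The congestion model is purely proxemic: seats, queue discipline and
  service rates are out of scope.
* The influence analysis is associational; no causal claims are made.
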