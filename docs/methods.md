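# Methods

## Problem setting

A facial mask removes the lower face entirely. The classic 68-point
landmark scheme partitions into an upper set of 26 points ({1,17} ∪
{18..22} ∪ {23..27} ∪ {28,29} ∪ {37..48}: jaw-top corners, brows, upper
nose bridge, eyes) and a lower set of 42 ({2..16} ∪ {30..36} ∪ {49..68}).
The lower points carry most of the inter-emotion displacement
(`reference_landmarks.displacement_table` quantifies this on user
data via per-landmark Euclidean distances between emotions); above a
mask, only the 12 eye-contour points move much. The package therefore
detects a variable-size set of *flexible* landmarks on the upper face
instead of a fixed annotation.

Percentages in `partition_stats` are of the full 68 and rounded half
away from zero (26/68 = 38.2 → 38, 12/68 = 17.6 → 18).

## Sampling curve

`x = cos t`, `y = sin(αt)/β`, `t ∈ [0, cπ]`, sampled at *n* inclusive,
equally spaced values (step `cπ/(n−1)`). Defaults α = 2 (two lobes,
one per eye), β = 2 (half-height lobes), c = 20 (ten figure-eight
rounds), n = 50 (five points per round on average).

Two sampling grids are available:

- `inclusive` (default): endpoints included, step `20π/49`. Because the
  step is *not* a rational multiple of the 2π round length, each round's
  five points land on slightly different positions — consecutive rounds
  drift, and the union of chords sweeps a band rather than a fixed
  polygon. This drift is the point: each eye/brow edge is crossed by
  several slightly offset chords.
- `algorithm1`: step `cπ/n` with n+1 values. Here five steps equal
  exactly 2π, every round retraces the same five points, and no drift
  occurs. Kept as an explicit variant for comparison.

The *continuous* curve is symmetric under `(x, y) → (−x, −y)` (realized
by `t → (c−1)π − t`); the inclusive sample multiset is deliberately
*not* closed under this map — closure would mean the rounds retrace.

Normalization maps the sample bounding box affinely onto
`[0, w−1] × [0, round(height_ratio·(h−1))]` of the upper-face crop
(`height_ratio` default 1.0). Placement translates the whole set so its
centroid sits on the seed point, pulls the translation back just enough
to keep the bounding box inside the frame (never clipping individual
points, which would distort chords), and only then rounds to integer
pixels (half away from zero). Rounding any earlier would quantize away
the inter-round drift.

## Seed point

Column sums (vertical projection) peak at the nose-bridge highlight;
row sums (horizontal projection) dip in the eye–brow band. Depending on
contrast, the raw row minimum lands on the eyes, on the brows, or
between them; Savitzky–Golay smoothing (window 31, polyorder 3) merges
the three regimes into one stable minimum. The vertical projection is
left raw — the column maximum is unambiguous — with a config override
to smooth it as well. If a profile is shorter than the window, the
window shrinks to the largest valid odd value instead of failing.
Arg-extrema are taken on values quantized to 1e−6 so floating-point
noise from the smoother cannot break exact ties; ties go to the lowest
index.

## Landmark detection

Algorithmic contract: for i = 0 … n−3, rasterize the chords
`p_i → p_{i+1}` and `p_{i+1} → p_{i+2}` (Bresenham; a segment is always
generated from its lexicographically smaller endpoint and flipped, so
reversal symmetry is exact), join them with the shared midpoint counted
once, read the image along the trace, and find all peaks with their
prominence, FWHM width (at half prominence) and left base. A peak is
accepted when prominence ≥ `min_prominence` and width ≥ `min_width`;
the left base maps through the trace to the landmark pixel.

Defaults: `min_prominence` = 25.5 (10% of the 8-bit dynamic range —
scale-free), `min_width` = 3 samples (rejects single-pixel noise
spikes). Peaks are sought on the raw profile; overlapping triples scan
every chord twice with different neighbors, which is deliberate
redundancy — near-duplicate landmarks carry overlapping but distinct
HOG neighborhoods and are kept, only exact pixel repeats are dropped
(first occurrence wins). An `invert` flag flips the image first for
dark-valley detection; by default the detector finds bright peaks
(background or sclera flanked by dark lashes/brows), whose left bases
sit in the dark structure adjacent to the boundary.

Peak semantics follow the standard prominence definition (height above
the higher of the two valleys bounded by the nearest higher samples or
the signal ends; plateau apexes at the plateau midpoint; the left base
is the lowest sample of the rising-side valley, nearest occurrence on
ties). The implementation wraps `scipy.signal.find_peaks`; an
independent O(n²) oracle written from the definitions (no scipy) lives
in the test suite and acceptance script and is checked exhaustively on
all ternary profiles up to length 12 plus random profiles.

## HOG descriptor

Gradients are central differences with replicated borders
(`Gx(y,x) = Y(y,x+1) − Y(y,x−1)`, likewise Gy); magnitude is the
Euclidean norm and orientation the four-quadrant arctangent of
`(Gy, Gx)` on image-frame axes in `[0°, 360°)` (y grows downward; the
convention is internal-consistent, absolute orientation does not
matter). The 20×20 blob around a landmark starts at `coord − 10`,
clamped at zero on the near edges and zero-padded on the far edges so
the shape is always exact. The blob splits into 2×2 cells of 10×10; each
cell accumulates an 18-bin signed-orientation histogram (20° bins),
magnitude-weighted with circular linear interpolation between the two
nearest bin centers, so total histogram mass equals total gradient
magnitude. The four histograms concatenate row-major and are
L2-normalized as a single 72-value block (`v/√(‖v‖² + ε²)`, ε = 1e−6),
giving contrast invariance. The landmark feature is `(x, y, d1..d72)` —
74 values, coordinates unnormalized pixel positions in the crop frame.

The 72-value layout (4 cells × 18 signed bins, one normalization block)
was chosen as the single canonical realization of a 72-length
magnitude-weighted orientation histogram; an alternative reading — 36
direction values plus 36 magnitude values — is noted but not built.

## Classifier

Per image, the detected landmarks (detection order preserved) become a
sequence padded/truncated to `max_landmarks` rows with a validity mask;
when truncating, the highest-prominence landmarks are kept, in their
original order. Architecture: two same-padded kernel-3 1-D convolutions
with ReLU and max-pool-2 over the 74-value feature axis of each
timestep, flatten, a single LSTM layer over the landmark timesteps
(masked steps carry state through unchanged), final hidden state into a
dense softmax. The LSTM cell is standard — sigmoid input/forget/output
gates, tanh candidate, `c_t = f_t ⊙ c_{t−1} + i_t ⊙ c̃_t`,
`h_t = o_t ⊙ tanh c_t` — with forget bias initialized to 1. A
power-law-decay forget-gate variant driven by timestep indices exists
in the literature around this architecture but does not compose with
the standard cell update as written; it is not implemented.

Inputs are standardized feature-wise (mean/sd fitted on the real rows
of the training set, stored with the model): raw pixel coordinates are
two orders of magnitude larger than the unit-norm HOG values and
otherwise saturate the gates. Training: categorical cross-entropy,
Adam (lr 1e−3), shuffled mini-batches; everything (init, shuffle) is
driven by one seed, and single-threaded runs are bit-reproducible. The
backward pass is hand-written and verified against central finite
differences in the test suite. Parameter count is reported at build
time. Evaluation uses standard one-vs-rest precision/recall/F1 and a
confusion matrix with rows as true classes (scikit-learn).

Library defaults (`max_landmarks` 64, hidden 64, conv channels
[32, 64]) suit full eight-class runs; tests and the acceptance script
use a smaller profile (24/32/[8, 16]) — at ~40k parameters it trains in
seconds on one CPU and is ample for the two-class separability and
permutation-control experiments (200 sequences, 15 epochs).

## Synthetic faces

The generator renders what the method assumes about upper faces, on a
default 236×96 canvas (average lab-posed upper-crop size; a 100×46
profile mirrors in-the-wild crops):

- skin background (level 180) with additive Gaussian noise (sd 4,
  clipped to [0, 255]);
- a nose-bridge specular highlight: Laplacian column profile, amplitude
  15, scale 2 px. Sharp and mild: ~10σ above column-mean noise (the
  column argmax is unambiguous) yet below boundary-grade prominence, as
  a real diffuse skin highlight is;
- eyes as a dark lash **outline** (~2 px, level 60) around a brighter
  sclera (150) with a small dark pupil — not a uniformly dark ellipse:
  real eyes are darkest at the lash line, and this puts the darkest
  profile samples (peak left bases) on the true boundary;
- eyebrows as dark stroked circular arcs (thickness 3).

Ground truth per sample: the boundary mask (eye outline + full brow
stroke), the true seed `(nose_col, midpoint of eye-center and brow-apex
rows)`, and the class label. Eight emotion classes deform the neutral
geometry (brow raise/lower −6…+3 px, eye opening ×0.75…×1.40, small
eye-row shifts); within-class jitter is ±1 px uniform on positions plus
a fresh noise seed. Separate eye/brow intensity overrides reproduce the
three contrast regimes the seed detector must unify.

What the generator does **not** model: skin texture, shadows, pose,
glasses, hair, illumination gradients, real eyelid/brow shapes.
Passing recovery tests therefore shows the geometry of the method is
implemented correctly under its own assumptions — not that it attains
any particular accuracy on real photographs, which additionally depends
on detector-quality face boxes and dataset-scale training.

## Numerical choices and degenerate inputs

- Rounding: half away from zero wherever a convention is needed
  (placement, percentages).
- Uniform images: no peaks, no landmarks (empty list, not an error);
  seed (0, 0) by lowest-index tie-breaking.
- Empty landmark list at sequence assembly: all-padding sequence with a
  warning, not an error.
- Savitzky–Golay window auto-shrinks on short profiles (logged).
- Masking is idempotent; the trapezoidal mask polygon spans the lower
  half of the face box, inset 5% per side at the chin.
- `upper_fraction` default 0.42 (a 236×96 upper crop over a roughly
  square face box); exposed because the lower edge of the upper-face
  region is inherently a convention.

## Known limitations

- Landmarks are integer pixels; no sub-pixel refinement.
- The detector finds bright-peak left bases only (plus the `invert`
  variant); a profile that enters a dark region and ends there yields
  no peak, so boundaries at trace ends can be missed.
- The classifier is desk-scale; no GPU path, no data augmentation.
- Face detection is pluggable but not provided beyond a whole-image box
  and a CSV sidecar reader.

## Problem sizes used in the checks

Recovery rates use 50 seeded default fixtures (~22 landmarks each);
the peak oracle is checked exhaustively on all ternary profiles of
length ≤ 12 plus 200–1000 random profiles; the classification
experiment uses 200 sequences (140 train / 60 test) with the small
model profile. These sizes give stable statistics (binomial sd ≈ 1% on
the 1000-landmark recovery pool) while keeping the full suite fast.
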