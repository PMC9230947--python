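# maskfer

Emotion recognition for **mask-occluded faces**. When a facial mask hides
the mouth, nose and cheeks, only the upper face — forehead, eyebrows, eyes
and upper nose bridge — remains for analysis. Of the classic 68-point
facial landmark annotation only 26 points (38%) survive above a mask, and
only the 12 eye-area points (18% of all 68) move appreciably between
emotions, so fixed-landmark pipelines lose most of their signal.

`maskfer` instead detects a *flexible* set of landmarks along an
infinity-shaped sampling curve:

1. **Seed point.** On the upper-face crop, the nose bridge is the
   brightest vertical structure and the eye–brow band the darkest
   horizontal one: `x_seed = argmax` of the column-sum projection,
   `y_seed = argmin` of the row-sum projection after Savitzky–Golay
   smoothing (window 31, order 3).
2. **Infinity curve.** The figure-eight `x = cos t`, `y = sin(αt)/β` is
   sampled at *n* = 50 points over `t ∈ [0, cπ]` with α = 2, β = 2,
   c = 20: ten traversals whose points drift between rounds, so repeated
   passes probe slightly different pixels. The curve is min–max rescaled
   to the crop and translated so its centroid sits on the seed.
3. **Boundary landmarks.** For every triple of consecutive curve points,
   the two chords are rasterized (Bresenham) and the pixel intensities
   form a 1-D profile. Peaks with prominence ≥ 25.5 (10% of the 8-bit
   range) *and* full width at half prominence ≥ 3 samples mark a bright
   stretch flanked by dark structure; each peak's **left base** — the
   rising-side valley — is taken as a landmark (the low→high intensity
   boundary, typically an eye or eyebrow edge).
4. **HOG features.** Each landmark is described by a 20×20 blob: 2×2
   cells × 18 signed-orientation bins (20° each), magnitude-weighted
   with linear bin interpolation, L2-normalized as one block — 72
   values, prepended with the landmark's (x, y) for a 74-value feature.
5. **Classification.** Per-image landmark features form a padded
   sequence; a 1-D CNN runs over each 74-value feature, an LSTM (cell
   update `c_t = f_t ⊙ c_{t−1} + i_t ⊙ c̃_t`) runs over the landmark
   sequence, and a softmax head predicts the emotion. The network is
   implemented in NumPy with hand-written backprop and Adam, so it is
   dependency-light and bit-reproducible under a fixed seed.

A synthetic upper-face generator (`maskfer.synthfaces`) renders faces
with the structure the method assumes — bright nose-bridge highlight,
dark eye outlines with brighter sclera, dark brow arcs, per-emotion
geometry deformations — together with ground-truth boundary masks and
seed points, so every stage is testable without external face datasets.

## Worked example

Generate fixtures, detect landmarks on one image:

```bash
$ maskfer gen-fixtures --out fx --n-per-class 1 --seed 0
wrote 8 fixtures to fx
$ maskfer detect --image fx/face_0000_neutral.png --out landmarks.csv
23 landmarks at seed (117, 56)
$ head -3 landmarks.csv
image_id,x,y,source_index,prominence,width
face_0000_neutral,202,58,0,89.0,11.977272727272727
face_0000_neutral,79,63,2,29.0,4.3125
```

The seed (117, 56) sits on the nose-bridge column inside the eye band;
each CSV row is one landmark with the peak evidence (prominence, FWHM
width) that produced it.

A small end-to-end run — 20 synthetic faces per class for three classes,
landmark extraction, CNN+LSTM training, held-out evaluation:

```python
from maskfer.config import load_config
from maskfer.pipeline import run_end_to_end

cfg = load_config(overrides={
    "rng_seed": 1, "fixtures.n_per_class": 20,
    "classify.class_names": ["neutral", "anger", "surprise"],
    "classify.max_landmarks": 32, "classify.hidden_size": 32,
    "classify.conv_channels": [8, 16], "classify.epochs": 25,
    "classify.batch_size": 16})
report = run_end_to_end(cfg)
print(report["metrics"]["accuracy"])          # 0.9333333333333333
print(report["metrics"]["confusion_matrix"])  # [[5,0,0],[1,4,0],[0,0,5]]
```

The 41,619-parameter model reaches 93.3% held-out accuracy on 15 test
faces in a few seconds of CPU time; the confusion matrix rows are true
classes (one "anger" face is taken for "neutral" — the two differ only
in brow height and eye opening, exactly the upper-face ambiguity the
method must resolve).

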