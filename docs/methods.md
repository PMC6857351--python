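# Methods

## The detection problem

Biplane digital subtraction angiography (DSA) acquires two synchronized
X-ray sequences of the contrast-filled cerebral arteries — a frontal and a
lateral view sharing the craniocaudal axis.  Saccular intracranial
aneurysms appear as focal outpouchings of the arterial lumen; the dominant
source of false positives in any 2D reading is the *vessel overlap*: two
distinct arteries crossing in projection produce an apparent mass that can
look exactly like an aneurysm in a single view.

`dsadetect` implements a two-stage screening pipeline over such sequences:

1. **Region localization (RLS).**  A localizer proposes the target arterial
   region (e.g. the posterior communicating artery territory) on each full
   frame; the crop is resampled to a fixed 288×288 interface.  "Region not
   found" is an explicit per-frame outcome, and such frames are skipped.
2. **Candidate detection (ADS).**  A pluggable detector sees each crop
   *together with* the same-index crop from the orthogonal view (dual
   input) and emits labeled boxes with confidences; candidates with
   confidence strictly above 0.6 are retained.
3. **Regional average grayscale suppression (RAGS).**  Retained aneurysm
   candidates below a confidence gate `c` are tested against the DSA
   attenuation physics (below); failures are relabeled as overlaps.
4. **Patient aggregation.**  A patient is called positive if any frame of
   either view retains an aneurysm (a strict OR designed for high
   sensitivity); the maximum aneurysm confidence over the sequence is the
   patient's *disease confidence*, which feeds the ROC analysis.

The learned detectors that would normally fill stages 1–2 (feature-pyramid
CNNs) are out of scope; the package defines their contracts and provides
classical reference implementations sufficient to exercise every stage on
synthetic data.

## The suppression rule

In DSA the gray value of a pixel is set by the amount of radiocontrast
agent along the ray behind it.  An overlap therefore contains *more* blood
than its neighborhood and reads darker, while a small aneurysm sac —
holding slow, partly stagnant flow — reads lighter than its parent vessel.
For a tested detection the rule:

1. extracts a rough vessel mask of the crop with Otsu's threshold
   (256-bin histogram, ties toward the lower threshold) and keeps original
   intensities only on the mask;
2. doubles the detection box's width and height about its center
   (enlargement factor 2.0, clipped to the image);
3. averages masked gray values inside the detection box,
   `AG_aneurysm = G_an / P_an`, and over the surrounding ring,
   `AG_surrounding = (G_enl − G_an) / (P_enl − P_an)`;
4. suppresses iff `AG_aneurysm < AG_surrounding` (strictly darker than the
   surround); equality retains.

Design choices made here, where the rule as stated leaves room:

* **Averages run over vessel-mask pixels only.**  Counting masked-out
  background (zeroed by the logical AND) would drag sparse boxes toward
  darkness; excluding it is the only reading consistent with comparing
  *vessel* grayscale.  The choice is switchable by passing a custom mask.
* **Suppression relabels to overlap** (keeping the box) rather than
  dropping it, because the rule's conclusion is "this object is an
  overlap"; a `drop` action exists for ROC sweeps.
* **Ties retain** the aneurysm label, consistent with the high-sensitivity
  goal, as do degenerate regions (no vessel pixels in the box, or an empty
  ring), which additionally warn.
* The gate default `c = 0.99` tests nearly every candidate; the
  `threshold_distribution` helper tabulates patient counts above/below a
  grid of `c` values to support choosing it.

Known limitation, inherent to the rule: large aneurysms also hold much
contrast agent and can read darker than their surround; if a detector is
unsure about one (confidence below `c`), the rule will suppress it.  No
mitigation is implemented.

## Training losses

`losses` provides framework-free scalar references for the two detector
training losses: focal loss `FL(p_t) = −α(1−p_t)^γ ln(p_t)` (defaults
α = 0.25, γ = 2.0; natural log, reducing to cross-entropy at α = 1, γ = 0)
and the smooth-L1 box loss summed over (x, y, w, h) with weight σ = 3.0.
The commonly printed smooth-L1 form — `0.5(σx)²` for `|x| < 1`, else
`(|x|−0.5)/σ²` — is discontinuous at `|x| = 1` whenever σ ≠ 1; it is kept
as the default for fidelity to how the loss is usually stated, and the
continuous Detectron form (branch at `1/σ²`, outer branch `|x|−0.5/σ²`) is
available via `continuous=True`.  Both are tested.

## The synthetic angiography simulator

No clinical cohort ships with the package; `synthetic_dsa` generates the
study conditions instead.  A scene is a small 3D vessel tree in the unit
cube: 2–4 smooth tubes running roughly craniocaudally (lumen radius
0.018–0.028 canvas units with a mild distal taper), optionally carrying one
saccular aneurysm.  Rendering voxelizes the tubes (union of spheres along
densely sampled centerlines, 288³ grid) and projects the density-weighted
lumen chord length `L(p)` along each pixel's ray — the frontal view
integrates out the depth axis, the lateral view the left–right axis, both
sharing the craniocaudal row.  Pixel intensity follows linear
(Beer–Lambert-like) attenuation

    I(p) = clip(255 − g_j · k · L(p)) + ε,   ε ~ N(0, σ_n²)

with gain `k = 2000` gray levels per unit chord (single vessels near
mid-gray, overlaps dark but typically not clipped), per-frame contrast
wash-in `g_j` rising linearly over the first third of the sequence then
plateauing at 1, and Gaussian pixel noise `σ_n = 2` gray levels by default
(8-bit scale).  Sequences are 6–12 frame pairs, the window radiologists
typically select during contrast transit.  Full frames embed the region
render in a bright 1024×1024 canvas at a recorded window, giving the
localization stage its ground truth.  All randomness flows from a single
seed; renders are byte-reproducible.

Two properties of real DSA are built in *by construction*, because the
pipeline's discriminative signals depend on them:

* **Overlaps are darker.**  Ground-truth overlap boxes are placed at
  projection-space crossings of distinct centerlines (2D distance below the
  summed radii while clearly separated in 3D) — apparent structures only.
  At a crossing both chords add, so overlap pixels are strictly darker than
  single-vessel pixels of the same caliber in the noise-free limit.
* **Small sacs are lighter, and bulge in both views.**  An aneurysm is a
  sphere (dome radius 2.0–2.4× the local lumen radius — a genuine
  dilation) whose center sits 2.4 dome radii off the centerline along a
  horizontal bud direction with substantial components in both projection
  axes, joined to the lumen by a thin contrast-filled neck (half the local
  lumen radius).  The sac interior carries a reduced contrast density of
  0.45 relative to flowing lumen, emulating slow, stagnant flow.  The
  geometry makes the sac project *beside* its parent vessel with a similar
  apparent radius at the same row in both views; the density makes it read
  lighter than the vessel.  Neither the grayscale gap nor the sac geometry
  is clinically calibrated — they are chosen once for separability, and
  that is precisely what passing tests show: the pipeline exploits these
  signals *when they are present*, not that they are present in clinical
  angiograms.

The truth vessel mask per view is taken at full-width-half-maximum of a
typical lumen (chord above one mean radius), excluding the faint
partial-volume rim — the standard way to delimit a projected tube.

What the simulator does **not** emulate: Circle-of-Willis anatomy,
contrast-agent fluid dynamics, X-ray scatter or beam hardening, patient
motion, and the appearance variability of clinical DSA.  Results on it
bound nothing about clinical performance.

## Reference localizer and detector

Both are classical stand-ins behind the stage contracts, in the spirit of
pre-learning vascular image analysis.

**Localizer.**  Otsu vessel mask; square windows (default 288, stride 32)
scored by vessel-pixel density via an integral image; the winner is
recentered on the bounding box of the mask within a 1.5× neighborhood,
which corrects the drift of a pure density argmax when the vasculature sits
asymmetrically in the window.  Confidence is the window density normalized
by a saturation density (0.08, capped at 1); frames whose global vessel
fraction falls below 10⁻⁴ report "not found".

**Detector.**  Otsu mask → Euclidean distance transform → skeleton; a
candidate is a skeleton point whose lumen radius is a local maximum (within
15 px) and exceeds the median skeleton radius in a 25–70 px annulus by at
least 1.3×, with greedy non-maximum suppression at 30 px separation.  The
box side is 2.8× the peak radius.  Base pseudo-confidence is
`0.95 · sigmoid(5 · (ratio − 1.45))`; the 0.95 cap encodes that a
hand-crafted radius ratio never carries the near-certainty a strong learned
detector can claim, so every candidate remains eligible for the grayscale
check at the default gate.  In dual mode, a peak in the corresponding view
at the same row (±9 px) with a similar apparent radius (±35%) — the
signature of a real, roughly spherical 3D structure — raises the confidence
by `0.5·(1−conf)`; a missing match multiplies it by 0.65.  Projection
crossings rarely have such a counterpart, which is the dual-view
discrimination the pipeline relies on.

## Evaluation

Confusion-matrix counts may be fractional so that cross-validation-averaged
matrices are representable verbatim.  Sensitivity, specificity and accuracy
use their standard definitions, raising an explicit error (rather than
returning 0) on empty denominators.  The ROC curve over disease confidence
groups tied confidences into single threshold steps (delegated to
scikit-learn's `roc_curve`) and the AUC is trapezoidal; tests verify it
against an independent Mann–Whitney pair-counting oracle, ties counted one
half.

## Problem sizes and numerical notes

The packaged demo cohort is 20 positive + 20 negative synthetic patients
with 6–12 frame pairs each, matching the prospective test cohort structure
the pipeline is designed for; tests exercise it noise-free, where the
simulator's guarantees are exact.  Property suites run on small randomized
rasters (≈ 6–32 px) at high repetition counts instead, where brute-force
pixel-loop oracles are affordable.  Geometry uses 0-based, half-open pixel
intervals throughout — `(x, y, w, h)` boxes cover `[x, x+w) × [y, y+h)` —
making IOU and regional sums exact integer-pixel counts.  Otsu on float
images bins to 256 levels; the affine-invariance property of the
suppression decision (intensities mapped by `a·x + b`, `a > 0`) holds
exactly at fixed vessel mask, while re-binning can move individual boundary
pixels.  Frontal/lateral sequences of unequal length are paired by index
and truncated to the shorter, with a warning.
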