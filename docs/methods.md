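# Methods

`kinimage` classifies upper-limb lifting movements recorded with optical
motion capture, distinguishing post-stroke from healthy movement patterns
and localizing which limb segment carries the discriminative signal.  This
note documents the models, the synthetic data the package is validated on,
the numerical choices, and the limits of what the tests show.

## The classification pipeline

**Input.** One recording is a single functional movement — lifting an
object (small cylinder SC or large cylinder LC to head height, or a glass
DG to mouth height) and lowering it — captured at 100 Hz as 3D positions
(mm) of four reflective markers along the limb: index-finger nail (FN),
lateral epicondyle (LEP), mid-humerus (MPH) and acromion (ACR).  The
coordinate convention is X lateral (left negative), Y vertical, Z anterior;
both the mirror axis and all preprocessing thresholds are configurable.

**Preprocessing.**

1. *Clipping.* Rest periods are removed using the smoothed speed of a
   reference marker (FN, 5-sample moving average).  Onset is the first
   sustained crossing (≥ 0.1 s) of 5 % of peak speed, backtracked to the
   last preceding sample below a 0.5 % floor — the standard kinematic-onset
   refinement, which places the boundary at the true beginning of the speed
   rise rather than at the threshold crossing; offset is symmetric from the
   tail.  A single temporal window is applied to all markers and axes so
   the three coordinate signals stay aligned when stacked into one image
   (clipping each plane on its own window would desynchronize them).  On
   noise-free minimum-jerk movements the detector recovers the true onset
   within ±3 samples; the test suite requires ±5.
2. *Side unification.* Left-limb recordings are reflected across the
   lateral axis so every movement is expressed as a right-limb movement;
   the L/R marker-name suffix is stripped.  The operation is an exact
   involution on generated mirror pairs.
3. *Resampling.* Each clipped coordinate signal is mapped to 32 samples by
   linear interpolation, removing duration as a trivial cue at the image
   level.

**Feature encoding.** Per marker and axis the chain
d<sub>i</sub> = |p<sub>i</sub> − p<sub>i−1</sub>|,
v<sub>i</sub> = (d<sub>i</sub> − d<sub>i−1</sub>)/T′,
a<sub>i</sub> = (v<sub>i</sub> − v<sub>i−1</sub>)/T′,
j<sub>i</sub> = (a<sub>i</sub> − a<sub>i−1</sub>)/T′
produces 12 feature rows (4 features × 3 axes).  Two deliberate choices:

* The chain differentiates the *absolute displacement* series, not signed
  position, exactly as defined above.  A side effect is that every feature
  is invariant to lateral mirroring by construction, which makes side
  unification exactly lossless downstream.
* T′ is the effective interval of the *resampled* signal — clipped duration
  divided by 31 — not the raw capture interval.  This preserves physical
  velocity/acceleration magnitudes for movements of different durations.

The chained differences yield 31/30/29/28 samples from 32 positions while
the image width is fixed at 32; each row is left-padded by replicating its
first value, which keeps late time samples aligned across rows.  Each of
the 12 rows is then min-max normalized to [0, 1] independently per
recording (a constant row maps to zeros; dataset-global normalization is
available behind a flag).  Per-row normalization means absolute magnitude
is discarded and classification rests on profile *shape* — multi-peaked
velocity, tremor roughness in the acceleration/jerk rows, flattened speed
profiles.  Stacking one 12×32 block per marker gives the activity image,
depth 1–4.

**Classifiers.** The CNN is
conv(f_Conv1, 3×3, valid, ReLU) → maxpool 2×2 → conv(f_Conv2, 3×3, valid,
ReLU) → maxpool 2×2 → flatten → dense(out_Dense1, ReLU) →
dropout(d_Drop1) → dense(n_classes, softmax), trained with Adam on
multi-class cross-entropy, batch size 32.  For the 12×32 input the spatial
map shrinks 12×32 → 10×30 → 5×15 → 3×13 → 1×6, so the flatten size is
6·f_Conv2.  The network is implemented directly in numpy (im2col
convolutions, first-occurrence argmax pooling, inverted dropout); at this
image size it trains in seconds on one CPU and is bit-reproducible given a
seed, since weight initialization, batch order and dropout masks all come
from one generator.  Valid (unpadded) convolution is used; with 3×3 kernels
any input of at least 12×30 survives the stack.

The comparison baselines consume the same images flattened to 384·C
vectors: a random forest (100 trees, depth ≤ 10), a linear-kernel SVM and
a multinomial logistic regression, the latter two at library-default
regularization (recorded in the results objects).

**Labelings.** `limb3` assigns HUL to every control limb, PUL to paretic
and NPUL to non-paretic stroke limbs; `group2` collapses PUL and NPUL into
G1 versus control G2.  For the reference cohort (35 stroke and 19 control
participants, two limbs each, three activities) the class sizes are
114/105/105 and 210/114.

**Splitting.** 80/20 validation hold-out, either stratified at recording
level (default) or grouping whole participants (stratified by participant
group) so that no subject appears on both sides — the leakage-safe
protocol, used in the acceptance experiments because the two limbs and
three activities of one person are strongly correlated.  All models in one
ablation share a single frozen split so row differences reflect marker
information rather than split luck.

**Metrics.** Accuracy, macro precision/recall, and ROC AUC (binary:
positive-class score; 3-class: macro one-vs-rest).  AUC is the headline
metric because both labelings are imbalanced.  Constant scores yield AUC
0.5 by convention.

**Hyperparameter search.** Six hyperparameters (lr, ep, f_Conv1, f_Conv2,
d_Drop1, out_Dense1) are optimized by GP Bayesian minimization of
1 − validation AUC: 10 random initial points, then a Matern-5/2 + white
noise surrogate in the unit cube (lr log-scaled, integers rounded) with
expected-improvement acquisition over 1024 random candidates per call;
40 calls by default.  Default box: lr ∈ [10⁻⁵, 10⁻²] (log-uniform),
ep ∈ [100, 300], filter counts and dense width ∈ [10, 100],
dropout ∈ [0, 0.25].  Each objective call retrains from scratch with a
call-indexed seed.

## The synthetic cohort generator

No clinical recordings ship with the package; a generator produces cohorts
with the same design (one movement per recording, four markers, three
activities, stroke group with paretic/non-paretic limbs, control group)
so that every downstream stage has ground truth.

The healthy template is the minimum-jerk point-to-point profile
x(τ) = A(10τ³ − 15τ⁴ + 6τ⁵), the standard model of smooth reaching
(peak speed 1.875·A/D).  The hand lifts (1.2–1.4 s depending on activity,
250–400 mm), pauses 0.25 s, and lowers; an anterior reach component (60 %
of the lift time) and a small lateral drift accompany it.  Proximal markers
inherit scaled copies of the hand displacement (gains 1.0 / 0.55 / 0.30 /
0.12 for FN / LEP / MPH / ACR) on fixed anatomical base positions.  Rest
padding of 0.5–1.0 s (uniform) at both ends makes onset detection
non-trivial; the true onset/offset indices are stored with each recording.

A `ClassEffect` injects post-stroke deficits:

| parameter | meaning | paretic | non-paretic | control |
|---|---|---|---|---|
| `duration_factor` | movement-time scaling | 1.5 | 1.15 | 1 |
| `peak_velocity_factor` | peak-speed ratio | 0.6 | 0.85 | 1 |
| `n_submovements` | lift fragmentation | 3 | 2 | 1 |
| `tremor_amplitude` (mm) | 4–12 Hz action tremor | 1.5 | 0.5 | 0 |
| `proximal_compensation` | extra MPH/ACR displacement | 0.3 | 0.1 | 0 |

Reduced peak velocity is realized by blending the minimum-jerk velocity
profile with a C²-smoothed trapezoid (quintic ramps, ramp fraction 0.08,
peak ratio 1.087): the blend spans peak-speed ratios [0.58, 1.0] and is
strictly monotone there (clipped below).  Fragmentation splits a stroke
into n overlapping sub-profiles of amplitude A/n and duration
D(1+n)/(2n), preserving endpoints while raising the squared-jerk cost.
Tremor is band-passed white noise (2nd-order Butterworth, 4–12 Hz,
filtfilt) scaled by the marker gain and enveloped by normalized movement
speed, so rest periods stay quiet (physiological action tremor) and onset
detection is driven by the smooth component.  Deficits are bilateral but
milder on the non-paretic side, reflecting the clinical observation that
stroke alters movement quality in both limbs.  The default magnitudes are
chosen so that the 2-class task is easy and the 3-class task harder — the
qualitative difficulty ordering of the clinical problem.  An optional
`affected_markers` restriction confines the velocity-profile, submovement
and tremor components to chosen markers (the time base stays global),
which provides ground truth for the marker-sensitivity experiment.

Left-hand recordings are generated right-handed and mirrored exactly
(X negated), so mirror pairs are bit-identical after side unification.
Cohorts are bit-reproducible from a single seed via per-recording child
seeds.

**What the generator does not emulate** — and hence what passing tests do
*not* show about clinical data: joint constraints and segment rigid-body
geometry (markers move along scaled copies of one path, not a true
kinematic chain), marker occlusion and gap artifacts, soft-tissue motion,
trunk strategies beyond a proximal displacement surplus, inter-individual
variability in movement style beyond seeded noise, and calibrated effect
sizes (the deficit magnitudes are plausible, not fitted to patients).
Results on synthetic cohorts validate the machinery, not clinical
performance.

## Validation experiments and problem sizes

The test and acceptance suites run entirely on synthetic cohorts, scaled
to desk-run times:

* *Structure*: cohort/class-count arithmetic (324 recordings,
  114/105/105 and 210/114), image geometry (12×32×C), finite-difference
  chains against brute-force oracles (1000 random series, 10⁻⁹ relative),
  mirror invariance over 100 seeds, normalization bounds.
* *Recovery*: on the default strong-effect cohort (324 recordings,
  participant-grouped 80/20 split, 100 epochs) the 2-class CNN must reach
  validation AUC ≥ 0.9; on an all-null cohort (identical movement
  statistics in all classes) the AUC must fall inside the 95 % chance band
  0.5 ± 1.96·√((n₁+n₂+1)/(12n₁n₂)) — the null sampling band of the
  Mann-Whitney statistic underlying the AUC.
* *Marker sensitivity*: with deficits confined to MPH, the MPH
  single-marker model must beat the FN model on validation AUC in ≥ 8 of
  10 seeded repeats (30-epoch runs).
* *Search*: the GP optimizer's returned optimum must equal its history
  minimum, and with 10 calls it must match or beat paired random search in
  ≥ 7 of 10 repeats (compact cohort, reduced search box with ep ∈ [10, 30]
  and widths ≤ 32 so each of the 200 trainings takes well under a second).

## Numerical choices and degenerate inputs

* Inclusive clip bounds, 0-based indices; clipping the full range is the
  identity.
* Resampling preserves endpoints exactly and stays within the input range
  (convex combinations); a length-32 input is returned unchanged.
* Constant rows normalize to zeros; a fully stationary marker encodes to
  an all-zero block.
* A flat recording raises a detection failure rather than returning a
  window; recordings with NaN samples are rejected at construction.
* Max-pooling ties break to the first occurrence; with valid convolutions
  an input below 6×6 cannot be built and raises a build error.
* LinearSVC at default settings may emit convergence warnings on these
  small flattened designs; its results are still deterministic given the
  seed.

## Known limitations

* The CNN is single-threaded numpy: ideal for reproducibility and this
  image size, not for large-scale use.
* 3-class AUC averaging (macro one-vs-rest) and macro precision/recall are
  one convention among several; results under other conventions differ.
* The stratified (non-grouped) split allows subject-level leakage by
  design, for comparability with recording-level protocols; grouped
  splitting is the defensible default for clinical claims and is what the
  acceptance experiments use.
* Whether the 40-call budget of the search includes the initial random
  design is a convention; here it does (10 of the 40 calls).
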