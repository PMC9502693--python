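# Methods

## Signal model and pipeline

The pipeline classifies the workload level k ∈ {1, 2, 3} of Stroop-style
task screens from two time-aligned sources recorded per screen:

* a **beat series**: heartbeat times τ₁…τ_N with, per beat, the ten
  hemodynamic measures a Finometer-class monitor derives from the
  continuous pressure waveform. The beat series is inherently unevenly
  sampled (one row per heartbeat). Computing these measures from the raw
  waveform is out of scope — they are the input contract.
* a **formant track**: the first three formant frequencies every 10 ms,
  as produced by an external Kalman-smoothing tracker. Tracker output is
  taken as-is (F1 ≤ F2 ≤ F3 is not enforced; smoothed trackers
  interpolate through unvoiced stretches, so no voicing mask is applied
  and all frames in a window enter the statistics).

The two modalities meet at the heartbeat. Each beat owns the half-open
window (τₙ − ½Δₙ, τₙ + ½Δₙ₊₁]; consecutive windows share edges exactly,
so the windows tile the recording and every frame has exactly one owner
(a frame exactly on a shared edge belongs to the earlier beat). The
first beat's left half-width and the last beat's right half-width are
undefined by the interval recursion; they are substituted with Δ₂ and
Δ_N respectively and clamped to the track span, which preserves the
tiling without inventing data. Windows with fewer than 3 frames cannot
support a quadratic fit and are a hard error; in tolerant mode the
previous beat's feature row is copied instead, which keeps beat counts
aligned across modalities without fabricating statistics.

## Feature definitions and numerical conventions

**Dynamics.** The delta operator is the standard regression slope over
±M neighbours with edge replication; M defaults to 2 (a 5-sample
window). Acceleration re-applies the same operator to the delta matrix
with the same edge rule. Deltas are applied at the *frame* level before
windowing (Γ) and at the *beat* level on the cardiovascular measures
(C(δ,a)); dynamics are never re-applied to the per-beat formant
statistics.

**Per-window statistics.** Ten per track: quadratic least-squares
coefficients on times re-centered at the beat (descending degree, so the
constant term is the fitted at-beat level — centering also conditions
the normal equations), min, max, mean, median, standard deviation with
the n−1 denominator, biased moment skewness, and plain (non-excess)
kurtosis, the default estimator conventions of the numerical environment
the method was originally developed in. A zero-variance window returns
skewness 0 and kurtosis 3 by convention rather than NaN, so degenerate
(e.g. constant or clipped) segments cannot poison a classifier. The
implementation solves one shared least-squares system per window for all
tracks; it is property-tested against a literal normal-equations/moment
oracle at 1e-9 on a thousand random windows.

**Fusion.** Row-wise concatenation of beat-aligned matrices,
[formant | cardio]. Both beat counts *and* beat times must agree;
positional alignment alone is rejected so permuted or shifted inputs
fail loudly.

## Classifiers

* `margin_ovr`: three binary linear maximum-margin classifiers
  (scikit-learn `SVC(kernel="linear")`), one per level against the rest,
  on predictors standardized by training-fold mean and n−1 std
  (standardization parameters are stored in the model and re-applied at
  scoring; refitting them per training fold is the only leakage-free
  choice). The soft score is the signed decision value; with all three
  scores negative the argmax still picks the least negative boundary,
  which is the stated decision rule. The regularization strength
  defaults to 1.0 (exposed in `ClassifierConfig`).
* `tree_ensemble`: a bootstrap forest (scikit-learn
  `RandomForestClassifier`) of 100 trees, minimum one observation per
  leaf, √d features per split. The soft score is the proportion of trees
  voting for each class; since min-leaf-1 trees are grown to purity,
  sklearn's probability averaging equals the vote proportion exactly.

Sequence (screen) decisions sum the raw N×3 score matrix over beats per
class and take the argmax. No calibration is applied to either score
type before summation — margins and vote proportions are summed as-is.
Exact score ties break toward the lowest level and are logged.
Decisions are invariant to positive rescaling of margin scores.

## Evaluation protocol

Classification is participant-dependent: for each of the 21 screens
(7 / 6 / 8 per level), a model is trained on the other 20 and scores the
held-out screen, yielding 21 sequence decisions and one decision per
heartbeat. Fold seeds are `config.seed XOR fold_index`, so folds are
independent but the whole evaluation is reproducible bit-for-bit.
Metrics: MCR_k = row-k off-diagonal / row-k total, MTR_k = column-k
off-diagonal / column-k total, overall MCR = off-diagonal / total, all
computed at full precision and rounded to 2 decimals only for display;
empty rows or columns yield flagged NaN, never silent zeros. Cohort
aggregation reports both the mean of per-participant overall MCRs with
its standard error (sample std / √P) and the pooled MCR of the summed
tables; the two differ when class counts are unbalanced, and neither is
privileged.

**A protocol caveat that matters for null experiments.** Leaving one
screen out always under-represents the held-out class in training
(7/6/8 becomes e.g. 6/6/8). On data with *no* class information, a
classifier that follows its training priors therefore errs at
mean_k (1 − (n_k − 1)/20) ≈ 69.5%, a few points *above* the 66.67%
theoretical chance level of the unbalanced trinary problem, and argmax
over correlated ensemble votes adds a further majority-class pull of a
few points. Zero-effect cohorts evaluated through this protocol land
around 70–75% rather than exactly at chance; this is leave-one-out
pessimism, not learnable signal, and is the expected behaviour of a
faithful implementation.

## Synthetic cohort generator

The generator emulates the study design so the pipeline is testable end
to end: per participant, 21 screens (7/6/8 across levels) with the level
blocks presented in one of the six level orders, rotating across
participants. Defaults describe the study conditions:

* **Beats.** Participant baseline heart rate ~ N(86, 8) bpm (a ~0.7 s
  typical pulse interval); per-beat intervals are 60/HR with 3%
  multiplicative jitter; the ten measures are built from simulated
  primaries (HR, SBP, DBP, SV, LVPE, dP/dt) with AR(1) within-screen
  drift (coefficient 0.8) plus a per-screen random offset, and the
  derived measures (MAP, cardiac output, total peripheral resistance)
  are computed from the primaries so physiological couplings hold. The
  heart-rate measure is exactly 60/Δₙ and the pulse-interval measure is
  exactly Δₙ, consistent with the beat grid.
* **Level effects.** Additive shifts per level with deliberately
  *heterogeneous* profiles across measures (HR +4/+8 bpm roughly linear;
  SBP +7/+10 mostly early; DBP +2/+6 mostly late; SV −4/−5; etc. —
  magnitudes in the ordinary range of Stroop cardiovascular
  reactivity). Heterogeneous dose-response profiles are what real
  physiological channels show, and they keep the three level centroids
  off a single line in feature space; with exactly proportional effects
  the middle level would be linearly inseparable from the other two in
  a one-vs-rest margin scheme — an artificial degeneracy, not a feature
  of real data (where the middle level is merely the hardest class).
* **Formants.** 100 frames/s tracks built from vowel-like segments.
  Segment targets draw from five template vowels standing in for the
  five colour words; because every screen of the task shows the same
  five words in near-equal proportion, segments draw from a balanced
  shuffled deck per screen rather than i.i.d. — otherwise screen-to-
  screen composition noise (~70 Hz on screen-mean F2) would swamp any
  plausible level shift. Level shifts again use heterogeneous profiles
  (F1 +35/+50, F2 +25/+100, F3 +30/+40 Hz), plus per-segment scatter
  (25 Hz), within-segment AR jitter (6 Hz) and a per-screen offset
  (8 Hz). Level 3 uses the externally paced faster segment rate
  (0.75/0.65 s per word); levels 1–2 are self-paced (~0.9 s).
* **Between-screen offsets** are a deliberate addition: without them,
  same-level screens are statistically identical and leave-one-screen-
  out classification becomes trivially perfect, unlike any real
  recording session where slow drift (posture, fatigue, recalibration)
  moves the operating point between screens. Their magnitudes (e.g.
  2 bpm HR, 3 mmHg SBP) are what makes the synthetic task non-trivial.
* `null_config()` removes every level effect and the pacing difference,
  producing three statistically identical levels for chance-level
  experiments.

All randomness flows from a single master seed through a
participant × screen seed tree, so equal configurations give
byte-identical cohorts.

**What the generator does not emulate.** No waveform-level physiology
(measures are generated directly at the beat level), no word identity or
congruence effects, no speech audio, no respiration or baroreflex
coupling between the cardiovascular measures and the voice, no missing
data or sensor artifacts. Passing tests on synthetic cohorts therefore
demonstrate that the pipeline's machinery (synchronization, features,
fusion, classification, evaluation) recovers known injected structure at
realistic noise levels — not that real recordings of these modalities
carry that structure.

## Problem sizes

The simulation-based checks use 10-participant cohorts with 30 s screens
(210 screens, ~9,000 heartbeats, 630,000 formant frames), which gives
pooled-MCR standard errors of roughly 2–3 percentage points at the
observed error rates; the statistics oracle runs 1,000 random windows.

## Known limitations

* The margin classifier's regularization strength and the forest's
  per-split sampling are not specified by the method description;
  defaults follow the original implementation environment and are
  exposed in `ClassifierConfig`.
* Sequence scores sum uncalibrated margins, so a screen's decision can
  be dominated by a few large-margin beats; this is the method as
  defined, not an implementation choice.
* The evaluation protocol's leave-one-out prior shift (above) biases
  null-data error a few points above chance; comparisons between feature
  sets on matched seeds are unaffected.
* Participant-independent (pooled) models are out of scope, as are
  anti-formant/bandwidth features and beat-level re-application of
  dynamics to the formant statistics.
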