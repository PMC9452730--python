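# Methods

`rtnf` is a desk-scale, fully simulatable re-creation of a two-step
subject-independent real-time fMRI neurofeedback (rt-fMRI NF) protocol for
depression: (1) build a brain-state classifier from a healthy "tutor"
participant's happy-autobiographical-imagery versus motor-imagery runs;
(2) use that classifier, unchanged, to deliver per-volume visual and
monetary feedback to patients so they learn to reproduce the tutor's
"happy" brain state. Everything runs on synthetic data, so every stage is
testable end to end without scanner access.

## Paradigm

A run is a 7-minute block design at TR = 2 s: 20 s rest, then four
repetitions of 40 s happy imagery ("H"), 40 s motor imagery ("M"), 20 s
rest ("+"), for 420 s = 210 volumes (80 HAPPY, 80 MOTOR, 50 REST). The run
length, block lengths and repetition count pin this layout down uniquely;
the schedule is nevertheless fully configurable (`build_paradigm` accepts
any (condition, duration) sequence whose durations are multiples of the
TR).

## Synthetic BOLD generator

Each run is

```
Y(v, t) = B(v) * (1 + Σ_c P_c(v) * (boxcar_c ⊛ h)(t)) + d(v, t) + ε(v, t)
```

- **Grid**: 20×24×20 voxels at a nominal 3 mm (the acquisition's voxel
  size), with an ellipsoidal brain support; baseline B = 100 inside, 0
  outside. The grid is configurable; this default keeps a full 112-run
  cohort simulation under a minute.
- **HRF** `h`: the canonical SPM double-gamma (peak ≈ 6 s, undershoot
  ≈ 16 s), via nilearn's regressor machinery. Regressors are scaled by the
  HRF's steady-state (long-block plateau) response so that a pattern
  amplitude of 0.01 means a sustained 1% signal change — the conventional
  way percent-signal-change is quoted for block designs.
- **Patterns** `P_c`: two disjoint multi-focal Gaussian-blob maps
  (anterior-ventral "happy", dorsal-posterior "motor"), peak amplitude 1%
  of baseline, a typical cortical BOLD effect size.
- **Noise** ε: stationary AR(1) per voxel (default marginal SD 0.5
  intensity units ≈ 0.5% of baseline, lag-1 coefficient 0.3), confined to
  the brain support. **Drift** d: linear, default ±0.5 units across the
  run. These defaults give single-voxel task CNR well below 1 before
  smoothing, which is what makes the decoding problem non-trivial at this
  scale.
- **Subjects**: a subject's pattern is `f·T + sqrt(1-f²)·I`, where T is the
  tutor template, I is a seeded smooth random field orthogonalized (over
  the support, mean-centred) against *both* templates and scaled to the
  template norm, and `f` is the **pattern fidelity** — exactly the spatial
  correlation with the template. f = 1 reproduces the tutor; f = 0 is
  uncorrelated. **Learning** is modelled as `f_s = min(1, f + (s-1)·λ)` per
  training session s; λ is the learning rate. This is a phenomenological
  stand-in that produces rising classifier accuracy across sessions; it
  makes no claim about neural mechanism.

What the generator does **not** emulate: head motion (beyond what
`apply_rigid` injects deliberately), physiological (cardiac/respiratory)
noise, spatial noise correlations, susceptibility artefacts, and
between-subject anatomical variability (all subjects share the grid).
Passing tests therefore demonstrate the pipeline's correctness and its
behaviour under the stated noise model, not performance on real scanner
data.

## Preprocessing

Offline (classifier construction): discard the first 10 volumes
(gradient-settling guard), rigid-body realignment to the first volume,
slice-timing correction, affine normalization to the template grid, 8 mm
FWHM Gaussian smoothing. Online (closed loop): resample with the *stored*
normalization parameters and smooth at 6 mm — nothing is re-estimated per
volume, which keeps the per-volume cost far below one TR (logged, ~1 ms at
the default grid).

Design choices where the field offers several options:

- **Normalization** is a 12-parameter affine to a configurable template
  grid (default: the tutor's own grid), estimated once from the mean of a
  1-minute (30-volume) "dummy" run by two-stage Powell minimization of the
  mean-squared difference (translations first, then the full affine, cubic
  resampling inside the cost). Full segmentation-based MNI normalization is
  deliberately out of scope; the affine preserves the architecture — dummy
  run → stored parameters → fast online resampling — without shipping a
  segmentation pipeline.
- **Realignment** estimates 6 rigid parameters per volume (mm/degrees,
  rotation about the volume centre) by Powell minimization with linear
  resampling, warm-started at the previous volume's estimate. On this
  problem size a direct least-squares registration is exact enough
  (injected 2-voxel translations are recovered to <1%) and fully
  deterministic. The demo configuration skips realignment because the
  generator injects no motion; it stays available (and tested) for data
  that has any.
- **Slice timing** uses Fourier phase shifting (exact for band-limited
  series), default interleaved-ascending order, reference slice 0.
- **Smoothing FWHM** defaults: 8 mm offline, 6 mm online — field-standard
  values at 3 mm voxels; the protocol description does not fix them.

## Classifier (MVPA)

Features are single preprocessed volumes over an intensity mask (voxels
above 0.5× the grand mean of positive voxels). Per run the features are
detrended; two modes exist:

- `"linear"`: remove a least-squares line per voxel over the whole run —
  the classical offline description;
- `"online"` (the default used by the experiment pipeline): a *causal*
  running linear fit anchored on the rest volumes seen so far, replayed
  identically by the closed loop (`OnlineDetrender`).

The online mode exists because training and deployment must see the same
feature distribution: a whole-run line absorbs part of the task response
(making task features two-sided around zero), whereas a rest-anchored
baseline leaves the task response one-sided. Training offline-style and
deploying online-style mixes the two and measurably degrades closed-loop
accuracy; training on the deployment transform removes the mismatch. The
rest-anchored fit also never contaminates the trend estimate with the very
signal being classified.

Classification is a linear SVM (C = 1, per-voxel standardization with
training statistics only; HAPPY = +1). The **effect map** combines the
discriminative weight with the activation difference,
`e_j = w_j · (mean_j(HAPPY) − mean_j(MOTOR))`, and the model keeps the top
5% of voxels by |e| (configurable; a threshold rule is also provided),
then retrains the SVM on the selected voxels — those weights are what the
closed loop evaluates. The exact effect-value formula in the original
toolchain is not public; this weight-times-activation-difference form is
implemented behind a narrow interface (`effect_map`) so an alternative can
be swapped in, and its correctness criterion is behavioural: the |e|-argmax
recovers a single informative voxel among 999 noise voxels in ≥95% of
seeded replicates.

A **hemodynamic label shift** (default 0 in the low-level API, 3 TRs ≈ 6 s
in the experiment configuration) delays the label assignment relative to
the stimulus schedule. Without it, the ~6 s BOLD lag leaks each happy
block's tail into the immediately following motor block (the layout has no
rest between H and M), which systematically depresses the happy-voxel
class contrast.

Validation is leave-one-run-out over the four tutor runs (mask statistics,
effect map and selection re-derived inside each fold); the report carries
per-fold accuracy/sensitivity/specificity and their means, with sensitivity
anchored on HAPPY. Published-style tables round half away from zero to two
decimals (`fold_average`); a fold mean of 0.9475 therefore prints as 0.95.

## Closed loop

Per volume: online preprocessing → rest-anchored detrend → restrict to the
model's selected voxels → standardize with stored constants → sign of
`w·x + b` (a tie at exactly 0 is called HAPPY — an arbitrary but
deterministic and logged rule). During task blocks a correct classification
adds one bar to a 10-bar thermometer and an error removes one, clamped to
[0, 10]; at each rest block the display resets to the previous task block's
mean bar level (rounded half to even; the very first rest block, which has
no predecessor, resets to the midpoint, 5 bars).

**Run accuracy** follows the protocol's printed formula: 100 × correct /
210 — rest volumes stay in the denominator and can never be correct, so
the attainable ceiling is 160/210 = 76.19%. A `task_only` mode (denominator
160) is also exposed and is the right scale for chance-level comparisons
(50% under label exchange). **Reward**: 1.5 USD at ≤50% accuracy, then 2
USD per started 5% band (3.5 USD for 51–55, 5.5 for 56–60, 7.5 for 61–65,
…, 21.5 at 100%), displayed during the final 3 s of the run (an event-log
entry here).

## Statistics

- **Exact Wilcoxon signed-rank versus zero**: zeros dropped (Wilcoxon's
  original procedure), mid-ranks for ties, and the exact null distribution
  of W⁺ built by integer convolution over the doubled ranks — numerically
  identical to enumerating all 2ⁿ sign assignments, used for every n ≤ 25
  (the protocol's n is 7; the two-tailed floor at n = 7 is 2/128 =
  0.015625). Above n = 25 a tie-corrected normal approximation takes over.
  Two-tailed p = min(1, 2·min(P(W⁺≤w), P(W⁺≥w))).
- **One-sample z-test**: z = (mean − 50)/(sd/√n) against the standard
  normal; the day-4 comparison is one-tailed upper (the direction the
  protocol tests, and the only sidedness consistent with its printed
  mean/SD/p triple).
- **Learning deltas** per participant: Run16−Run1, (Run15+Run16−Run1−Run2)/2,
  mean(Day 4)−mean(Day 1); each delta vector feeds the exact Wilcoxon.
  **Slopes**: OLS of accuracy against the 1-based run or session index.
- **Clinical deltas**: improvements between the three evaluations (CE1 day
  before, CE2 day after, CE3 ten days later), computed as earlier − later
  so a positive value is an improvement on BDI-II/HDRS (lower score =
  better); group exact Wilcoxon per instrument per interval. All-zero
  intervals (e.g. a perfectly stable follow-up) are reported as untestable
  rather than forced through. The report generator flags unanimous-sign
  samples with the exact floor 2/2ⁿ, since a two-tailed p below that floor
  is impossible at the given n.
- **Screening**: eligible iff 10 ≤ BDI-II ≤ 29 and suicide item < 2 and
  Okasha < 5; risk exclusion takes precedence over severity when both
  apply (safety-first, a deliberate choice — the source rules don't order
  them). Severity bands: <10 none, 10–19 mild, 20–29 moderate, >29 severe
  (the 19/20 split is our choice; the 10 and 29 cut-points are fixed by
  the recruitment rules). No multiple-testing correction is applied,
  matching the analysis being reproduced.

## Reproducibility and problem sizes

All randomness flows from explicit integer seeds (configs refuse implicit
ones); identical seeds give bit-identical runs, and `run_experiment` writes
a manifest with a hash of the numeric outputs that reruns must reproduce.
The default demo experiment — 1 tutor (4 runs) + 7 patients × 16 runs of
210 volumes on the 20×24×20 grid — completes in well under a minute on one
CPU; the property suite uses 5–10 seeded replicates of cohort-level
simulations and 100–500 replicates of the cheap statistical properties.

## Known limitations

- The synthetic learning model moves fidelity linearly per session; real
  neurofeedback learning curves are noisier and can plateau or regress.
- Chance-level behaviour at fidelity 0 holds on average across subjects; a
  single subject's idiosyncratic pattern can project onto the classifier
  and sit stably above or below 50% for that subject.
- The affine normalization cannot absorb nonlinear anatomical differences;
  on real multi-subject data this underestimates the achievable
  cross-subject alignment.
- The exact Wilcoxon is conditional on the observed ranks; with heavy ties
  the mid-rank enumeration is the standard but not unique convention.
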