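# rtnf

A simulatable real-time fMRI neurofeedback (rt-fMRI NF) pipeline with a
**subject-independent** brain-state classifier, for methods work on
decoded-neurofeedback protocols in depression.

Most fMRI neurofeedback trains patients on their *own* neural activity —
which is problematic when the condition itself (here, depression) alters
the very networks being fed back. The alternative this package implements:
train a classifier on a *healthy* "tutor" participant discriminating two
cognitive states — happy autobiographical imagery vs. motor imagery — and
then use that fixed classifier, in a common template space, to give a
patient per-volume feedback so they learn to reproduce the tutor's happy
brain state. Since no public dataset accompanies this protocol, the
package ships a first-class synthetic-data generator, so the whole closed
loop is reproducible on a laptop.

The pieces (one module each, usable independently):

- `rtnf.paradigm` — the block design: 20 s rest + 4 × (40 s happy, 40 s
  motor, 20 s rest) at TR = 2 s → 210 volumes per 7-minute run.
- `rtnf.synth` — block-design BOLD simulation: `baseline · (1 + Σ_c P_c ·
  (boxcar_c ⊛ HRF))` + linear drift + AR(1) noise on a 20×24×20 grid of
  3 mm voxels, with a *pattern fidelity* parameter f ∈ [0, 1] (spatial
  correlation of a subject's activation maps with the tutor template) and
  per-session learning f_s = min(1, f + (s−1)·λ).
- `rtnf.preprocess` — offline chain (discard 10 volumes, rigid realignment,
  slice timing, affine normalization, 8 mm smoothing) and the abbreviated
  online path driven by dummy-run normalization parameters (resample +
  6 mm smooth, well under one TR per volume).
- `rtnf.mvpa` — intensity mask, detrending, linear SVM (HAPPY = +1), the
  effect map e_j = w_j · (mean_j(HAPPY) − mean_j(MOTOR)), top-5%
  informative-voxel selection, leave-one-run-out cross-validation.
- `rtnf.neurofeedback` — the closed loop: per-TR classification,
  thermometer bars (±1 per outcome, rest-block reset to the previous
  block's mean), run accuracy = 100 × correct/210, and the monetary reward
  schedule (1.5 USD at ≤50%, +2 USD per started 5% band).
- `rtnf.stats` — exact (full 2ⁿ enumeration) one-sample Wilcoxon
  signed-rank versus zero, one-sample z-test versus 50%, learning deltas
  and slopes, clinical change scores (BDI-II / HDRS at three evaluations),
  and the recruitment screens.
- `rtnf.experiment` / `rtnf.cli` — end-to-end seeded experiments with a
  hashed manifest, fixture generation, and a thin `rtnf` command
  (`synth`, `train`, `nf`, `stats`, `experiment`, `fixtures`).

## Worked example

Train the tutor classifier and put one synthetic patient through a
closed-loop run (`examples/03_closed_loop_session.py`):

```python
from rtnf import build_paradigm, make_subject_profile, run_feedback, simulate_run
from rtnf.experiment import default_config, train_tutor_model

cfg = default_config(master_seed=1, n_patients=1)
model, report, norm = train_tutor_model(cfg)

paradigm = build_paradigm()
patient = make_subject_profile(pattern_fidelity=0.4, seed=99)
run = simulate_run(paradigm, patient, seed=7)
result = run_feedback(run, model, norm, paradigm, label_shift=cfg.label_shift)
```

This prints (exact numbers for these seeds):

```
correct classifications: 104 / 210 volumes (rest volumes cannot score; ceiling 160)
run accuracy: 49.52%  (100 x correct / 210, the study's reported formula)
monetary reward: 1.50 USD (1.5 USD at <=50%, +2 USD per started 5% band above)
thermometer trajectory (first task block): [5, 5, 5, 6, 7, 8, 9, 10, 10, 10, ...]
```

A fidelity-0.4 patient sits near the middle of the range: 104 of the 160
scoreable task volumes match the tutor model (65% of task volumes), which
the protocol's denominator-210 formula reports as 49.5% and rewards at the
1.5 USD floor. A fidelity-1.0 subject (the tutor replayed) scores >90% of
task volumes; a fidelity-0 subject averages ~50% of them. The cohort
example (`examples/04_learning_statistics.py`) runs 7 patients × 4 days ×
4 runs with positive learning rates and prints the group statistics, e.g.:

```
group accuracy by training day (%):
  day1: 41.80 (SD 3.25)   ...   day4: 68.59 (SD 6.34)
day-4 one-sample z-test vs 50%: z = 7.76, one-tailed p = 4.2e-15
day4 - day1: median 27.14%, exact Wilcoxon two-tailed p = 0.01562
HDRS CE2-CE1: Median = 7; Range = 2 to 15; Wilcoxon Test (0), 2-tailed p = 0.0156
```

The Wilcoxon p of 0.015625 = 2/2⁷ is the exact two-tailed floor for seven
same-signed differences — the signature of "all seven patients improved".

## Layout

```
src/rtnf/          library modules
examples/          narrative scripts, one per capability
tests/             pytest suite (unit, property and acceptance tests)
scripts/           acceptance.py
docs/methods.md    the model, parameter and design-choice documentation
```
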