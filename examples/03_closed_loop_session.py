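"""One simulated closed-loop neurofeedback run for a patient.

A synthetic patient whose activation patterns only partially match the
tutor's is streamed through the loop: each 2-second volume is preprocessed
with the dummy-run normalization parameters, classified by the tutor's SVM,
and fed to the thermometer (one bar up per correct classification, one down
per error, reset to the previous block's mean at each rest). The run ends
with the accuracy and the monetary reward shown to the participant.
"""

from rtnf import build_paradigm, make_subject_profile, run_feedback, simulate_run
from rtnf.experiment import default_config, train_tutor_model

cfg = default_config(master_seed=1, n_patients=1)
model, _, norm = train_tutor_model(cfg)

paradigm = build_paradigm()
patient = make_subject_profile(pattern_fidelity=0.4, seed=99)
run = simulate_run(paradigm, patient, seed=7)

result = run_feedback(run, model, norm, paradigm, label_shift=cfg.label_shift)

correct = sum(o.correct for o in result.outcomes)
print(f"correct classifications: {correct} / 210 volumes "
      f"(rest volumes cannot score; ceiling 160)")
print(f"run accuracy: {result.accuracy_percent:.2f}%  "
      f"(100 x correct / 210, the study's reported formula)")
print(f"monetary reward: {result.reward_usd:.2f} USD "
      f"(1.5 USD at <=50%, +2 USD per started 5% band above)")
print(f"thermometer trajectory (first task block): "
      f"{result.bar_trajectory[10:30]}")
print(result.events[-1])
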