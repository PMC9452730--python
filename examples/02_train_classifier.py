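"""Train the subject-independent brain-state classifier on tutor data.

Simulates the healthy tutor's four classifier-construction runs, applies the
offline preprocessing chain (discard 10 volumes, slice-time, normalization,
8 mm smoothing), trains the linear SVM with effect-map voxel selection, and
prints the leave-one-run-out cross-validation report — the per-fold
accuracy/sensitivity/specificity table this kind of study publishes.
"""

from rtnf.experiment import default_config, train_tutor_model

cfg = default_config(master_seed=1, n_patients=1)
model, report, norm = train_tutor_model(cfg)

print("leave-one-run-out cross-validation (4 folds, HAPPY = positive class)")
for i in range(report.n_folds):
    print(f"  fold {i + 1}: accuracy {report.fold_accuracy[i]:.2f}  "
          f"sensitivity {report.fold_sensitivity[i]:.2f}  "
          f"specificity {report.fold_specificity[i]:.2f}")
print(f"  average: accuracy {report.average_accuracy:.2f}  "
      f"sensitivity {report.average_sensitivity:.2f}  "
      f"specificity {report.average_specificity:.2f}")
print(f"\ninformative voxels selected (top 5% by |effect|): {len(model.selected)}")
print("effect values couple the SVM weight with each voxel's "
      "happy-minus-motor activation difference")
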