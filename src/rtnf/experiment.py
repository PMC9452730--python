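"""End-to-end experiment orchestration and fixture generation.

`run_experiment` replays the whole two-step protocol on synthetic data:
simulate the healthy tutor's four classifier-construction runs, run the
offline preprocessing chain, train and cross-validate the SVM/effect-map
classifier, then put each simulated patient through 4 training days of 4
closed-loop runs and compute the learning statistics. All randomness flows
from the explicit seeds in the config; a rerun with the same config
reproduces the same numeric outputs (verified through the manifest hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mvpa, neurofeedback as nf, preprocess, stats, synth
from .paradigm import build_paradigm

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class SubjectSpec:
    """Serializable subject description (expanded to a SubjectProfile)."""

    seed: int
    pattern_fidelity: float = 1.0
    noise_sigma: float = 0.5
    ar1_coefficient: float = 0.3
    drift_amplitude: float = 0.5
    learning_rate: float = 0.0


@dataclass
class ExperimentConfig:
    tr_seconds: float = 2.0
    grid_shape: tuple[int, int, int] = synth.DEFAULT_SHAPE
    tutor: SubjectSpec | None = None
    patients: list[SubjectSpec] = field(default_factory=list)
    n_tutor_runs: int = 4
    days: int = 4
    runs_per_day: int = 4
    n_discard: int = 10
    do_realign: bool = True
    offline_fwhm_mm: float = preprocess.DEFAULT_OFFLINE_FWHM_MM
    online_fwhm_mm: float = preprocess.DEFAULT_ONLINE_FWHM_MM
    selection_rule: str = "top_fraction"
    selection_value: float = 0.05
    detrend: str = "online"     # feature detrending identical to the closed loop
    label_shift: int = 3        # hemodynamic delay, TRs (~6 s at TR 2 s)
    svm_cost: float = 1.0
    accuracy_mode: str = "all_volumes"
    master_seed: int = 0

    def validate(self) -> None:
        if self.tutor is None:
            raise ValueError("config is missing the tutor profile (field 'tutor')")
        if not self.patients:
            raise ValueError("config has no patients (field 'patients')")
        for name in ("tr_seconds", "n_tutor_runs", "days", "runs_per_day"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name!r} must be positive")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        raw = yaml.safe_load(text)
        if raw.get("tutor") is not None:
            raw["tutor"] = SubjectSpec(**raw["tutor"])
        raw["patients"] = [SubjectSpec(**p) for p in raw.get("patients", [])]
        raw["grid_shape"] = tuple(raw.get("grid_shape", synth.DEFAULT_SHAPE))
        return cls(**raw)


def default_config(master_seed: int = 0, n_patients: int = 7) -> ExperimentConfig:
    """The study-like demo configuration: one high-fidelity tutor and a
    7-patient cohort starting near chance with per-session learning."""
    rng = np.random.default_rng(master_seed)
    patients = [
        SubjectSpec(
            seed=int(rng.integers(2**31 - 1)),
            pattern_fidelity=float(rng.uniform(0.05, 0.25)),
            learning_rate=float(rng.uniform(0.10, 0.25)),
        )
        for _ in range(n_patients)
    ]
    return ExperimentConfig(
        tutor=SubjectSpec(seed=int(rng.integers(2**31 - 1)), pattern_fidelity=1.0),
        patients=patients,
        master_seed=master_seed,
        # the generator injects no head motion, so the demo skips the
        # realignment estimate (it recovers ~0 and only costs time)
        do_realign=False,
    )


def _profile_from_spec(spec: SubjectSpec, cfg: ExperimentConfig) -> synth.SubjectProfile:
    return synth.make_subject_profile(
        pattern_fidelity=spec.pattern_fidelity,
        seed=spec.seed,
        shape=tuple(cfg.grid_shape),
        noise_sigma=spec.noise_sigma,
        ar1_coefficient=spec.ar1_coefficient,
        drift_amplitude=spec.drift_amplitude,
        learning_rate=spec.learning_rate,
    )


def train_tutor_model(
    cfg: ExperimentConfig,
) -> tuple[mvpa.EffectMapModel, mvpa.CVReport, preprocess.NormParams]:
    """Step 1: simulate the tutor's runs, preprocess offline, train + CV."""
    cfg.validate()
    paradigm = build_paradigm(cfg.tr_seconds)
    tutor = _profile_from_spec(cfg.tutor, cfg)
    rng = np.random.default_rng(cfg.master_seed)

    # the tutor grid doubles as the template space; a 1-minute dummy run
    # provides the normalization estimate exactly as the online path will use
    dummy_paradigm = build_paradigm(cfg.tr_seconds, (("REST", 60.0),))
    dummy = synth.simulate_run(dummy_paradigm, tutor, seed=int(rng.integers(2**31 - 1)))
    template = dummy.mean_volume()
    norm = preprocess.estimate_norm_params(
        dummy, template, smoothing_fwhm_mm=cfg.online_fwhm_mm
    )

    runs = []
    for _ in range(cfg.n_tutor_runs):
        raw = synth.simulate_run(paradigm, tutor, seed=int(rng.integers(2**31 - 1)))
        pre, _ = preprocess.offline_preprocess(
            raw, norm, n_discard=cfg.n_discard, fwhm_mm=cfg.offline_fwhm_mm,
            do_realign=cfg.do_realign,
        )
        runs.append(pre)

    mask = mvpa.make_mask(np.mean([r.mean_volume() for r in runs], axis=0))
    features = mvpa.extract_features(runs, mask, detrend=cfg.detrend,
                                     label_shift=cfg.label_shift)
    report = mvpa.cross_validate(features, cfg.selection_rule, cfg.selection_value,
                                 C=cfg.svm_cost)
    model = mvpa.train_effect_map_model(features, cfg.selection_rule,
                                        cfg.selection_value, C=cfg.svm_cost)
    return model, report, norm


def run_patient_protocol(
    patient: synth.SubjectProfile,
    model: mvpa.EffectMapModel,
    norm: preprocess.NormParams,
    cfg: ExperimentConfig,
    seed: int,
) -> list[nf.RunResult]:
    """Step 2 for one patient: days x runs_per_day closed-loop runs, with
    the patient's pattern fidelity advancing by learning_rate per day."""
    paradigm = build_paradigm(cfg.tr_seconds)
    rng = np.random.default_rng(seed)
    results: list[nf.RunResult] = []
    for day in range(1, cfg.days + 1):
        for _ in range(cfg.runs_per_day):
            raw = synth.simulate_run(paradigm, patient, session=day,
                                     seed=int(rng.integers(2**31 - 1)))
            results.append(
                nf.run_feedback(raw, model, norm, paradigm,
                                accuracy_mode=cfg.accuracy_mode,
                                label_shift=cfg.label_shift)
            )
    return results


def accuracy_table(all_results: dict[str, list[nf.RunResult]]) -> pd.DataFrame:
    rows = {
        pid: {f"run{i + 1}": r.accuracy_percent for i, r in enumerate(results)}
        for pid, results in all_results.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def compute_stats_report(table: pd.DataFrame, runs_per_day: int = 4) -> dict:
    """Accuracy aggregates, learning deltas with exact Wilcoxon tests,
    Day-4 z-test against 50, and per-participant slopes."""
    days = stats.day_means(table, runs_per_day=runs_per_day)
    day_cols = list(days.columns)
    if all(f"run{i}" in table.columns for i in range(1, stats.N_RUNS + 1)):
        deltas = stats.learning_deltas(table)
    else:
        # reduced protocols: generic first/last summaries only
        run_cols = [c for c in table.columns if c.startswith("run")]
        deltas = pd.DataFrame({
            "last_run_minus_first_run": table[run_cols[-1]] - table[run_cols[0]],
            "last_day_minus_first_day": days[day_cols[-1]] - days[day_cols[0]],
        }, index=table.index)
    report: dict = {
        "per_day_mean": {c: float(days[c].mean()) for c in days.columns},
        "per_day_sd": {c: float(days[c].std(ddof=1)) for c in days.columns},
        "deltas": {},
        "slopes": {},
    }
    for col in deltas.columns:
        d = deltas[col].to_numpy()
        try:
            t = stats.wilcoxon_signed_rank_exact(d)
            test = {"W_plus": t.statistic, "p_two_tailed": t.p_value, "n": t.n}
        except ValueError as exc:
            t, test = None, {"error": str(exc)}
        report["deltas"][col] = {
            "median": float(np.median(d)),
            "range": [float(d.min()), float(d.max())],
            "wilcoxon": test,
            "summary": stats.format_test_line(col, d, t),
        }
    last_day = days[day_cols[-1]]
    if len(table) >= 2 and last_day.std(ddof=1) > 0:
        zt = stats.ztest_one_sample(last_day.to_numpy(), null_value=50.0)
        report["last_day_vs_50"] = {"z": zt.statistic, "p_one_tailed": zt.p_value,
                                    "n": zt.n, "day": day_cols[-1]}
    run_cols = [c for c in table.columns if c.startswith("run")]
    for pid, row in table.iterrows():
        acc = row[run_cols].to_numpy(float)
        slopes = {"per_run": stats.learning_slope(acc, "run")}
        if len(acc) >= 2 * runs_per_day:
            slopes["per_session"] = stats.learning_slope(
                acc, "session", runs_per_day=runs_per_day)
        report["slopes"][str(pid)] = slopes
    return report


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_experiment(cfg: ExperimentConfig, outdir: str | Path) -> Path:
    """Run the full protocol and write the artifact directory.

    Contents: model bundle, cross-validation report, per-run feedback logs
    (TSV), the accuracy table, the statistics report (JSON) and a manifest
    with the package version, config hash and a hash of the numeric outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        cfg.validate()
        model, cv_report, norm = train_tutor_model(cfg)
        mvpa.save_model(model, outdir / "model",
                        affine=synth.default_affine(tuple(cfg.grid_shape)))
        (outdir / "cv_report.json").write_text(json.dumps({
            "fold_accuracy": cv_report.fold_accuracy,
            "fold_sensitivity": cv_report.fold_sensitivity,
            "fold_specificity": cv_report.fold_specificity,
            "average_accuracy": cv_report.average_accuracy,
            "average_sensitivity": cv_report.average_sensitivity,
            "average_specificity": cv_report.average_specificity,
        }, indent=2))

        rng = np.random.default_rng(cfg.master_seed + 1)
        all_results: dict[str, list[nf.RunResult]] = {}
        for i, spec in enumerate(cfg.patients):
            pid = f"patient{i + 1}"
            profile = _profile_from_spec(spec, cfg)
            results = run_patient_protocol(profile, model, norm, cfg,
                                           seed=int(rng.integers(2**31 - 1)))
            all_results[pid] = results
            logdir = outdir / "runs" / pid
            logdir.mkdir(parents=True, exist_ok=True)
            for j, res in enumerate(results):
                rows = [
                    (o.volume_index, o.expected.value,
                     o.predicted.value if o.predicted else "",
                     int(o.correct), o.bar_count)
                    for o in res.outcomes
                ]
                pd.DataFrame(
                    rows, columns=["volume", "expected", "predicted",
                                   "correct", "bar_count"]
                ).to_csv(logdir / f"run{j + 1:02d}.tsv", sep="\t", index=False)

        table = accuracy_table(all_results)
        table.to_csv(outdir / "accuracy_table.tsv", sep="\t")
        report = _round_floats(compute_stats_report(table, cfg.runs_per_day))
        (outdir / "stats_report.json").write_text(json.dumps(report, indent=2))

        numeric_payload = json.dumps(
            {"table": _round_floats(table.round(10).to_dict()), "stats": report},
            sort_keys=True,
        )
        manifest = {
            "rtnf_version": __version__,
            "config_sha256": hashlib.sha256(cfg.to_yaml().encode()).hexdigest(),
            "outputs_sha256": hashlib.sha256(numeric_payload.encode()).hexdigest(),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (outdir / "config.yaml").write_text(cfg.to_yaml())
    except Exception:
        (outdir / "FAILED").write_text(
            "experiment did not complete; partial outputs in this directory "
            "are not trustworthy\n"
        )
        raise
    return outdir


# ---------------------------------------------------------------------------
# fixtures

def make_fixtures(seed: int, outdir: str | Path) -> Path:
    """Small canonical datasets used across the test-suite and examples:
    a separable two-cloud SVM problem, a single-informative-voxel feature
    set, and a 7-patient cohort of subject specs with positive learning."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    n, dim = 100, 5
    centre = np.zeros(dim)
    centre[0] = 3.0
    X = np.vstack([
        rng.normal(+centre, 1.0, size=(n, dim)),
        rng.normal(-centre, 1.0, size=(n, dim)),
    ])
    y = np.array([1] * n + [-1] * n)
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(dim)])
    df["label"] = y
    df.to_csv(outdir / "separable_clouds.csv", index=False)

    n_vox, n_samp, informative = 200, 80, 17
    Xv = rng.normal(0.0, 1.0, size=(n_samp, n_vox))
    yv = np.array([1, -1] * (n_samp // 2))
    Xv[:, informative] += 1.5 * yv
    dfv = pd.DataFrame(Xv, columns=[f"v{i}" for i in range(n_vox)])
    dfv["label"] = yv
    dfv.to_csv(outdir / "single_informative_voxel.csv", index=False)
    (outdir / "single_informative_voxel.yaml").write_text(
        yaml.safe_dump({"informative_voxel": informative})
    )

    cohort = default_config(master_seed=seed, n_patients=7)
    (outdir / "cohort_config.yaml").write_text(cohort.to_yaml())
    return outdir
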