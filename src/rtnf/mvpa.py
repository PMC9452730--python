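"""Subject-independent brain-state decoding.

Pipeline: intensity-based brain mask -> per-run linear detrending ->
volume-wise feature vectors for the two task conditions -> linear SVM ->
per-voxel effect map e_j = w_j * (mean_j(HAPPY) - mean_j(MOTOR)) ->
informative-voxel selection -> leave-one-run-out cross-validation report.

Class coding is HAPPY = +1 (the positive class for sensitivity), MOTOR = -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from sklearn.svm import SVC

from .images import BoldRun
from .paradigm import Condition

POSITIVE_CLASS = Condition.HAPPY  # +1
NEGATIVE_CLASS = Condition.MOTOR  # -1

DEFAULT_TOP_FRACTION = 0.05


# ---------------------------------------------------------------------------
# containers

@dataclass
class FeatureMatrix:
    """Task volumes as samples (rows) over masked voxels (columns)."""

    X: np.ndarray               # (n_samples, n_voxels)
    y: np.ndarray               # +1 (HAPPY) / -1 (MOTOR) per sample
    run_ids: np.ndarray         # run index per sample
    voxel_indices: np.ndarray   # flat index of each column into the 3-D grid
    grid_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        self.y = np.asarray(self.y, int)
        self.run_ids = np.asarray(self.run_ids, int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x voxels)")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")
        if len(self.y) != len(self.X) or len(self.run_ids) != len(self.X):
            raise ValueError("label / run-id length mismatch with X")
        if not set(np.unique(self.y)) <= {-1, 1}:
            raise ValueError("labels must be +1 (HAPPY) or -1 (MOTOR); no REST samples")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]


@dataclass
class EffectMapModel:
    """Trained decision rule on the selected informative voxels.

    ``weights``/``bias`` act on voxels listed in ``selected`` (flat grid
    indices, ordered by decreasing |effect|), after standardization with the
    stored per-voxel constants. ``effect_values`` covers every mask voxel.
    """

    weights: np.ndarray          # per selected voxel
    bias: float
    effect_values: np.ndarray    # per mask voxel
    mask_indices: np.ndarray     # flat indices of mask voxels
    selected: np.ndarray         # flat indices of selected voxels (subset of mask)
    grid_shape: tuple[int, int, int]
    feature_mean: np.ndarray     # standardization constants, per selected voxel
    feature_std: np.ndarray
    class_coding: dict = field(
        default_factory=lambda: {"HAPPY": 1, "MOTOR": -1}
    )

    def __post_init__(self) -> None:
        if len(self.selected) < 1:
            raise ValueError("at least one voxel must be selected")
        if not set(self.selected.tolist()) <= set(self.mask_indices.tolist()):
            raise ValueError("selected voxels must lie inside the mask")
        if len(self.effect_values) != len(self.mask_indices):
            raise ValueError("one effect value per mask voxel required")

    def decision_value(self, x_selected: np.ndarray) -> float:
        if x_selected.shape[-1] != len(self.selected):
            raise ValueError(
                f"feature length {x_selected.shape[-1]} != "
                f"{len(self.selected)} selected voxels"
            )
        z = (x_selected - self.feature_mean) / self.feature_std
        return float(z @ self.weights + self.bias)

    def predict(self, x_selected: np.ndarray) -> Condition:
        """Ties at decision value exactly 0 go to HAPPY (documented rule)."""
        return POSITIVE_CLASS if self.decision_value(x_selected) >= 0 else NEGATIVE_CLASS


@dataclass
class CVReport:
    """Per-fold accuracy / sensitivity / specificity and their means."""

    fold_accuracy: list[float]
    fold_sensitivity: list[float]
    fold_specificity: list[float]
    confusion: list[dict] | None = None  # tp/fn/tn/fp per fold, when computed

    @property
    def n_folds(self) -> int:
        return len(self.fold_accuracy)

    @property
    def average_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def average_sensitivity(self) -> float:
        return float(np.mean(self.fold_sensitivity))

    @property
    def average_specificity(self) -> float:
        return float(np.mean(self.fold_specificity))


def fold_average(values: list[float], decimals: int = 2) -> float:
    """Arithmetic fold mean, rounded half away from zero to `decimals`."""
    m = float(np.mean(values))
    scale = 10**decimals
    return float(np.floor(abs(m) * scale + 0.5) / scale * np.sign(m))


# ---------------------------------------------------------------------------
# operations

def make_mask(mean_volume: np.ndarray, threshold_fraction: float = 0.5) -> np.ndarray:
    """Boolean brain mask: voxels brighter than `threshold_fraction` times
    the grand mean of the positive voxels."""
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    mean_volume = np.asarray(mean_volume, float)
    positive = mean_volume[mean_volume > 0]
    if positive.size == 0:
        raise ValueError("mask is empty: no positive voxels in the mean volume")
    mask = mean_volume > threshold_fraction * positive.mean()
    if not mask.any():
        raise ValueError("mask is empty at this threshold")
    return mask


def detrend_linear(series: np.ndarray, run_ids: np.ndarray | None = None) -> np.ndarray:
    """Remove a least-squares line (intercept + slope) per voxel, per run.

    `series` is (n_timepoints, n_voxels); `run_ids` marks run membership of
    each timepoint (single run if omitted). Output has ~zero mean per run.
    """
    series = np.asarray(series, float)
    if series.ndim == 1:
        series = series[:, None]
    n = len(series)
    if run_ids is None:
        run_ids = np.zeros(n, int)
    run_ids = np.asarray(run_ids)
    if len(run_ids) != n:
        raise ValueError("run_ids length must match number of timepoints")
    out = np.empty_like(series)
    for run in np.unique(run_ids):
        sel = run_ids == run
        m = int(sel.sum())
        if m < 3:
            raise ValueError(f"run {run} has {m} < 3 timepoints")
        t = np.arange(m, dtype=float)
        design = np.column_stack([np.ones(m), t])
        coef, *_ = np.linalg.lstsq(design, series[sel], rcond=None)
        out[sel] = series[sel] - design @ coef
    return out


class OnlineDetrender:
    """Incremental per-voxel linear detrending for the closed loop.

    Offline training removes a least-squares line per voxel; the online
    stream mirrors that causally with a running linear fit anchored on the
    rest volumes seen so far (rest periods carry baseline + drift but no
    task response, so the trend estimate is never contaminated by the very
    signal being classified). Each incoming volume returns its residual
    from the extrapolated trend; before two rest volumes have arrived the
    running rest mean (or the volume itself) is used.
    """

    def __init__(self, n_voxels: int) -> None:
        self.t = 0          # global volume counter
        self.n_rest = 0     # rest volumes accumulated in the fit
        self.s_t = 0.0
        self.s_tt = 0.0
        self.s_x = np.zeros(n_voxels)
        self.s_tx = np.zeros(n_voxels)

    def update(self, x: np.ndarray, is_rest: bool = False) -> np.ndarray:
        x = np.asarray(x, float)
        t = float(self.t)
        self.t += 1
        if is_rest:
            self.n_rest += 1
            self.s_t += t
            self.s_tt += t * t
            self.s_x += x
            self.s_tx += t * x
        if self.n_rest == 0:
            return np.zeros_like(x)
        if self.n_rest < 3:
            return x - self.s_x / self.n_rest
        det = self.n_rest * self.s_tt - self.s_t**2
        if det <= 1e-12:
            return x - self.s_x / self.n_rest
        slope = (self.n_rest * self.s_tx - self.s_t * self.s_x) / det
        intercept = (self.s_x - slope * self.s_t) / self.n_rest
        return x - (intercept + slope * t)


def detrend_online(series: np.ndarray, labels: list[Condition]) -> np.ndarray:
    """Causal rest-anchored detrending of a whole run, volume by volume.

    Replays :class:`OnlineDetrender` over the series — the exact transform
    the closed loop applies — so classifiers trained on these features see
    the same feature distribution at deployment.
    """
    series = np.asarray(series, float)
    det = OnlineDetrender(series.shape[1])
    return np.stack([
        det.update(series[t], is_rest=labels[t] == Condition.REST)
        for t in range(len(series))
    ])


def extract_features(
    runs: list[BoldRun],
    mask: np.ndarray,
    detrend: str | None = "linear",
    label_shift: int = 0,
) -> FeatureMatrix:
    """Build the samples-by-voxels matrix from preprocessed task volumes.

    Every HAPPY/MOTOR volume is one sample; REST volumes never enter.
    ``detrend`` selects the per-run trend removal: "linear" (least-squares
    line over the whole run, the offline description), "online" (causal
    rest-anchored running fit, matching the closed loop) or None.
    ``label_shift`` delays the label assignment by that many TRs to absorb
    hemodynamic lag (default 0).
    """
    if detrend not in (None, "linear", "online"):
        raise ValueError(f"unknown detrend mode {detrend!r}")
    mask = np.asarray(mask, bool)
    voxel_indices = np.flatnonzero(mask.ravel())
    X_parts, y_parts, run_parts = [], [], []
    for ridx, run in enumerate(runs):
        flat = run.data.reshape(-1, run.n_volumes)[voxel_indices].T  # (t, vox)
        labels = run.labels
        if label_shift:
            labels = [Condition.REST] * label_shift + labels[:-label_shift]
        if detrend == "linear":
            flat = detrend_linear(flat)
        elif detrend == "online":
            flat = detrend_online(flat, labels)
        keep = [i for i, l in enumerate(labels) if l != Condition.REST]
        X_parts.append(flat[keep])
        y_parts.append([1 if labels[i] == POSITIVE_CLASS else -1 for i in keep])
        run_parts.append([ridx] * len(keep))
    return FeatureMatrix(
        X=np.concatenate(X_parts),
        y=np.concatenate(y_parts),
        run_ids=np.concatenate(run_parts),
        voxel_indices=voxel_indices,
        grid_shape=tuple(mask.shape),
    )


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std < 1e-12, 1.0, std)
    return mean, std


def train_svm(
    X: np.ndarray, y: np.ndarray, C: float = 1.0
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Linear SVM on standardized features.

    Returns (weights, bias, feature_mean, feature_std); the decision value of
    a raw vector x is w @ ((x - mean)/std) + b.
    """
    y = np.asarray(y, int)
    if len(np.unique(y)) < 2:
        raise ValueError("SVM training needs both classes present")
    mean, std = _standardize_fit(np.asarray(X, float))
    Z = (X - mean) / std
    clf = SVC(kernel="linear", C=C)
    clf.fit(Z, y)
    w = clf.coef_.ravel().copy()
    b = float(clf.intercept_[0])
    # sklearn orders classes ascending (-1, +1), so coef_ already gives
    # positive decision values for the +1 (HAPPY) class
    return w, b, mean, std


def effect_map(
    weights: np.ndarray, X: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Per-voxel effect value e_j = w_j * (mean_j over HAPPY - mean_j over MOTOR).

    Couples the discriminative weight with the voxel's class-conditional
    activation difference, so voxels that are both heavily weighted and
    strongly modulated score highest.
    """
    y = np.asarray(y, int)
    if not (np.any(y == 1) and np.any(y == -1)):
        raise ValueError("both class means must be defined")
    diff = X[y == 1].mean(axis=0) - X[y == -1].mean(axis=0)
    e = np.asarray(weights, float) * diff
    if not np.all(np.isfinite(e)):
        raise ValueError("effect map contains non-finite values")
    return e


def select_voxels(
    e: np.ndarray,
    rule: str = "top_fraction",
    value: float = DEFAULT_TOP_FRACTION,
) -> np.ndarray:
    """Indices (into the effect vector) of informative voxels, ordered by
    decreasing |e|.

    rule = "top_fraction": keep the top `value` fraction by |e| (at least 1).
    rule = "threshold":    keep voxels with |e| > value.
    """
    mag = np.abs(np.asarray(e, float))
    order = np.argsort(-mag, kind="stable")
    if rule == "top_fraction":
        if not 0 < value <= 1:
            raise ValueError("top fraction must be in (0, 1]")
        k = max(1, int(round(value * len(mag))))
        sel = order[:k]
    elif rule == "threshold":
        sel = order[mag[order] > value]
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    if len(sel) == 0:
        raise ValueError("selection rule selects zero voxels")
    return sel


def train_effect_map_model(
    features: FeatureMatrix,
    rule: str = "top_fraction",
    value: float = DEFAULT_TOP_FRACTION,
    C: float = 1.0,
) -> EffectMapModel:
    """Full training: SVM over the mask, effect map, selection, re-trained
    SVM restricted to the informative voxels (the rule used online)."""
    w_full, _, _, _ = train_svm(features.X, features.y, C=C)
    e = effect_map(w_full, features.X, features.y)
    sel_cols = select_voxels(e, rule, value)
    Xs = features.X[:, sel_cols]
    w, b, mean, std = train_svm(Xs, features.y, C=C)
    return EffectMapModel(
        weights=w,
        bias=b,
        effect_values=e,
        mask_indices=features.voxel_indices,
        selected=features.voxel_indices[sel_cols],
        grid_shape=features.grid_shape,
        feature_mean=mean,
        feature_std=std,
    )


def cross_validate(
    features: FeatureMatrix,
    rule: str = "top_fraction",
    value: float = DEFAULT_TOP_FRACTION,
    C: float = 1.0,
) -> CVReport:
    """Leave-one-run-out cross-validation (4 folds for the 4-run protocol).

    Mask, effect map and voxel selection are re-derived inside each training
    fold; sensitivity counts HAPPY as the positive class.
    """
    runs = np.unique(features.run_ids)
    if len(runs) < 2:
        raise ValueError("cross-validation needs at least 2 runs")
    acc, sens, spec, confusion = [], [], [], []
    for held_out in runs:
        train_sel = features.run_ids != held_out
        test_sel = ~train_sel
        w_full, _, _, _ = train_svm(features.X[train_sel], features.y[train_sel], C=C)
        e = effect_map(w_full, features.X[train_sel], features.y[train_sel])
        cols = select_voxels(e, rule, value)
        w, b, mean, std = train_svm(features.X[train_sel][:, cols],
                                    features.y[train_sel], C=C)
        Z = (features.X[test_sel][:, cols] - mean) / std
        pred = np.where(Z @ w + b >= 0, 1, -1)
        truth = features.y[test_sel]
        tp = int(np.sum((pred == 1) & (truth == 1)))
        fn = int(np.sum((pred == -1) & (truth == 1)))
        tn = int(np.sum((pred == -1) & (truth == -1)))
        fp = int(np.sum((pred == 1) & (truth == -1)))
        acc.append((tp + tn) / len(truth))
        sens.append(tp / (tp + fn) if tp + fn else 0.0)
        spec.append(tn / (tn + fp) if tn + fp else 0.0)
        confusion.append({"tp": tp, "fn": fn, "tn": tn, "fp": fp})
    return CVReport(acc, sens, spec, confusion)


def select_best_classifier(reports: list[CVReport]) -> int:
    """Index of the report with the highest average accuracy; ties broken by
    higher average sensitivity, then by the lowest index."""
    if not reports:
        raise ValueError("no reports to choose from")
    best = 0
    for i, r in enumerate(reports[1:], start=1):
        cur = reports[best]
        if (r.average_accuracy, r.average_sensitivity) > (
            cur.average_accuracy, cur.average_sensitivity
        ):
            best = i
    return best


# ---------------------------------------------------------------------------
# model persistence (mask + weight/effect volumes as NIfTI, metadata as YAML)

def save_model(model: EffectMapModel, directory: str | Path,
               affine: np.ndarray | None = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.eye(4)
    shape = model.grid_shape

    mask_vol = np.zeros(shape)
    mask_vol.ravel()[model.mask_indices] = 1
    nib.save(nib.Nifti1Image(mask_vol.astype(np.float32), affine),
             str(directory / "mask.nii.gz"))

    effect_vol = np.zeros(shape)
    effect_vol.ravel()[model.mask_indices] = model.effect_values
    nib.save(nib.Nifti1Image(effect_vol.astype(np.float32), affine),
             str(directory / "effect_map.nii.gz"))

    weight_vol = np.zeros(shape)
    weight_vol.ravel()[model.selected] = model.weights
    nib.save(nib.Nifti1Image(weight_vol.astype(np.float32), affine),
             str(directory / "weights.nii.gz"))

    meta = {
        "bias": float(model.bias),
        "grid_shape": list(shape),
        "class_coding": model.class_coding,
        "selected": [int(i) for i in model.selected],
        "weights": [float(v) for v in model.weights],
        "feature_mean": [float(v) for v in model.feature_mean],
        "feature_std": [float(v) for v in model.feature_std],
    }
    (directory / "model.yaml").write_text(yaml.safe_dump(meta))
    return directory


def load_model(directory: str | Path) -> EffectMapModel:
    directory = Path(directory)
    meta = yaml.safe_load((directory / "model.yaml").read_text())
    mask_vol = np.asanyarray(nib.load(str(directory / "mask.nii.gz")).dataobj)
    effect_vol = np.asanyarray(nib.load(str(directory / "effect_map.nii.gz")).dataobj)
    mask_indices = np.flatnonzero(mask_vol.ravel() > 0)
    return EffectMapModel(
        weights=np.array(meta["weights"], float),
        bias=float(meta["bias"]),
        effect_values=np.asarray(effect_vol, float).ravel()[mask_indices],
        mask_indices=mask_indices,
        selected=np.array(meta["selected"], int),
        grid_shape=tuple(meta["grid_shape"]),
        feature_mean=np.array(meta["feature_mean"], float),
        feature_std=np.array(meta["feature_std"], float),
        class_coding=meta["class_coding"],
    )
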