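import numpy as np
import pytest

from rtnf.mvpa import (
    CVReport,
    FeatureMatrix,
    OnlineDetrender,
    cross_validate,
    detrend_linear,
    detrend_online,
    effect_map,
    fold_average,
    load_model,
    make_mask,
    save_model,
    select_best_classifier,
    select_voxels,
    train_effect_map_model,
    train_svm,
)
from rtnf.paradigm import Condition


def cloud_features(rng, n_per_class=60, dim=20, sep=3.0, n_runs=4):
    """Two Gaussian clouds split evenly over runs."""
    mu = np.zeros(dim)
    mu[:3] = sep
    X = np.vstack([
        rng.normal(+mu, 1.0, size=(n_per_class, dim)),
        rng.normal(-mu, 1.0, size=(n_per_class, dim)),
    ])
    y = np.array([1] * n_per_class + [-1] * n_per_class)
    runs = np.tile(np.arange(n_runs), len(X) // n_runs + 1)[: len(X)]
    order = rng.permutation(len(X))
    return FeatureMatrix(X[order], y[order], runs[order],
                         np.arange(dim), (dim, 1, 1))


class TestMakeMask:
    def test_uniform_positive_field_fully_included(self):
        vol = np.full((6, 6, 6), 5.0)
        assert make_mask(vol, 0.5).all()

    def test_zero_voxels_excluded(self):
        vol = np.zeros((6, 6, 6))
        vol[:3] = 4.0
        mask = make_mask(vol, 0.5)
        assert mask[:3].all() and not mask[3:].any()

    def test_two_to_one_contrast_recovers_interior_exactly(self):
        # enumeration oracle: interior at 2, exterior at 1 (equal volumes),
        # fraction 0.8: threshold 0.8 * 1.5 = 1.2 strips the exterior
        vol = np.ones((8, 8, 8))
        interior = np.zeros((8, 8, 8), bool)
        interior[:4] = True
        vol[interior] = 2.0
        grand = vol[vol > 0].mean()
        expected = vol > 0.8 * grand
        mask = make_mask(vol, 0.8)
        assert np.array_equal(mask, expected)
        assert np.array_equal(mask, interior)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            make_mask(np.zeros((4, 4, 4)), 0.5)
        with pytest.raises(ValueError):
            make_mask(np.ones((4, 4, 4)), 1.5)


class TestDetrend:
    def test_pure_line_removed_to_zero(self):
        t = np.arange(50, dtype=float)
        series = (3.0 + 0.25 * t)[:, None]
        out = detrend_linear(series)
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_line_plus_sinusoid_recovers_projected_sinusoid(self):
        # closed-form oracle: the residual equals the sinusoid minus its own
        # least-squares projection onto {1, t}
        t = np.arange(80, dtype=float)
        sin = np.sin(2 * np.pi * t / 16)
        series = (5.0 - 0.1 * t + sin)[:, None]
        design = np.column_stack([np.ones_like(t), t])
        proj = design @ np.linalg.lstsq(design, sin, rcond=None)[0]
        out = detrend_linear(series)
        assert np.allclose(out[:, 0], sin - proj, atol=1e-8)

    def test_constant_series_becomes_zeros(self):
        out = detrend_linear(np.full((10, 3), 7.0))
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_per_run_independence(self, rng):
        series = rng.standard_normal((20, 4))
        run_ids = np.array([0] * 10 + [1] * 10)
        out = detrend_linear(series, run_ids)
        a = detrend_linear(series[:10])
        b = detrend_linear(series[10:])
        assert np.allclose(out, np.vstack([a, b]))

    def test_too_short_run_rejected(self):
        with pytest.raises(ValueError, match="< 3"):
            detrend_linear(np.ones((2, 1)))


class TestOnlineDetrender:
    def test_tracks_linear_drift_through_rest_anchors(self):
        # drifting baseline, task bumps on top: residuals on rest volumes ~0,
        # task volumes keep their bump
        n = 60
        t = np.arange(n, dtype=float)
        labels = [Condition.REST if (i // 10) % 2 == 0 else Condition.HAPPY
                  for i in range(n)]
        drift = 100.0 + 0.2 * t
        bump = np.array([3.0 if l == Condition.HAPPY else 0.0 for l in labels])
        series = (drift + bump)[:, None]
        out = detrend_online(series, labels)
        rest = np.array([l == Condition.REST for l in labels])
        assert np.abs(out[rest][5:]).max() < 1e-6
        assert np.allclose(out[~rest][5:], 3.0, atol=0.5)

    def test_streaming_matches_batch_replay(self, rng):
        series = rng.standard_normal((30, 5)) + 50
        labels = [Condition.REST] * 10 + [Condition.MOTOR] * 10 + [Condition.REST] * 10
        det = OnlineDetrender(5)
        streamed = np.stack([
            det.update(series[i], is_rest=labels[i] == Condition.REST)
            for i in range(30)
        ])
        assert np.array_equal(streamed, detrend_online(series, labels))


class TestSVM:
    def test_separable_clouds_perfect_training_accuracy(self, rng):
        fm = cloud_features(rng)
        w, b, mean, std = train_svm(fm.X, fm.y)
        pred = np.where(((fm.X - mean) / std) @ w + b >= 0, 1, -1)
        assert (pred == fm.y).all()

    def test_permuted_labels_give_chance_cv_accuracy(self, rng):
        fm = cloud_features(rng, n_per_class=100, dim=10, sep=0.0)
        report = cross_validate(fm, value=1.0)
        assert 0.35 <= report.average_accuracy <= 0.65

    def test_duplicated_features_give_identical_decision_values(self, rng):
        fm = cloud_features(rng, n_per_class=30, dim=8)
        w1, b1, m1, s1 = train_svm(fm.X, fm.y)
        X2 = np.hstack([fm.X, fm.X])
        w2, b2, m2, s2 = train_svm(X2, fm.y)
        d1 = ((fm.X - m1) / s1) @ w1 + b1
        d2 = ((X2 - m2) / s2) @ w2 + b2
        assert np.allclose(d1, d2, atol=1e-6)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 4))
        with pytest.raises(ValueError, match="both classes"):
            train_svm(X, np.ones(10, int))


class TestEffectMap:
    def test_zero_weights_give_zero_effects(self, rng):
        fm = cloud_features(rng, n_per_class=20, dim=6)
        assert np.allclose(effect_map(np.zeros(6), fm.X, fm.y), 0.0)

    def test_equals_brute_force_per_voxel_loop(self, rng):
        fm = cloud_features(rng, n_per_class=20, dim=12)
        w = rng.standard_normal(12)
        e = effect_map(w, fm.X, fm.y)
        for j in range(12):
            diff = fm.X[fm.y == 1, j].mean() - fm.X[fm.y == -1, j].mean()
            assert e[j] == pytest.approx(w[j] * diff, abs=1e-12)

    def test_label_swap_flips_every_sign(self, rng):
        fm = cloud_features(rng, n_per_class=20, dim=6)
        w = rng.standard_normal(6)
        assert np.allclose(effect_map(w, fm.X, fm.y),
                           -effect_map(w, fm.X, -fm.y))

    def test_single_informative_voxel_found(self, rng):
        hits = 0
        for rep in range(20):
            r = np.random.default_rng(5000 + rep)
            X = r.normal(size=(60, 200))
            y = np.array([1, -1] * 30)
            X[:, 77] += 1.5 * y
            w, b, m, s = train_svm(X, y)
            e = effect_map(w, (X - m) / s, y)
            hits += int(np.argmax(np.abs(e)) == 77)
        assert hits >= 18

    def test_undefined_class_mean_rejected(self, rng):
        X = rng.standard_normal((5, 3))
        with pytest.raises(ValueError, match="class means"):
            effect_map(np.ones(3), X, np.ones(5, int))


class TestSelectVoxels:
    def test_top_full_fraction_selects_everything(self, rng):
        e = rng.standard_normal(40)
        assert set(select_voxels(e, "top_fraction", 1.0)) == set(range(40))

    def test_ordered_by_decreasing_magnitude(self, rng):
        e = rng.standard_normal(40)
        sel = select_voxels(e, "top_fraction", 0.25)
        mags = np.abs(e)[sel]
        assert all(m1 >= m2 for m1, m2 in zip(mags, mags[1:]))
        assert np.abs(e)[sel].min() >= np.sort(np.abs(e))[-10]

    def test_threshold_above_max_rejected(self, rng):
        e = rng.standard_normal(10)
        with pytest.raises(ValueError, match="zero voxels"):
            select_voxels(e, "threshold", np.abs(e).max() + 1)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            select_voxels(np.ones(4), "magic")


class TestCrossValidation:
    @pytest.mark.parametrize(
        "folds, expected",
        [
            ([0.97, 0.87, 0.92, 0.84], 0.90),
            ([0.90, 0.96, 0.96, 0.91], 0.93),
            ([0.76, 0.86, 0.83, 0.72], 0.79),
        ],
    )
    def test_fold_averaging_reproduces_printed_participant_averages(
        self, folds, expected
    ):
        report = CVReport(folds, folds, folds)
        assert report.average_accuracy == pytest.approx(expected, abs=0.005)
        assert fold_average(folds) == pytest.approx(expected, abs=0.005)

    def test_specificity_rounding_of_half_values(self):
        # fold mean 0.9475 prints as 0.95 under round-half-away-from-zero
        assert fold_average([0.90, 0.99, 0.95, 0.95]) == 0.95

    def test_perfect_classifier_on_separable_fixture(self, rng):
        fm = cloud_features(rng, n_per_class=40, sep=5.0)
        report = cross_validate(fm, value=1.0)
        assert report.n_folds == 4
        assert report.fold_accuracy == [1.0] * 4
        assert report.fold_sensitivity == [1.0] * 4
        assert report.fold_specificity == [1.0] * 4

    def test_averages_equal_fold_means_and_confusion_recomputes(self, rng):
        fm = cloud_features(rng, sep=1.0)
        report = cross_validate(fm, value=1.0)
        assert report.average_accuracy == pytest.approx(
            np.mean(report.fold_accuracy))
        for k, c in enumerate(report.confusion):
            total = sum(c.values())
            acc = (c["tp"] + c["tn"]) / total
            assert report.fold_accuracy[k] == pytest.approx(acc)
            if c["tp"] + c["fn"]:
                assert report.fold_sensitivity[k] == pytest.approx(
                    c["tp"] / (c["tp"] + c["fn"]))

    def test_single_run_rejected(self, rng):
        fm = cloud_features(rng, n_runs=1)
        with pytest.raises(ValueError, match="at least 2 runs"):
            cross_validate(fm)


class TestSelectBestClassifier:
    def test_printed_averages_pick_participant_two(self):
        reports = [
            CVReport([0.90] * 4, [0.88] * 4, [0.92] * 4),
            CVReport([0.93] * 4, [0.92] * 4, [0.95] * 4),
            CVReport([0.79] * 4, [0.81] * 4, [0.77] * 4),
        ]
        assert select_best_classifier(reports) == 1

    def test_single_report_and_empty_list(self):
        only = CVReport([0.5] * 4, [0.5] * 4, [0.5] * 4)
        assert select_best_classifier([only]) == 0
        with pytest.raises(ValueError):
            select_best_classifier([])

    def test_accuracy_tie_broken_by_sensitivity_then_index(self):
        a = CVReport([0.9] * 4, [0.80] * 4, [0.9] * 4)
        b = CVReport([0.9] * 4, [0.95] * 4, [0.9] * 4)
        c = CVReport([0.9] * 4, [0.95] * 4, [0.9] * 4)
        assert select_best_classifier([a, b, c]) == 1
        assert select_best_classifier([b, a, c]) == 0


class TestModelPersistence:
    def test_bundle_round_trip(self, rng, tmp_path):
        fm = cloud_features(rng)
        model = train_effect_map_model(fm, value=0.5)
        save_model(model, tmp_path / "bundle")
        back = load_model(tmp_path / "bundle")
        assert np.allclose(back.weights, model.weights, atol=1e-6)
        assert back.bias == pytest.approx(model.bias, abs=1e-9)
        assert np.array_equal(back.selected, model.selected)
        x = rng.standard_normal(len(model.selected))
        assert back.decision_value(x) == pytest.approx(
            model.decision_value(x), abs=1e-5)
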