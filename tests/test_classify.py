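import numpy as np
import pandas as pd
import pytest

from dwgc.classify import (
    ClassifierSpec,
    FeatureMatrix,
    assemble_features,
    cohen_kappa,
    compare_feature_sets,
    decoding_accuracy_curve,
    default_classifier_grid,
    fit_decoder,
    kfold_evaluate,
)
from dwgc.model import ArModelSpec, dwgc_sequence
from dwgc.paradigm import generate_paradigm
from dwgc.roi import ActivationFeature
from dwgc.synthetic import SimulationConfig, simulate_roi_series

from conftest import coupled_config


@pytest.fixture(scope="module")
def small_run():
    """A short 4-node MI run with DWGC connectivity and an ACTIVE stream."""
    paradigm = generate_paradigm(2.0, 10.0, 20.0, ["MIL", "MIR"], 8, seed=1)
    C1 = np.zeros((4, 4))
    C1[1, 0] = 0.8
    C2 = np.zeros((4, 4))
    C2[3, 2] = 0.8
    config = SimulationConfig(
        n_nodes=4,
        base_ar_coeffs=np.full(4, 0.3),
        coupling_schedule={"MIL": C1, "MIR": C2},
        seed=2,
    )
    series, truth = simulate_roi_series(config, paradigm)
    conn = dwgc_sequence(series, ArModelSpec(), k=4)
    activation = ActivationFeature(values=series.values - series.values.mean())
    return conn, activation, truth.condition_labels


class TestAssembleFeatures:
    def test_dwgc_mode_has_one_column_per_ordered_pair(self, small_run):
        conn, act, labels = small_run
        fm = assemble_features(conn, None, labels, mode="dwgc")
        assert fm.X.shape[1] == 4 * 3
        assert fm.n_samples == conn.n_windows
        assert all(v == "dwgc" for v in fm.provenance.values())

    def test_both_mode_appends_active_columns(self, small_run):
        conn, act, labels = small_run
        fm = assemble_features(conn, act, labels, mode="both")
        assert fm.X.shape[1] == 12 + 4
        assert sum(v == "activation" for v in fm.provenance.values()) == 4

    def test_rows_are_identical_across_modes(self, small_run):
        conn, act, labels = small_run
        fd = assemble_features(conn, None, labels, mode="dwgc")
        fa = assemble_features(conn, act, labels, mode="activation")
        np.testing.assert_array_equal(fd.volume_index, fa.volume_index)
        np.testing.assert_array_equal(fd.labels, fa.labels)

    def test_empty_connectivity_rejected(self, small_run):
        _, act, labels = small_run
        with pytest.raises(ValueError, match="empty"):
            assemble_features(None, act, labels, mode="dwgc")

    def test_short_label_vector_names_offending_index(self, small_run):
        conn, act, labels = small_run
        with pytest.raises(ValueError, match=str(int(conn.window_starts.max()))):
            assemble_features(conn, None, labels[:50], mode="dwgc")

    def test_csv_round_trip(self, small_run, tmp_path):
        conn, act, labels = small_run
        fm = assemble_features(conn, None, labels, mode="dwgc")
        fm.to_csv(tmp_path / "features.csv")
        back = FeatureMatrix.from_csv(tmp_path / "features.csv")
        np.testing.assert_allclose(back.X.to_numpy(), fm.X.to_numpy())
        np.testing.assert_array_equal(back.labels, fm.labels)


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(np.diag([10, 20, 30])) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # p_o = 0.8, p_e = 0.5 -> kappa = 0.6
        assert cohen_kappa([[40, 10], [10, 40]]) == pytest.approx(0.6)

    def test_chance_level_agreement(self):
        assert cohen_kappa([[25, 25], [25, 25]]) == pytest.approx(0.0)

    def test_degenerate_single_cell_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert cohen_kappa([[50, 0], [0, 0]]) == 0.0

    def test_agrees_with_sklearn_on_random_labelings(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(0)
        for _ in range(5):
            y_true = rng.integers(0, 3, size=200)
            y_pred = rng.integers(0, 3, size=200)
            conf = np.zeros((3, 3), dtype=int)
            for a, b in zip(y_true, y_pred):
                conf[a, b] += 1
            assert cohen_kappa(conf) == pytest.approx(
                cohen_kappa_score(y_true, y_pred), abs=1e-12
            )


def _blocked_features(n_blocks=30, block_len=5, n_feat=4, classes=("A", "B"),
                      separation=0.0, seed=0):
    """Noise features in constant-label blocks, optionally class-separated."""
    rng = np.random.default_rng(seed)
    rows, labels, blocks = [], [], []
    for b in range(n_blocks):
        label = classes[b % len(classes)]
        mu = separation * (classes.index(label))
        rows.append(rng.normal(mu, 1.0, size=(block_len, n_feat)))
        labels += [label] * block_len
        blocks += [b] * block_len
    X = pd.DataFrame(np.vstack(rows), columns=[f"f{i}" for i in range(n_feat)])
    return FeatureMatrix(
        X=X,
        labels=np.asarray(labels),
        volume_index=np.arange(len(X)),
        block_id=np.asarray(blocks),
    )


class TestKfoldEvaluate:
    def test_separable_classes_reach_perfect_accuracy(self):
        fm = _blocked_features(separation=8.0, seed=1)
        report = kfold_evaluate(fm, ClassifierSpec("svm_rbf"), K=5, seed=0)
        assert report.accuracy == 1.0
        assert report.kappa == 1.0

    def test_confusion_counts_every_held_out_sample(self):
        fm = _blocked_features(seed=2)
        report = kfold_evaluate(fm, ClassifierSpec("gaussian_nb"), K=5, seed=0)
        assert report.confusion.to_numpy().sum() == fm.n_samples
        assert len(report.predictions) == fm.n_samples

    def test_blocks_never_straddle_folds(self):
        fm = _blocked_features(seed=3)
        report = kfold_evaluate(fm, ClassifierSpec("gaussian_nb"), K=5, seed=0)
        per_block = report.predictions.groupby("block_id")["fold"].nunique()
        assert (per_block == 1).all()

    def test_same_seed_reproduces_report(self):
        fm = _blocked_features(seed=4)
        r1 = kfold_evaluate(fm, ClassifierSpec("svm_rbf"), K=4, seed=9)
        r2 = kfold_evaluate(fm, ClassifierSpec("svm_rbf"), K=4, seed=9)
        assert r1.accuracy == r2.accuracy
        pd.testing.assert_frame_equal(r1.predictions, r2.predictions)

    def test_class_thinner_than_k_rejected(self):
        fm = _blocked_features(n_blocks=4, block_len=1)
        with pytest.raises(ValueError, match="fewer than K"):
            kfold_evaluate(fm, ClassifierSpec("gaussian_nb"), K=5)

    def test_rbf_preset_matches_printed_parameters(self):
        pipe = default_classifier_grid()["svm_rbf"].build()
        clf = pipe.named_steps["clf"]
        assert clf.C == 19.0 and clf.gamma == "scale"
        poly = default_classifier_grid()["svm_poly"].build().named_steps["clf"]
        assert poly.kernel == "poly" and poly.degree == 1


class TestDaCurve:
    def _predictions(self, paradigm, correct_from=0):
        rows = []
        labels = paradigm.condition_labels()
        n_pos = paradigm.volumes_per_task_block()
        for block in paradigm.task_blocks():
            i0 = int(round(block.onset_s / paradigm.tr_seconds))
            for m in range(n_pos):
                true = labels[i0 + m]
                pred = true if m >= correct_from else "rest"
                rows.append({"volume": i0 + m, "true": true, "pred": pred})
        return pd.DataFrame(rows)

    def test_ten_second_blocks_give_five_points(self):
        paradigm = generate_paradigm(2.0, 10.0, 20.0, ["MIL", "MIR"], 4, seed=0)
        curve = decoding_accuracy_curve(self._predictions(paradigm), paradigm)
        assert len(curve) == 5

    def test_all_correct_gives_flat_one(self):
        paradigm = generate_paradigm(2.0, 10.0, 20.0, ["MIL"], 3, seed=0)
        curve = decoding_accuracy_curve(self._predictions(paradigm), paradigm)
        np.testing.assert_array_equal(curve.values, 1.0)

    def test_late_correctness_shows_in_curve(self):
        paradigm = generate_paradigm(2.0, 10.0, 20.0, ["MIL"], 5, seed=0)
        curve = decoding_accuracy_curve(self._predictions(paradigm, correct_from=2), paradigm)
        np.testing.assert_array_equal(curve.values, [0.0, 0.0, 1.0, 1.0, 1.0])

    def test_ragged_blocks_rejected(self):
        from dwgc.paradigm import Block, Paradigm

        ragged = Paradigm(
            tr_seconds=2.0,
            blocks=[
                Block("rest", 0.0, 10.0),
                Block("MIL", 10.0, 10.0),
                Block("rest", 20.0, 10.0),
                Block("MIL", 30.0, 20.0),
            ],
            total_duration_s=50.0,
        )
        preds = pd.DataFrame({"volume": [5], "true": ["MIL"], "pred": ["MIL"]})
        with pytest.raises(ValueError, match="unequal"):
            decoding_accuracy_curve(preds, ragged)


class TestCompareFeatureSets:
    def test_identical_sets_show_zero_difference(self):
        fm = _blocked_features(separation=2.0, seed=5)
        cmp = compare_feature_sets(fm, fm, ClassifierSpec("gaussian_nb"), n_repeats=5)
        assert cmp.mean_difference == 0.0
        assert cmp.t_statistic == pytest.approx(0.0)

    def test_single_repeat_reports_undefined_t(self):
        fm1 = _blocked_features(separation=2.0, seed=6)
        fm2 = _blocked_features(separation=0.0, seed=7)
        cmp = compare_feature_sets(fm1, fm2, ClassifierSpec("gaussian_nb"), n_repeats=1)
        assert np.isnan(cmp.t_statistic)

    def test_informative_features_beat_noise(self):
        fm1 = _blocked_features(separation=3.0, seed=8)
        fm2 = _blocked_features(separation=0.0, seed=8)
        cmp = compare_feature_sets(fm1, fm2, ClassifierSpec("gaussian_nb"), n_repeats=8)
        assert cmp.mean_difference > 0.2
        assert cmp.p_value < 0.05

    def test_mismatched_rows_rejected(self):
        fm1 = _blocked_features(n_blocks=10)
        fm2 = _blocked_features(n_blocks=12)
        with pytest.raises(ValueError, match="identical sample rows"):
            compare_feature_sets(fm1, fm2)


class TestDecoder:
    def test_fit_predict_round_trip(self, tmp_path):
        fm = _blocked_features(separation=6.0, seed=9)
        decoder = fit_decoder(fm, ClassifierSpec("svm_rbf"))
        preds = decoder.predict(fm.X)
        assert (preds == fm.labels).mean() > 0.95
        decoder.save(tmp_path / "model.joblib")
        loaded = type(decoder).load(tmp_path / "model.joblib")
        assert loaded.feature_names == decoder.feature_names
        assert loaded.predict_row(fm.X.iloc[0].to_numpy()) == preds[0]
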