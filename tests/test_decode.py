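"""Fold assignment, averaged-ERP construction, classifiers, time-course."""

import numpy as np
import pytest

from erpdecode import (
    ClassifierSpec,
    DecodingInfeasibleError,
    DecodingRun,
    SimulationConfig,
    assign_folds,
    average_folds,
    baseline_correct,
    decode_timecourse,
    fit_predict,
    normalize_fold,
    simulate_participant,
    window_mean,
)

from conftest import make_epochs


class TestAssignFolds:
    def test_40_trials_gives_13_per_average(self, rng):
        es = make_epochs(rng.normal(size=(80, 4, 20)), M=2)
        fa = assign_folds(es, n_folds=3, rng=0)
        assert fa.n_per_average == 13

    def test_unbalanced_classes_equated(self, rng):
        labels = np.array([0] * 30 + [1] * 45)
        es = make_epochs(rng.normal(size=(75, 4, 20)), labels=labels, M=2)
        fa = assign_folds(es, rng=1)
        assert fa.n_per_average == 10
        assert fa.folds.shape == (2, 3, 10)

    def test_too_few_trials_is_infeasible(self, rng):
        labels = np.array([0] * 10 + [1] * 2)
        es = make_epochs(rng.normal(size=(12, 4, 20)), labels=labels, M=2)
        with pytest.raises(DecodingInfeasibleError):
            assign_folds(es, rng=0)

    def test_folds_disjoint_kept_and_class_pure(self, rng):
        es = make_epochs(rng.normal(size=(90, 4, 20)), M=3)
        es.keep[::7] = False
        fa = assign_folds(es, rng=2)
        for k in range(3):
            idx = fa.folds[k].ravel()
            assert len(set(idx)) == len(idx)  # no within-class reuse
            assert np.all(es.labels[idx] == k)
            assert np.all(es.keep[idx])


class TestAverageFolds:
    def test_identical_trials_average_to_themselves(self, rng):
        trial = rng.normal(size=(4, 20))
        es = make_epochs(np.tile(trial, (12, 1, 1)), M=2)
        fa = assign_folds(es, rng=0)
        avg = average_folds(es, fa)
        assert avg.shape == (2, 3, 4, 20)
        assert np.allclose(avg, trial)

    def test_averaging_sharpens_template_recovery(self):
        cfg = SimulationConfig(
            preset="P3b", trials_per_class=90, effect_amplitude=10.0,
            blink_prob_per_class=(0.0, 0.0), artifact_prob=0.0, master_seed=3,
        )
        es, gt = simulate_participant(cfg, 0)
        support = np.abs(gt.class_templates[0]) > 0.05 * np.abs(gt.class_templates).max()

        def scores(n_per):
            """(correlation on the template's support, rmse) averaged over
            random subsets and both classes."""
            rng = np.random.default_rng(0)
            rs, errs = [], []
            for draw in range(5):
                for k in range(2):
                    idx = rng.choice(np.flatnonzero(es.labels == k), n_per, replace=False)
                    avg = es.data[idx].mean(axis=0)
                    tmpl = gt.class_templates[k]
                    rs.append(np.corrcoef(avg[support], tmpl[support])[0, 1])
                    errs.append(np.sqrt(((avg - tmpl) ** 2).mean()))
            return np.mean(rs), np.mean(errs)

        r13, e13 = scores(13)
        r2, e2 = scores(2)
        assert r13 > r2
        assert e13 < e2


class TestNormalizeFold:
    def test_train_standardized_and_constant_feature_guarded(self, rng):
        tr = rng.normal(size=(10, 5))
        tr[:, 2] = 4.0  # constant feature
        te = rng.normal(size=(4, 5))
        tr2, te2 = normalize_fold(tr, te)
        ok = [0, 1, 3, 4]
        assert np.allclose(tr2[:, ok].mean(axis=0), 0, atol=1e-12)
        assert np.allclose(tr2[:, ok].std(axis=0, ddof=1), 1, atol=1e-12)
        assert np.all(tr2[:, 2] == 0) and np.all(te2[:, 2] == 0)

    def test_invariant_to_per_feature_affine_rescaling(self, rng):
        tr = rng.normal(size=(8, 3))
        te = rng.normal(size=(5, 3))
        a = rng.uniform(0.5, 3.0, size=3)
        b = rng.normal(size=3)
        base = normalize_fold(tr, te)
        scaled = normalize_fold(a * tr + b, a * te + b)
        assert np.allclose(base[0], scaled[0], atol=1e-9)
        assert np.allclose(base[1], scaled[1], atol=1e-9)


class TestFitPredict:
    def test_separable_binary(self):
        X = np.array([[0.0, 0], [0.2, 0], [5.0, 0], [5.2, 0]])
        y = np.array([0, 0, 1, 1])
        pred = fit_predict(ClassifierSpec("svm"), X, y, np.array([[0.1, 0], [5.1, 0]]))
        assert pred.tolist() == [0, 1]

    def test_training_point_far_from_boundary_classified_home(self):
        X = np.array([[-3.0], [-2.5], [2.5], [3.0]])
        y = np.array([0, 0, 1, 1])
        pred = fit_predict(ClassifierSpec("svm"), X, y, np.array([[-3.0]]))
        assert pred[0] == 0

    def test_svm_matches_reference_implementation(self, rng):
        from sklearn.svm import SVC

        for _ in range(20):
            X = rng.normal(size=(8, 5))
            y = rng.integers(0, 2, size=8)
            if len(np.unique(y)) < 2:
                continue
            Xt = rng.normal(size=(6, 5))
            mine = fit_predict(ClassifierSpec("svm"), X, y, Xt)
            ref = SVC(kernel="linear", C=1.0).fit(X, y)
            # compare away from the decision boundary, where the reference
            # solver's own tolerance cannot flip the label
            d = ref.decision_function(Xt)
            far = np.abs(d) > 0.05
            assert np.array_equal(mine[far], ref.predict(Xt)[far])

    def test_ecoc_separable_three_class(self):
        X = np.array(
            [[0.0, 0], [0.3, 0], [5.0, 0], [5.3, 0], [0.0, 5], [0.3, 5]], dtype=float
        )
        y = np.array([0, 0, 1, 1, 2, 2])
        Xt = np.array([[0.1, 0.1], [5.1, 0.0], [0.1, 5.1]])
        pred = fit_predict(ClassifierSpec("ecoc_svm"), X, y, Xt)
        assert pred.tolist() == [0, 1, 2]

    def test_rlda_full_shrinkage_is_diagonal_discriminant(self, rng):
        # gamma = 1: closed-form naive-Bayes-like rule with pooled diagonal
        X = rng.normal(size=(12, 2)) + np.array([[2.0, -1.0]] * 6 + [[-2.0, 1.0]] * 6)
        y = np.array([0] * 6 + [1] * 6)
        Xt = rng.normal(size=(7, 2))
        pred = fit_predict(ClassifierSpec("rlda", gamma=1.0), X, y, Xt)
        mu = np.stack([X[y == k].mean(axis=0) for k in (0, 1)])
        resid = X - mu[y]
        var = (resid**2).sum(axis=0) / (len(y) - 2)
        scores = Xt @ (mu / var).T - 0.5 * np.sum(mu**2 / var, axis=1)
        assert np.array_equal(pred, np.argmax(scores, axis=1))

    def test_svm_and_rlda_agree_far_from_boundary(self, rng):
        X = np.concatenate([rng.normal(-4, 1, 20), rng.normal(4, 1, 20)])[:, None]
        y = np.array([0] * 20 + [1] * 20)
        Xt = np.array([[-6.0], [6.0], [-5.0], [5.0]])
        svm = fit_predict(ClassifierSpec("svm"), X, y, Xt)
        rlda = fit_predict(ClassifierSpec("rlda", gamma=0.5), X, y, Xt)
        assert np.array_equal(svm, rlda)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_predict(
                ClassifierSpec("svm"), rng.normal(size=(4, 2)), np.zeros(4), np.zeros((1, 2))
            )

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ClassifierSpec("rlda")  # gamma missing
        with pytest.raises(ValueError):
            ClassifierSpec("svm", gamma=0.5)
        with pytest.raises(ValueError):
            ClassifierSpec("qda")


@pytest.fixture(scope="module")
def high_snr_participant():
    cfg = SimulationConfig(
        preset="P3b", trials_per_class=40, effect_amplitude=30.0,
        blink_prob_per_class=(0.0, 0.0), artifact_prob=0.0, master_seed=11,
    )
    es, _ = simulate_participant(cfg, 0)
    return baseline_correct(es, (-200, 0))


class TestDecodeTimecourse:
    def test_high_snr_near_perfect_in_window_chance_prestim(self, high_snr_participant):
        es = high_snr_participant
        spec = ClassifierSpec("svm")
        run = decode_timecourse(es, spec, n_iterations=10, seed=0, window=(300, 600), decim=2)
        # near-ceiling where the Gaussian effect peaks; high overall
        assert window_mean(run, (400, 500)) > 0.95
        assert window_mean(run, (300, 600)) > 0.8
        pre = decode_timecourse(es, spec, n_iterations=10, seed=0, window=(-200, 0), decim=2)
        assert abs(window_mean(pre, (-200, 0)) - 0.5) < 0.2

    def test_deterministic_under_seed(self, high_snr_participant):
        es = high_snr_participant
        spec = ClassifierSpec("svm")
        a = decode_timecourse(es, spec, n_iterations=3, seed=5, window=(300, 400))
        b = decode_timecourse(es, spec, n_iterations=3, seed=5, window=(300, 400))
        assert np.array_equal(a.accuracy, b.accuracy)
        assert np.all((a.accuracy >= 0) & (a.accuracy <= 1))
        assert a.chance == 0.5

    def test_invariant_under_channel_permutation(self, high_snr_participant, rng):
        es = high_snr_participant
        spec = ClassifierSpec("svm")
        scalp = es.montage.scalp_indices
        perm = rng.permutation(scalp)
        a = decode_timecourse(es, spec, n_iterations=3, seed=1, window=(300, 400),
                              channels=scalp)
        b = decode_timecourse(es, spec, n_iterations=3, seed=1, window=(300, 400),
                              channels=perm)
        assert np.allclose(a.accuracy, b.accuracy)

    def test_scale_invariant_when_normalized(self, high_snr_participant):
        es = high_snr_participant
        spec = ClassifierSpec("svm", normalize=True)
        a = decode_timecourse(es, spec, n_iterations=3, seed=2, window=(300, 400))
        scaled = es.copy()
        scaled.data *= 10.0
        b = decode_timecourse(scaled, spec, n_iterations=3, seed=2, window=(300, 400))
        assert np.allclose(a.accuracy, b.accuracy)

    def test_rlda_and_ecoc_paths_run(self, high_snr_participant):
        es = high_snr_participant
        r = decode_timecourse(es, ClassifierSpec("rlda", gamma=0.5),
                              n_iterations=2, seed=0, window=(300, 400))
        assert window_mean(r, (300, 400)) > 0.8
        e2 = decode_timecourse(es, ClassifierSpec("ecoc_svm"),
                               n_iterations=2, seed=0, window=(300, 400))
        assert window_mean(e2, (300, 400)) > 0.8


class TestWindowMean:
    def test_constant_run(self):
        run = DecodingRun(
            accuracy=np.full((4, 6), 0.6), times=np.arange(6) * 10.0,
            spec=ClassifierSpec("svm"), chance=0.5, n_folds=3, seed=0,
        )
        assert window_mean(run, (0, 50)) == pytest.approx(0.6)
        assert window_mean(run, (20, 20)) == pytest.approx(0.6)

    def test_hand_enumerated_toy(self):
        acc = np.array([[0.2, 0.4, 0.6, 0.8, 1.0], [0.4, 0.6, 0.8, 1.0, 0.2]])
        run = DecodingRun(
            accuracy=acc, times=np.array([0.0, 10, 20, 30, 40]),
            spec=ClassifierSpec("svm"), chance=0.5, n_folds=3, seed=0,
        )
        # iteration means: [.3,.5,.7,.9,.6]; mean over 10..30 = (.5+.7+.9)/3
        assert window_mean(run, (10, 30)) == pytest.approx(0.7)

    def test_empty_overlap_rejected(self):
        run = DecodingRun(
            accuracy=np.zeros((1, 3)), times=np.array([0.0, 10, 20]),
            spec=ClassifierSpec("svm"), chance=0.5, n_folds=3, seed=0,
        )
        with pytest.raises(ValueError):
            window_mean(run, (100, 200))
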