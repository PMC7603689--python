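"""Metrics, confusion counts and the three evaluation protocols."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from negspace.eval_harness import (
    REGISTRY,
    ClassifierSpec,
    ConfusionCounts,
    build_balanced_dataset,
    benchmark,
    confusion,
    metric_acc,
    metric_auc,
    metric_gmeans,
    metric_mcc,
    metric_se,
    metric_sp,
    metrics_from_predictions,
    puk_kernel,
    run_loocv,
    run_repeated_kfold,
    run_split,
)
from negspace.pair_space import NEGATIVE_LABEL as NEG, POSITIVE_LABEL as POS


class TestConfusion:
    def test_perfect_and_all_positive(self):
        y = [POS] * 3 + [NEG] * 3
        assert confusion(y, y) == ConfusionCounts(3, 3, 0, 0)
        y2 = [POS, POS, NEG, NEG]
        assert confusion(y2, [POS] * 4) == ConfusionCounts(2, 0, 2, 0)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            confusion([POS], [POS, NEG])

    def test_balanced_203_design_counts(self):
        # 190/13 and 176/27 over 203+203 instances
        c = ConfusionCounts(TP=190, TN=176, FP=27, FN=13)
        assert c.total == 406


class TestMetrics:
    def test_balanced_design_worked_example(self):
        """SE 93.6 / SP 86.7 on the 203+203 design give ACC 90.1,
        MCC 0.805 and g-means 90.1."""
        c = ConfusionCounts(TP=190, TN=176, FP=27, FN=13)
        assert metric_se(c) == pytest.approx(93.6, abs=0.05)
        assert metric_sp(c) == pytest.approx(86.7, abs=0.05)
        assert metric_acc(c) == pytest.approx(90.1, abs=0.05)
        assert metric_mcc(c) == pytest.approx(0.805, abs=0.0005)
        assert metric_gmeans(metric_se(c), metric_sp(c)) == pytest.approx(
            90.1, abs=0.05
        )

    def test_gmeans_from_printed_percentages(self):
        assert metric_gmeans(93.6, 86.7) == pytest.approx(90.1, abs=0.05)
        assert metric_gmeans(89.7, 96.3) == pytest.approx(92.9, abs=0.05)
        assert metric_gmeans(75.0, 75.0) == 75.0

    def test_mcc_conventions(self):
        assert metric_mcc(ConfusionCounts(5, 5, 0, 0)) == 1.0
        assert metric_mcc(ConfusionCounts(2, 2, 2, 2)) == 0.0
        assert metric_mcc(ConfusionCounts(0, 4, 0, 0)) == 0.0  # zero factor

    def test_undefined_metrics_are_nan(self):
        c = ConfusionCounts(TP=0, TN=3, FP=1, FN=0)
        assert np.isnan(metric_se(c))
        assert np.isnan(metric_auc([POS, POS], [0.1, 0.2]))

    def test_auc_endpoints(self):
        y = [POS, POS, NEG, NEG]
        assert metric_auc(y, [0.9, 0.8, 0.2, 0.1]) == 1.0
        assert metric_auc(y, [0.5] * 4) == 0.5

    @settings(max_examples=50, derandomize=True)
    @given(
        n=st.integers(4, 50),
        data=st.data(),
    )
    def test_auc_matches_pair_counting_oracle(self, n, data):
        """Rank AUC equals exhaustive O(n^2) positive-negative pair counting."""
        labels = data.draw(
            st.lists(st.sampled_from([POS, NEG]), min_size=n, max_size=n)
        )
        if POS not in labels or NEG not in labels:
            labels[0], labels[1] = POS, NEG
        scores = data.draw(
            st.lists(st.integers(0, 10), min_size=n, max_size=n)
        )
        wins = ties = total = 0
        for yi, si in zip(labels, scores):
            for yj, sj in zip(labels, scores):
                if yi == POS and yj == NEG:
                    total += 1
                    wins += si > sj
                    ties += si == sj
        assert metric_auc(labels, scores) == pytest.approx(
            (wins + 0.5 * ties) / total
        )

    @pytest.mark.filterwarnings("ignore:A single label")
    @settings(max_examples=60, derandomize=True)
    @given(tp=st.integers(0, 40), tn=st.integers(0, 40),
           fp=st.integers(0, 40), fn=st.integers(0, 40))
    def test_mcc_matches_reference_implementation(self, tp, tn, fp, fn):
        from sklearn.metrics import matthews_corrcoef

        if tp + tn + fp + fn == 0:
            return
        y_true = [POS] * (tp + fn) + [NEG] * (tn + fp)
        y_pred = ([POS] * tp + [NEG] * fn + [NEG] * tn + [POS] * fp)
        ours = metric_mcc(ConfusionCounts(tp, tn, fp, fn))
        assert ours == pytest.approx(
            matthews_corrcoef(y_true, y_pred), abs=1e-12
        )

    @settings(max_examples=40, derandomize=True)
    @given(tp=st.integers(1, 40), tn=st.integers(1, 40),
           fp=st.integers(0, 40), fn=st.integers(0, 40))
    def test_metric_identities(self, tp, tn, fp, fn):
        c = ConfusionCounts(tp, tn, fp, fn)
        se, sp = metric_se(c), metric_sp(c)
        g = metric_gmeans(se, sp)
        assert min(se, sp) - 1e-9 <= g <= max(se, sp) + 1e-9
        if tp + fn == tn + fp:  # balanced classes
            assert metric_acc(c) == pytest.approx((se + sp) / 2)


def test_puk_kernel_is_one_at_zero_distance(rng):
    X = rng.normal(size=(4, 3))
    K = puk_kernel(X, X)
    np.testing.assert_allclose(np.diag(K), 1.0)
    assert np.all((K > 0) & (K <= 1))


@pytest.fixture(scope="module")
def toy_xy():
    rng = np.random.default_rng(3)
    X = np.vstack([
        rng.normal(loc=0.0, size=(15, 4)),
        rng.normal(loc=2.5, size=(15, 4)),
    ])
    y = np.array([POS] * 15 + [NEG] * 15)
    return X, y


class TestProtocols:
    def test_loocv_makes_n_predictions(self, toy_xy):
        X, y = toy_xy
        report = run_loocv(REGISTRY["nb"], X[:6], y[12:18], seed=0)
        assert report.protocol == "loocv"
        assert len(report.runs) == 1

    def test_loocv_counts_sum_to_n(self, toy_xy):
        X, y = toy_xy
        report = run_loocv(REGISTRY["1nn"], X, y)
        m = report.runs[0]
        # recover counts from SE/SP on the known class sizes
        assert m["SE"] * 15 / 100 + m["SP"] * 15 / 100 == pytest.approx(
            m["ACC"] * 30 / 100
        )

    def test_kfold_runs_and_fold_balance(self, toy_xy):
        X, y = toy_xy
        report = run_repeated_kfold(REGISTRY["nb"], X, y, k=5, reps=3, seed=0)
        assert len(report.runs) == 3
        for m in report.runs:
            assert 0 <= m["ACC"] <= 100

    def test_split_respects_reps(self, toy_xy):
        X, y = toy_xy
        report = run_split(REGISTRY["nb"], X, y, reps=4, seed=0)
        assert len(report.runs) == 4
        for m in ("SE", "SP", "ACC", "g_means"):
            assert report.averages[m] == pytest.approx(
                np.mean([r[m] for r in report.runs])
            )

    def test_majority_dummy_on_balanced_data(self, toy_xy):
        from sklearn.dummy import DummyClassifier

        X, y = toy_xy
        dummy = ClassifierSpec(
            "dummy", lambda s: DummyClassifier(strategy="constant",
                                               constant=POS), seeded=False
        )
        report = run_loocv(dummy, X, y)
        m = report.runs[0]
        assert m["ACC"] == pytest.approx(50.0)
        assert m["MCC"] == 0.0

    def test_classifier_registry_all_fit_and_predict(self, toy_xy):
        X, y = toy_xy
        for spec in REGISTRY.values():
            preds = spec.build(0).fit(X, y).predict(X)
            metrics = metrics_from_predictions(list(y), list(preds))
            assert 0 <= metrics["ACC"] <= 100


class TestBenchmark:
    def test_bookkeeping_and_determinism(self, tiny_data):
        specs = [REGISTRY["nb"]]
        r1 = benchmark(tiny_data.positives, tiny_data.pool, specs,
                       ["random"], protocol="split", reps=3, seed=11,
                       protocol_kwargs={"reps": 1})
        r2 = benchmark(tiny_data.positives, tiny_data.pool, specs,
                       ["random"], protocol="split", reps=3, seed=11,
                       protocol_kwargs={"reps": 1})
        key = ("nb", "random")
        assert len(r1[key].runs) == 3
        assert r1[key].averages == r2[key].averages

    def test_balanced_dataset_shape(self, tiny_data):
        X, y = build_balanced_dataset(
            tiny_data.positives, tiny_data.pool, range(len(tiny_data.positives))
        )
        assert len(X) == 2 * len(tiny_data.positives)
        assert list(y).count(POS) == list(y).count(NEG)

    def test_kmeans_sampling_beats_random_for_tree_ensemble(self, tiny_datasets):
        """Directional contrast: averaged held-out g-means with K-means-sampled
        training negatives is at least that with randomly sampled ones for the
        random forest, over ten seeds on planted-strata data."""
        g_random, g_kmeans = [], []
        for seed in range(10):
            data = tiny_datasets(seed)
            res = benchmark(
                data.positives, data.pool, [REGISTRY["rf"]],
                ["random", "kmeans"], protocol="split", reps=3, seed=seed,
                protocol_kwargs={"reps": 1},
            )
            g_random.append(res[("rf", "random")].averages["g_means"])
            g_kmeans.append(res[("rf", "kmeans")].averages["g_means"])
        assert np.mean(g_kmeans) >= np.mean(g_random)
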