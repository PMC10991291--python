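import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as lifelines_logrank

import fedsurv as fs
from fedsurv.exceptions import SizeError, UndefinedMetricError
from fedsurv.fedstats import StandardizationParams
from fedsurv.cox import FinalModel
from oracles import direct_logrank
from conftest import make_network, random_survival


def _model(beta, names, means=None, sds=None):
    p = len(names)
    return FinalModel(
        features=list(names),
        beta=np.asarray(beta, float),
        se=np.ones(p),
        standardization=StandardizationParams(
            means=np.zeros(p) if means is None else np.asarray(means, float),
            sds=np.ones(p) if sds is None else np.asarray(sds, float),
            feature_names=list(names),
        ),
        strata=["n"],
    )


def _dataset(X, names):
    n = X.shape[0]
    return fs.NodeDataset(
        "n", np.array([f"p{i}" for i in range(n)], object),
        times=np.arange(1.0, n + 1), events=np.ones(n, int),
        features=X, feature_names=list(names),
    )


class TestRiskScores:
    def test_zero_beta_gives_unit_scores(self):
        data = _dataset(np.random.default_rng(0).normal(size=(4, 2)), ["a", "b"])
        scores = fs.risk_scores(_model([0.0, 0.0], ["a", "b"]), data)
        np.testing.assert_allclose(scores, 1.0)

    def test_log2_linear_predictor_scores_two(self):
        data = _dataset(np.full((1, 1), np.log(2.0)), ["a"])
        assert fs.risk_scores(_model([1.0], ["a"]), data)[0] == pytest.approx(2.0)

    def test_doubling_beta_squares_scores(self):
        X = np.random.default_rng(1).normal(size=(5, 2))
        data = _dataset(X, ["a", "b"])
        s1 = fs.risk_scores(_model([0.3, -0.2], ["a", "b"]), data)
        s2 = fs.risk_scores(_model([0.6, -0.4], ["a", "b"]), data)
        np.testing.assert_allclose(s2, s1**2, rtol=1e-12)

    def test_missing_feature(self):
        data = _dataset(np.zeros((2, 1)), ["a"])
        with pytest.raises(KeyError):
            fs.risk_scores(_model([1.0], ["zz"]), data)


class TestThresholdAndStratify:
    @pytest.mark.parametrize(
        "medians,expected",
        [((0.5, 0.97, 1.3), 0.97), ((0.8, 1.2), 1.0), ((0.97,), 0.97)],
    )
    def test_median_of_medians(self, medians, expected):
        assert fs.global_threshold(medians) == pytest.approx(expected)

    def test_empty_medians(self):
        with pytest.raises(SizeError):
            fs.global_threshold([])

    def test_boundary_is_high_risk(self):
        labels = fs.stratify([0.5, 0.97, 2.0], 0.97)
        assert labels.tolist() == ["low", "high", "high"]

    def test_all_at_threshold(self):
        assert fs.stratify([1.0, 1.0], 1.0).tolist() == ["high", "high"]

    def test_empty_scores(self):
        assert fs.stratify([], 1.0).tolist() == []


class TestKaplanMeier:
    def test_two_deaths(self):
        km = fs.km_curve([2.0, 4.0], [1, 1])
        np.testing.assert_allclose(km.survival, [0.5, 0.0])

    def test_censoring_suppresses_step(self):
        km = fs.km_curve([2.0, 4.0], [1, 0])
        np.testing.assert_allclose(km.event_times, [2.0])
        np.testing.assert_allclose(km.survival, [0.5])

    def test_matches_reference_implementation(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 40))
            t, e = random_survival(rng, n)
            if e.sum() == 0:
                continue
            km = fs.km_curve(t, e)
            ref = (
                KaplanMeierFitter()
                .fit(t, e)
                .survival_function_at_times(km.event_times)
                .values
            )
            np.testing.assert_allclose(km.survival, ref, atol=1e-10)

    def test_monotone_and_terminal_behaviour(self, rng):
        for _ in range(50):
            t, e = random_survival(rng, int(rng.integers(3, 30)))
            if e.sum() == 0:
                continue
            km = fs.km_curve(t, e)
            assert np.all(np.diff(km.survival) <= 1e-12)
            assert np.all((km.survival >= 0) & (km.survival <= 1))
            assert np.all(np.diff(km.n_at_risk) <= 0)
            last_is_event_only = t.max() in km.event_times and not (
                (t == t.max()) & (e == 0)
            ).any()
            assert (km.survival[-1] == 0) == last_is_event_only


class TestLogRank:
    def test_identical_groups_give_null(self):
        t = np.array([1.0, 2.0, 3.0])
        e = np.array([1, 0, 1])
        chi2, p = fs.logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_term_by_term_example(self):
        ta, ea = [1.0, 2.0], [1, 1]
        tb, eb = [3.0, 4.0], [1, 1]
        ome, var = direct_logrank(ta, ea, tb, eb)
        chi2, _p = fs.logrank_test(ta, ea, tb, eb)
        assert chi2 == pytest.approx(ome**2 / var, rel=1e-12)

    def test_matches_reference_implementation(self, rng):
        checked = 0
        for _ in range(200):
            na, nb = int(rng.integers(3, 30)), int(rng.integers(3, 30))
            ta, ea = random_survival(rng, na)
            tb, eb = random_survival(rng, nb)
            try:
                chi2, p = fs.logrank_test(ta, ea, tb, eb)
            except (UndefinedMetricError, SizeError):
                continue
            ref = lifelines_logrank(ta, tb, ea, eb)
            assert chi2 == pytest.approx(ref.test_statistic, abs=1e-10)
            assert p == pytest.approx(ref.p_value, abs=1e-10)
            checked += 1
        assert checked > 150

    def test_symmetric_in_group_labels(self, rng):
        ta, ea = random_survival(rng, 20)
        tb, eb = random_survival(rng, 25)
        ea[0] = 1
        c1, p1 = fs.logrank_test(ta, ea, tb, eb)
        c2, p2 = fs.logrank_test(tb, eb, ta, ea)
        assert c1 == pytest.approx(c2, rel=1e-12)
        assert 0 < p1 <= 1

    def test_no_events_undefined(self):
        with pytest.raises(UndefinedMetricError):
            fs.logrank_test([1.0], [0], [2.0], [0])


@pytest.fixture(scope="module")
def evaluated():
    datasets, truth = make_network(
        seed=23, nodes=(("a", 200), ("b", 250), ("c", 200)), p=4,
        blocks=((4, 0.1),),
        true_beta={"radiomic_1": 1.0, "radiomic_3": -1.0},
    )
    fed = fs.build_federation(datasets, fs.PipelineConfig(seed=8))
    agg = fs.federated_moments(fed)
    std = fs.standardization_params(agg, datasets[0].feature_names)
    model = fs.fit_unpenalized(fed, sorted(truth.informative), std)
    return fed, fs.evaluate_final(fed, model)


class TestEvaluateFinal:
    def test_cardinality(self, evaluated):
        fed, report = evaluated
        assert set(report.test_c_index) == set(fed.node_ids)
        km_tables = [
            km
            for s in report.stratification.per_node.values()
            for km in (s.km_low, s.km_high)
            if km is not None
        ]
        assert len(report.stratification.per_node) == 3
        assert len(km_tables) == 6

    def test_counts_sum_to_test_size(self, evaluated):
        fed, report = evaluated
        for h in fed.nodes:
            s = report.stratification.per_node[h.node_id]
            assert s.n_low + s.n_high == len(h.split.test_indices)

    def test_strong_signal_discriminates(self, evaluated):
        _fed, report = evaluated
        for node_id, c in report.test_c_index.items():
            assert c is not None and c > 0.65, (node_id, c)

    def test_threshold_is_median_of_node_medians(self, evaluated):
        _fed, report = evaluated
        strat = report.stratification
        assert strat.threshold == pytest.approx(
            np.median(list(strat.node_medians.values()))
        )

    def test_undefined_node_isolated(self):
        """A node whose test set cannot form a comparable pair reports None
        without disturbing the other nodes."""
        datasets, _ = make_network(
            seed=31, nodes=(("a", 100), ("b", 120)), p=2, blocks=((2, 0.0),),
            true_beta={"radiomic_1": 0.5},
        )
        # node 'c': two patients, the earlier one censored -> no comparable pair
        tiny = fs.NodeDataset(
            "c", np.array(["x1", "x2"], object),
            times=np.array([10.0, 20.0]), events=np.array([0, 1]),
            features=np.zeros((2, 2)), feature_names=datasets[0].feature_names,
        )
        handles = [
            fs.NodeHandle(d, fs.split_node(d, 0.2, seed=1)) for d in datasets
        ]
        handles.append(
            fs.NodeHandle(
                tiny,
                fs.SplitAssignment(
                    node_id="c",
                    train_indices=np.array([], dtype=int),
                    test_indices=np.array([0, 1]),
                    seed=0,
                    fraction_test=0.99,
                ),
            )
        )
        fed = fs.Federation(handles, fs.PrivacyPolicy(n_features=2))
        agg = fs.federated_moments(fed, node_ids=["a", "b"])
        std = fs.standardization_params(agg, datasets[0].feature_names)
        model = fs.fit_unpenalized(fed, ["radiomic_1"], std, node_ids=["a", "b"])
        report = fs.evaluate_final(fed, model)
        assert report.test_c_index["c"] is None
        assert report.test_c_index["a"] is not None
        assert report.test_c_index["b"] is not None
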