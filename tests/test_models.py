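"""Whole-genome regression EM solvers, random forest, scoring, accuracy."""

import numpy as np
import pytest

import soysim as ss
from soysim.models import TrainingSet, assemble_training_window, fit_rf, fit_wgr


@pytest.fixture(scope="module")
def dense_instance():
    rng = np.random.default_rng(42)
    n, m = 50, 100
    M = rng.integers(0, 3, size=(n, m)).astype(float)
    y = 1.0 + M @ rng.normal(0, 0.3, m) + rng.normal(0, 1, n)
    return TrainingSet(M=M, y=y, cycle=np.zeros(n, dtype=int))


def _ridge_oracle(ts, lam):
    # joint solve with unpenalised intercept on centred markers
    n, m = ts.M.shape
    Xc = ts.M - ts.M.mean(axis=0)
    A = np.column_stack([np.ones(n), Xc])
    P = np.zeros((m + 1, m + 1))
    P[1:, 1:] = lam * np.eye(m)
    return np.linalg.solve(A.T @ A + P, A.T @ ts.y)[1:]


class TestWGR:
    def test_em_gblup_equals_ridge_closed_form(self, dense_instance):
        lam = 50.0
        model = fit_wgr("GBLUP", dense_instance,
                        hyperparams={"fixed_lambda": lam}, tol=1e-12, max_iter=20_000)
        beta = _ridge_oracle(dense_instance, lam)
        rel = np.max(np.abs(model.beta - beta)) / np.max(np.abs(beta))
        assert rel < 1e-6

    def test_noiseless_limit_reproduces_response(self):
        rng = np.random.default_rng(1)
        M = rng.integers(0, 3, size=(80, 20)).astype(float)
        y = M @ rng.normal(0, 1, 20)  # exact marker signal, no residual
        ts = TrainingSet(M=M, y=y, cycle=np.zeros(80, dtype=int))
        model = fit_wgr("GBLUP", ts, max_iter=2000)
        pred = model.predict(M)
        assert 1 - np.var(y - pred) / np.var(y) > 0.999

    def test_monomorphic_marker_effect_exactly_zero(self, dense_instance):
        M = dense_instance.M.copy()
        M[:, 7] = 1.0
        ts = TrainingSet(M=M, y=dense_instance.y, cycle=dense_instance.cycle)
        for method in ("GBLUP", "BayesA", "BayesB", "FLM"):
            model = fit_wgr(method, ts)
            assert model.beta[7] == 0.0

    def test_constant_response_gives_intercept_only(self, dense_instance):
        ts = TrainingSet(M=dense_instance.M, y=np.full(50, 2.5),
                         cycle=dense_instance.cycle)
        with pytest.warns(UserWarning):
            model = fit_wgr("GBLUP", ts)
        assert np.all(model.beta == 0)
        assert np.allclose(model.predict(dense_instance.M), 2.5)

    @pytest.mark.parametrize("method", ["GBLUP", "BayesA", "BayesB", "FLM"])
    def test_centering_response_shifts_predictions(self, dense_instance, method):
        a = fit_wgr(method, dense_instance)
        shifted = TrainingSet(M=dense_instance.M, y=dense_instance.y + 10.0,
                              cycle=dense_instance.cycle)
        b = fit_wgr(method, shifted)
        da = a.predict(dense_instance.M)
        db = b.predict(dense_instance.M)
        assert np.allclose(db - da, 10.0, atol=1e-6)

    def test_bayesb_concentrates_on_sparse_signal(self):
        # 10 true QTL among 500 markers: the variable-selection prior puts a
        # larger share of total |effect| on the true QTL than ridge does
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            M = rng.integers(0, 3, size=(200, 500)).astype(float)
            qtl = rng.choice(500, 10, replace=False)
            beta = np.zeros(500)
            beta[qtl] = rng.normal(0, 1, 10)
            y = M @ beta + rng.normal(0, 2, 200)
            ts = TrainingSet(M=M, y=y, cycle=np.zeros(200, dtype=int))
            share = {}
            for method in ("GBLUP", "BayesB"):
                mo = fit_wgr(method, ts)
                eff = np.abs(mo.beta * mo.gamma)
                share[method] = eff[qtl].sum() / eff.sum()
            wins += share["BayesB"] >= share["GBLUP"]
        assert wins >= 3

    def test_unknown_method(self, dense_instance):
        with pytest.raises(ValueError):
            fit_wgr("MCMC", dense_instance)


class TestRandomForest:
    def test_constant_response(self, dense_instance):
        ts = TrainingSet(M=dense_instance.M, y=np.full(50, 1.5),
                         cycle=dense_instance.cycle)
        model = fit_rf(ts, n_trees=10, seed=0)
        assert np.allclose(model.predict(dense_instance.M), 1.5)

    def test_single_stump_recovers_group_means(self):
        # one dominant marker; brute-force best-split search is the oracle
        rng = np.random.default_rng(2)
        n = 300
        M = np.zeros((n, 5))
        M[:, 2] = rng.integers(0, 3, n)
        y = 4.0 * (M[:, 2] >= 1) + rng.normal(0, 0.1, n)
        ts = TrainingSet(M=M, y=y, cycle=np.zeros(n, dtype=int))
        model = fit_rf(ts, n_trees=1, mtry=5, seed=3, max_depth=1, bootstrap=False)
        pred = model.predict(M)
        # oracle: best single split minimising SSE over all features/cuts
        best = (np.inf, None)
        for j in range(5):
            for cut in np.unique(M[:, j])[:-1]:
                left = M[:, j] <= cut
                sse = ((y[left] - y[left].mean()) ** 2).sum() + \
                      ((y[~left] - y[~left].mean()) ** 2).sum()
                if sse < best[0]:
                    best = (sse, (j, cut, y[left].mean(), y[~left].mean()))
        j, cut, ml, mr = best[1]
        exp = np.where(M[:, j] <= cut, ml, mr)
        assert np.allclose(pred, exp, atol=1e-9)

    def test_training_fit_beats_out_of_bag(self):
        rng = np.random.default_rng(4)
        M = rng.integers(0, 3, size=(300, 50)).astype(float)
        y = M @ rng.normal(0, 0.5, 50) + rng.normal(0, 1, 300)
        ts = TrainingSet(M=M, y=y, cycle=np.zeros(300, dtype=int))
        model = fit_rf(ts, n_trees=100, seed=5, oob_score=True)
        pred = model.predict(M)
        r2_train = 1 - np.var(y - pred) / np.var(y)
        assert r2_train >= model.ensemble.oob_score_

    def test_invalid_tree_count(self, dense_instance):
        with pytest.raises(ValueError):
            fit_rf(dense_instance, n_trees=0)


class TestScoring:
    def test_modes_return_expected_vectors(self, small_founders, small_arch):
        tbv = ss.compute_tbv(small_founders, small_arch)
        ss.simulate_phenotypes(small_founders, small_arch, seed=6)
        assert np.array_equal(ss.score_candidates("TBV", small_founders), tbv)
        assert np.array_equal(
            ss.score_candidates("Pheno", small_founders), small_founders.phenotype
        )
        r1 = ss.score_candidates("Random", small_founders, rng=np.random.default_rng(7))
        r2 = ss.score_candidates("Random", small_founders, rng=np.random.default_rng(7))
        assert np.array_equal(r1, r2)

    def test_gs_mode_requires_model(self, small_founders):
        with pytest.raises(ValueError):
            ss.score_candidates("GBLUP", small_founders)


class TestPredictionAccuracy:
    def test_perfect_and_inverted(self):
        tbv = np.array([1.0, 2.0, 5.0, 3.0])
        assert ss.prediction_accuracy(tbv, tbv) == pytest.approx(1.0)
        assert ss.prediction_accuracy(-tbv, tbv) == pytest.approx(-1.0)

    def test_null_correlation_bound(self):
        rng = np.random.default_rng(8)
        tbv = rng.normal(size=10_000)
        scores = rng.normal(size=10_000)
        assert abs(ss.prediction_accuracy(scores, tbv)) < 0.05

    def test_zero_variance_flagged(self):
        assert np.isnan(ss.prediction_accuracy(np.ones(5), np.arange(5.0)))


class TestTrainingWindow:
    @staticmethod
    def _history(n_cycles, n=10, m=4):
        rng = np.random.default_rng(9)
        return [
            (c, rng.integers(0, 3, size=(n, m)), rng.normal(size=n))
            for c in range(1, n_cycles + 1)
        ]

    def test_window_keeps_last_three_cycles(self):
        ts = assemble_training_window(self._history(5), window=3)
        assert sorted(np.unique(ts.cycle)) == [3, 4, 5]

    def test_single_cycle_truncated_window(self):
        ts = assemble_training_window(self._history(1), window=3)
        assert ts.n_records == 10 and set(ts.cycle) == {1}

    def test_record_cap(self):
        ts = assemble_training_window(self._history(3), window=3, max_records=15)
        assert ts.n_records == 15
        assert ts.cycle[0] == 2  # oldest rows dropped first

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            assemble_training_window([], window=3)


def test_model_dump_sidecar(tmp_path, dense_instance):
    import json

    model = fit_wgr("BayesB", dense_instance, max_iter=50)
    path = tmp_path / "model.json"
    model.dump(path)
    payload = json.loads(path.read_text())
    assert payload["method"] == "BayesB"
    assert len(payload["beta"]) == dense_instance.M.shape[1]
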