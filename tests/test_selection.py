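"""Selection-cascade contracts: loading percentile + exclusivity,
bootstrapped Gini importance, stability selection, and strict-filtering
of the full cascade."""

import numpy as np
import pandas as pd
import pytest

from omicsurv.cluster import PCAModel
from omicsurv.exceptions import ValidationError
from omicsurv.selection import (
    gini_bootstrap_filter,
    lasso_stability_select,
    select_by_loadings,
    select_signature,
)


def _model_from_loadings(loadings: pd.DataFrame) -> PCAModel:
    n_comp = loadings.shape[1]
    return PCAModel(
        loadings=loadings,
        scores=pd.DataFrame(np.zeros((3, n_comp)), columns=loadings.columns),
        explained_variance_ratio=np.linspace(0.5, 0.1, n_comp),
        n_components=n_comp,
    )


class TestLoadingSelection:
    def _loadings(self):
        # 20 features x 2 PCs; f0 tops PC1 only, f1 tops both, rest small
        rng = np.random.default_rng(0)
        L = pd.DataFrame(
            rng.uniform(0.01, 0.2, (20, 2)),
            index=[f"f{i}" for i in range(20)],
            columns=["PC1", "PC2"],
        )
        L.loc["f0", "PC1"] = 0.9
        L.loc["f1"] = [0.95, 0.95]
        L.loc["f2", "PC2"] = 0.9
        return L

    def test_exclusive_top_decile_kept(self):
        trace = select_by_loadings(_model_from_loadings(self._loadings()))
        assert "f0" in trace.surviving and "f2" in trace.surviving

    def test_feature_marked_in_two_pcs_excluded(self):
        trace = select_by_loadings(_model_from_loadings(self._loadings()))
        assert "f1" not in trace.surviving

    def test_feature_below_percentile_everywhere_excluded(self):
        trace = select_by_loadings(_model_from_loadings(self._loadings()))
        assert "f5" not in trace.surviving

    def test_invariant_to_sign_flips_and_order(self):
        L = self._loadings()
        base = set(select_by_loadings(_model_from_loadings(L)).surviving)
        flipped = L.copy()
        flipped["PC2"] = -flipped["PC2"]
        assert set(select_by_loadings(_model_from_loadings(flipped)).surviving) == base
        perm = L.sample(frac=1.0, random_state=1)
        assert set(select_by_loadings(_model_from_loadings(perm)).surviving) == base

    def test_requires_two_components(self):
        L = self._loadings()[["PC1"]]
        model = _model_from_loadings(L)
        model.n_components = 1
        with pytest.raises(ValidationError):
            select_by_loadings(model)


class TestGiniFilter:
    def _data(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 120
        y = np.r_[np.zeros(60), np.ones(60)]
        X = rng.standard_normal((n, 51))
        X[:, 0] = y * 4 + rng.normal(0, 0.05, n)  # perfect separator
        cols = [f"f{i}" for i in range(51)]
        return pd.DataFrame(X, columns=cols), y

    def test_perfect_separator_has_maximal_importance(self):
        X, y = self._data()
        trace = gini_bootstrap_filter(X, y, n_boot=50, seed=0)
        assert trace.diagnostics["cumulative_importance"].idxmax() == "f0"
        assert "f0" in trace.surviving

    def test_same_seed_reproduces_importances(self):
        X, y = self._data()
        a = gini_bootstrap_filter(X, y, n_boot=20, seed=3)
        b = gini_bootstrap_filter(X, y, n_boot=20, seed=3)
        pd.testing.assert_frame_equal(a.diagnostics, b.diagnostics)

    def test_unreachable_threshold_warns_not_errors(self):
        X, y = self._data()
        with pytest.warns(UserWarning, match="empty survivor"):
            trace = gini_bootstrap_filter(
                X, y, n_boot=5, mode="absolute", importance_threshold=1e9, seed=0
            )
        assert trace.surviving == []

    def test_single_class_labels_rejected(self):
        X, _ = self._data()
        with pytest.raises(ValidationError, match="class"):
            gini_bootstrap_filter(X, np.zeros(len(X)), n_boot=2)


class TestLassoStability:
    def test_planted_features_recovered(self):
        rng = np.random.default_rng(7)
        n = 300
        y = rng.integers(0, 2, n)
        X = rng.standard_normal((n, 105))
        X[:, :5] += 2.0 * y[:, None]
        frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(105)])
        sig = lasso_stability_select(frame, y, n_runs=50, n_select=5, seed=0)
        assert set(sig.feature_ids()) == {f"f{i}" for i in range(5)}

    def test_pure_noise_inclusion_below_half_in_expectation(self):
        maxima = []
        for seed in range(4):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.standard_normal((150, 30)))
            y = rng.integers(0, 2, 150)
            sig = lasso_stability_select(X, y, n_runs=40, n_select=5, seed=seed)
            maxima.append(sig.trace.diagnostics["inclusion_frequency"].max())
        assert np.mean(maxima) < 0.5

    def test_returns_requested_count_ranked_by_frequency(self):
        rng = np.random.default_rng(8)
        n = 200
        y = rng.integers(0, 2, n)
        X = rng.standard_normal((n, 20))
        X[:, :10] += rng.uniform(0.5, 2.5, 10) * y[:, None]
        sig = lasso_stability_select(pd.DataFrame(X), y, n_runs=30, n_select=9, seed=1)
        assert len(sig) == 9
        freqs = sig.entries["frequency"].to_numpy()
        assert (np.diff(freqs) <= 1e-12).all()
        assert sig.entries["rank"].tolist() == list(range(1, 10))


def test_cascade_strictly_filters(small_table):
    table, model, assignment, truth = small_table
    signature, traces = select_signature(
        table,
        assignment.labels.to_numpy(),
        model=model,
        gini_n_boot=30,
        lasso_n_runs=30,
        n_select=6,
        seed=0,
    )
    counts = [len(t.surviving) for t in traces]
    assert counts[0] >= counts[1] >= counts[2] == len(signature)
    for trace in traces:
        assert set(trace.surviving) <= set(trace.entering)


def test_cascade_mostly_recovers_planted(small_table):
    table, model, assignment, truth = small_table
    signature, _ = select_signature(
        table,
        assignment.labels.to_numpy(),
        model=model,
        gini_n_boot=50,
        lasso_n_runs=50,
        n_select=6,
        seed=1,
    )
    planted = {f"{g}|{l}" for g, l in truth.planted_features}
    hits = sum(1 for f in signature.feature_ids() if f in planted)
    assert hits >= len(signature) - 1
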