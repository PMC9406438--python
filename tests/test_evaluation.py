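"""Evaluation oracles: Monte-Carlo summaries, Mann–Whitney AUC identity,
Youden cut-offs, logistic-model identities and Fisher enumeration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from omicsurv.evaluation import (
    cross_omics_profile,
    fisher_association,
    logistic_signature_model,
    monte_carlo_eval,
    nagelkerke_r2,
    null_model_accuracy,
    odds_ratio,
    roc_youden,
)
from omicsurv.exceptions import ValidationError
from omicsurv.selection import Signature


class TestMonteCarlo:
    def test_separable_data_scores_one_everywhere(self):
        rng = np.random.default_rng(0)
        y = np.r_[np.ones(40), 2 * np.ones(30)]
        X = np.c_[y * 10 + rng.normal(0, 0.1, 70)]
        ev = monte_carlo_eval(X, y, model="svm", n_iter=25, seed=0)
        assert (ev.table.to_numpy() == 1.0).all()

    def test_permuted_labels_hit_majority_rate(self):
        rng = np.random.default_rng(1)
        n = 410
        y = np.r_[np.ones(240), 2 * np.ones(170)]
        rng.shuffle(y)
        X = rng.standard_normal((n, 5))
        ev = monte_carlo_eval(X, y, model="svm", n_iter=100, test_fraction=0.127, seed=1)
        assert ev.table.loc["accuracy", "mean"] == pytest.approx(0.585, abs=0.05)

    def test_same_seed_reproduces_summary(self):
        rng = np.random.default_rng(2)
        y = rng.integers(1, 3, 60)
        X = rng.standard_normal((60, 3)) + (y == 2)[:, None]
        a = monte_carlo_eval(X, y, model="rf", n_iter=5, seed=9)
        b = monte_carlo_eval(X, y, model="rf", n_iter=5, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_summary_points_ordered(self):
        rng = np.random.default_rng(3)
        y = rng.integers(1, 3, 80)
        X = rng.standard_normal((80, 4)) + 0.8 * (y == 2)[:, None]
        ev = monte_carlo_eval(X, y, model="svm", n_iter=40, seed=4)
        for _, row in ev.table.iterrows():
            assert row["min"] <= row["q1"] <= row["median"] <= row["q3"] <= row["max"]
            assert 0 <= row["min"] and row["max"] <= 1


class TestROC:
    def test_perfect_separation(self):
        r = roc_youden([1, 2, 3, 4], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert 2 < r.cutoff <= 3
        assert r.youden_j == pytest.approx(1.0)

    def test_three_quarters_concordant_pairs(self):
        r = roc_youden([1, 3, 2, 4], [0, 0, 1, 1])
        assert r.auc == pytest.approx(0.75)

    def test_exchangeable_distributions_give_half(self):
        r = roc_youden([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert r.auc == pytest.approx(0.5)

    def test_constant_values_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            r = roc_youden([2, 2, 2, 2], [0, 0, 1, 1])
        assert r.auc == 0.5 and r.cutoff is None

    def test_auc_equals_mann_whitney_on_random_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            v = rng.normal(size=30).round(1)  # ties included
            y = rng.integers(0, 2, 30)
            if len(np.unique(y)) < 2:
                continue
            r = roc_youden(v, y)
            sk = roc_auc_score(y, v)
            assert r.auc == pytest.approx(max(sk, 1 - sk), abs=1e-12)

    def test_orientation_reported_for_protective_feature(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 200)
        v = -2.0 * y + rng.normal(0, 1, 200)
        r = roc_youden(v, y)
        assert r.direction == "low" and r.auc > 0.8

    def test_ci_contains_auc(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 100)
        v = y + rng.normal(0, 1, 100)
        for method in ("hanley-mcneil", "delong"):
            r = roc_youden(v, y, ci_method=method)
            assert r.ci[0] <= r.auc <= r.ci[1]


class TestLogisticModel:
    def _fit(self, seed=0, junk=True):
        rng = np.random.default_rng(seed)
        n = 410
        y = np.r_[np.ones(240), 2 * np.ones(170)]
        cols = {
            "a": (y == 2) * 2.0 + rng.normal(0, 1, n),
            "b": (y == 2) * 1.5 + rng.normal(0, 1, n),
        }
        if junk:
            cols["junk"] = rng.normal(0, 1, n)
        X = pd.DataFrame(cols)
        cuts = {c: float(np.median(X[c])) for c in X}
        return logistic_signature_model(X, y, cutoffs=cuts), X, y

    def test_odds_ratio_identity_holds_exactly(self):
        model, _, _ = self._fit()
        np.testing.assert_allclose(
            model.coefficients["or_adj"], np.exp(model.coefficients["B"]), rtol=1e-12
        )
        np.testing.assert_allclose(
            model.coefficients["ci_low"],
            np.exp(model.coefficients["B"] - 1.96 * model.coefficients["se"]),
            rtol=1e-3,
        )

    def test_backward_elimination_removes_junk(self):
        model, _, _ = self._fit()
        assert "junk" in model.removed
        assert (model.coefficients["p"] <= 0.05).all()

    def test_null_accuracy_is_majority_share(self):
        model, _, y = self._fit()
        assert model.null_accuracy == pytest.approx(240 / 410)

    def test_nagelkerke_null_model_is_zero(self):
        assert nagelkerke_r2(-100.0, -100.0, 200) == 0.0

    def test_nagelkerke_within_unit_interval(self):
        model, _, _ = self._fit()
        assert 0 <= model.nagelkerke_r2 <= 1

    def test_separable_predictor_triggers_penalized_fallback(self):
        y = np.r_[np.ones(50), 2 * np.ones(50)]
        X = pd.DataFrame({"perfect": np.r_[np.zeros(50), np.ones(50)]})
        with pytest.warns(UserWarning, match="separation"):
            model = logistic_signature_model(X, y, cutoffs={"perfect": 0.5})
        assert model.separation
        assert model.accuracy == 1.0

    def test_continuous_mode_hosmer_lemeshow_in_range(self):
        rng = np.random.default_rng(1)
        n = 400
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.5 + x)))
        y = (rng.random(n) < p).astype(int) + 1
        model = logistic_signature_model(pd.DataFrame({"x": x}), y, binarize=False)
        assert 0 <= model.hosmer_lemeshow_p <= 1
        assert model.hosmer_lemeshow_p > 0.01  # correctly specified model fits

    def test_missing_cutoff_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValidationError, match="cut-off"):
            logistic_signature_model(X, [1, 1, 2, 2], cutoffs={})


class TestFisher:
    def test_balanced_table_p_one(self):
        p, _ = fisher_association([0, 0, 1, 1], [0, 1, 0, 1])
        assert p == pytest.approx(1.0)

    def test_diagonal_two_by_two(self):
        p, _ = fisher_association([0, 0, 1, 1], [0, 0, 1, 1])
        assert p == pytest.approx(1 / 3)

    def test_diagonal_five_by_five(self):
        p, table = fisher_association([0] * 5 + [1] * 5, [0] * 5 + [1] * 5)
        assert p == pytest.approx(2 / 252)
        assert table.tolist() == [[5, 0], [0, 5]]

    def test_empty_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="margin"):
            p, _ = fisher_association([0, 0, 0], [0, 1, 1])
        assert p == 1.0


def test_null_model_accuracy_majority_fraction():
    assert null_model_accuracy([1] * 240 + [2] * 170) == pytest.approx(240 / 410)
    with pytest.raises(ValidationError):
        null_model_accuracy([])


def test_odds_ratio_is_exp():
    assert odds_ratio(0.0) == 1.0
    assert odds_ratio(np.log(7.0)) == pytest.approx(7.0)


class TestCrossOmicsProfile:
    def test_planted_loss_gene_more_negative_in_cluster_two(self, small_cohort):
        bundle, truth = small_cohort
        cna_gene = next(g for g, l in truth.planted_features if l == "cna")
        entries = pd.DataFrame(
            [{"feature": f"{cna_gene}|cna", "gene": cna_gene, "layer": "cna", "rank": 1, "frequency": 1.0}]
        ).set_index("feature")
        prof = cross_omics_profile(Signature(entries=entries), bundle, truth.labels.to_numpy())
        by_cluster = prof.set_index("cluster")["mean_cna_log2"]
        assert by_cluster[2] < by_cluster[1]

    def test_gene_absent_from_layer_yields_missing_cell(self, small_cohort):
        bundle, truth = small_cohort
        gene = bundle.annotation["gene"].iloc[0]
        entries = pd.DataFrame(
            [{"feature": f"{gene}|expression", "gene": gene, "layer": "expression", "rank": 1, "frequency": 1.0}]
        ).set_index("feature")
        slim = type(bundle)(
            segments=bundle.segments,
            annotation=bundle.annotation,
            methylation=bundle.methylation.drop(columns=[gene]),
            expression=bundle.expression,
            clinical=bundle.clinical,
        )
        prof = cross_omics_profile(Signature(entries=entries), slim, truth.labels.to_numpy())
        assert prof["mean_beta"].isna().all()
        assert prof["median_expression"].notna().all()

    def test_empty_signature_empty_table(self, small_cohort):
        bundle, truth = small_cohort
        empty = Signature(
            entries=pd.DataFrame(columns=["gene", "layer", "rank", "frequency"])
        )
        prof = cross_omics_profile(empty, bundle, truth.labels.to_numpy())
        assert prof.empty
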