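"""Reduction-stage oracles: interval-overlap mapping, frequency filters,
integration assembly and the correlation construct filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicsurv import FilterParams
from omicsurv.exceptions import ValidationError
from omicsurv.reduction import (
    CorrelationFilter,
    apply_layer_filters,
    build_integration_table,
    correlation_filter,
    map_segments_to_genes,
)


def _seg(rows):
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "log2_ratio"])


def _ann(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


class TestSegmentMapping:
    def test_gene_inside_single_segment_takes_its_value(self):
        seg = _seg([("s1", "chr1", 100, 200, -0.5)])
        ann = _ann([("G1", "chr1", 150, 180)])
        out = map_segments_to_genes(seg, ann)
        assert out.loc["s1", "G1"] == -0.5

    def test_overlap_length_weighted_mean(self):
        # gene 71..110 (40 bp): 30 bp overlap at -0.4, 10 bp at 0.0 -> -0.3
        seg = _seg([("s1", "chr1", 1, 100, -0.4), ("s1", "chr1", 101, 200, 0.0)])
        ann = _ann([("G1", "chr1", 71, 110)])
        out = map_segments_to_genes(seg, ann)
        assert out.loc["s1", "G1"] == pytest.approx(-0.3)

    def test_gene_without_segments_is_missing(self):
        seg = _seg([("s1", "chr1", 1, 100, 0.2)])
        ann = _ann([("G1", "chr1", 1, 50), ("G2", "chr9", 1, 50)])
        out = map_segments_to_genes(seg, ann)
        assert np.isnan(out.loc["s1", "G2"])

    def test_unknown_chromosome_segments_ignored_with_warning(self):
        seg = _seg([("s1", "chr1", 1, 100, 0.2), ("s1", "chrUn", 1, 100, 9.0)])
        ann = _ann([("G1", "chr1", 1, 50)])
        with pytest.warns(UserWarning, match="chrUn"):
            out = map_segments_to_genes(seg, ann)
        assert out.loc["s1", "G1"] == pytest.approx(0.2)

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValidationError):
            map_segments_to_genes(_seg([("s1", "chr1", 1, 2, 0.0)]), _ann([]))


class TestLayerFilters:
    def _matrix(self, col_values):
        return pd.DataFrame(
            {name: vals for name, vals in col_values.items()},
            index=[f"s{i}" for i in range(10)],
        )

    def test_cna_frequency_boundary(self):
        cna = self._matrix(
            {
                "kept": [0.3] * 3 + [0.0] * 7,  # altered in 3/10 >= 30%
                "dropped": [0.3] * 2 + [0.0] * 8,  # 2/10 < 30%
            }
        )
        empty = self._matrix({})
        c, _, _ = apply_layer_filters(cna, empty, empty)
        assert list(c.columns) == ["kept"]

    def test_methylation_frequency_boundary(self):
        meth = self._matrix(
            {
                "kept": [0.5] * 4 + [0.1] * 6,  # beta >= 0.3 in 4/10 >= 40%
                "dropped": [0.5] * 3 + [0.1] * 7,
            }
        )
        empty = self._matrix({})
        _, m, _ = apply_layer_filters(empty, meth, empty)
        assert list(m.columns) == ["kept"]

    def test_expression_null_boundary(self):
        expr = self._matrix(
            {
                "dropped": [0.0] * 6 + [5.0] * 4,  # 6/10 null > 50%
                "kept": [0.0] * 5 + [5.0] * 5,  # exactly 50% allowed
                "kept_nan": [np.nan] * 5 + [5.0] * 5,
            }
        )
        empty = self._matrix({})
        _, _, e = apply_layer_filters(empty, empty, expr)
        assert set(e.columns) == {"kept", "kept_nan"}

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 500), bump=st.floats(0.05, 0.5))
    def test_raising_thresholds_never_keeps_more(self, seed, bump):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(20)]
        cna = pd.DataFrame(rng.normal(0, 0.3, (20, 15)), index=idx)
        meth = pd.DataFrame(rng.random((20, 15)), index=idx)
        expr = pd.DataFrame(
            rng.random((20, 15)) * (rng.random((20, 15)) > 0.4), index=idx
        )
        base = FilterParams()
        stricter = FilterParams(
            cna_freq=min(1.0, base.cna_freq + bump),
            meth_freq=min(1.0, base.meth_freq + bump),
            expr_null_max=max(0.0, base.expr_null_max - bump),
        )
        loose = apply_layer_filters(cna, meth, expr, base)
        tight = apply_layer_filters(cna, meth, expr, stricter)
        for lo, hi in zip(tight, loose):
            assert lo.shape[1] <= hi.shape[1]


class TestIntegrationTable:
    def _layers(self, n=8):
        rng = np.random.default_rng(0)
        idx = [f"s{i}" for i in range(n)]
        mk = lambda genes, lo=0.0, hi=1.0: pd.DataFrame(
            rng.uniform(lo, hi, (n, len(genes))), index=idx, columns=genes
        )
        return (
            mk(["A", "B", "C"], -0.5, 0.5),
            mk(["B", "D", "E", "F"]),
            mk(["A", "G", "H", "I", "J"], 1, 100),
        )

    def test_concatenation_counts(self):
        c, m, e = self._layers()
        table = build_integration_table(c, m, e)
        assert table.n_features == 12
        assert table.layer_counts() == {"cna": 3, "methylation": 4, "expression": 5}

    def test_same_gene_in_two_layers_stays_distinct(self):
        c, m, e = self._layers()
        table = build_integration_table(c, m, e)
        assert "B|cna" in table.data.columns and "B|methylation" in table.data.columns

    def test_disjoint_samples_rejected(self):
        c, m, e = self._layers()
        m = m.set_axis([f"t{i}" for i in range(len(m))], axis=0)
        with pytest.raises(ValidationError, match="sample"):
            build_integration_table(c, m, e)

    def test_empty_layer_omitted_with_warning(self):
        c, m, e = self._layers()
        with pytest.warns(UserWarning, match="cna"):
            table = build_integration_table(c.iloc[:, :0], m, e)
        assert "cna" not in table.layer_counts()

    def test_standardized_columns(self):
        c, m, e = self._layers()
        table = build_integration_table(c, m, e)
        np.testing.assert_allclose(table.data.mean(), 0, atol=1e-12)
        np.testing.assert_allclose(table.data.std(ddof=0), 1, atol=1e-12)


class TestCorrelationFilter:
    def _table(self, data: dict):
        frame = pd.DataFrame(data)
        return build_integration_table(
            frame, frame.iloc[:, :0], frame.iloc[:, :0], standardize=True
        )

    def test_duplicate_kept_independent_dropped(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=50)
        table = self._table({"A": a, "B": a.copy(), "C": rng.normal(size=50)})
        out = correlation_filter(table)
        assert set(out.data.columns) == {"A|cna", "B|cna"}

    def test_idempotent(self, small_table):
        table = small_table[0]
        once = correlation_filter(table)
        twice = correlation_filter(once)
        assert list(once.data.columns) == list(twice.data.columns)

    def test_pair_below_threshold_dropped(self):
        # construct empirical r exactly 0.79 by orthogonalization
        rng = np.random.default_rng(3)
        n, r = 50, 0.79
        a = rng.normal(size=n)
        a = (a - a.mean()) / a.std()
        e = rng.normal(size=n)
        e = e - e.mean()
        e = e - (e @ a) / (a @ a) * a  # orthogonal to a
        e = e / e.std()
        b = r * a + np.sqrt(1 - r**2) * e
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(0.79, abs=1e-12)
        table = self._table({"A": a, "B": b})
        out = correlation_filter(table, r_threshold=0.8)
        assert out.n_features == 0

    def test_anticorrelated_pair_kept(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=50)
        table = self._table({"A": a, "B": -a, "C": rng.normal(size=50)})
        out = correlation_filter(table)
        assert set(out.data.columns) == {"A|cna", "B|cna"}

    def test_constant_feature_dropped_with_warning(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=30)
        frame = pd.DataFrame({"A": a, "B": a.copy(), "K": np.ones(30)})
        filt = CorrelationFilter()
        with pytest.warns(UserWarning, match="constant"):
            filt.fit(frame.to_numpy())
        assert filt.get_support().tolist() == [True, True, False]

    def test_permutation_invariance(self, small_table):
        table = small_table[0]
        rng = np.random.default_rng(6)
        perm = rng.permutation(table.data.shape[1])
        shuffled = table.subset([table.data.columns[i] for i in perm])
        out_a = set(correlation_filter(table).data.columns)
        out_b = set(correlation_filter(shuffled).data.columns)
        assert out_a == out_b

    def test_planted_constructs_survive(self, small_table):
        table, _, _, truth = small_table
        planted = {f"{g}|{l}" for g, l in truth.planted_features}
        assert planted <= set(table.data.columns)
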