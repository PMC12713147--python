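import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from gcniche import (
    CountMatrix,
    ParameterError,
    ValidationError,
    call_positivity,
    distance_to_nearest,
    gc_ppv,
    rank_percentile,
    smoothed_decay,
    wilcoxon_contrast,
)

from conftest import make_cell_table


def _cm(dense, genes=None):
    dense = np.asarray(dense)
    genes = genes or [f"g{i}" for i in range(dense.shape[0])]
    cells = [f"c{i}" for i in range(dense.shape[1])]
    return CountMatrix.from_parts(genes, cells, sparse.csr_matrix(dense))


def exact_ranksum_p(x, y):
    """Exhaustive-enumeration two-sided rank-sum p-value."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    n1 = len(x)
    obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    stats = np.array([
        ranks[list(c)].sum() for c in itertools.combinations(range(len(pooled)), n1)
    ])
    return float(np.mean(np.abs(stats - mu) >= abs(obs - mu) - 1e-12))


class TestPositivity:
    def test_threshold_boundaries_and_oracle(self):
        cm = _cm([[0, 1, 2], [3, 0, 1]])
        pos = call_positivity(cm, threshold=1).toarray()
        np.testing.assert_array_equal(pos, [[False, True, True], [True, False, True]])
        rng = np.random.default_rng(0)
        dense = rng.poisson(1.0, size=(20, 30))
        np.testing.assert_array_equal(
            call_positivity(_cm(dense), threshold=2).toarray(), dense >= 2
        )

    def test_threshold_must_be_positive(self):
        with pytest.raises(ParameterError):
            call_positivity(_cm([[1]]), threshold=0)


class TestPPV:
    def test_four_of_five_positive_tfh_in_gc_gives_point_eight(self):
        pos = sparse.csr_matrix(np.array([[1, 1, 1, 1, 1, 0]], dtype=bool))
        tfh = np.array([True] * 5 + [True])
        in_gc = np.array([True, True, True, True, False, False])
        row = gc_ppv(pos, ["g"], tfh, in_gc, min_pos=1).iloc[0]
        assert row.n_pos_tfh == 5 and row.n_pos_tfh_in_gc == 4
        assert row.ppv == pytest.approx(0.8)

    def test_zero_positive_gene_is_excluded_with_undefined_ppv(self):
        pos = sparse.csr_matrix(np.zeros((1, 4), dtype=bool))
        out = gc_ppv(pos, ["g"], np.ones(4, bool), np.zeros(4, bool), min_pos=1)
        assert not out.iloc[0].included and np.isnan(out.iloc[0].ppv)

    def test_no_tfh_raises(self):
        pos = sparse.csr_matrix(np.ones((1, 4), dtype=bool))
        with pytest.raises(ValidationError, match="Tfh"):
            gc_ppv(pos, ["g"], np.zeros(4, bool), np.zeros(4, bool))

    def test_ppv_matches_set_intersection_oracle(self):
        rng = np.random.default_rng(1)
        pos = sparse.csr_matrix(rng.random((30, 200)) < 0.3)
        tfh = rng.random(200) < 0.5
        in_gc = rng.random(200) < 0.4
        out = gc_ppv(pos, [f"g{i}" for i in range(30)], tfh, in_gc, min_pos=1)
        P = pos.toarray()
        for gi in range(30):
            positives = {c for c in range(200) if P[gi, c] and tfh[c]}
            inside = {c for c in positives if in_gc[c]}
            if positives:
                assert out.iloc[gi].ppv == pytest.approx(len(inside) / len(positives))


class TestRankPercentile:
    def _rows(self, ppvs, min_pos_included=True):
        n = len(ppvs)
        return pd.DataFrame({
            "gene": [f"g{i:05d}" for i in range(n)],
            "n_pos_tfh": np.full(n, 100),
            "n_pos_tfh_in_gc": (np.asarray(ppvs) * 100).astype(int),
            "ppv": ppvs,
            "included": np.full(n, min_pos_included),
        })

    def test_rank_25_of_5101_gives_99_point_5(self):
        ppvs = np.linspace(1.0, 0.0, 5101)
        out = rank_percentile(self._rows(ppvs))
        assert out.loc[out["rank"] == 25, "percentile"].iloc[0] == 99.5

    def test_rank_one_gives_100_and_last_rank_formula(self):
        ppvs = np.linspace(0.9, 0.1, 5101)
        out = rank_percentile(self._rows(ppvs))
        assert out.loc[out["rank"] == 1, "percentile"].iloc[0] == 100.0
        last = out.loc[out["rank"] == 5101, "percentile"].iloc[0]
        assert last == pytest.approx(round(100 * (1 - 5100 / 5101), 1))

    def test_percentile_strictly_decreasing_and_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(2)
        ppvs = rng.random(50)
        out = rank_percentile(self._rows(ppvs))
        inc = out[out.included].sort_values("rank")
        assert (np.diff(inc.percentile) < 0).all()
        transformed = rank_percentile(self._rows(np.sqrt(ppvs)))
        assert list(transformed.gene) == list(out.gene)

    def test_ties_break_by_n_pos_then_name(self):
        rows = pd.DataFrame({
            "gene": ["b", "a", "c"],
            "n_pos_tfh": [50, 90, 90],
            "n_pos_tfh_in_gc": [25, 45, 45],
            "ppv": [0.5, 0.5, 0.5],
            "included": [True, True, True],
        })
        out = rank_percentile(rows).sort_values("rank")
        assert list(out.gene) == ["a", "c", "b"]


class TestWilcoxon:
    def test_textbook_separated_groups_exact_p(self):
        X = np.array([[1, 2, 3, 4, 5, 6]], float)
        res = wilcoxon_contrast(
            X, ["g"], np.arange(3), np.arange(3, 6), normalize=False
        )
        assert res.table.p_value.iloc[0] == pytest.approx(0.1, abs=1e-12)
        assert exact_ranksum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_constant_groups_give_p_one_and_zero_lfc(self):
        X = np.full((1, 10), 7.0)
        res = wilcoxon_contrast(X, ["g"], np.arange(5), np.arange(5, 10), normalize=False)
        assert res.table.p_value.iloc[0] == 1.0
        assert res.table.log2fc.iloc[0] == 0.0

    def test_asymptotic_p_close_to_exact_for_moderate_groups(self):
        rng = np.random.default_rng(3)
        worst = 0.0
        for _ in range(60):
            n1, n2 = rng.integers(3, 9, size=2)
            x = rng.normal(size=n1)
            y = rng.normal(rng.uniform(-1, 1), size=n2)
            X = np.concatenate([x, y])[None, :]
            res = wilcoxon_contrast(
                X, ["g"], np.arange(n1), np.arange(n1, n1 + n2), normalize=False
            )
            worst = max(worst, abs(res.table.p_value.iloc[0] - exact_ranksum_p(x, y)))
        assert worst <= 0.02

    def test_antisymmetry_of_log2fc_and_p(self):
        rng = np.random.default_rng(4)
        X = rng.poisson(2.0, size=(5, 40)).astype(float)
        g1, g2 = np.arange(20), np.arange(20, 40)
        a = wilcoxon_contrast(X, list("abcde"), g1, g2, normalize=False)
        b = wilcoxon_contrast(X, list("abcde"), g2, g1, normalize=False)
        np.testing.assert_allclose(a.table.log2fc, -b.table.log2fc, atol=1e-9)
        np.testing.assert_allclose(a.table.p_value, b.table.p_value, atol=1e-12)

    def test_group_errors(self):
        X = np.ones((1, 10))
        with pytest.raises(ValidationError, match="overlap"):
            wilcoxon_contrast(X, ["g"], np.arange(5), np.arange(4, 10))
        with pytest.raises(ParameterError, match="at least 3"):
            wilcoxon_contrast(X, ["g"], np.arange(2), np.arange(5, 10))

    def test_bonferroni_dominates_raw_p(self):
        rng = np.random.default_rng(5)
        X = rng.poisson(1.0, size=(30, 60)).astype(float)
        res = wilcoxon_contrast(X, [f"g{i}" for i in range(30)],
                                np.arange(30), np.arange(30, 60), normalize=False)
        assert (res.table.p_adj >= res.table.p_value - 1e-15).all()
        assert (res.table.p_adj <= 1.0).all()


class TestDistance:
    def test_three_four_five_triangle_and_self_distance(self):
        cells = make_cell_table([[0, 0], [3, 4]], ["Tfh", "LZ_GCB"])
        d = distance_to_nearest(cells, np.array([False, True]))
        assert d.iloc[0] == pytest.approx(5.0)
        assert d.iloc[1] == 0.0

    def test_matches_bruteforce_pairwise_minimum(self):
        rng = np.random.default_rng(6)
        xy = rng.uniform(0, 800, size=(400, 2))
        targets = rng.random(400) < 0.1
        cells = make_cell_table(xy, np.where(targets, "LZ_GCB", "Tfh"))
        d = distance_to_nearest(cells, targets).to_numpy()
        D = np.hypot(xy[:, 0][:, None] - xy[targets][:, 0][None, :],
                     xy[:, 1][:, None] - xy[targets][:, 1][None, :])
        np.testing.assert_allclose(d, D.min(axis=1), atol=1e-9)

    def test_sample_without_targets_is_flagged_nan(self):
        cells = make_cell_table(
            [[0, 0], [1, 1], [2, 2], [3, 3]], ["LZ_GCB", "Tfh", "Tfh", "Tfh"],
            samples=["S1", "S1", "S2", "S2"],
        )
        with pytest.warns(UserWarning, match="S2"):
            d = distance_to_nearest(cells, cells.type_l1 == "LZ_GCB")
        assert np.isfinite(d.iloc[:2]).all() and d.iloc[2:].isna().all()


class TestDecay:
    def test_constant_expression_gives_flat_curve(self):
        rng = np.random.default_rng(7)
        d = rng.uniform(0, 300, 500)
        curve = smoothed_decay(np.full(500, 3.5), d, bandwidth=25)
        ok = np.isfinite(curve.values)
        np.testing.assert_allclose(curve.values[ok], 3.5, atol=1e-9)

    def test_huge_bandwidth_returns_global_mean(self):
        rng = np.random.default_rng(8)
        d = rng.uniform(0, 300, 400)
        e = rng.normal(2.0, 1.0, 400)
        curve = smoothed_decay(e, d, bandwidth=1e9)
        np.testing.assert_allclose(curve.values, e.mean(), rtol=1e-6)

    def test_exponential_decay_length_recovered(self):
        rng = np.random.default_rng(9)
        d = rng.uniform(0, 300, 3000)
        expr = 5.0 * np.exp(-d / 50.0) + rng.normal(0, 0.25, 3000)
        curve = smoothed_decay(expr, d, bandwidth=25)
        use = (curve.grid >= 25) & (curve.grid <= 200) & (curve.values > 0.05)
        slope = np.polyfit(curve.grid[use], np.log(curve.values[use]), 1)[0]
        d0 = -1.0 / slope
        assert abs(d0 - 50.0) / 50.0 < 0.20

    def test_empty_input_and_bad_grid_raise(self):
        with pytest.raises(ValidationError):
            smoothed_decay(np.array([]), np.array([]), bandwidth=25)
        with pytest.raises(ParameterError, match="grid"):
            smoothed_decay(np.ones(3), np.ones(3), bandwidth=25, grid=np.array([1.0, 1.0]))
        with pytest.raises(ParameterError, match="bandwidth"):
            smoothed_decay(np.ones(3), np.ones(3), bandwidth=0)
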