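import itertools
import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from dgescreen.core import ContrastSpec
from dgescreen.errors import IntegrityError, SchemaError
from dgescreen.stats import (
    adjust_p,
    contrast_stats,
    expressing_fraction,
    log_cpm,
    mean_expression,
    rank_sum_p,
)

from conftest import make_dataset


def permutation_oracle(t, c):
    """Brute-force two-sided rank-sum p over all n! pooled permutations.

    Independent of the implementation's combination enumeration; only
    feasible for total sizes <= 8.
    """
    pooled = np.concatenate([t, c])
    n, nt = pooled.size, len(t)
    ranks = scipy.stats.rankdata(pooled)
    expected = nt * (n + 1) / 2.0
    observed = abs(ranks[:nt].sum() - expected)
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        w = sum(ranks[i] for i in perm[:nt])
        hits += abs(w - expected) >= observed - 1e-9
        total += 1
    return hits / total


class TestLogCpm:
    @pytest.mark.parametrize("x, expected", [(0, 0.0), (1, 1.0), (3, 2.0)])
    def test_stated_values(self, x, expected):
        assert log_cpm(x) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(IntegrityError):
            log_cpm(-0.5)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1e6), min_size=2, max_size=20))
    def test_monotone(self, xs):
        xs = sorted(xs)
        ys = log_cpm(xs)
        assert np.all(np.diff(ys) >= 0)


class TestMeanExpression:
    def test_all_zero(self, tiny_ds):
        ds = make_dataset(
            [("c1", "A", "s", "GABAergic"), ("c2", "A", "s", "GABAergic"),
             ("c3", "A", "s", "GABAergic")],
            ["g"], [[0.0], [0.0], [0.0]],
        )
        assert mean_expression(ds, "g", ["c1", "c2", "c3"]) == 0.0

    def test_cpm_one_and_three(self):
        ds = make_dataset(
            [("c1", "A", "s", "GABAergic"), ("c2", "A", "s", "GABAergic")],
            ["g"], [[1.0], [3.0]],
        )
        assert mean_expression(ds, "g", ["c1", "c2"]) == pytest.approx(1.5)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(42)
        cpm = rng.gamma(2.0, 50.0, size=17)
        records = [(f"c{i}", "A", "s", "GABAergic") for i in range(17)]
        ds = make_dataset(records, ["g"], cpm[:, None])
        expected = float(np.mean(np.log2(1 + cpm)))  # independent recomputation
        assert mean_expression(ds, "g", [f"c{i}" for i in range(17)]) == pytest.approx(expected)

    def test_empty_cells_error(self, tiny_ds):
        with pytest.raises(IntegrityError):
            mean_expression(tiny_ds, "gA", [])


class TestRankSumP:
    def test_complete_ties_give_one(self):
        assert rank_sum_p([5, 5, 5], [5, 5, 5]) == 1.0

    def test_fully_separated_three_vs_three(self):
        # 20 equally likely 3-of-6 rank assignments; both separated tails -> 2/20
        assert rank_sum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_empty_group_errors(self):
        with pytest.raises(IntegrityError):
            rank_sum_p([], [1.0])

    @pytest.mark.parametrize("nt,nc", [(2, 3), (3, 3), (3, 4), (4, 4), (2, 6), (5, 3)])
    def test_matches_permutation_oracle_with_ties(self, nt, nc):
        rng = np.random.default_rng(nt * 100 + nc)
        for _ in range(5):
            t = rng.integers(0, 3, nt).astype(float)
            c = rng.integers(0, 3, nc).astype(float)
            if np.min(np.concatenate([t, c])) == np.max(np.concatenate([t, c])):
                continue
            assert rank_sum_p(t, c) == pytest.approx(permutation_oracle(t, c))

    @pytest.mark.parametrize("nt,nc", [(2, 3), (4, 4), (3, 5), (5, 5), (1, 7)])
    def test_matches_scipy_exact_without_ties(self, nt, nc):
        rng = np.random.default_rng(nt * 10 + nc)
        for _ in range(5):
            t = rng.normal(size=nt)
            c = rng.normal(size=nc)
            ref = scipy.stats.mannwhitneyu(t, c, alternative="two-sided", method="exact")
            assert rank_sum_p(t, c) == pytest.approx(ref.pvalue)

    @pytest.mark.parametrize("nt,nc", [(3, 12), (5, 14)])
    def test_matches_scipy_enumerated_null_with_ties(self, nt, nc):
        # independent exact route for tied data beyond the n! oracle's reach:
        # scipy enumerates the exact permutation null of the rank sum, and the
        # two-sided rule (deviation from the null mean, matching the normal
        # approximation) is applied to that distribution here
        def rank_sum_statistic(x, y, axis):
            pooled = np.concatenate([x, y], axis=axis)
            ranks = scipy.stats.rankdata(pooled, axis=axis)
            return np.take(ranks, np.arange(x.shape[axis]), axis=axis).sum(axis=axis)

        rng = np.random.default_rng(nt + nc)
        t = rng.integers(0, 4, nt).astype(float)
        c = rng.integers(0, 4, nc).astype(float)
        ref = scipy.stats.permutation_test(
            (t, c), rank_sum_statistic, permutation_type="independent",
            n_resamples=np.inf, alternative="greater", vectorized=True,
        )
        null = np.asarray(ref.null_distribution)
        n = nt + nc
        expected = nt * (n + 1) / 2.0
        observed = abs(float(ref.statistic) - expected)
        p_ref = float(np.mean(np.abs(null - expected) >= observed - 1e-9))
        assert rank_sum_p(t, c) == pytest.approx(p_ref)

    def test_asymptotic_agrees_with_monte_carlo_at_30v30(self):
        rng = np.random.default_rng(7)
        t = np.round(rng.normal(0.6, 1.0, 30), 1)  # rounding induces ties
        c = np.round(rng.normal(0.0, 1.0, 30), 1)
        p = rank_sum_p(t, c)
        pooled = np.concatenate([t, c])
        ranks = scipy.stats.rankdata(pooled)
        expected = 30 * 61 / 2.0
        observed = abs(ranks[:30].sum() - expected)
        hits = 0
        batches, batch = 8, 50_000
        for b in range(batches):
            brng = np.random.default_rng(1000 + b)
            idx = np.argsort(brng.random((batch, 60)), axis=1)[:, :30]
            sums = ranks[idx].sum(axis=1)
            hits += int(np.sum(np.abs(sums - expected) >= observed - 1e-9))
        p_mc = hits / (batches * batch)
        # MC standard error ~5e-4 at p~0.1; allow approximation + MC noise
        assert p == pytest.approx(p_mc, abs=2e-3)

    @settings(max_examples=40, deadline=None)
    @given(
        t=st.lists(st.integers(min_value=-50, max_value=50), min_size=2, max_size=5),
        c=st.lists(st.integers(min_value=-50, max_value=50), min_size=2, max_size=5),
    )
    def test_invariant_under_monotone_transform(self, t, c):
        t = [float(x) for x in t]
        c = [float(x) for x in c]
        p0 = rank_sum_p(t, c)
        f = lambda xs: [3.0 * x + 7.0 for x in xs]
        g = lambda xs: [math.atan(x) for x in xs]
        assert rank_sum_p(f(t), f(c)) == pytest.approx(p0)
        assert rank_sum_p(g(t), g(c)) == pytest.approx(p0)
        assert 0.0 <= p0 <= 1.0


class TestAdjustP:
    def test_bonferroni_simple(self):
        assert adjust_p([0.01], "bonferroni", 10)[0] == pytest.approx(0.1)

    def test_bonferroni_capped(self):
        assert adjust_p([0.5], "bonferroni", 10)[0] == 1.0

    def test_bh_hand_worked(self):
        # step-up by hand: 0.01*3/1=0.03, 0.02*3/2=0.03, 0.04*3/3=0.04
        np.testing.assert_allclose(
            adjust_p([0.01, 0.02, 0.04], "bh", 3), [0.03, 0.03, 0.04]
        )

    def test_bh_matches_statsmodels_when_m_equals_n(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(11)
        p = rng.random(200)
        ours = adjust_p(p, "bh")
        ref = statsmodels.multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, ref)

    def test_bonferroni_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(12)
        p = rng.random(50)
        np.testing.assert_allclose(
            adjust_p(p, "bonferroni"),
            statsmodels.multipletests(p, method="bonferroni")[1],
        )

    def test_m_smaller_than_list_errors(self):
        with pytest.raises(SchemaError):
            adjust_p([0.1, 0.2], "bh", 1)

    def test_out_of_range_p_errors(self):
        with pytest.raises(IntegrityError):
            adjust_p([1.5], "bonferroni", 2)

    @settings(max_examples=50, deadline=None)
    @given(
        p=st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30),
        extra=st.integers(min_value=0, max_value=100),
    )
    def test_bh_below_bonferroni_and_above_raw(self, p, extra):
        m = len(p) + extra
        bh = adjust_p(p, "bh", m)
        bonf = adjust_p(p, "bonferroni", m)
        assert np.all(bh <= bonf + 1e-12)
        assert np.all(bh >= np.asarray(p) - 1e-12)
        assert np.all((bh >= 0) & (bh <= 1))


class TestExpressingFraction:
    def test_half_expressing(self):
        records = [(f"c{i}", "A", "s", "GABAergic") for i in range(4)]
        ds = make_dataset(records, ["g"], [[0.0], [0.0], [4.0], [7.0]])
        assert expressing_fraction(ds, "g", [f"c{i}" for i in range(4)]) == 0.5

    def test_all_zero(self):
        records = [(f"c{i}", "A", "s", "GABAergic") for i in range(3)]
        ds = make_dataset(records, ["g"], [[0.0]] * 3)
        assert expressing_fraction(ds, "g", [f"c{i}" for i in range(3)]) == 0.0

    def test_threshold_matches_brute_count(self):
        rng = np.random.default_rng(5)
        cpm = rng.gamma(1.0, 2.0, 25)
        records = [(f"c{i}", "A", "s", "GABAergic") for i in range(25)]
        ds = make_dataset(records, ["g"], cpm[:, None])
        cells = [f"c{i}" for i in range(25)]
        brute = sum(1 for v in cpm if v > 1.0) / 25  # direct count oracle
        assert expressing_fraction(ds, "g", cells, expr_threshold=1.0) == pytest.approx(brute)


class TestContrastStats:
    @pytest.fixture
    def paired_ds(self):
        rng = np.random.default_rng(21)
        n = 30
        records = [(f"t{i}", "A", "T", "GABAergic") for i in range(n)] + [
            (f"k{i}", "A", "K", "GABAergic") for i in range(n)
        ]
        cpm = np.column_stack(
            [
                np.zeros(2 * n),                             # constant zero
                np.concatenate([rng.gamma(3, 40, n), rng.gamma(3, 5, n)]),  # shifted
                rng.gamma(2, 10, 2 * n),                     # null gene
            ]
        )
        return make_dataset(records, ["g_const", "g_up", "g_null"], cpm)

    def _contrast(self, ds):
        t = [c for c in ds.cell_ids if c.startswith("t")]
        k = [c for c in ds.cell_ids if c.startswith("k")]
        return ContrastSpec("TvK", tuple(t), tuple(k))

    def test_constant_gene(self, paired_ds):
        table = contrast_stats(paired_ds, self._contrast(paired_ds), ["g_const"])
        row = table.iloc[0]
        assert row.diff_mean == 0.0
        assert row.p_raw == 1.0
        assert row.beta == 0.0

    def test_antisymmetric_under_swap(self, paired_ds):
        con = self._contrast(paired_ds)
        rev = ContrastSpec("KvT", con.contrast_cells, con.target_cells)
        genes = ["g_const", "g_up", "g_null"]
        fwd = contrast_stats(paired_ds, con, genes)
        bwd = contrast_stats(paired_ds, rev, genes)
        np.testing.assert_allclose(fwd.diff_mean, -bwd.diff_mean)
        np.testing.assert_allclose(fwd.p_raw, bwd.p_raw)
        np.testing.assert_allclose(fwd.beta, -bwd.beta)

    def test_invariant_under_cell_permutation(self, paired_ds):
        con = self._contrast(paired_ds)
        rng = np.random.default_rng(0)
        shuffled = ContrastSpec(
            "TvK",
            tuple(rng.permutation(con.target_cells)),
            tuple(rng.permutation(con.contrast_cells)),
        )
        genes = ["g_up", "g_null"]
        a = contrast_stats(paired_ds, con, genes)
        b = contrast_stats(paired_ds, shuffled, genes)
        np.testing.assert_allclose(a.drop(columns="gene"), b.drop(columns="gene"))

    def test_planted_effect_recovered_within_sampling_error(self):
        # 3-fold planted gene at n=100/side; repeated seeds bound the error
        from dgescreen.simulate import PlantedEffect, SimConfig, simulate_dataset
        from dgescreen.simulate import population_mean, _cell_table

        effect = float(np.log2(3.0))
        diffs = []
        for seed in range(5):
            cfg = SimConfig(
                n_regions=1,
                subclasses=(("T", "GABAergic"), ("K", "GABAergic")),
                cells_per_type_per_region=100,
                n_genes=5,
                expressing_prob_baseline=1.0,
                planted=(PlantedEffect("g00000", "relative_selective", "T",
                                       log2_effect=effect),),
                seed=seed,
            )
            ds, _ = simulate_dataset(cfg)
            t = [c for c in ds.cell_ids if "_T_" in c]
            k = [c for c in ds.cell_ids if "_K_" in c]
            table = contrast_stats(ds, ContrastSpec("TvK", tuple(t), tuple(k)), ["g00000"])
            diffs.append(float(table.diff_mean.iloc[0]))
        # population diff from the generative model (quadrature expectation)
        meta = _cell_table(cfg)
        mask_t = (meta["subclass_label"] == "T").to_numpy()
        pop = population_mean(cfg, meta, "g00000", mask_t) - population_mean(
            cfg, meta, "g00000", ~mask_t
        )
        assert np.mean(diffs) == pytest.approx(pop, abs=0.15)

    def test_worked_fold_example(self):
        # GE 7.8 vs 5.4 -> diff 2.4, clears the 3-fold log2 cutoff 1.585
        diff = 7.8 - 5.4
        assert diff == pytest.approx(2.4)
        assert diff > np.log2(3.0)

    def test_empty_gene_list_errors(self, paired_ds):
        with pytest.raises(SchemaError):
            contrast_stats(paired_ds, self._contrast(paired_ds), [])

    def test_output_sorted_by_gene(self, paired_ds):
        table = contrast_stats(
            paired_ds, self._contrast(paired_ds), ["g_up", "g_const", "g_null"]
        )
        assert list(table.gene) == sorted(table.gene)

    def test_p_adj_uses_dataset_multiplicity_by_default(self, paired_ds):
        table = contrast_stats(paired_ds, self._contrast(paired_ds), ["g_null"])
        row = table.iloc[0]
        assert row.p_adj == pytest.approx(min(1.0, row.p_raw * paired_ds.n_genes))
        catalog_only = contrast_stats(paired_ds, self._contrast(paired_ds), ["g_null"], m=1)
        assert catalog_only.iloc[0].p_adj == pytest.approx(row.p_raw)

    def test_p_adj_never_below_p_raw(self, paired_ds):
        for method in ("bonferroni", "bh"):
            table = contrast_stats(
                paired_ds, self._contrast(paired_ds),
                ["g_const", "g_up", "g_null"], correction=method,
            )
            assert np.all(table.p_adj >= table.p_raw - 1e-12)
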