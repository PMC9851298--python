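"""Cell-specific networks and the Monte-Carlo empirical null."""

import numpy as np
import pytest

import deltarank as dr
from deltarank.csn import _pair_indices
from deltarank.errors import DegenerateInputError, ValidationError


class TestEmpiricalNull:
    def test_two_gene_tie_free_support(self):
        null = dr.empirical_null(np.array([1.0, 2.0]), n_shuffles=500, seed=0)
        assert set(np.unique(null.samples)) == {-1.0, 1.0}

    def test_all_tied_ranks_give_zero_samples(self):
        null = dr.empirical_null(np.full(6, 3.5), n_shuffles=100, seed=0)
        assert np.all(null.samples == 0)

    def test_fixed_seed_reproducible(self):
        r = np.arange(1.0, 21.0)
        a = dr.empirical_null(r, n_shuffles=1000, seed=42)
        b = dr.empirical_null(r, n_shuffles=1000, seed=42)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_m_below_two_degenerate(self):
        with pytest.raises(DegenerateInputError):
            dr.empirical_null(np.array([1.0]), 100)

    def test_pair_sampler_is_uniform_over_distinct_ordered_pairs(self):
        rng = np.random.default_rng(0)
        a, b = _pair_indices(4, 120_000, rng)
        assert np.all(a != b)
        counts = np.bincount(a * 4 + b, minlength=16).reshape(4, 4)
        off_diag = counts[~np.eye(4, dtype=bool)]
        assert np.all(np.diag(counts) == 0)
        # each of the 12 ordered pairs should appear ~10000 times
        assert off_diag.min() > 9000 and off_diag.max() < 11000


class TestAnalyticNullPmf:
    def test_m3_enumeration(self):
        pmf = dr.analytic_null_pmf(3)
        assert pmf[1] == pmf[-1] == pytest.approx(1 / 3)
        assert pmf[2] == pmf[-2] == pytest.approx(1 / 6)

    def test_m2(self):
        assert dr.analytic_null_pmf(2) == {-1: 0.5, 1: 0.5}

    @pytest.mark.parametrize("m", [2, 5, 17, 50])
    def test_normalization(self, m):
        assert sum(dr.analytic_null_pmf(m).values()) == pytest.approx(1.0)

    def test_empirical_null_is_unbiased_for_the_analytic_pmf(self):
        """Chi-square goodness of fit of 10,000 draws from a tie-free m=50
        rank vector against the closed-form pmf (97 degrees of freedom)."""
        from scipy.stats import chisquare

        m = 50
        ranks = np.arange(1.0, m + 1)
        null = dr.empirical_null(ranks, n_shuffles=10_000, seed=3)
        pmf = dr.analytic_null_pmf(m)
        support = sorted(pmf)
        counts = {d: 0 for d in support}
        vals, cnts = np.unique(null.samples.astype(int), return_counts=True)
        for v, c in zip(vals, cnts):
            counts[int(v)] = c
        observed = np.array([counts[d] for d in support], dtype=float)
        expected = np.array([pmf[d] * null.n for d in support])
        p = chisquare(observed, expected).pvalue
        assert p > 1e-3


class TestEmpiricalPvalue:
    def test_add_one_rule_extremes(self):
        null = dr.NullDistribution(samples=np.arange(-5000.0, 5000.0), n=10_000)
        assert dr.empirical_pvalue(1e9, null) == pytest.approx(1 / 10_001)
        assert dr.empirical_pvalue(0.0, null) == 1.0

    def test_direct_count(self):
        null = dr.NullDistribution(
            samples=np.array([-9, -8, -7, -6, -5, 1, 2, 3, 4, 4.0]), n=10
        )
        # exactly half the samples are at least as extreme as 5
        assert dr.empirical_pvalue(5.0, null) == pytest.approx(6 / 11)


class TestCellSpecificNetwork:
    def test_all_tied_cell_yields_empty_network(self):
        net = dr.BackgroundNetwork([("g0", "g1"), ("g2", "g3")])
        csn = dr.cell_specific_network(
            np.full(4, 2.5), net, ["g0", "g1", "g2", "g3"], n_shuffles=200, seed=0
        )
        assert len(csn) == 0

    def test_extreme_edge_retained(self):
        m = 100
        ranks = np.arange(1.0, m + 1)
        gene_ids = [f"g{i}" for i in range(m)]
        net = dr.BackgroundNetwork([(f"g{m-1}", "g0"), ("g49", "g50")])
        csn = dr.cell_specific_network(
            ranks, net, gene_ids, n_shuffles=10_000, seed=1
        )
        kept = {dr.edge_label(e) for e, _, _ in csn.significant_edges}
        assert f"g{m-1}|g0" in kept
        assert "g49|g50" not in kept

    def test_alpha_zero_empty(self):
        ranks = np.arange(1.0, 11.0)
        net = dr.BackgroundNetwork([("g9", "g0")])
        csn = dr.cell_specific_network(
            ranks, net, [f"g{i}" for i in range(10)], n_shuffles=100, alpha=0.0, seed=0
        )
        assert len(csn) == 0

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(5)
        ranks = rng.permutation(np.arange(1.0, 51.0))
        gene_ids = [f"g{i}" for i in range(50)]
        net = dr.BackgroundNetwork([("g0", "g10"), ("g5", "g40"), ("g49", "g2")])
        a = dr.cell_specific_network(ranks, net, gene_ids, 2000, seed=9)
        b = dr.cell_specific_network(ranks, net, gene_ids, 2000, seed=9)
        assert a.significant_edges == b.significant_edges

    def test_null_calibration_five_percent_of_random_edges(self):
        """For a random-permutation cell, ~5% of 1,000 random edges are
        called significant at alpha = 0.05."""
        rng = np.random.default_rng(7)
        m = 300
        ranks = rng.permutation(np.arange(1.0, m + 1))
        gene_ids = [f"g{i}" for i in range(m)]
        edges = []
        seen = set()
        while len(edges) < 1000:
            i, j = rng.integers(0, m, 2)
            if i == j or frozenset((i, j)) in seen:
                continue
            seen.add(frozenset((i, j)))
            edges.append((f"g{i}", f"g{j}"))
        net = dr.BackgroundNetwork(edges)
        csn = dr.cell_specific_network(
            ranks, net, gene_ids, n_shuffles=10_000, alpha=0.05, seed=2
        )
        assert 0.03 <= len(csn) / 1000 <= 0.07


class TestCellTypeNetwork:
    def test_single_cell_type_is_its_own_column(self, drm_default, sim_default):
        labels = np.array(["solo"] + ["rest"] * (drm_default.n_cells - 1))
        table = dr.cell_type_network(drm_default, labels, "solo")
        np.testing.assert_array_equal(table.mean_delta.values, drm_default.raw[:, 0])

    def test_opposite_deltas_average_to_zero(self):
        drm = dr.DeltaRankMatrix(
            raw=np.array([[3.0, -3.0]]),
            edge_ids=[("a", "b")],
            cell_ids=["c1", "c2"],
        )
        table = dr.cell_type_network(drm, ["t", "t"], "t")
        assert table.mean_delta.iloc[0] == 0

    def test_unknown_type_rejected(self, drm_default, sim_default):
        with pytest.raises(ValidationError):
            dr.cell_type_network(drm_default, sim_default.labels, "no-such-type")


class TestCommonPattern:
    def _csn(self, cell_id, edges):
        return dr.CellSpecificNetwork(
            cell_id=cell_id,
            significant_edges=[(e, 1.0, 0.01) for e in edges],
            alpha=0.05,
        )

    def test_occurrence_fractions(self):
        net = dr.BackgroundNetwork([("N", "A"), ("N", "B"), ("X", "Y")])
        csns = [
            self._csn("c1", [("N", "A")]),
            self._csn("c2", [("N", "A")]),
            self._csn("c3", [("N", "A"), ("N", "B")]),
            self._csn("c4", []),
        ]
        table = dr.common_pattern(csns, net, "N")
        by_edge = dict(zip(table.edge_id, table.fraction))
        assert by_edge == {"N|A": 0.75, "N|B": 0.25}

    def test_invariant_to_input_order(self):
        net = dr.BackgroundNetwork([("N", "A"), ("N", "B")])
        csns = [self._csn(f"c{i}", [("N", "A")] if i % 2 else []) for i in range(6)]
        fwd = dr.common_pattern(csns, net, "N").fraction.tolist()
        rev = dr.common_pattern(csns[::-1], net, "N").fraction.tolist()
        assert fwd == rev

    def test_gene_absent_from_network_rejected(self):
        net = dr.BackgroundNetwork([("A", "B")])
        with pytest.raises(ValidationError):
            dr.common_pattern([self._csn("c", [])], net, "Z")
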