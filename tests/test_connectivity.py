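"""Core statistic: shared genes, expansion, counting, expectation, null."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crossnet import (
    GeneSet,
    Interactome,
    NullConfig,
    connectivity_test,
    count_inter_edges,
    expand_with_interactors,
    expected_analytic,
    permutation_null,
    shared_nodes,
)
from crossnet.errors import EmptySetError, ParameterError

from conftest import brute_force_cross_count, exhaustive_cross_mean


def gene_set(*symbols: str) -> GeneSet:
    return GeneSet.from_symbols("s", symbols)


class TestSharedNodes:
    def test_pathway_gwas_overlap(self, coag_like_sets):
        """The two networks share exactly their common genes (CD40, PLAU)."""
        a, b = coag_like_sets
        assert shared_nodes(a, b) == {"CD40", "PLAU"}

    def test_disjoint_and_identity(self):
        assert shared_nodes(gene_set("A"), gene_set("B")) == set()
        a = gene_set("A", "B")
        assert shared_nodes(a, a) == {"A", "B"}


class TestExpansion:
    def test_first_neighbors_on_path(self, path4):
        e = expand_with_interactors(path4, gene_set("C"), depth=1)
        assert e.members == {"B", "C", "D"}

    def test_depth_zero_is_identity(self, path4):
        e = expand_with_interactors(path4, gene_set("C"), depth=0)
        assert e.members == {"C"}

    def test_off_graph_bookkeeping(self, path4):
        e = expand_with_interactors(path4, gene_set("C", "X"), depth=1)
        assert e.members == {"B", "C", "D"}
        assert e.off_graph == {"X"}

    def test_negative_depth_rejected(self, path4):
        with pytest.raises(ParameterError):
            expand_with_interactors(path4, gene_set("C"), depth=-1)

    def test_deep_expansion_saturates_at_component(self, path4):
        e = expand_with_interactors(path4, gene_set("A"), depth=10)
        assert e.members == {"A", "B", "C", "D"}


class TestCounting:
    def test_path_example(self, path4):
        ea = expand_with_interactors(path4, gene_set("A", "B"), depth=0)
        eb = expand_with_interactors(path4, gene_set("B", "C", "D"), depth=0)
        assert count_inter_edges(path4, ea, eb) == 2  # A-B and B-C, not C-D

    def test_full_overlap_counts_each_edge_once(self, triangle):
        e = expand_with_interactors(triangle, gene_set("X", "Y", "Z"), depth=0)
        assert count_inter_edges(triangle, e, e) == 3

    def test_empty_side_counts_zero(self, path4):
        ea = expand_with_interactors(path4, gene_set("A"), depth=0)
        eb = expand_with_interactors(path4, gene_set("Q"), depth=0)
        assert count_inter_edges(path4, ea, eb) == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_on_random_graphs(self, data):
        """Vectorized counting equals naive edge iteration, and is symmetric."""
        n = data.draw(st.integers(4, 10))
        nodes = [f"N{i}" for i in range(n)]
        edges = data.draw(
            st.lists(
                st.tuples(st.sampled_from(nodes), st.sampled_from(nodes)),
                min_size=1, max_size=25,
            ).filter(lambda es: any(u != v for u, v in es))
        )
        g = Interactome.from_edges(edges, nodes=nodes)
        sa = data.draw(st.sets(st.sampled_from(nodes), max_size=n))
        sb = data.draw(st.sets(st.sampled_from(nodes), max_size=n))
        ea = expand_with_interactors(g, GeneSet.from_symbols("a", sa), 0)
        eb = expand_with_interactors(g, GeneSet.from_symbols("b", sb), 0)
        got = count_inter_edges(g, ea, eb)
        assert got == brute_force_cross_count(g, ea.members, eb.members)
        assert got == count_inter_edges(g, eb, ea)


class TestExpectedAnalytic:
    def test_path_graph_closed_form(self, path4):
        assert expected_analytic(path4, 2, 2) == pytest.approx(
            3 * (0.5 - 1 / 36), rel=1e-12
        )

    def test_boundaries(self, path4):
        assert expected_analytic(path4, 0, 2) == 0.0
        assert expected_analytic(path4, 4, 4) == path4.n_edges

    def test_out_of_range(self, path4):
        with pytest.raises(ParameterError):
            expected_analytic(path4, 5, 2)

    def test_matches_exhaustive_enumeration(self, path4, triangle):
        for g, a, b in [(path4, 2, 2), (path4, 1, 3), (triangle, 2, 1)]:
            assert expected_analytic(g, a, b) == pytest.approx(
                exhaustive_cross_mean(g, a, b), rel=1e-12
            )


class TestPermutationNull:
    def test_determinism(self):
        g = Interactome.from_edges(
            [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("E", "F"),
             ("F", "A"), ("B", "E")]
        )
        a, b = gene_set("A", "B"), gene_set("D", "E")
        cfg = NullConfig(n_perm=99, sampler="uniform", seed=5)
        n1 = permutation_null(g, a, b, 1, cfg)
        n2 = permutation_null(g, a, b, 1, cfg)
        assert np.array_equal(n1.samples, n2.samples)
        n3 = permutation_null(g, a, b, 1, NullConfig(
            n_perm=99, sampler="uniform", seed=6))
        assert not np.array_equal(n1.samples, n3.samples)

    @pytest.mark.parametrize("sampler", ["uniform", "degree_matched"])
    def test_fixed_expanded_mean_converges_to_analytic(self, path4, sampler):
        """Monte-Carlo mean agrees with the closed form within 3 SE.

        Under uniform sampling the target is the independent-subsets
        expectation; degree matching is also exercised for determinism but
        only the uniform mean is compared to the closed form.
        """
        a, b = gene_set("A", "B"), gene_set("C", "D")
        cfg = NullConfig(
            scheme="fixed_expanded", sampler=sampler, n_perm=10000, seed=2
        )
        null = permutation_null(path4, a, b, 0, cfg)
        if sampler == "uniform":
            target = expected_analytic(path4, 2, 2)
            se = null.sd / np.sqrt(cfg.n_perm)
            assert abs(null.mean - target) <= 3 * se

    def test_degenerate_null_sd_zero(self):
        """On a complete graph every placement spans the same count."""
        k4 = Interactome.from_edges(
            [(a, b) for a in "ABCD" for b in "ABCD" if a < b]
        )
        a, b = gene_set("A", "B", "C", "D"), gene_set("A", "B", "C", "D")
        cfg = NullConfig(n_perm=99, sampler="uniform")
        null = permutation_null(k4, a, b, 0, cfg)
        assert null.sd == 0.0
        r = connectivity_test(k4, a, b, 0, cfg)
        assert not r.z_defined
        assert r.p_empirical == 1.0

    def test_config_validation(self):
        with pytest.raises(ParameterError):
            NullConfig(n_perm=10)
        with pytest.raises(ParameterError):
            NullConfig(scheme="bogus")
        with pytest.raises(ParameterError):
            NullConfig(degree_bin_base=1.0)


class TestConnectivityTest:
    def test_symmetry_in_the_two_sets(self):
        g = Interactome.from_edges(
            [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("E", "A"),
             ("B", "E"), ("C", "F"), ("F", "G")]
        )
        a = gene_set("A", "B", "F")
        b = gene_set("C", "F")
        for sampler in ("uniform", "degree_matched"):
            cfg = NullConfig(n_perm=199, sampler=sampler, seed=3)
            r1 = connectivity_test(g, a, b, 1, cfg)
            r2 = connectivity_test(g, b, a, 1, cfg)
            assert (r1.observed, r1.expected_null, r1.sd_null, r1.z,
                    r1.p_empirical) == (
                r2.observed, r2.expected_null, r2.sd_null, r2.z,
                r2.p_empirical)

    def test_self_comparison(self, path4):
        """A vs A: observed = edges inside the expanded set; shared = A."""
        a = gene_set("A", "B")
        r = connectivity_test(
            path4, a, a, 1, NullConfig(n_perm=99, sampler="uniform")
        )
        # expansion of {A,B} at depth 1 is {A,B,C}; edges within: A-B, B-C
        assert r.observed == 2
        assert r.shared_genes == ["A", "B"]

    def test_p_value_lower_bound(self, path4):
        a, b = gene_set("A", "B"), gene_set("C", "D")
        cfg = NullConfig(n_perm=99, sampler="uniform")
        r = connectivity_test(path4, a, b, 1, cfg)
        assert 1 / (cfg.n_perm + 1) <= r.p_empirical <= 1.0

    def test_off_graph_set_rejected(self, path4):
        with pytest.raises(EmptySetError):
            connectivity_test(
                path4, gene_set("Q", "R"), gene_set("A"), 1,
                NullConfig(n_perm=99),
            )

    def test_shared_gene_interactors_are_first_neighbors(self, path4):
        a, b = gene_set("A", "B"), gene_set("B", "D")
        r = connectivity_test(
            path4, a, b, 1, NullConfig(n_perm=99, sampler="uniform")
        )
        assert r.shared_genes == ["B"]
        assert r.shared_gene_interactors == {"B": ["A", "C"]}

    def test_added_cross_edge_increments_observed_and_z(self):
        """Planting one inter-set edge raises observed by 1 and never lowers
        z against the original null samples."""
        g = Interactome.from_edges(
            [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("E", "F")]
        )
        a, b = gene_set("A"), gene_set("E")
        cfg = NullConfig(n_perm=199, sampler="uniform", seed=11)
        ea = expand_with_interactors(g, a, 1)
        eb = expand_with_interactors(g, b, 1)
        before = count_inter_edges(g, ea, eb)
        null = permutation_null(g, a, b, 1, cfg)
        g2 = g.copy()
        g2.graph.add_edge("B", "D")  # B in expA, D in expB
        ea2 = expand_with_interactors(g2, a, 1)
        eb2 = expand_with_interactors(g2, b, 1)
        after = count_inter_edges(g2, ea2, eb2)
        assert after == before + 1
        z_before = (before - null.mean) / null.sd
        z_after = (after - null.mean) / null.sd
        assert z_after > z_before
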