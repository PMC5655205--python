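import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbncs.io_formats import ExpressionMatrix
from dbncs.scoring_assembly import (
    Clique,
    CSConfig,
    OrientedEdge,
    assemble,
    background_standardize,
    comprehensive_score,
    compute_components,
    decompose_cliques,
    orient_clique,
    standardize_components,
)
from dbncs.structure_learning import Skeleton
from dbncs.temporal import build_delay_matrix
from dbncs.io_formats import read_grn, write_network

from .conftest import ar1_series


class TestBackgroundStandardize:
    def test_min_max_mapping(self):
        np.testing.assert_allclose(
            background_standardize(np.array([0.0, 5.0, 10.0])), [0.0, 0.5, 1.0]
        )

    def test_all_equal_maps_to_half(self):
        np.testing.assert_allclose(
            background_standardize(np.array([3.0, 3.0, 3.0])), [0.5, 0.5, 0.5]
        )

    @given(
        st.lists(st.integers(-100, 100), min_size=2, max_size=10, unique=True),
        st.floats(0.5, 10),
        st.floats(-5, 5),
    )
    @settings(max_examples=30, deadline=None)
    def test_affine_invariance(self, vals, a, b):
        v = np.asarray(vals, dtype=float)
        np.testing.assert_allclose(
            background_standardize(a * v + b), background_standardize(v), atol=1e-9
        )


class TestComprehensiveScore:
    def test_sigma_one_ignores_trs(self):
        cfg = CSConfig(sigma=1.0, omega=0.5)
        assert comprehensive_score(0.8, 0.4, 0.9, cfg) == comprehensive_score(0.8, 0.4, 0.0, cfg)

    def test_unit_score_at_full_weights(self):
        assert comprehensive_score(1.0, 0.0, 0.0, CSConfig(sigma=1.0, omega=1.0)) == 1.0

    def test_worked_numeric_example(self):
        # 0.6*(0.5*0.8 + 0.5*0.4)^2 + 0.4*0.5^2 = 0.316
        val = comprehensive_score(0.8, 0.4, 0.5, CSConfig(sigma=0.6, omega=0.5))
        assert val == pytest.approx(0.316)

    def test_monotone_in_each_component(self):
        cfg = CSConfig(sigma=0.6, omega=0.5)
        base = comprehensive_score(0.4, 0.4, 0.4, cfg)
        assert comprehensive_score(0.6, 0.4, 0.4, cfg) >= base
        assert comprehensive_score(0.4, 0.6, 0.4, cfg) >= base
        assert comprehensive_score(0.4, 0.4, 0.6, cfg) >= base

    def test_out_of_range_config_rejected(self):
        with pytest.raises(ValueError):
            CSConfig(sigma=1.5)
        with pytest.raises(ValueError):
            CSConfig(omega=-0.1)


class TestDecomposeCliques:
    def test_one_clique_per_edge(self, rng):
        w = np.zeros((6, 6))
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)]:
            w[i, j] = w[j, i] = 1.0
        skel = Skeleton([f"G{i}" for i in range(6)], w, 0)
        cliques = decompose_cliques(skel)
        assert len(cliques) == 5
        assert {(c.i, c.j) for c in cliques} == set(skel.edges())

    def test_empty_skeleton_gives_no_cliques(self):
        skel = Skeleton(["A", "B"], np.zeros((2, 2)), 0)
        assert decompose_cliques(skel) == []


def _pair_setup(seed, shift=2, noise=0.1):
    r = np.random.default_rng(seed)
    x = ar1_series(r, 50)
    y = np.r_[np.zeros(shift), x[:-shift]] + noise * r.standard_normal(50)
    expr = ExpressionMatrix(["X", "Y"], np.vstack([x, y]))
    skel = Skeleton(["X", "Y"], np.array([[0, 1.0], [1.0, 0]]), 0)
    delays = build_delay_matrix(expr, skel, 5)
    comp = standardize_components(compute_components(expr, skel, delays))
    return expr, skel, delays, comp


class TestOrientClique:
    def test_planted_direction_recovered(self):
        """Shifted regulator with mild noise: the delay-aligned MI points at
        the true direction; static scoring (sigma=1) isolates that signal."""
        ok = 0
        for seed in range(20):
            expr, skel, delays, comp = _pair_setup(100 + seed)
            edge = orient_clique(
                decompose_cliques(skel)[0], expr.gene_ids, delays, comp,
                CSConfig(sigma=1.0),
            )
            ok += edge.regulator == "X"
        assert ok >= 16

    def test_exact_tie_breaks_to_lexicographic_regulator(self):
        # mirror-symmetric series make the two directions numerically equal
        v = np.array([0.0, 1, 2, 1, 0, 1, 2, 1, 0, 1])
        expr = ExpressionMatrix(["B", "A"], np.vstack([v, v]))
        skel = Skeleton(["B", "A"], np.array([[0, 1.0], [1.0, 0]]), 0)
        delays = build_delay_matrix(expr, skel, 3)
        comp = standardize_components(compute_components(expr, skel, delays))
        edge = orient_clique(
            decompose_cliques(skel)[0], expr.gene_ids, delays, comp, CSConfig()
        )
        assert edge.tie_broken
        assert edge.regulator == "A"  # lexicographically smaller gene id

    def test_never_emits_both_directions(self):
        expr, skel, delays, comp = _pair_setup(3)
        edges = [
            orient_clique(c, expr.gene_ids, delays, comp, CSConfig())
            for c in decompose_cliques(skel)
        ]
        pairs = [(e.regulator, e.target) for e in edges]
        assert all((b, a) not in pairs for a, b in pairs)


class TestAssemble:
    def test_nine_edges_assemble_into_nine_delay_entries(self):
        genes = [f"G{i}" for i in range(1, 11)]
        edges = [
            OrientedEdge(genes[i], genes[i + 1], delay=(i % 3) + 1, cs=0.5)
            for i in range(9)
        ]
        grn = assemble(edges, genes, k_max=5)
        assert grn.prior.n_edges == 9
        assert int((grn.delays.delays > 0).sum()) == 9

    def test_empty_edge_list(self):
        grn = assemble([], ["A", "B"], k_max=3)
        assert grn.prior.n_edges == 0

    def test_duplicate_edge_keeps_max_score(self):
        edges = [
            OrientedEdge("A", "B", 1, cs=0.2),
            OrientedEdge("A", "B", 2, cs=0.9),
        ]
        with pytest.warns(UserWarning, match="duplicate"):
            grn = assemble(edges, ["A", "B"], k_max=3)
        assert grn.edge_scores[("A", "B")] == 0.9
        assert grn.delays.delays[0, 1] == 2

    def test_round_trips_through_io(self, tmp_path):
        genes = ["A", "B", "C"]
        edges = [OrientedEdge("A", "B", 2, 0.4), OrientedEdge("C", "B", 1, 0.7)]
        grn = assemble(edges, genes, k_max=3)
        path = tmp_path / "grn.tsv"
        write_network(grn, path, fmt="tsv")
        back = read_grn(path)
        assert back.prior.edges == grn.prior.edges
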