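"""End-to-end searches across coherency models (small planted networks)."""

import numpy as np
import pytest

from netbiclust.core import (
    SearchConfig,
    StageError,
    run,
    search_constant,
    search_order_preserving,
    search_plaid,
    search_symmetric,
)
from netbiclust.model import Bicluster
from netbiclust.network import AdjacencyView, Network, to_minimal_bipartite
from netbiclust.preprocess import (
    ItemizedMatrix,
    build_sequences,
)
from netbiclust.synth import BenchmarkConfig, generate, match_report


def small_cfg(**kw):
    defaults = dict(coherencies=("constant",), alphabets=(3,),
                    min_coverage=0.5, max_modules=50)
    defaults.update(kw)
    return SearchConfig(**defaults)


def mat_from_items(cell_items, n_rows, n_cols, symmetric=False):
    rows = [[] for _ in range(n_rows)]
    for (i, j), it in sorted(cell_items.items()):
        items = it if isinstance(it, tuple) else (it,)
        rows[i].append((j, items, float(items[0])))
    return ItemizedMatrix([f"r{i}" for i in range(n_rows)],
                          [f"c{j}" for j in range(n_cols)],
                          rows, alphabet=(-1, 0, 1), delta=1 / 3,
                          symmetric=symmetric)


def scatter_background(rng, cells, n_rows, n_cols, density=0.08):
    for i in range(n_rows):
        for j in range(n_cols):
            if (i, j) not in cells and rng.random() < density:
                cells[(i, j)] = int(rng.choice([-1, 1]))


class TestRun:
    def test_empty_view_yields_no_modules(self):
        view = AdjacencyView([], [], [])
        assert run(view, small_cfg()) == []

    def test_unknown_coherency_rejected(self):
        with pytest.raises(ValueError):
            SearchConfig(coherencies=("spiral",))

    def test_invalid_decay_rejected(self):
        with pytest.raises(ValueError):
            SearchConfig(theta_decay=1.5)

    def test_recovers_planted_constant_module(self):
        cfg = BenchmarkConfig(n_nodes=150, density=0.08, n_modules=2,
                              module_size=(16, 20), coherency="constant")
        net, sol = generate(cfg, seed=4)
        mods = run(to_minimal_bipartite(net), small_cfg())
        rep = match_report(mods, sol)
        assert rep.ms_hidden_to_found >= 0.9

    def test_deterministic_given_config(self):
        cfg = BenchmarkConfig(n_nodes=120, density=0.08, n_modules=2,
                              module_size=(14, 18))
        net, _ = generate(cfg, seed=9)
        view = to_minimal_bipartite(net)
        a = run(view, small_cfg())
        b = run(view, small_cfg())
        assert [(m.rows, m.cols) for m in a] == [(m.rows, m.cols) for m in b]

    def test_emitted_modules_respect_their_coherency(self):
        cfg = BenchmarkConfig(n_nodes=150, density=0.08, n_modules=2,
                              module_size=(16, 20), noise=0.1)
        net, _ = generate(cfg, seed=6)
        mods = run(to_minimal_bipartite(net), small_cfg())
        for bc in mods:
            assert bc.noise["deviating"] <= 0.2 + 1e-9


class TestSearchConstant:
    def test_definitional_toy_module(self, rng):
        cells = {}
        for i in range(4):
            cells[(i, 0)], cells[(i, 1)], cells[(i, 2)] = 1, -1, 1
        scatter_background(rng, cells, 30, 20)
        mat = mat_from_items(cells, 30, 20)
        mods = search_constant(mat, small_cfg(extend_max_noise=None, alpha=0.05))
        best = max(mods, key=lambda m: len(m.rows & set(range(4))))
        assert set(range(4)) <= best.rows
        assert {0, 1, 2} <= best.cols

    def test_theta_loop_reaches_small_support(self, rng):
        # a 5-row module among 100 rows is only reachable once theta <= 5%
        cells = {}
        for i in range(5):
            for j in range(4):
                cells[(i, j)] = 1
        scatter_background(rng, cells, 100, 40, density=0.05)
        mat = mat_from_items(cells, 100, 40)
        mods = search_constant(mat, small_cfg(alpha=0.05))
        assert any(set(range(5)) <= m.rows and set(range(4)) <= m.cols
                   for m in mods)


class TestSearchSymmetric:
    def test_exact_mirror_pair(self, rng):
        cells = {}
        for j, k in enumerate((1, -1, 1)):
            for i in range(3):
                cells[(i, j)] = k
            for i in range(3, 6):
                cells[(i, j)] = -k
        scatter_background(rng, cells, 40, 20)
        mat = mat_from_items(cells, 40, 20)
        mods = search_symmetric(mat, small_cfg(coherencies=("symmetric",),
                                               alpha=0.05))
        best = max(mods, key=lambda m: len(m.rows & set(range(6))))
        assert set(range(6)) <= best.rows
        signs = [best.signs[i] for i in range(6)]
        assert signs[:3] == [signs[0]] * 3
        assert signs[3:] == [-signs[0]] * 3

    def test_all_positive_data_reduces_to_constant(self, rng):
        cells = {}
        for i in range(5):
            for j in range(4):
                cells[(i, j)] = 1
        scatter_background(rng, cells, 40, 20, density=0.06)
        cells = {k: abs(v) for k, v in cells.items()}
        mat = mat_from_items(cells, 40, 20)
        cfg = small_cfg(alpha=0.05)
        cons = search_constant(mat, cfg)
        sym = search_symmetric(mat, cfg)
        assert {(m.rows, m.cols) for m in cons} == {(m.rows, m.cols) for m in sym}
        for m in sym:
            assert all(s == 1 for s in m.signs.values())


class TestSearchPlaid:
    def build_overlap_instance(self, rng, additive=True):
        # two 4x4 modules overlapping on one cell; items clamped to alphabet
        cells = {}
        for i in range(4):
            for j in range(4):
                cells[(i, j)] = 1
        for i in range(3, 7):
            for j in range(3, 7):
                cells[(i, j)] = -1
        cells[(3, 3)] = 0 if additive else 1   # 1 + (-1) = 0 when additive
        scatter_background(rng, cells, 40, 25, density=0.05)
        return mat_from_items(cells, 40, 25)

    def test_additive_overlap_keeps_both_modules_full(self, rng):
        mat = self.build_overlap_instance(rng, additive=True)
        mods = search_plaid(mat, small_cfg(coherencies=("plaid",), alpha=0.05))
        found_a = any(set(range(4)) <= m.rows and set(range(4)) <= m.cols
                      for m in mods)
        found_b = any(set(range(3, 7)) <= m.rows and set(range(3, 7)) <= m.cols
                      for m in mods)
        assert found_a and found_b

    def test_no_overlap_reduces_to_constant_output(self, rng):
        cells = {}
        for i in range(4):
            for j in range(4):
                cells[(i, j)] = 1
        scatter_background(rng, cells, 40, 25, density=0.05)
        mat = mat_from_items(cells, 40, 25)
        cfg = small_cfg(alpha=0.05)
        plaid = search_plaid(mat, cfg)
        cons = search_constant(mat, cfg)
        assert {(m.rows, m.cols) for m in plaid} == {(m.rows, m.cols) for m in cons}


class TestSearchDense:
    def test_uniform_background_yields_no_significant_module(self):
        from netbiclust.core import search_dense
        from netbiclust.synth import BenchmarkConfig, generate
        from netbiclust.network import to_minimal_bipartite
        from netbiclust.preprocess import (DiscretizationScheme, discretize,
                                           normalize)

        cfg = BenchmarkConfig(n_nodes=200, density=0.1, n_modules=0,
                              module_size=(10, 12))
        net, _ = generate(cfg, seed=8)
        norm = normalize(to_minimal_bipartite(net))
        mat = discretize(norm, DiscretizationScheme(3, 0.25, "none"))
        assert search_dense(mat, small_cfg(coherencies=("dense",))) == []


class TestSearchOrderPreserving:
    def test_worked_two_row_example(self, rng):
        # rows x3, x5 order columns y2 <= y6 <= y7 identically
        n_rows, n_cols = 30, 12
        values = {}
        for i in (3, 5, 8, 9, 12):
            values[(i, 2)], values[(i, 6)], values[(i, 7)] = 0.1, 0.5, 0.9
        for i in range(n_rows):
            for j in range(n_cols):
                if (i, j) not in values and rng.random() < 0.2:
                    values[(i, j)] = float(rng.normal())
        rows = [[] for _ in range(n_rows)]
        for (i, j), v in sorted(values.items()):
            rows[i].append((j, (1,), v))
        mat = ItemizedMatrix([f"r{i}" for i in range(n_rows)],
                             [f"c{j}" for j in range(n_cols)], rows,
                             alphabet=(-1, 0, 1), delta=1 / 3)
        db = build_sequences(AdjacencyView(
            mat.row_nodes, mat.col_nodes,
            [[(j, v) for j, _, v in r] for r in mat.rows]))
        # the default spurious-pattern floor is calibrated for sparse
        # networks; this dense toy instance needs a lower guard
        cfg = small_cfg(coherencies=("order_preserving",), alpha=0.1,
                        extend_max_noise=None, support_floor_sigma=2.0)
        mods = search_order_preserving(db, cfg, mat)
        assert any({2, 6, 7} <= m.cols and {3, 5, 8, 9, 12} <= m.rows
                   for m in mods)

    def test_reversed_row_not_supporting(self):
        from netbiclust.postprocess import order_agreement
        rows = [[(2, (1,), 0.1), (6, (1,), 0.5), (7, (1,), 0.9)],
                [(2, (1,), 0.9), (6, (1,), 0.5), (7, (1,), 0.1)]]
        mat = ItemizedMatrix(["a", "b"], [f"c{j}" for j in range(8)], rows,
                             alphabet=(-1, 0, 1), delta=1 / 3)
        groups = (frozenset({2}), frozenset({6}), frozenset({7}))
        assert order_agreement(mat, 0, groups) == pytest.approx(1.0)
        assert order_agreement(mat, 1, groups) < 0.5
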