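"""The mapping -> mining -> postprocessing pipeline across coherency models.

The engine mines candidate modules at a decreasing support threshold
(multiplicative decay from a high starting fraction), maps patterns to
biclusters, makes them noise-tolerant through bounded extension, merges and
filters them, and stops when enough dissimilar modules are found, when the
accepted modules cover enough of the network's interactions, when the
support threshold reaches a data-driven floor, or when further levels stop
adding modules.  The support floor guards against the combinatorial blow-up
of spurious patterns: it sits several standard deviations above the
expected co-support of unrelated columns under the network's density.

Coherency models:

* ``constant`` — closed frequent itemsets over (column, item) tokens.
* ``dense``    — the constant search restricted to the top alphabet items
  (hyperclique-style), reported with the module's mean interaction weight.
* ``symmetric`` — constant seeds plus greedy per-row sign correction: each
  candidate row enters with the sign ``c_i`` that best matches the pattern.
* ``plaid``    — noise-tolerant constant modules; cells deviating inside a
  module are re-tested as the sum of the expected values of all overlapping
  modules and, when additive within half a discretization bin, marked
  explained and kept through further extension rounds.
* ``order_preserving`` — closed sequence patterns over value-ordered
  columns; large networks are first decomposed into candidate column blocks
  from frequent ordered pairs, and exact sequence mining runs per block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import Bicluster, COHERENCIES
from .mining import (
    Constraint,
    ItemsetMiningContext,
    mine_sequences,
    pattern_to_bicluster,
    remove_items,
)
from .network import AdjacencyView, Network, decompose_heterogeneous, to_minimal_bipartite
from .postprocess import (
    extend,
    filter_biclusters,
    merge,
    module_mismatch,
    significance,
)
from .postprocess import reduce as reduce_module
from .preprocess import (
    DiscretizationScheme,
    ItemizedMatrix,
    build_sequences,
    build_transactions,
    discretize,
    itemize_labeled,
    normalize,
)


@dataclass(frozen=True)
class SearchConfig:
    """Pipeline parameters; the defaults are the recommended setting.

    ``theta_start``/``theta_decay`` drive the support loop (80% start, 10%
    multiplicative decay); the loop stops at ``max_modules`` dissimilar
    modules, at ``min_coverage`` of present interactions, at the support
    floor, or after ``patience`` levels without progress.  ``alphabets``
    lists the discretization sizes searched jointly.  ``extend_max_noise``
    bounds the mismatch fraction tolerated when growing modules (None
    disables extension).  ``node_budget``/``max_patterns`` cap each mining
    call; within the caps the searches are exhaustive.
    """

    coherencies: tuple[str, ...] = ("constant",)
    alphabets: tuple[int, ...] = (3, 5, 7)
    theta_start: float = 0.8
    theta_decay: float = 0.9
    max_modules: int = 50
    min_coverage: float = 0.10
    merge_overlap: float = 0.8
    filter_sim: float = 0.7
    alpha: float = 0.01
    multi_item_fraction: float = 0.25
    normalization: str = "zero_mean_rows"
    min_confidence: float = 0.5
    extend_max_noise: Optional[float] = 0.2
    merge_enabled: bool = True
    min_rows: int = 2
    min_cols: int = 2
    support_floor_sigma: float = 5.0
    node_budget: Optional[int] = 200_000
    max_patterns: Optional[int] = 10_000
    patience: int = 2
    op_n_ranks: Optional[int] = None
    covered_tol: float = 0.25
    plaid_max_iter: int = 10
    constraints: tuple[Constraint, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.theta_decay < 1:
            raise ValueError("theta_decay must lie in (0, 1)")
        for name in ("theta_start", "merge_overlap", "filter_sim", "min_coverage"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        for c in self.coherencies:
            if c not in COHERENCIES:
                raise ValueError(f"unknown coherency {c!r}")


class StageError(RuntimeError):
    """Wraps module-level errors with the pipeline stage that raised them."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[{stage}] {err}")
        self.stage = stage
        self.cause = err


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _support_cascade(cfg: SearchConfig, n_rows: int, s_max: int,
                     floor: int) -> list[int]:
    """Distinct absolute support levels from theta_start down to the floor,
    skipping levels above the maximum achievable support."""
    out: list[int] = []
    theta = cfg.theta_start
    for _ in range(400):
        s = max(math.ceil(theta * n_rows - 1e-9), floor)
        if s <= s_max and (not out or s < out[-1]):
            out.append(s)
        if s <= floor:
            break
        theta *= cfg.theta_decay
    return out


def _itemset_floor(cfg: SearchConfig, db, n_rows: int) -> int:
    supp: dict = {}
    for tr in db.transactions:
        for t in set(tr):
            supp[t] = supp.get(t, 0) + 1
    if not supp:
        return cfg.min_rows
    fbar = np.mean(list(supp.values())) / max(n_rows, 1)
    mu = n_rows * fbar * fbar
    return max(cfg.min_rows, math.ceil(mu + cfg.support_floor_sigma * math.sqrt(mu)))


def _coverage(mods: Sequence[Bicluster], mat: ItemizedMatrix) -> float:
    present = mat.n_elements
    if present == 0:
        return 0.0
    cells = set()
    for bc in mods:
        for i in bc.rows:
            row = mat.row_cells(i)
            for j in bc.cols:
                if j in row:
                    cells.add((i, j))
    return len(cells) / present


def _covered_list(mods: Sequence[Bicluster], db) -> list[tuple[frozenset, frozenset]]:
    pos_of = {rid: p for p, rid in enumerate(db.row_ids)}
    out = []
    for bc in mods:
        if not isinstance(bc.pattern, dict):
            continue
        toks = set()
        for j, k in bc.pattern.items():
            toks.add((j, k))
            if bc.coherency == "symmetric":
                toks.add((j, -k))
        rows = frozenset(pos_of[i] for i in bc.rows if i in pos_of)
        out.append((frozenset(toks), rows))
    return out


def _bin_centers(mat: ItemizedMatrix) -> dict[int, float]:
    cuts = mat.cut_points
    if not cuts:
        return {k: float(k) for k in mat.alphabet}
    inner = cuts[1] - cuts[0] if len(cuts) > 1 else 1.0
    edges = [cuts[0] - inner] + list(cuts) + [cuts[-1] + inner]
    return {item: (edges[b] + edges[b + 1]) / 2
            for b, item in enumerate(mat.alphabet)}


def _canonical_cells(bc: Bicluster) -> frozenset:
    cached = getattr(bc, "_canon_cells", None)
    if cached is None:
        cached = frozenset((i, j) if i <= j else (j, i)
                           for i in bc.rows for j in bc.cols)
        bc._canon_cells = cached
    return cached


def _dedup_mirrors(mods: list[Bicluster], sim: float) -> list[Bicluster]:
    """Drop modules mostly contained, as undirected interaction sets, in a
    larger module.  The symmetric fill of a homogeneous network stores each
    interaction twice, so every module also surfaces as partial mirrors
    (column-slices with swapped roles); those are redundant evidence."""
    order = sorted(mods, key=lambda b: (-b.n_cells,
                                        b.p_value if b.p_value is not None else 1.0,
                                        sorted(b.rows), sorted(b.cols)))
    kept: list[Bicluster] = []
    kept_cells: list[frozenset] = []
    for bc in order:
        cells = _canonical_cells(bc)
        if any(len(cells & kc) / max(len(cells), 1) >= sim for kc in kept_cells):
            continue
        kept.append(bc)
        kept_cells.append(cells)
    return kept


def _absorbed(bc: Bicluster, mods: list[Bicluster], tol: float = 0.25) -> bool:
    """True when a candidate's rows and columns already sit inside an
    accepted module (up to a tolerated fraction of stray rows)."""
    for m in mods:
        if bc.coherency != m.coherency:
            continue
        if bc.cols <= m.cols or (bc.rows <= m.cols and bc.cols <= m.rows):
            outside = len(bc.rows - m.rows) if bc.cols <= m.cols                 else len(bc.cols - m.rows)
            if outside <= tol * len(bc.rows):
                return True
    return False


def _size_ok(bc: Bicluster, cfg: SearchConfig) -> bool:
    return len(bc.rows) >= cfg.min_rows and len(bc.cols) >= cfg.min_cols


def _apply_bc_constraints(mods: list[Bicluster],
                          constraints: Sequence[Constraint]) -> list[Bicluster]:
    hard = [c for c in constraints if c.kind != "succinct" or c.remove]
    if not constraints:
        return mods
    out = []
    for bc in mods:
        if isinstance(bc.pattern, dict):
            phi = sorted(bc.pattern.values())
        else:
            phi = sorted(j for g in (bc.pattern or ()) for j in g)
        if all(c.predicate(phi) for c in constraints):
            out.append(bc)
    return out


# ---------------------------------------------------------------------------
# itemset-based searches (constant / dense / symmetric / plaid)
# ---------------------------------------------------------------------------

def _itemset_search(mat: ItemizedMatrix, cfg: SearchConfig, coherency: str,
                    annotations=None) -> list[Bicluster]:
    db = build_transactions(mat, annotations)
    removed = frozenset().union(*(c.remove for c in cfg.constraints)) \
        if cfg.constraints else frozenset()
    if removed:
        db = remove_items(db, removed)
    if coherency == "dense":
        top_k = math.ceil(len(mat.alphabet) / 4)
        top_items = set(sorted(mat.alphabet)[-top_k:])
        keep = [[t for t in tr
                 if not isinstance(t, tuple) or not isinstance(t[1], int)
                 or t[1] in top_items] for tr in db.transactions]
        pairs = [(tr, rid) for tr, rid in zip(keep, db.row_ids) if tr]
        from .preprocess import TransactionalDB
        db = TransactionalDB([p[0] for p in pairs], [p[1] for p in pairs],
                             db.n_rows_total, db.n_cols)
    n = len(db.transactions)
    if n == 0:
        return []

    pushable = [c for c in cfg.constraints if c.pushable]
    am_pred = (lambda phi: all(c.predicate(phi) for c in pushable)) if pushable else None

    floor = _itemset_floor(cfg, db, n)
    # one reusable mining context per database: the support loop re-mines the
    # same structures at every level
    ctx = ItemsetMiningContext(db, base_floor=floor)
    max_co = ctx.max_co_support()
    # the largest cross-column co-support bounds the support any >=2-column
    # pattern can reach, so higher levels need not be mined at all
    s_max = max(max_co.values(), default=0)
    cascade = _support_cascade(cfg, n, s_max, floor)

    accepted: list[Bicluster] = []
    n_tests = 0
    stale = 0
    n_dissim_prev = 0
    for abs_sup in cascade:
        covered = _covered_list(accepted, db)
        stats: dict = {}
        pats = ctx.mine(
            abs_sup, anti_monotone=am_pred,
            node_budget=cfg.node_budget, max_patterns=cfg.max_patterns,
            covered=covered, covered_tol=cfg.covered_tol, self_prune=True,
            min_items=2, use_max_co=True, stats_out=stats)
        # Bonferroni over the hypotheses actually examined, not only the
        # patterns that happened to be emitted
        n_tests += max(stats.get("candidates", 0), len(pats), 1)
        new = []
        for p in pats:
            if p.support < cfg.min_rows:
                continue
            try:
                bc = pattern_to_bicluster(p, db, mat, coherency)
            except ValueError:
                continue
            if len(bc.cols) < cfg.min_cols:
                continue
            if coherency == "symmetric":
                bc.signs = {i: 1 for i in bc.rows}
            new.append(bc)
        if cfg.extend_max_noise is not None:
            seen: dict = {}
            grown: list[Bicluster] = list(accepted)
            new.sort(key=lambda b: (-len(b.rows) * len(b.cols), sorted(b.cols)))
            n_ext = 0
            for bc in new:
                if n_ext >= 150:
                    break
                if _absorbed(bc, grown):
                    continue
                n_ext += 1
                ext = extend(bc, mat, cfg.extend_max_noise)
                ext = reduce_module(ext, mat, cfg.extend_max_noise)
                key = (ext.rows, ext.cols)
                if key not in seen and _size_ok(ext, cfg):
                    seen[key] = ext
                    grown.append(ext)
            new = list(seen.values())
        pool = accepted + [b for b in new if _size_ok(b, cfg)]
        if cfg.merge_enabled:
            pool = merge(pool, cfg.merge_overlap, mat)
        for bc in pool:
            bc.p_value = significance(bc, mat, n_tests)
        pool = _apply_bc_constraints(pool, cfg.constraints)
        pool = filter_biclusters(pool, cfg.filter_sim, cfg.alpha)

        accepted = pool
        # mirrors of already-counted modules do not count as dissimilar
        dissimilar = _dedup_mirrors(accepted, cfg.filter_sim) \
            if mat.symmetric else accepted
        # patience only starts counting once the search has found something:
        # high-support levels are legitimately empty
        progress = len(dissimilar) > n_dissim_prev
        n_dissim_prev = len(dissimilar)
        stale = 0 if (progress or not accepted) else stale + 1
        if (len(dissimilar) >= cfg.max_modules
                or _coverage(dissimilar, mat) >= cfg.min_coverage
                or stale > cfg.patience):
            break

    # final refinement: modules assembled by merging late in the loop may
    # never have been re-extended; one more extend/reduce pass settles them
    if cfg.extend_max_noise is not None and accepted:
        refined: dict = {}
        for bc in accepted:
            ext = reduce_module(extend(bc, mat, cfg.extend_max_noise),
                                mat, cfg.extend_max_noise)
            if _size_ok(ext, cfg):
                refined[(ext.rows, ext.cols)] = ext
        accepted = list(refined.values())
        if cfg.merge_enabled:
            accepted = merge(accepted, cfg.merge_overlap, mat)
        for bc in accepted:
            bc.p_value = significance(bc, mat, n_tests)
        accepted = filter_biclusters(accepted, cfg.filter_sim, cfg.alpha)
    if mat.symmetric:
        accepted = _dedup_mirrors(accepted, cfg.filter_sim)
    if coherency == "plaid":
        accepted = _plaid_refine(accepted, mat, cfg, n_tests)
    if coherency == "dense":
        for bc in accepted:
            vals = [mat.row_values(i).get(j) for i in bc.rows for j in bc.cols]
            vals = [v for v in vals if v is not None]
            bc.mean_weight = float(np.mean(vals)) if vals else None
    return accepted


def _explained_cells(mods: Sequence[Bicluster], mat: ItemizedMatrix,
                     tol: float) -> set[tuple[int, int]]:
    """Cells whose value matches the summed expectations of >= 2 modules.

    Contributions are evaluated on each module's relaxed candidate pattern
    (majority vote over its rows), because a column shared by overlapping
    modules deviates inside each of them individually and may have been
    trimmed from both before the additive test can run."""
    from .postprocess import _constant_candidate_cols

    centers = _bin_centers(mat)
    contrib: dict[tuple[int, int], float] = {}
    count: dict[tuple[int, int], int] = {}
    for bc in mods:
        if not isinstance(bc.pattern, dict):
            continue
        signs = bc.signs or {}
        cand_cols, cand_pattern = _constant_candidate_cols(
            mat, sorted(bc.rows), signs, 0.45)
        pattern = dict(cand_pattern)
        pattern.update(bc.pattern)
        for i in bc.rows:
            sign = signs.get(i, 1)
            for j, k in pattern.items():
                cell = (i, j)
                contrib[cell] = contrib.get(cell, 0.0) + sign * centers[k]
                count[cell] = count.get(cell, 0) + 1
    out = set()
    for cell, total in contrib.items():
        if count[cell] < 2:
            continue
        i, j = cell
        v = mat.row_values(i).get(j)
        if v is not None and abs(v - total) <= tol:
            out.add(cell)
    return out


def _plaid_refine(mods: list[Bicluster], mat: ItemizedMatrix,
                  cfg: SearchConfig, n_tests: int) -> list[Bicluster]:
    """Iteratively mark overlap cells whose value matches the cumulative
    expectation of their modules, and re-extend with those cells counted as
    coherent.  Stops when no cell changes state (cap ``plaid_max_iter``)."""
    cuts = mat.cut_points
    tol = (cuts[1] - cuts[0]) / 2 if len(cuts) > 1 else mat.delta / 2
    explained: set[tuple[int, int]] = set()
    for _ in range(cfg.plaid_max_iter):
        new_explained = _explained_cells(mods, mat, tol)
        if new_explained == explained:
            break
        explained = new_explained
        if cfg.extend_max_noise is not None:
            mods = [extend(bc, mat, cfg.extend_max_noise, explained=explained)
                    for bc in mods]
        mods = merge(mods, cfg.merge_overlap, mat)
        for bc in mods:
            bc.p_value = significance(bc, mat, n_tests)
            bc.noise = module_mismatch(bc, mat, explained)
        mods = filter_biclusters(mods, cfg.filter_sim, cfg.alpha)
    return mods


def search_constant(mat: ItemizedMatrix, cfg: SearchConfig, **kw) -> list[Bicluster]:
    return _itemset_search(mat, cfg, "constant", **kw)


def search_dense(mat: ItemizedMatrix, cfg: SearchConfig, **kw) -> list[Bicluster]:
    return _itemset_search(mat, cfg, "dense", **kw)


def search_symmetric(mat: ItemizedMatrix, cfg: SearchConfig, **kw) -> list[Bicluster]:
    return _itemset_search(mat, cfg, "symmetric", **kw)


def search_plaid(mat: ItemizedMatrix, cfg: SearchConfig, **kw) -> list[Bicluster]:
    return _itemset_search(mat, cfg, "plaid", **kw)


# ---------------------------------------------------------------------------
# order-preserving search
# ---------------------------------------------------------------------------

def _ordered_pair_counts(db, n_cols: int) -> Optional[np.ndarray]:
    """Directed counts P[a, b] = number of rows placing a strictly before b."""
    if n_cols > 6000:
        return None
    P = np.zeros(n_cols * n_cols, dtype=np.int32)
    triu_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    chunk: list[np.ndarray] = []
    size = 0
    for seq in db.sequences:
        flat: list[int] = []
        bounds = [0]
        for g in seq:
            cols = sorted(c for c in g if isinstance(c, int))
            flat.extend(cols)
            bounds.append(len(flat))
        L = len(flat)
        if L < 2:
            continue
        idx = np.asarray(flat, dtype=np.int64)
        iu = triu_cache.get(L)
        if iu is None:
            iu = np.triu_indices(L, 1)
            triu_cache[L] = iu
        a, b = idx[iu[0]], idx[iu[1]]
        # mask out pairs inside the same tied group (no order between them)
        if len(bounds) - 1 != L:
            grp = np.empty(L, dtype=np.int64)
            for gi in range(len(bounds) - 1):
                grp[bounds[gi]:bounds[gi + 1]] = gi
            keep = grp[iu[0]] != grp[iu[1]]
            a, b = a[keep], b[keep]
        chunk.append(a * n_cols + b)
        size += a.size
        if size > 4_000_000:
            P += np.bincount(np.concatenate(chunk),
                             minlength=n_cols * n_cols).astype(np.int32)
            chunk, size = [], 0
    if chunk:
        P += np.bincount(np.concatenate(chunk),
                         minlength=n_cols * n_cols).astype(np.int32)
    return P.reshape(n_cols, n_cols)


def _components(edges: np.ndarray, n_cols: int) -> list[list[int]]:
    parent = list(range(n_cols))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[ra] = rb
    groups: dict[int, list[int]] = {}
    for c in range(n_cols):
        groups.setdefault(find(c), []).append(c)
    return [g for g in groups.values() if len(g) >= 2]


def _seq_arrays(db):
    """Flat per-row (cols, group ids) arrays for fast component filtering."""
    cols_list, grp_list = [], []
    for seq in db.sequences:
        cc, gg = [], []
        for gi, g in enumerate(seq):
            for col in sorted(g, key=repr):
                if isinstance(col, int):
                    cc.append(col)
                    gg.append(gi)
        cols_list.append(np.asarray(cc, dtype=np.int64))
        grp_list.append(np.asarray(gg, dtype=np.int64))
    return cols_list, grp_list


def search_order_preserving(db, cfg: SearchConfig,
                            mat: ItemizedMatrix) -> list[Bicluster]:
    """Sequential-pattern search for modules preserving a column ordering.

    For large databases the search first groups columns into candidate
    blocks using exact frequent-ordered-pair counts (unrelated columns
    rarely co-occur in a fixed order in sparse networks), then runs the
    exact closed-sequence miner inside each block.
    """
    from .preprocess import SequentialDB

    n = len(db.sequences)
    if n == 0:
        return []
    lens = [sum(len(g) for g in seq) for seq in db.sequences]
    avg_len = float(np.mean(lens))
    n_cols = db.n_cols
    # degree-aware guard: the expected ordered co-support of two unrelated
    # columns is n*f_a*f_b/2; use the 90th presence percentile so that
    # high-degree column pairs stay below the floor
    pres = np.zeros(n_cols, dtype=np.int64)
    for seq in db.sequences:
        for g in seq:
            for col in g:
                if isinstance(col, int):
                    pres[col] += 1
    f_hi = float(np.quantile(pres[pres > 0], 0.9)) / n if (pres > 0).any() else 0.0
    mu = n * f_hi * f_hi / 2.0
    floor = max(cfg.min_rows,
                math.ceil(mu + cfg.support_floor_sigma * math.sqrt(mu)))

    use_blocks = n * avg_len * avg_len > 2e6
    seq_cols, seq_grps = _seq_arrays(db) if use_blocks else ([], [])
    P = _ordered_pair_counts(db, n_cols) if use_blocks else None
    if P is None:
        use_blocks = False
    s_max = int(P.max()) if P is not None else n
    cascade = _support_cascade(cfg, n, s_max, floor)

    accepted: list[Bicluster] = []
    n_tests = 0
    stale = 0
    n_dissim_prev = 0
    pos_of = {rid: p for p, rid in enumerate(db.row_ids)}

    for abs_sup in cascade:
        covered = []
        for bc in accepted:
            rows = frozenset(pos_of[i] for i in bc.rows if i in pos_of)
            covered.append((frozenset(bc.cols), rows))
        pats = []
        if use_blocks:
            sym = np.maximum(P, P.T)
            edges = np.argwhere(np.triu(sym, 1) >= abs_sup)
            for comp in _components(edges, n_cols):
                comp_set = set(comp)
                # a component whose columns sit inside an accepted module is
                # that module's evidence; nothing new can come from it
                if any(len(comp_set - bc.cols) <= 0.1 * len(comp_set)
                       for bc in accepted):
                    continue
                lookup = np.zeros(n_cols, dtype=bool)
                lookup[list(comp_set)] = True
                seqs, ids = [], []
                for (cc, gg), rid in zip(zip(seq_cols, seq_grps), db.row_ids):
                    keep = lookup[cc] if cc.size else np.array([], dtype=bool)
                    if int(keep.sum()) < 2:
                        continue
                    kc, kg = cc[keep], gg[keep]
                    groups_out: list[frozenset] = []
                    prev_g = None
                    for col, gi in zip(kc, kg):
                        if gi != prev_g:
                            groups_out.append(frozenset([int(col)]))
                            prev_g = gi
                        else:
                            groups_out[-1] = groups_out[-1] | {int(col)}
                    seqs.append(groups_out)
                    ids.append(rid)
                if len(seqs) < abs_sup:
                    continue
                sub = SequentialDB(seqs, ids, db.n_rows_total, db.n_cols)
                sub_pos = {rid: p for p, rid in enumerate(ids)}
                sub_cov = []
                for toks, rows in covered:
                    sub_cov.append((toks, frozenset(
                        sub_pos[db.row_ids[r]] for r in rows
                        if db.row_ids[r] in sub_pos)))
                stats: dict = {}
                for p in mine_sequences(sub, abs_sup,
                                        node_budget=cfg.node_budget,
                                        max_patterns=cfg.max_patterns,
                                        covered=sub_cov,
                                        covered_tol=cfg.covered_tol,
                                        self_prune=True, min_items=2,
                                        stats_out=stats):
                    pats.append((p, sub))
                n_tests += stats.get("candidates", 0)
        else:
            stats = {}
            pats = [(p, db) for p in mine_sequences(
                db, abs_sup, node_budget=cfg.node_budget,
                max_patterns=cfg.max_patterns, covered=covered,
                covered_tol=cfg.covered_tol, self_prune=True, min_items=2,
                stats_out=stats)]
            n_tests += stats.get("candidates", 0)

        n_tests += max(len(pats), 1)
        new = []
        for p, src in pats:
            if p.support < cfg.min_rows:
                continue
            try:
                bc = pattern_to_bicluster(p, src, mat, "order_preserving")
            except ValueError:
                continue
            if len(bc.cols) < cfg.min_cols:
                continue
            new.append(bc)
        new.sort(key=lambda b: -b.n_cells)
        if cfg.extend_max_noise is not None:
            seen: dict = {}
            grown: list[Bicluster] = list(accepted)
            for bc in new[:500]:
                if _absorbed(bc, grown):
                    continue
                ext = extend(bc, mat, cfg.extend_max_noise)
                ext = reduce_module(ext, mat, cfg.extend_max_noise)
                key = (ext.rows, ext.cols)
                if key not in seen and _size_ok(ext, cfg):
                    seen[key] = ext
                    grown.append(ext)
            new = list(seen.values())
        pool = accepted + [b for b in new if _size_ok(b, cfg)]
        if cfg.merge_enabled:
            pool = merge(pool, cfg.merge_overlap, mat)
        for bc in pool:
            bc.p_value = significance(bc, mat, n_tests)
        pool = filter_biclusters(pool, cfg.filter_sim, cfg.alpha)

        accepted = pool
        dissimilar = _dedup_mirrors(accepted, cfg.filter_sim) \
            if mat.symmetric else accepted
        progress = len(dissimilar) > n_dissim_prev
        n_dissim_prev = len(dissimilar)
        stale = 0 if (progress or not accepted) else stale + 1
        if (len(dissimilar) >= cfg.max_modules
                or _coverage(dissimilar, mat) >= cfg.min_coverage
                or stale > cfg.patience):
            break
    if cfg.extend_max_noise is not None and accepted:
        refined: dict = {}
        for bc in accepted:
            ext = reduce_module(extend(bc, mat, cfg.extend_max_noise),
                                mat, cfg.extend_max_noise)
            if _size_ok(ext, cfg):
                refined[(ext.rows, ext.cols)] = ext
        accepted = list(refined.values())
        if cfg.merge_enabled:
            accepted = merge(accepted, cfg.merge_overlap, mat)
        for bc in accepted:
            bc.p_value = significance(bc, mat, n_tests)
        accepted = filter_biclusters(accepted, cfg.filter_sim, cfg.alpha)
    if mat.symmetric:
        accepted = _dedup_mirrors(accepted, cfg.filter_sim)
    return accepted


# ---------------------------------------------------------------------------
# entry points
# ---------------------------------------------------------------------------

def run(view: AdjacencyView, cfg: SearchConfig,
        annotations=None) -> list[Bicluster]:
    """Full pipeline on one adjacency view; deterministic given the config."""
    for c in cfg.coherencies:
        if c not in COHERENCIES:
            raise StageError("config", ValueError(f"unknown coherency {c!r}"))
    if view.is_empty:
        return []

    try:
        if view.weighted:
            norm = normalize(view, cfg.normalization)
        else:
            norm = view
    except Exception as e:  # noqa: BLE001
        raise StageError("normalize", e) from e

    results: list[Bicluster] = []
    for coherency in cfg.coherencies:
        if coherency == "order_preserving":
            try:
                if view.weighted:
                    db = build_sequences(norm, annotations=annotations,
                                         n_bins=cfg.op_n_ranks)
                    mat = discretize(norm, DiscretizationScheme(
                        alphabet_size=cfg.alphabets[0],
                        multi_item_fraction=cfg.multi_item_fraction,
                        normalization="none"))
                else:
                    mat = itemize_labeled(view)
                    db = build_sequences(mat, annotations=annotations)
            except Exception as e:  # noqa: BLE001
                raise StageError("mapping", e) from e
            try:
                results.extend(search_order_preserving(db, cfg, mat))
            except Exception as e:  # noqa: BLE001
                raise StageError("mining", e) from e
            continue
        per_alpha: list[Bicluster] = []
        alphabets = cfg.alphabets if view.weighted else (0,)
        for L in alphabets:
            try:
                if view.weighted:
                    mat = discretize(norm, DiscretizationScheme(
                        alphabet_size=L,
                        multi_item_fraction=cfg.multi_item_fraction,
                        normalization="none"))
                else:
                    mat = itemize_labeled(view)
            except Exception as e:  # noqa: BLE001
                raise StageError("mapping", e) from e
            try:
                per_alpha.extend(_itemset_search(mat, cfg, coherency,
                                                 annotations=annotations))
            except Exception as e:  # noqa: BLE001
                raise StageError("mining", e) from e
        # modules found under different coherency strengths are jointly
        # postprocessed
        try:
            per_alpha = merge(per_alpha, cfg.merge_overlap) \
                if cfg.merge_enabled else per_alpha
            per_alpha = filter_biclusters(per_alpha, cfg.filter_sim, cfg.alpha)
        except Exception as e:  # noqa: BLE001
            raise StageError("postprocessing", e) from e
        results.extend(per_alpha)

    seen: set = set()
    out = []
    for bc in sorted(results,
                     key=lambda b: (b.p_value if b.p_value is not None else 1.0,
                                    -b.n_cells, sorted(b.rows), sorted(b.cols))):
        key = (bc.rows, bc.cols, bc.coherency)
        if key not in seen:
            seen.add(key)
            out.append(bc)
    return out


def run_on_network(net: Network, cfg: SearchConfig,
                   annotations=None) -> list[tuple[AdjacencyView, list[Bicluster]]]:
    """Decompose a network into its adjacency views and run each."""
    views = decompose_heterogeneous(net) if not net.is_homogeneous() \
        else [to_minimal_bipartite(net)]
    out = []
    for v in views:
        mods = run(v, cfg, annotations=annotations) if not v.is_empty else []
        out.append((v, mods))
    return out
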