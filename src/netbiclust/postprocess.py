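"""Postprocessing of candidate modules: merge, filter, extend, reduce,
statistical significance.

Merging unions module pairs whose interaction-cell Jaccard similarity
reaches the overlap threshold (default 80%), which recovers modules split
by missing interactions.  Filtering removes modules that are similar to a
strictly larger module (default 70%) or that lack statistical significance
under a row-independence null with empirical item marginals (Bonferroni
corrected binomial tail).  Extension adds rows/columns whose mismatch
against the module pattern stays below a noise bound; reduction removes
offenders.  Extension and reduction double as the engine's noise-tolerance
mechanism for symmetric sign correction and plaid cell re-assignment.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .model import Bicluster, cell_jaccard
from .preprocess import ItemizedMatrix


# ---------------------------------------------------------------------------
# cached per-matrix indexes
# ---------------------------------------------------------------------------

def col_index(mat: ItemizedMatrix) -> dict[int, list[tuple[int, tuple[int, ...], float]]]:
    idx = getattr(mat, "_col_index", None)
    if idx is None:
        idx = {}
        for i, lst in enumerate(mat.rows):
            for c, items, v in lst:
                idx.setdefault(c, []).append((i, items, v))
        mat._col_index = idx
    return idx


def item_frequencies(mat: ItemizedMatrix) -> dict[int, dict[int, float]]:
    freq = getattr(mat, "_item_freq", None)
    if freq is None:
        n = max(len(mat.rows), 1)
        freq = {}
        for c, entries in col_index(mat).items():
            d: dict[int, float] = {}
            for _, items, _ in entries:
                for it in items:   # a multi-item element counts once per item
                    d[it] = d.get(it, 0) + 1
            freq[c] = {k: v / n for k, v in d.items()}
        mat._item_freq = freq
    return freq


def presence_frequencies(mat: ItemizedMatrix) -> dict[int, float]:
    n = max(len(mat.rows), 1)
    return {c: len(entries) / n for c, entries in col_index(mat).items()}


# ---------------------------------------------------------------------------
# coherency mismatch
# ---------------------------------------------------------------------------

def _cell_matches(items: tuple[int, ...], expected: int) -> bool:
    return expected in items


def row_profile(mat: ItemizedMatrix, i: int, pattern: dict[int, int],
                sign: int = 1,
                explained: Optional[set[tuple[int, int]]] = None) -> tuple[int, int]:
    """(matching, missing) counts of row ``i`` against a constant pattern."""
    cells = mat.row_cells(i)
    match = missing = 0
    for j, kj in pattern.items():
        items = cells.get(j)
        if items is None:
            missing += 1
        elif _cell_matches(tuple(sign * it for it in items), kj) or (
                explained and (i, j) in explained):
            match += 1
    return match, missing


def _lnds_length(seq: Sequence[int]) -> int:
    """Longest non-decreasing subsequence length (patience sorting)."""
    tails: list[int] = []
    for x in seq:
        pos = bisect_right(tails, x)
        if pos == len(tails):
            tails.append(x)
        else:
            tails[pos] = x
    return len(tails)


def order_agreement(mat: ItemizedMatrix, i: int,
                    groups: Sequence[frozenset[int]]) -> float:
    """Fraction of pattern columns a row can keep while respecting the
    pattern's ordering (missing columns count against the row)."""
    pos = {c: gi for gi, g in enumerate(groups) for c in g}
    values = mat.row_values(i)
    present = [(values[c], c) for c in pos if c in values]
    if not present:
        return 0.0
    present.sort()
    seq = [pos[c] for _, c in present]
    total = sum(len(g) for g in groups)
    return _lnds_length(seq) / total


def module_mismatch(bc: Bicluster, mat: ItemizedMatrix,
                    explained: Optional[set[tuple[int, int]]] = None) -> dict:
    """Fractions of deviating and missing cells, written into ``bc.noise``."""
    n_cells = bc.n_cells
    if n_cells == 0:
        return {"deviating": 1.0, "missing": 1.0}
    if bc.coherency == "order_preserving":
        groups = bc.pattern or (frozenset(bc.cols),)
        agree = [order_agreement(mat, i, groups) for i in bc.rows]
        deviating = 1.0 - float(np.mean(agree)) if agree else 1.0
        missing = sum(1 for i in bc.rows for j in bc.cols
                      if j not in mat.row_cells(i)) / n_cells
        return {"deviating": max(deviating - missing, 0.0), "missing": missing}
    pattern = bc.pattern if isinstance(bc.pattern, dict) else {}
    match = missing = 0
    for i in bc.rows:
        sign = (bc.signs or {}).get(i, 1)
        m, miss = row_profile(mat, i, pattern, sign, explained)
        match += m
        missing += miss
    return {"deviating": (n_cells - match - missing) / n_cells,
            "missing": missing / n_cells}


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------

def significance(bc: Bicluster, mat: ItemizedMatrix, n_tests: int = 1) -> float:
    """Bonferroni-corrected binomial tail of observing >= |I| supporters.

    The per-row probability of matching phi_B is the product over J of the
    empirical item frequencies (for order-preserving modules, the presence
    probabilities times the fraction of orderings the pattern admits).
    """
    if not bc.cols:
        raise ValueError("bicluster without columns has no significance")
    n = len(mat.rows)
    freq = item_frequencies(mat)
    if bc.coherency == "order_preserving":
        pres = presence_frequencies(mat)
        q = 1.0
        for j in bc.cols:
            q *= pres.get(j, 0.0)
        groups = bc.pattern or (frozenset(bc.cols),)
        sizes = [len(g) for g in groups]
        q *= math.prod(math.factorial(s) for s in sizes) / math.factorial(sum(sizes))
    else:
        pattern = bc.pattern if isinstance(bc.pattern, dict) else {}
        q = 1.0
        for j in bc.cols:
            kj = pattern.get(j)
            fj = freq.get(j, {})
            if kj is None:
                q *= max(fj.values(), default=0.0)
            elif bc.coherency == "symmetric" and kj != 0:
                q *= fj.get(kj, 0.0) + fj.get(-kj, 0.0)
            else:
                q *= fj.get(kj, 0.0)
    q = min(max(q, 0.0), 1.0)
    p = float(stats.binom.sf(len(bc.rows) - 1, n, q))
    return float(min(1.0, p * max(n_tests, 1)))


# ---------------------------------------------------------------------------
# merge and filter
# ---------------------------------------------------------------------------

def _merged_pair(a: Bicluster, b: Bicluster) -> Bicluster:
    big, small = (a, b) if a.n_cells >= b.n_cells else (b, a)
    pattern = None
    if isinstance(big.pattern, dict):
        pattern = dict(small.pattern or {})
        pattern.update(big.pattern)
    elif big.pattern is not None:
        pattern = big.pattern
    signs = None
    if big.signs is not None or small.signs is not None:
        signs = dict(small.signs or {})
        signs.update(big.signs or {})
    return Bicluster(rows=a.rows | b.rows, cols=a.cols | b.cols,
                     coherency=big.coherency, delta=big.delta,
                     pattern=pattern, signs=signs,
                     merged_from=a.merged_from + b.merged_from)


def merge(biclusters: Sequence[Bicluster], overlap: float = 0.8,
          mat: Optional[ItemizedMatrix] = None) -> list[Bicluster]:
    """Union pairs with cell-Jaccard >= ``overlap`` until a fixpoint.

    Pairs are processed in descending similarity (ties: combined size, then
    node order) so the result does not depend on input order.  Cells that
    the union introduces without a backing interaction are recorded in the
    module's missing-cell statistics when ``mat`` is given.
    """
    import heapq

    mods: dict[int, Bicluster] = dict(enumerate(biclusters))
    next_id = len(mods)
    heap: list = []

    def push_pairs(x: int, others: Iterable[int]) -> None:
        a = mods[x]
        for y in others:
            if y == x:
                continue
            b = mods[y]
            s = cell_jaccard(a, b)
            if s >= overlap:
                key = (-s, -(a.n_cells + b.n_cells),
                       tuple(sorted(a.rows | b.rows)),
                       tuple(sorted(a.cols | b.cols)))
                heapq.heappush(heap, (key, x, y))

    ids = list(mods)
    for i, x in enumerate(ids):
        push_pairs(x, ids[i + 1:])
    while heap:
        _, x, y = heapq.heappop(heap)
        if x not in mods or y not in mods:
            continue
        merged = _merged_pair(mods.pop(x), mods.pop(y))
        mods[next_id] = merged
        push_pairs(next_id, list(mods))
        next_id += 1
    out = list(mods.values())
    if mat is not None:
        for m in out:
            m.noise = module_mismatch(m, mat)
    return out


def filter_biclusters(biclusters: Sequence[Bicluster], sim: float = 0.7,
                      alpha: float = 0.01) -> list[Bicluster]:
    """Drop insignificant modules and near-duplicates of larger modules."""
    mods = [b for b in biclusters if b.p_value is None or b.p_value < alpha]
    mods.sort(key=lambda b: (-b.n_cells, -len(b.rows),
                             b.p_value if b.p_value is not None else 1.0,
                             sorted(b.rows), sorted(b.cols)))
    kept: list[Bicluster] = []
    for b in mods:
        drop = False
        for k in kept:
            s = cell_jaccard(b, k)
            if s == 1.0 or (k.n_cells > b.n_cells and s >= sim):
                drop = True
                break
        if not drop:
            kept.append(b)
    return kept


# ---------------------------------------------------------------------------
# extension and reduction
# ---------------------------------------------------------------------------

_ITEM_OFFSET = 8   # shifts signed items into non-negative code space


def _np_col_cache(mat):
    """Per column: (row indexes, items) as flat arrays, multi-items expanded."""
    cache = getattr(mat, "_np_cols", None)
    if cache is None:
        cache = {}
        for j, entries in col_index(mat).items():
            rr, ii = [], []
            for i, items, _ in entries:
                for it in items:
                    rr.append(i)
                    ii.append(it)
            cache[j] = (np.asarray(rr, dtype=np.int64),
                        np.asarray(ii, dtype=np.int64))
        mat._np_cols = cache
    return cache


def _np_row_cache(mat):
    cache = getattr(mat, "_np_rows", None)
    if cache is None:
        cache = []
        for lst in mat.rows:
            cc, ii = [], []
            for c, items, _ in lst:
                for it in items:
                    cc.append(c)
                    ii.append(it)
            cache.append((np.asarray(cc, dtype=np.int64),
                          np.asarray(ii, dtype=np.int64)))
        mat._np_rows = cache
    return cache


def _constant_candidate_rows(mat, pattern, max_noise, allow_signs,
                             explained=None):
    n = len(mat.rows)
    cidx = _np_col_cache(mat)
    empty = np.array([], dtype=np.int64)
    plus_hits, minus_hits = [], []
    for j, kj in pattern.items():
        rr, ii = cidx.get(j, (empty, empty))
        plus_hits.append(rr[ii == kj])
        if allow_signs:
            minus_hits.append(rr[ii == -kj])
    plus = np.bincount(np.concatenate(plus_hits), minlength=n)         if plus_hits else np.zeros(n, dtype=np.int64)
    minus = np.bincount(np.concatenate(minus_hits), minlength=n)         if allow_signs and minus_hits else np.zeros(n, dtype=np.int64)
    if explained:
        for (i, j) in explained:
            if j in pattern and pattern[j] not in mat.row_cells(i).get(j, ()):
                plus[i] += 1
    need = (1.0 - max_noise) * len(pattern)
    rows, signs = [], {}
    score = np.maximum(plus, minus) if allow_signs else plus
    for i in np.flatnonzero((score >= max(need, 1e-9)) & (score > 0)):
        i = int(i)
        rows.append(i)
        signs[i] = -1 if (allow_signs and minus[i] > plus[i]) else 1
    return rows, signs


def _constant_candidate_cols(mat, rows, signs, max_noise, explained=None):
    if not rows:
        return [], {}
    rcache = _np_row_cache(mat)
    n_cols = len(mat.col_nodes)
    codes = []
    for i in rows:
        cc, ii = rcache[i]
        s = signs.get(i, 1)
        codes.append(cc * (2 * _ITEM_OFFSET) + (s * ii + _ITEM_OFFSET))
    cnt = np.bincount(np.concatenate(codes),
                      minlength=n_cols * 2 * _ITEM_OFFSET)
    table = cnt.reshape(n_cols, 2 * _ITEM_OFFSET)
    best_idx = table.argmax(axis=1)
    best_cnt = table[np.arange(n_cols), best_idx]
    if explained:
        rows_set = set(rows)
        extra: dict[int, int] = {}
        for (i, j) in explained:
            if i in rows_set:
                kj = int(best_idx[j]) - _ITEM_OFFSET
                if kj not in mat.row_cells(i).get(j, ()):
                    extra[j] = extra.get(j, 0) + 1
        for j, e in extra.items():
            best_cnt[j] += e
    need = (1.0 - max_noise) * len(rows)
    cols = [int(j) for j in np.flatnonzero(best_cnt >= max(need, 1e-9))]
    pattern = {j: int(best_idx[j]) - _ITEM_OFFSET for j in cols}
    return cols, pattern


def extend(bc: Bicluster, mat: ItemizedMatrix, max_noise: float = 0.2,
           n_iter: int = 4,
           explained: Optional[set[tuple[int, int]]] = None) -> Bicluster:
    """Grow a module with rows/columns whose mismatch stays within
    ``max_noise``; for symmetric modules each candidate row may enter with
    either sign (greedy per-row sign correction).  Original rows and columns
    are never removed here (see :func:`reduce`)."""
    if bc.coherency == "order_preserving":
        return _extend_order_preserving(bc, mat, max_noise, n_iter)
    allow_signs = bc.coherency == "symmetric"
    pattern = dict(bc.pattern or {})
    if not pattern:
        return bc
    rows, signs = set(bc.rows), dict(bc.signs or {})
    cols = set(bc.cols)
    for it in range(max(n_iter, 2)):
        cand_rows, cand_signs = _constant_candidate_rows(
            mat, pattern, max_noise, allow_signs, explained)
        rows = set(bc.rows) | set(cand_rows)
        signs = {**{i: 1 for i in rows}, **cand_signs, **(bc.signs or {})}
        # small seeds attract background supporters; the first column pass
        # therefore uses a relaxed majority vote, later passes the strict
        # noise bound (spurious rows are gone once the pattern has grown)
        col_noise = max(max_noise, 0.45) if it == 0 else max_noise
        cand_cols, cand_pattern = _constant_candidate_cols(
            mat, sorted(rows), signs, col_noise, explained)
        cols = set(bc.cols) | set(cand_cols)
        new_pattern = dict(pattern)
        for j in cols:
            if j in cand_pattern:
                new_pattern.setdefault(j, cand_pattern[j])
        if new_pattern == pattern and rows == set(bc.rows) and cols == set(bc.cols):
            break
        pattern = new_pattern
    # canonical global sign: majority of rows positive
    if allow_signs and signs and sum(signs.values()) < 0:
        signs = {i: -s for i, s in signs.items()}
        pattern = {j: -k for j, k in pattern.items()}
    out = Bicluster(rows=frozenset(rows), cols=frozenset(cols),
                    coherency=bc.coherency, delta=bc.delta,
                    pattern={j: pattern[j] for j in cols if j in pattern},
                    signs={i: signs.get(i, 1) for i in rows} if allow_signs else None,
                    merged_from=bc.merged_from, mean_weight=bc.mean_weight)
    out.noise = module_mismatch(out, mat, explained)
    return out


def _extend_order_preserving(bc, mat, max_noise, n_iter):
    rows = set(bc.rows)
    cols = set(bc.cols)
    for it in range(max(n_iter, 2)):
        # columns present in enough member rows are candidates; short seeds
        # attract background supporters, so the first pass uses a relaxed
        # majority vote (as in the constant extension)
        pres: dict[int, int] = {}
        for i in rows:
            for j in mat.row_cells(i):
                pres[j] = pres.get(j, 0) + 1
        frac = min(1.0 - max_noise, 0.55) if it == 0 else 1.0 - max_noise
        need = frac * len(rows)
        cand_cols = {j for j, c in pres.items() if c >= need} | set(bc.cols)
        # consensus order: mean normalized rank of each column across rows
        rank_sum: dict[int, float] = {j: 0.0 for j in cand_cols}
        rank_n: dict[int, int] = {j: 0 for j in cand_cols}
        for i in rows:
            values = mat.row_values(i)
            present = sorted((values[j], j) for j in cand_cols if j in values)
            if len(present) < 2:
                continue
            for r, (_, j) in enumerate(present):
                rank_sum[j] += r / (len(present) - 1)
                rank_n[j] += 1
        order = sorted(cand_cols,
                       key=lambda j: (rank_sum[j] / rank_n[j] if rank_n[j] else 0.5, j))
        # coarsen consensus ranks into co-occurrence groups of ~4 columns
        # (the n/4-rank convention): small consensus errors and value jitter
        # must not break the ordering of otherwise coherent rows
        groups = tuple(frozenset(order[k:k + 4])
                       for k in range(0, len(order), 4))
        # a qualifying row must contain nearly all pattern columns, so only
        # rows with enough presence need their ordering checked
        cidx = _np_col_cache(mat)
        empty = np.array([], dtype=np.int64)
        pres_rows = np.bincount(
            np.concatenate([cidx.get(j, (empty, empty))[0] for j in order])
            if order else empty, minlength=len(mat.rows))
        candidates = np.flatnonzero(pres_rows >= (1.0 - max_noise) * len(order))
        new_rows = {int(i) for i in candidates
                    if order_agreement(mat, int(i), groups) >= 1.0 - max_noise}
        # iterate on the agreement-selected core so spurious seed
        # supporters cannot poison the consensus; originals rejoin at the end
        if new_rows == rows and cand_cols == cols:
            rows, cols = new_rows, cand_cols
            break
        rows, cols = new_rows, cand_cols
    out = Bicluster(rows=frozenset(rows | set(bc.rows)), cols=frozenset(cols),
                    coherency="order_preserving", delta=bc.delta,
                    pattern=groups, merged_from=bc.merged_from)
    out.noise = module_mismatch(out, mat)
    return out


def reduce(bc: Bicluster, mat: ItemizedMatrix, max_noise: float = 0.0,
           explained: Optional[set[tuple[int, int]]] = None) -> Bicluster:
    """Remove rows, then columns, whose mismatch fraction exceeds ``max_noise``."""
    if bc.coherency == "order_preserving":
        groups = bc.pattern or (frozenset(bc.cols),)
        rows = frozenset(i for i in bc.rows
                         if order_agreement(mat, i, groups) >= 1.0 - max_noise)
        out = Bicluster(rows=rows, cols=bc.cols, coherency=bc.coherency,
                        delta=bc.delta, pattern=bc.pattern,
                        merged_from=bc.merged_from)
        out.noise = module_mismatch(out, mat)
        return out
    pattern = dict(bc.pattern or {})
    keep_rows = []
    for i in bc.rows:
        sign = (bc.signs or {}).get(i, 1)
        m, _ = row_profile(mat, i, pattern, sign, explained)
        if pattern and m >= (1.0 - max_noise) * len(pattern):
            keep_rows.append(i)
    keep_cols = []
    for j in bc.cols:
        kj = pattern.get(j)
        if kj is None:
            continue
        ok = 0
        for i in keep_rows:
            sign = (bc.signs or {}).get(i, 1)
            items = mat.row_cells(i).get(j)
            if items is not None and (
                    kj in tuple(sign * it for it in items)
                    or (explained and (i, j) in explained)):
                ok += 1
        if keep_rows and ok >= (1.0 - max_noise) * len(keep_rows):
            keep_cols.append(j)
    out = Bicluster(rows=frozenset(keep_rows), cols=frozenset(keep_cols),
                    coherency=bc.coherency, delta=bc.delta,
                    pattern={j: pattern[j] for j in keep_cols},
                    signs={i: (bc.signs or {}).get(i, 1) for i in keep_rows}
                    if bc.signs is not None else None,
                    merged_from=bc.merged_from)
    out.noise = module_mismatch(out, mat)
    return out
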