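"""Frequent-pattern miners over transactional and sequential databases.

Closed itemsets are mined with a vertical search using prefix-preserving
closure extensions (each closed set is generated exactly once from its
canonical parent); association patterns reuse the closed sets and relax
their supporters through single-item-consequent rules; order-preserving
structure is mined as closed "weak order" patterns — sequences of
co-occurrence groups where a row supports a pattern when its value ranking
never contradicts the pattern's group order.

Every miner is exact: on any database it enumerates all and only the
frequent (closed) patterns, which is what the brute-force oracle tests
assert.  For large sparse networks the callers bound the search with a node
budget and an emission cap; the traversal visits extensions in decreasing
support order, so truncation degrades to a support-greedy beam that still
surfaces the strongest patterns first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .model import Bicluster
from .preprocess import ANNOTATION, ItemizedMatrix, SequentialDB, Token, TransactionalDB


def _tok_key(t: Token) -> tuple:
    return (str(type(t).__name__), repr(t))


def is_annotation(t: Token) -> bool:
    return isinstance(t, tuple) and len(t) == 2 and t[0] == ANNOTATION


@dataclass(frozen=True)
class Pattern:
    """A frequent pattern and its exact supporting rows.

    ``items`` holds the token set of itemset/rule patterns; ``sequence``
    holds the ordered co-occurrence groups of sequence patterns.  ``rows``
    are positions in the source database (translate through ``db.row_ids``
    to matrix rows).
    """

    kind: str                      # itemset | rule | sequence
    rows: tuple[int, ...]
    items: frozenset = frozenset()
    sequence: tuple[frozenset, ...] = ()
    closed: bool = True

    @property
    def support(self) -> int:
        return len(self.rows)

    def all_tokens(self) -> frozenset:
        if self.kind == "sequence":
            return frozenset(t for g in self.sequence for t in g)
        return self.items

    def phi(self) -> list:
        """The expected-value multiset phi_B (annotation tokens excluded)."""
        toks = [t for t in self.all_tokens() if not is_annotation(t)]
        if self.kind == "sequence":
            return sorted(toks, key=_tok_key)
        return sorted((it for _, it in toks), key=lambda v: (str(type(v)), str(v)))

    def sort_key(self) -> tuple:
        body = tuple(sorted((_tok_key(t) for t in g)) for g in self.sequence) \
            if self.kind == "sequence" else tuple(sorted(_tok_key(t) for t in self.items))
        return (-self.support, body, self.rows)


def _resolve_support(min_support: float | int, n_rows: int) -> int:
    """Fractional thresholds in (0, 1] scale by the row count; ints are absolute."""
    if min_support <= 0:
        raise ValueError("min_support must be positive")
    if min_support <= 1:
        return max(1, math.ceil(min_support * n_rows - 1e-9))
    return int(min_support)


class _Budget:
    def __init__(self, nodes: Optional[int], patterns: Optional[int]):
        self.nodes = nodes if nodes is not None else float("inf")
        self.patterns = patterns if patterns is not None else float("inf")
        self.nodes_spent = 0
        self.exhausted = False

    def spend_node(self, k: int = 1) -> bool:
        self.nodes -= k
        self.nodes_spent += k
        if self.nodes < 0:
            self.exhausted = True
        return not self.exhausted

    def spend_pattern(self) -> bool:
        self.patterns -= 1
        if self.patterns < 0:
            self.exhausted = True
        return not self.exhausted


def _is_covered(tokens: Iterable, rows: Sequence[int],
                covered: Sequence[tuple[frozenset, frozenset]],
                tol: float = 0.0) -> bool:
    """True when the candidate's tokens lie inside a covered pattern and at
    most a fraction ``tol`` of its supporting rows fall outside it (sparse
    background coincidences add a few stray supporters to any real block)."""
    toks_list = list(tokens)
    rows_list = list(rows)
    slack = int(tol * len(rows_list))
    for toks, rws in covered:
        if all(t in toks for t in toks_list):
            outside = sum(1 for r in rows_list if r not in rws)
            if outside <= slack:
                return True
    return False


# ---------------------------------------------------------------------------
# closed frequent itemsets
# ---------------------------------------------------------------------------

class ItemsetMiningContext:
    """Reusable vertical-search state for one transactional database.

    Building the token universe, the per-token row lists and the pairwise
    co-support matrix dominates the cost of a single mining call; the
    iterative support loop re-mines the same database at many thresholds, so
    the engine builds this context once and mines per level.  ``base_floor``
    is the lowest absolute support the context can serve.
    """

    def __init__(self, db: TransactionalDB, base_floor: int = 2):
        self.n = len(db.transactions)
        self.base_floor = max(1, base_floor)
        supp_count: dict[Token, int] = {}
        for tr in db.transactions:
            for t in set(tr):
                supp_count[t] = supp_count.get(t, 0) + 1
        tokens = [t for t, c in supp_count.items() if c >= self.base_floor]
        tokens.sort(key=lambda t: (-supp_count[t], _tok_key(t)))
        self.tokens = tokens
        self.K = len(tokens)
        self.tok_id = {t: i for i, t in enumerate(tokens)}
        self.supports = np.array([supp_count[t] for t in tokens], dtype=np.int64)
        self.row_tokens = [
            np.array(sorted({self.tok_id[t] for t in tr if t in self.tok_id}),
                     dtype=np.int64)
            for tr in db.transactions]
        tid: list[list[int]] = [[] for _ in range(self.K)]
        for r, arr in enumerate(self.row_tokens):
            for j in arr:
                tid[j].append(r)
        self.tid = [np.array(lst, dtype=np.int64) for lst in tid]
        self._cooc = None
        self._max_co = None

    # -- pairwise co-supports -------------------------------------------------
    def cooc(self):
        """K x K co-support matrix (CSR, diagonal = token support)."""
        if self._cooc is None:
            from scipy import sparse
            indptr = [0]
            indices: list[int] = []
            for arr in self.row_tokens:
                indices.extend(int(j) for j in arr)
                indptr.append(len(indices))
            M = sparse.csr_matrix(
                (np.ones(len(indices), dtype=np.int32), indices, indptr),
                shape=(self.n, self.K))
            self._cooc = (M.T @ M).tocsr()
        return self._cooc

    def max_co_support(self) -> dict:
        """Largest co-support of each token with a token of a different
        column.  The two items of one boundary element co-occur strongly but
        cannot span a two-column module, so same-column pairs are excluded;
        this lets mining skip almost every background token."""
        if self._max_co is None:
            C = self.cooc()
            col_of = np.full(self.K, -1, dtype=np.int64)
            for t, i in self.tok_id.items():
                if isinstance(t, tuple) and len(t) == 2 and isinstance(t[0], int):
                    col_of[i] = t[0]
            maxima = np.zeros(self.K, dtype=np.int64)
            for i in range(self.K):
                lo, hi = C.indptr[i], C.indptr[i + 1]
                idx = C.indices[lo:hi]
                dat = C.data[lo:hi]
                keep = (idx != i) & ((col_of[idx] != col_of[i]) | (col_of[i] < 0))
                if keep.any():
                    maxima[i] = int(dat[keep].max())
            self._max_co = {t: int(maxima[i]) for t, i in self.tok_id.items()}
        return self._max_co

    def _cooc_row(self, x: int) -> np.ndarray:
        C = self.cooc()
        out = np.zeros(self.K, dtype=np.int64)
        lo, hi = C.indptr[x], C.indptr[x + 1]
        out[C.indices[lo:hi]] = C.data[lo:hi]
        return out

    # -- the search -----------------------------------------------------------
    def mine(
        self,
        minsup: int,
        *,
        anti_monotone: Optional[Callable[[list], bool]] = None,
        node_budget: Optional[int] = None,
        max_patterns: Optional[int] = None,
        covered: Sequence[tuple[frozenset, frozenset]] = (),
        covered_tol: float = 0.0,
        self_prune: bool = False,
        min_items: int = 1,
        use_max_co: bool = False,
        stats_out: Optional[dict] = None,
    ) -> list[Pattern]:
        n, K, tokens, tid = self.n, self.K, self.tokens, self.tid
        if K == 0 or minsup > n:
            return []
        if minsup < self.base_floor:
            raise ValueError("minsup below the context's base floor")
        budget = _Budget(node_budget, max_patterns)
        max_co = self.max_co_support() if (use_max_co and min_items >= 2) else None

        results: list[Pattern] = []
        prune_list: list[tuple[frozenset, frozenset]] = list(covered)

        def phi_of(mask: np.ndarray, extra: Optional[int] = None) -> list:
            ids = list(np.flatnonzero(mask))
            if extra is not None:
                ids.append(extra)
            return [tokens[i][1] for i in ids
                    if not is_annotation(tokens[i]) and isinstance(tokens[i], tuple)]

        def emit(mask: np.ndarray, rows: np.ndarray) -> bool:
            if int(mask.sum()) < min_items:
                return True
            if not budget.spend_pattern():
                return False
            items = frozenset(tokens[i] for i in np.flatnonzero(mask))
            results.append(Pattern(kind="itemset", items=items,
                                   rows=tuple(int(r) for r in rows)))
            if self_prune and len(items) >= 4:
                prune_list.append((items, frozenset(int(r) for r in rows)))
            return True

        def counts_of(rows: np.ndarray) -> np.ndarray:
            if len(rows) == 0:
                return np.zeros(K, dtype=np.int64)
            flat = np.concatenate([self.row_tokens[r] for r in rows])
            return np.bincount(flat, minlength=K)

        def expand(c_mask: np.ndarray, rows: np.ndarray, counts: np.ndarray,
                   core: int = -1) -> None:
            if budget.exhausted:
                return
            cand = np.flatnonzero((counts >= minsup) & ~c_mask)
            cand = cand[cand > core]  # prefix-preserving closure: unique parents
            # decreasing projected support => strongest extensions first
            cand = cand[np.argsort(-counts[cand], kind="stable")]
            depth = int(c_mask.sum())
            at_root = len(rows) == n
            for x in cand:
                if at_root and max_co is not None \
                        and max_co.get(tokens[x], 0) < minsup:
                    continue
                if not budget.spend_node():
                    return
                if anti_monotone is not None \
                        and not anti_monotone(phi_of(c_mask, int(x))):
                    continue
                if at_root:
                    t2 = tid[x]
                else:
                    t2 = np.intersect1d(rows, tid[x], assume_unique=True)
                if len(t2) < minsup:
                    continue
                if prune_list and (depth <= 2 or self_prune) and _is_covered(
                        [tokens[i] for i in np.flatnonzero(c_mask)] + [tokens[x]],
                        t2, prune_list, covered_tol):
                    continue
                # at the root the projected counts are exactly one row of the
                # co-support matrix; deeper nodes count over their rows
                counts2 = self._cooc_row(int(x)) if at_root else counts_of(t2)
                closure = counts2 == len(t2)
                # prefix-preserving check: no new closure item ranked before x
                if not np.array_equal(closure[:x], c_mask[:x]):
                    continue
                # the closure may absorb items beyond the candidate; a failing
                # closure fails in every superset, so the whole branch goes
                if anti_monotone is not None and not anti_monotone(phi_of(closure)):
                    continue
                if not emit(closure, t2):
                    return
                expand(closure, t2, counts2, core=int(x))
                if budget.exhausted:
                    return

        all_rows = np.arange(n, dtype=np.int64)
        root_counts = self.supports.copy()
        root_mask = root_counts == n
        if root_mask.any() and n >= minsup and (
                anti_monotone is None or anti_monotone(phi_of(root_mask))):
            emit(root_mask, all_rows)
        expand(root_mask, all_rows, root_counts)
        if stats_out is not None:
            stats_out["candidates"] = budget.nodes_spent
        results.sort(key=Pattern.sort_key)
        return results


def mine_closed_itemsets(
    db: TransactionalDB,
    min_support: float | int,
    *,
    anti_monotone: Optional[Callable[[list], bool]] = None,
    node_budget: Optional[int] = None,
    max_patterns: Optional[int] = None,
    covered: Sequence[tuple[frozenset, frozenset]] = (),
    covered_tol: float = 0.0,
    self_prune: bool = False,
    min_items: int = 1,
    max_co_support: Optional[dict] = None,
) -> list[Pattern]:
    """All and only closed frequent itemsets, with exact supporting rows.

    ``anti_monotone`` is an optional pushable predicate over the pattern's
    value multiset: a branch is pruned as soon as the candidate fails it,
    which cannot change the (post-filtered) output because failures are
    inherited by supersets.  ``covered`` short-circuits branches whose
    tokens and supporters are already inside an accepted module;
    ``self_prune`` additionally skips branches subsumed (within
    ``covered_tol``) by a pattern already emitted in this call — the
    similarity computation pushed into the mining step.  Both prunes are
    lossy relaxations and stay off by default, keeping the search exact.
    ``min_items`` suppresses the emission (not the exploration) of smaller
    patterns.  Iterative callers should build an :class:`ItemsetMiningContext`
    once and mine per support level.
    """
    n = len(db.transactions)
    if n == 0:
        return []
    minsup = _resolve_support(min_support, n)
    if minsup > n:
        return []
    ctx = ItemsetMiningContext(db, base_floor=minsup)
    return ctx.mine(minsup, anti_monotone=anti_monotone,
                    node_budget=node_budget, max_patterns=max_patterns,
                    covered=covered, covered_tol=covered_tol,
                    self_prune=self_prune, min_items=min_items,
                    use_max_co=max_co_support is not None)


# ---------------------------------------------------------------------------
# association patterns (noise-tolerant supporters)
# ---------------------------------------------------------------------------

def mine_association_patterns(
    db: TransactionalDB,
    min_support: float | int,
    min_confidence: float = 0.5,
    **mine_kwargs,
) -> list[Pattern]:
    """Noise-tolerant patterns from single-consequent association rules.

    For each closed frequent itemset ``Z`` and item ``y`` in ``Z``, the rule
    ``Z\\{y} => y`` with confidence ``supp(Z)/supp(Z\\{y})`` at or above
    ``min_confidence`` contributes the antecedent's supporting rows, so a
    row missing one item of ``Z`` may still support the pattern.  At
    ``min_confidence = 1`` this reduces exactly to the closed itemsets.
    """
    if not 0 < min_confidence <= 1:
        raise ValueError("min_confidence must lie in (0, 1]")
    closed = mine_closed_itemsets(db, min_support, **mine_kwargs)
    if not closed:
        return []

    tidsets: dict[Token, set[int]] = {}
    for r, tr in enumerate(db.transactions):
        for t in set(tr):
            tidsets.setdefault(t, set()).add(r)

    out = []
    for pat in closed:
        rows = set(pat.rows)
        if len(pat.items) >= 2 and min_confidence < 1:
            for y in pat.items:
                ante = pat.items - {y}
                ante_rows = set.intersection(*(tidsets[t] for t in ante))
                conf = pat.support / len(ante_rows)
                if conf >= min_confidence:
                    rows |= ante_rows
        out.append(Pattern(kind="rule", items=pat.items,
                           rows=tuple(sorted(rows))))
    out.sort(key=Pattern.sort_key)
    return out


# ---------------------------------------------------------------------------
# closed sequences (weak orders with co-occurrence groups)
# ---------------------------------------------------------------------------

def seq_contains(big: Sequence[frozenset], small: Sequence[frozenset]) -> bool:
    """Standard sequence containment: ``small``'s groups embed into distinct
    groups of ``big`` in order, each as a subset (ties map into one tied
    element)."""
    i = 0
    for g in small:
        while i < len(big) and not g <= big[i]:
            i += 1
        if i == len(big):
            return False
        i += 1
    return True


def mine_sequences(
    db: SequentialDB,
    min_support: float | int,
    *,
    node_budget: Optional[int] = None,
    max_patterns: Optional[int] = None,
    covered: Sequence[tuple[frozenset, frozenset]] = (),
    covered_tol: float = 0.0,
    self_prune: bool = False,
    min_items: int = 1,
    max_co_support: Optional[dict] = None,
    stats_out: Optional[dict] = None,
) -> list[Pattern]:
    """Closed frequent sequences (with co-occurrence groups) and supporters.

    A pattern is an ordered tuple of groups; a row supports it when each
    group maps into a single (tied) element of the row and the mapped
    elements occur in strictly increasing order.  Sequential databases built
    from networks contain each column exactly once per row, which the
    support bookkeeping relies on.  A pattern is closed when no equally
    supported super-sequence exists.
    """
    n = len(db.sequences)
    if n == 0:
        return []
    minsup = _resolve_support(min_support, n)
    if minsup > n:
        return []
    budget = _Budget(node_budget, max_patterns)

    # element index of each token within each row (tokens are unique per row)
    rank: list[dict[Token, int]] = []
    for seq in db.sequences:
        m: dict[Token, int] = {}
        for g_idx, grp in enumerate(seq):
            for t in grp:
                m[t] = g_idx
        rank.append(m)

    supp_count: dict[Token, int] = {}
    for m in rank:
        for t in m:
            supp_count[t] = supp_count.get(t, 0) + 1
    tokens = [t for t, s in supp_count.items() if s >= minsup]
    tokens.sort(key=lambda t: (-supp_count[t], _tok_key(t)))
    tok_rank = {t: i for i, t in enumerate(tokens)}

    raw: list[Pattern] = []
    prune_list: list[tuple[frozenset, frozenset]] = list(covered)

    # supporter state per row: (row, element index matched by the last group)
    def extend(pattern: list[frozenset], state: list[tuple[int, int]]) -> None:
        if budget.exhausted:
            return
        last_max_id = max(tok_rank[t] for t in pattern[-1])
        n_items = sum(len(g) for g in pattern)

        options = []
        for t in tokens:
            if any(t in g for g in pattern):
                continue
            rk_t = rank
            # I-step: token joins the last group (same tied element);
            # canonical generation adds group members in ascending id order
            if tok_rank[t] > last_max_id:
                st = [(r, e) for r, e in state if rk_t[r].get(t) == e]
                if len(st) >= minsup:
                    options.append(("I", t, st))
            # S-step: token starts a new, strictly later group
            st = []
            for r, e in state:
                e2 = rk_t[r].get(t)
                if e2 is not None and e2 > e:
                    st.append((r, e2))
            if len(st) >= minsup:
                options.append(("S", t, st))

        options.sort(key=lambda o: (-len(o[2]), o[0], _tok_key(o[1])))
        for step, t, new_state in options:
            if not budget.spend_node():
                return
            if step == "I":
                new_pattern = pattern[:-1] + [pattern[-1] | {t}]
            else:
                new_pattern = pattern + [frozenset([t])]
            rows = tuple(r for r, _ in new_state)
            if prune_list and (n_items + 1 <= 2 or self_prune) and _is_covered(
                    [tok for g in new_pattern for tok in g], rows,
                    prune_list, covered_tol):
                continue
            if n_items + 1 >= min_items:
                if not budget.spend_pattern():
                    return
                raw.append(Pattern(kind="sequence", sequence=tuple(new_pattern),
                                   rows=rows))
                if self_prune and n_items + 1 >= 4:
                    prune_list.append(
                        (frozenset(t for g in new_pattern for t in g),
                         frozenset(rows)))
            extend(new_pattern, new_state)
            if budget.exhausted:
                return

    for t in tokens:
        if (min_items >= 2 and max_co_support is not None
                and max_co_support.get(t, 0) < minsup):
            continue
        state = [(r, rank[r][t]) for r in range(n) if t in rank[r]]
        if len(state) < minsup:
            continue
        if min_items <= 1:
            if not budget.spend_pattern():
                break
            raw.append(Pattern(kind="sequence", sequence=(frozenset([t]),),
                               rows=tuple(r for r, _ in state)))
        extend([frozenset([t])], state)
        if budget.exhausted:
            break

    if stats_out is not None:
        stats_out["candidates"] = budget.nodes_spent
    # closedness: equal support implies equal supporting rows, so subsumption
    # only needs checking inside same-rows buckets
    by_rows: dict[tuple, list[Pattern]] = {}
    for p in raw:
        by_rows.setdefault(p.rows, []).append(p)
    out = []
    for group in by_rows.values():
        for p in group:
            if not any(q is not p and q.sequence != p.sequence
                       and seq_contains(q.sequence, p.sequence) for q in group):
                out.append(p)
    out.sort(key=Pattern.sort_key)
    return out


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Constraint:
    """A declarative predicate over the pattern phi_B.

    ``kind`` follows the classical taxonomy: succinct constraints rewrite
    the database or filter directly; anti-monotone constraints may be pushed
    into candidate growth (``pushable``); monotone and convertible ones are
    checked post-hoc.
    """

    name: str
    kind: str  # succinct | monotone | anti_monotone | convertible
    predicate: Callable[[list], bool]
    remove: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in ("succinct", "monotone", "anti_monotone", "convertible"):
            raise ValueError(f"unknown constraint kind {self.kind!r}")

    @property
    def pushable(self) -> bool:
        return self.kind == "anti_monotone"


def remove_items_constraint(values: Iterable) -> Constraint:
    vals = frozenset(values)
    return Constraint(name=f"remove({sorted(map(str, vals))})", kind="succinct",
                      predicate=lambda phi: not any(v in vals for v in phi),
                      remove=vals)


def count_val_min(k: int) -> Constraint:
    return Constraint(name=f"countVal>={k}", kind="monotone",
                      predicate=lambda phi: len(set(phi)) >= k)


def avg_max(c: float) -> Constraint:
    return Constraint(name=f"avg<={c}", kind="convertible",
                      predicate=lambda phi: bool(phi) and sum(phi) / len(phi) <= c)


def must_include(values: Iterable) -> Constraint:
    vals = frozenset(values)
    return Constraint(name=f"include({sorted(map(str, vals))})", kind="succinct",
                      predicate=lambda phi: vals <= set(phi))


def extrema(min_item=None, max_item=None) -> Constraint:
    return Constraint(
        name=f"min={min_item},max={max_item}", kind="succinct",
        predicate=lambda phi: bool(phi)
        and (min_item is None or min(phi) == min_item)
        and (max_item is None or max(phi) == max_item))


def max_items_from(values: Iterable, k: int) -> Constraint:
    vals = frozenset(values)
    return Constraint(name=f"|phi&{sorted(map(str, vals))}|<={k}", kind="anti_monotone",
                      predicate=lambda phi: sum(1 for v in phi if v in vals) <= k)


def constraints_from_config(cfg: dict) -> list[Constraint]:
    """Build constraints from the config mapping used by the CLI/YAML surface."""
    out = []
    if "remove" in cfg:
        out.append(remove_items_constraint(cfg["remove"]))
    if "count_val_min" in cfg:
        out.append(count_val_min(int(cfg["count_val_min"])))
    if "avg_max" in cfg:
        out.append(avg_max(float(cfg["avg_max"])))
    if "must_include" in cfg:
        out.append(must_include(cfg["must_include"]))
    if "min_item" in cfg or "max_item" in cfg:
        out.append(extrema(cfg.get("min_item"), cfg.get("max_item")))
    return out


def remove_items(db: TransactionalDB, values: Iterable) -> TransactionalDB:
    """Succinct remove(S): delete tokens whose item value lies in S pre-mining."""
    vals = set(values)
    txs, ids = [], []
    for tr, rid in zip(db.transactions, db.row_ids):
        kept = [t for t in tr
                if is_annotation(t) or not (isinstance(t, tuple) and t[1] in vals)]
        if kept:
            txs.append(kept)
            ids.append(rid)
    return TransactionalDB(txs, ids, db.n_rows_total, db.n_cols)


def apply_constraints(patterns: Sequence[Pattern],
                      constraints: Sequence[Constraint]) -> list[Pattern]:
    """Post-hoc filtering; identical in outcome to pushing anti-monotone
    constraints into growth (pushing is an optimization only)."""
    out = []
    for p in patterns:
        phi = p.phi()
        if all(c.predicate(phi) for c in constraints):
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# pattern -> candidate bicluster
# ---------------------------------------------------------------------------

def pattern_to_bicluster(pat: Pattern, db, mat: ItemizedMatrix,
                         coherency: Optional[str] = None) -> Bicluster:
    """Map a mined pattern to its candidate module.

    ``I`` is the supporting rows (translated to matrix indexes), ``J`` the
    columns named in phi_B; the coherency is inherited from the miner kind
    unless overridden.  Patterns referencing only annotation tokens carry no
    columns and are rejected.
    """
    rows = frozenset(db.row_ids[r] for r in pat.rows)
    if pat.kind == "sequence":
        groups = tuple(frozenset(t for t in g if not is_annotation(t))
                       for g in pat.sequence)
        groups = tuple(g for g in groups if g)
        cols = frozenset(t for g in groups for t in g)
        if not cols:
            raise ValueError("pattern references annotation tokens only")
        return Bicluster(rows=rows, cols=cols,
                         coherency=coherency or "order_preserving",
                         delta=mat.delta, pattern=groups)
    cells: dict = {}
    for c, it in sorted((t for t in pat.items if not is_annotation(t)), key=_tok_key):
        # multi-item closures can carry two adjacent items for one column;
        # keep the deterministically smaller one as the expected value
        if c not in cells or it < cells[c]:
            cells[c] = it
    if not cells:
        raise ValueError("pattern references annotation tokens only")
    return Bicluster(rows=rows, cols=frozenset(cells),
                     coherency=coherency or "constant",
                     delta=mat.delta, pattern=cells)
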