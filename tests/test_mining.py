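"""Miners checked against brute-force enumeration oracles.

The oracles enumerate every candidate itemset / rule / sequence explicitly
and are deliberately independent of the vertical / prefix-growth searches
they validate.
"""

from itertools import combinations

import numpy as np
import pytest

from netbiclust.mining import (
    Pattern,
    apply_constraints,
    avg_max,
    count_val_min,
    extrema,
    max_items_from,
    mine_association_patterns,
    mine_closed_itemsets,
    mine_sequences,
    must_include,
    pattern_to_bicluster,
    remove_items,
    remove_items_constraint,
    seq_contains,
)
from netbiclust.preprocess import (
    DiscretizationScheme,
    ItemizedMatrix,
    SequentialDB,
    TransactionalDB,
    discretize,
)
from netbiclust.network import AdjacencyView


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_closed_itemsets(transactions, minsup):
    items = sorted({t for tr in transactions for t in tr}, key=repr)
    freq = {}
    for k in range(1, len(items) + 1):
        for sub in combinations(items, k):
            rows = tuple(i for i, tr in enumerate(transactions) if set(sub) <= set(tr))
            if len(rows) >= minsup:
                freq[frozenset(sub)] = rows
    return {s: r for s, r in freq.items()
            if not any(s < s2 and len(r2) == len(r) for s2, r2 in freq.items())}


def brute_association(transactions, minsup, minconf):
    closed = brute_closed_itemsets(transactions, minsup)
    out = {}
    for z, z_rows in closed.items():
        rows = set(z_rows)
        if len(z) >= 2 and minconf < 1:
            for y in z:
                ante = z - {y}
                ante_rows = {i for i, tr in enumerate(transactions) if ante <= set(tr)}
                if len(z_rows) / len(ante_rows) >= minconf:
                    rows |= ante_rows
        out[z] = tuple(sorted(rows))
    return out


def _row_supports(seq, pattern):
    """Exact containment check: groups map into distinct tied elements in order."""
    idx = {}
    for e, grp in enumerate(seq):
        for t in grp:
            idx[t] = e
    prev = -1
    for grp in pattern:
        positions = {idx.get(t) for t in grp}
        if None in positions or len(positions) != 1:
            return False
        (e,) = positions
        if e <= prev:
            return False
        prev = e
    return True


def brute_closed_sequences(sequences, minsup):
    """Enumerate every ordered partition of every token subset."""
    tokens = sorted({t for s in sequences for g in s for t in g}, key=repr)

    def ordered_partitions(sub):
        if not sub:
            yield ()
            return
        rest = list(sub)
        n = len(rest)
        for mask in range(1, 1 << n):
            first = frozenset(rest[i] for i in range(n) if mask >> i & 1)
            remainder = [rest[i] for i in range(n) if not mask >> i & 1]
            for tail in ordered_partitions(remainder):
                yield (first,) + tail

    freq = {}
    for k in range(1, len(tokens) + 1):
        for sub in combinations(tokens, k):
            for pat in ordered_partitions(sub):
                rows = tuple(i for i, s in enumerate(sequences) if _row_supports(s, pat))
                if len(rows) >= minsup:
                    freq[pat] = rows
    closed = {}
    for p, rows in freq.items():
        subsumed = any(p != q and len(r2) == len(rows) and seq_contains(q, p)
                       for q, r2 in freq.items())
        if not subsumed:
            closed[p] = rows
    return closed


def random_transactions(rng, max_rows=8, max_items=6):
    n = int(rng.integers(1, max_rows + 1))
    alphabet = [chr(65 + i) for i in range(int(rng.integers(2, max_items + 1)))]
    return [
        sorted(rng.choice(alphabet,
                          size=int(rng.integers(1, len(alphabet) + 1)),
                          replace=False))
        for _ in range(n)
    ]


def random_sequences(rng, max_rows=8, max_items=4):
    n = int(rng.integers(1, max_rows + 1))
    alphabet = [chr(97 + i) for i in range(int(rng.integers(2, max_items + 1)))]
    seqs = []
    for _ in range(n):
        k = int(rng.integers(1, len(alphabet) + 1))
        toks = list(rng.choice(alphabet, size=k, replace=False))
        groups, cur = [], [toks[0]]
        for t in toks[1:]:
            if rng.random() < 0.3:
                cur.append(t)
            else:
                groups.append(frozenset(cur))
                cur = [t]
        groups.append(frozenset(cur))
        seqs.append(groups)
    return seqs


def as_tdb(transactions):
    return TransactionalDB([list(t) for t in transactions],
                           list(range(len(transactions))), len(transactions), 0)


def as_sdb(sequences):
    return SequentialDB([list(s) for s in sequences],
                        list(range(len(sequences))), len(sequences), 0)


# ---------------------------------------------------------------------------
# closed itemsets
# ---------------------------------------------------------------------------

class TestClosedItemsets:
    def test_spec_example(self):
        pats = mine_closed_itemsets(as_tdb([["A", "B"], ["A", "B"], ["A", "C"]]), 2)
        got = {frozenset(p.items): p.rows for p in pats}
        assert got == {frozenset("A"): (0, 1, 2), frozenset("AB"): (0, 1)}

    def test_single_transaction_minsup_one(self):
        pats = mine_closed_itemsets(as_tdb([["A", "B", "C"]]), 1)
        assert len(pats) == 1 and pats[0].items == frozenset("ABC")

    def test_minsup_above_db_size_empty(self):
        assert mine_closed_itemsets(as_tdb([["A"], ["A"]]), 5) == []

    def test_empty_db(self):
        assert mine_closed_itemsets(as_tdb([]), 2) == []

    def test_matches_brute_force_on_random_dbs(self, rng):
        for _ in range(250):
            txs = random_transactions(rng)
            minsup = int(rng.integers(1, len(txs) + 1))
            expect = brute_closed_itemsets(txs, minsup)
            pats = mine_closed_itemsets(as_tdb(txs), minsup / len(txs))
            assert len({p.items for p in pats}) == len(pats)  # no duplicates
            got = {p.items: p.rows for p in pats}
            assert got == {s: r for s, r in expect.items()}

    def test_support_monotonicity(self, rng):
        for _ in range(30):
            txs = random_transactions(rng)
            low = {p.items
                   for p in mine_closed_itemsets(as_tdb(txs), 1 / len(txs))}
            high = {p.items
                    for p in mine_closed_itemsets(as_tdb(txs), min(2, len(txs)))}
            assert high <= low

    def test_deterministic_order(self, rng):
        txs = random_transactions(rng)
        a = mine_closed_itemsets(as_tdb(txs), 1 / len(txs))
        b = mine_closed_itemsets(as_tdb(txs), 1 / len(txs))
        assert [(p.items, p.rows) for p in a] == [(p.items, p.rows) for p in b]


# ---------------------------------------------------------------------------
# association patterns
# ---------------------------------------------------------------------------

class TestAssociationPatterns:
    def test_spec_example_low_confidence_rule(self):
        pats = mine_association_patterns(
            as_tdb([["A", "B", "C"], ["A", "B", "C"], ["A", "B"]]), 2, 0.6)
        got = {p.items: p.rows for p in pats}
        # AB=>C holds at confidence 2/3, so the ABC pattern gains row 2
        assert got[frozenset("ABC")] == (0, 1, 2)

    def test_confidence_one_reduces_to_closed_itemsets(self, rng):
        for _ in range(50):
            txs = random_transactions(rng)
            closed = {p.items: p.rows for p in mine_closed_itemsets(as_tdb(txs), 2)}
            rules = {p.items: p.rows
                     for p in mine_association_patterns(as_tdb(txs), 2, 1.0)}
            assert closed == rules

    def test_confidence_above_one_is_error(self):
        with pytest.raises(ValueError):
            mine_association_patterns(as_tdb([["A"]]), 1, 1.5)

    def test_matches_brute_force(self, rng):
        for _ in range(150):
            txs = random_transactions(rng)
            minsup = int(rng.integers(1, len(txs) + 1))
            conf = float(rng.choice([0.4, 0.6, 0.8]))
            expect = brute_association(txs, minsup, conf)
            got = {p.items: p.rows
                   for p in mine_association_patterns(as_tdb(txs),
                                                      minsup / len(txs), conf)}
            assert got == expect


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

class TestSequences:
    def test_identical_rows_give_maximal_chain(self):
        rows = [[frozenset("x"), frozenset("y"), frozenset("z")]] * 2
        pats = mine_sequences(as_sdb(rows), 2)
        best = max(pats, key=lambda p: len(p.sequence))
        assert best.sequence == (frozenset("x"), frozenset("y"), frozenset("z"))
        assert best.rows == (0, 1)

    def test_opposite_orders_leave_singletons(self):
        rows = [[frozenset("a"), frozenset("b")], [frozenset("b"), frozenset("a")]]
        pats = mine_sequences(as_sdb(rows), 2)
        assert {p.sequence for p in pats} == {(frozenset("a"),), (frozenset("b"),)}

    def test_minsup_one_yields_each_full_row(self):
        rows = [[frozenset("a"), frozenset("b")], [frozenset("c")]]
        pats = mine_sequences(as_sdb(rows), 1 / len(rows))
        seqs = {p.sequence for p in pats}
        assert (frozenset("a"), frozenset("b")) in seqs
        assert (frozenset("c"),) in seqs

    def test_empty_db(self):
        assert mine_sequences(as_sdb([]), 1) == []

    def test_matches_brute_force_on_random_dbs(self, rng):
        for _ in range(150):
            seqs = random_sequences(rng)
            minsup = int(rng.integers(1, len(seqs) + 1))
            expect = brute_closed_sequences(seqs, minsup)
            got = {p.sequence: p.rows
                   for p in mine_sequences(as_sdb(seqs), minsup / len(seqs))}
            assert got == expect


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------

def make_item_db():
    # tokens are (col, item) as produced by build_transactions
    rows = [
        [(0, -2), (1, 2), (2, 3)],
        [(0, -2), (1, 2), (2, 3)],
        [(0, -1), (1, 1), (2, 0)],
    ]
    return as_tdb(rows)


class TestConstraints:
    def test_succinct_remove_deletes_items_before_mining(self):
        db = remove_items(make_item_db(), {-1, 0, 1})
        pats = mine_closed_itemsets(db, 1 / 3)
        for p in pats:
            assert all(item not in {-1, 0, 1} for _, item in p.items)

    def test_count_val_min_rejects_two_distinct_items(self):
        p = Pattern(kind="itemset", items=frozenset([(0, 2), (1, 2), (2, 3)]),
                    rows=(0,))
        assert apply_constraints([p], [count_val_min(3)]) == []
        assert apply_constraints([p], [count_val_min(2)]) == [p]

    def test_avg_max_accepts_negative_mean(self):
        p = Pattern(kind="itemset", items=frozenset([(0, -2), (1, 1)]), rows=(0,))
        assert apply_constraints([p], [avg_max(0)]) == [p]
        assert apply_constraints([p], [avg_max(-1)]) == []

    def test_extrema_and_must_include(self):
        p = Pattern(kind="itemset", items=frozenset([(0, -3), (1, 3)]), rows=(0,))
        assert apply_constraints([p], [extrema(-3, 3)]) == [p]
        assert apply_constraints([p], [must_include({-3})]) == [p]
        assert apply_constraints([p], [must_include({5})]) == []

    def test_anti_monotone_pushdown_equals_posthoc(self, rng):
        for _ in range(40):
            txs = [[(j, int(rng.integers(-2, 3)))
                    for j in range(int(rng.integers(1, 5)))]
                   for _ in range(int(rng.integers(1, 7)))]
            con = max_items_from({-2, -1}, 1)
            frac = 1 / len(txs)
            pushed = mine_closed_itemsets(as_tdb(txs), frac,
                                          anti_monotone=con.predicate)
            posthoc = apply_constraints(
                mine_closed_itemsets(as_tdb(txs), frac), [con])
            assert {p.items for p in pushed} == {p.items for p in posthoc}

    def test_anti_monotone_property_holds_on_subsets(self, rng):
        con = max_items_from({-2, -1}, 1)
        for _ in range(50):
            phi = [int(v) for v in rng.integers(-2, 3, size=5)]
            if con.predicate(phi):
                for k in range(len(phi)):
                    assert con.predicate(phi[:k] + phi[k + 1:])

    def test_remove_constraint_predicate(self):
        c = remove_items_constraint({-1, 0, 1})
        assert c.predicate([-2, 2]) and not c.predicate([-2, 0])


# ---------------------------------------------------------------------------
# pattern -> bicluster
# ---------------------------------------------------------------------------

def tiny_matrix():
    view = AdjacencyView(
        [f"x{i}" for i in range(5)], [f"y{j}" for j in range(5)],
        [[(0, -1.2), (3, 1.3)] for _ in range(5)])
    return discretize(view, DiscretizationScheme(multi_item_fraction=0.0))


class TestPatternToBicluster:
    def test_itemset_pattern_maps_to_constant_module(self):
        mat = tiny_matrix()
        from netbiclust.preprocess import build_transactions
        db = build_transactions(mat)
        pat = Pattern(kind="itemset", items=frozenset([(0, 2), (3, 2)]),
                      rows=(0, 1, 4))
        bc = pattern_to_bicluster(pat, db, mat)
        assert bc.rows == frozenset({0, 1, 4})
        assert bc.cols == frozenset({0, 3})
        assert bc.coherency == "constant"
        assert bc.delta == pytest.approx(1 / 3)

    def test_sequence_pattern_maps_to_order_preserving(self):
        mat = tiny_matrix()
        from netbiclust.preprocess import build_sequences
        db = build_sequences(mat)
        pat = Pattern(kind="sequence",
                      sequence=(frozenset({0}), frozenset({3})), rows=(0, 2))
        bc = pattern_to_bicluster(pat, db, mat)
        assert bc.coherency == "order_preserving"
        assert bc.cols == frozenset({0, 3})
        assert bc.pattern == (frozenset({0}), frozenset({3}))

    def test_annotation_only_pattern_rejected(self):
        mat = tiny_matrix()
        from netbiclust.preprocess import build_transactions
        db = build_transactions(mat)
        pat = Pattern(kind="itemset",
                      items=frozenset([("#", "T1"), ("#", "T2")]), rows=(0, 1))
        with pytest.raises(ValueError, match="annotation"):
            pattern_to_bicluster(pat, db, mat)
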