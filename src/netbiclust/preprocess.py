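"""Normalization, discretization and itemization of adjacency views.

Real-valued interaction weights are mapped to a small signed item alphabet
(size ``|L|``, odd; coherency strength ``delta = 1/|L|``) by overall
Gaussian discretization: cut points sit at the ``|L|``-quantiles of a
normal distribution fitted to the present values.  Values falling within a
boundary fraction (default 25%) of a cut point receive the two adjacent
items, which absorbs discretization noise.  From the itemized matrix,
transactional databases (one transaction of ``(column, item)`` tokens per
row node) and sequential databases (columns ordered by value, ties grouped
as co-occurrences) are built in time and memory proportional to the number
of interactions.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Hashable, Sequence, Union

import numpy as np
from scipy import stats

from .network import AdjacencyView

# annotation tokens are namespaced so they can never collide with (col, item)
ANNOTATION = "#"

Token = Hashable


class DegenerateValueError(ValueError):
    """Raised when the weight distribution cannot support quantile cuts."""


@dataclass(frozen=True)
class DiscretizationScheme:
    """Parameters of the itemization step.

    ``alphabet_size`` must be odd so the item alphabet is symmetric around
    zero (items ``-(|L|//2) .. |L|//2``); ``delta = 1/|L|`` is the implied
    coherency strength.  ``multi_item_fraction`` is the relative distance to
    a cut point below which an element receives the adjacent item as well.
    ``outlier_z`` clamps extreme z-scores before the quantile fit so that
    outliers cannot stretch the cut points (clamping rather than removal
    preserves node degrees).
    """

    alphabet_size: int = 3
    multi_item_fraction: float = 0.25
    normalization: str = "zero_mean_rows"
    outlier_z: float = 3.0

    def __post_init__(self) -> None:
        if self.alphabet_size < 2:
            raise ValueError("alphabet_size must be >= 2")
        if self.alphabet_size % 2 == 0:
            raise ValueError("alphabet_size must be odd for a signed alphabet")
        if not 0.0 <= self.multi_item_fraction < 0.5:
            raise ValueError("multi_item_fraction must lie in [0, 0.5)")

    @property
    def delta(self) -> float:
        return 1.0 / self.alphabet_size

    @property
    def items(self) -> tuple[int, ...]:
        h = self.alphabet_size // 2
        return tuple(range(-h, h + 1))


@dataclass
class ItemizedMatrix:
    """Discretized sparse adjacency view; an element may hold 1 or 2 items.

    ``rows[i]`` lists ``(col, items, raw_value)`` with ``items`` a tuple of
    one or two adjacent alphabet symbols (two only for values inside the
    multi-item boundary fraction of a cut point).  ``raw_value`` keeps the
    provenance link to the (normalized) weight, which the plaid search needs
    to test additive explanations.
    """

    row_nodes: list[str]
    col_nodes: list[str]
    rows: list[list[tuple[int, tuple[int, ...], float]]]
    alphabet: tuple[int, ...]
    delta: float
    cut_points: tuple[float, ...] = ()
    labeled: bool = False
    label_map: dict[str, int] = field(default_factory=dict)
    symmetric: bool = False

    def __post_init__(self) -> None:
        for lst in self.rows:
            for _, items, _ in lst:
                assert 1 <= len(items) <= 2
                if len(items) == 2:
                    assert abs(items[0] - items[1]) == 1, "multi-items must be adjacent"

    def shape(self) -> tuple[int, int]:
        return len(self.row_nodes), len(self.col_nodes)

    @property
    def n_elements(self) -> int:
        return sum(len(r) for r in self.rows)

    @property
    def n_tokens(self) -> int:
        return sum(len(items) for r in self.rows for _, items, _ in r)

    def row_cells(self, i: int) -> dict[int, tuple[int, ...]]:
        cache = getattr(self, "_cells_cache", None)
        if cache is None:
            cache = [None] * len(self.rows)
            self._cells_cache = cache
        if cache[i] is None:
            cache[i] = {c: items for c, items, _ in self.rows[i]}
        return cache[i]

    def row_values(self, i: int) -> dict[int, float]:
        cache = getattr(self, "_values_cache", None)
        if cache is None:
            cache = [None] * len(self.rows)
            self._values_cache = cache
        if cache[i] is None:
            cache[i] = {c: v for c, _, v in self.rows[i]}
        return cache[i]


@dataclass
class TransactionalDB:
    """One transaction of ``(col, item)`` tokens per non-empty row node."""

    transactions: list[list[Token]]
    row_ids: list[int]            # indexes into the source matrix rows
    n_rows_total: int
    n_cols: int

    def __len__(self) -> int:
        return len(self.transactions)

    def write_tokens(self, path) -> None:
        with open(path, "w") as fh:
            for rid, tr in zip(self.row_ids, self.transactions):
                fh.write(str(rid) + "\t" + " ".join(_fmt_token(t) for t in tr) + "\n")


@dataclass
class SequentialDB:
    """Per row, the columns sorted ascending by value; ties form groups."""

    sequences: list[list[frozenset[Token]]]
    row_ids: list[int]
    n_rows_total: int
    n_cols: int

    def __len__(self) -> int:
        return len(self.sequences)

    def write_tokens(self, path) -> None:
        with open(path, "w") as fh:
            for rid, seq in zip(self.row_ids, self.sequences):
                body = " -> ".join("{" + ",".join(sorted(_fmt_token(t) for t in g)) + "}"
                                   for g in seq)
                fh.write(f"{rid}\t{body}\n")


def _fmt_token(t: Token) -> str:
    if isinstance(t, tuple) and len(t) == 2 and t[0] == ANNOTATION:
        return f"@{t[1]}"
    if isinstance(t, tuple):
        return f"{t[0]}:{t[1]}"
    return str(t)


def normalize(view: AdjacencyView, mode: str = "zero_mean_rows") -> AdjacencyView:
    """Zero-mean row-oriented normalization over present interactions only.

    Missing elements remain missing; rows with a single interaction become 0.
    """
    if not view.weighted:
        raise ValueError("cannot normalize a labeled view")
    if mode in (None, "none"):
        return view
    if mode != "zero_mean_rows":
        raise ValueError(f"unknown normalization mode {mode!r}")
    rows = []
    for lst in view.rows:
        if not lst:
            rows.append([])
            continue
        mu = sum(float(v) for _, v in lst) / len(lst)
        rows.append([(c, float(v) - mu) for c, v in lst])
    # row-centering perturbs the value symmetry, but the view still shares
    # one node space between row and column roles
    return AdjacencyView(list(view.row_nodes), list(view.col_nodes), rows,
                         weighted=True, symmetric=view.symmetric,
                         orientation=view.orientation,
                         row_type=view.row_type, col_type=view.col_type)


def assign_multi_items(
    value: float,
    bin_edges: tuple[float, float],
    item: int,
    fraction: float = 0.25,
    *,
    lowest: bool = False,
    highest: bool = False,
    inner_width: float | None = None,
) -> tuple[int, ...]:
    """Assign one item, or two adjacent items near a discretization boundary.

    An element ``a_ij`` in bin ``[c1, c2]`` receives the neighbouring bin's
    item as well when ``min(c2 - a_ij, a_ij - c1) / (c2 - c1) < fraction``
    (default 25%).  Extreme bins only bridge inward, and their unbounded
    side is measured against ``inner_width`` (the width of the nearest
    interior bin) since their own width is infinite.
    """
    c1, c2 = bin_edges
    if not (c1 <= value <= c2) and not (lowest and value <= c2) and not (highest and value >= c1):
        raise ValueError(f"value {value} outside bin [{c1}, {c2}]")
    width = c2 - c1
    if lowest or highest:
        width = inner_width if inner_width is not None else width
    if width <= 0 or not math.isfinite(width):
        return (item,)
    if not lowest:
        d_low = (value - c1) / width
        if d_low < fraction and (highest or d_low <= (c2 - value) / width):
            return (item - 1, item)
    if not highest:
        d_high = (c2 - value) / width
        if d_high < fraction:
            return (item, item + 1)
    return (item,)


def gaussian_cut_points(values: Sequence[float], n_bins: int,
                        outlier_z: float = 3.0) -> tuple[float, ...]:
    """Cut points at the ``n_bins``-quantiles of a normal fit to the values."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DegenerateValueError("no values to discretize")
    mu, sd = float(arr.mean()), float(arr.std())
    if sd <= 0:
        raise DegenerateValueError(
            "constant value distribution; treat the network as labeled instead")
    clamped = np.clip(arr, mu - outlier_z * sd, mu + outlier_z * sd)
    mu, sd = float(clamped.mean()), float(clamped.std())
    if sd <= 0:
        raise DegenerateValueError(
            "constant value distribution; treat the network as labeled instead")
    qs = np.arange(1, n_bins) / n_bins
    return tuple(mu + sd * stats.norm.ppf(qs))


def discretize(view: AdjacencyView, scheme: DiscretizationScheme) -> ItemizedMatrix:
    """Map present elements to items via overall Gaussian quantile cuts.

    Outliers beyond ``scheme.outlier_z`` standard deviations are clamped to
    the extreme items.  Values within the multi-item boundary fraction of a
    cut point receive both adjacent items.
    """
    if not view.weighted:
        raise ValueError("discretize expects a weighted view; labels map 1:1 to items")
    values = [float(v) for _, _, v in view.iter_cells()]
    L = scheme.alphabet_size
    cuts = gaussian_cut_points(values, L, scheme.outlier_z)
    items = DiscretizationScheme(alphabet_size=L).items
    edges = (-math.inf,) + cuts + (math.inf,)
    inner_width = cuts[1] - cuts[0] if L >= 3 else None

    cuts_list = list(cuts)
    rows: list[list[tuple[int, tuple[int, ...], float]]] = []
    for lst in view.rows:
        out = []
        for c, v in lst:
            v = float(v)
            b = bisect_right(cuts_list, v)
            assigned = assign_multi_items(
                v, (edges[b], edges[b + 1]), items[b],
                fraction=scheme.multi_item_fraction,
                lowest=(b == 0), highest=(b == L - 1), inner_width=inner_width)
            out.append((c, assigned, v))
        rows.append(out)
    return ItemizedMatrix(list(view.row_nodes), list(view.col_nodes), rows,
                          alphabet=items, delta=scheme.delta, cut_points=cuts,
                          symmetric=view.symmetric)


def itemize_labeled(view: AdjacencyView) -> ItemizedMatrix:
    """Map a labeled view to items 1..|L| (labels map 1:1 to items)."""
    if view.weighted:
        raise ValueError("itemize_labeled expects a labeled view")
    labels = sorted({str(v) for _, _, v in view.iter_cells()})
    label_map = {lab: i + 1 for i, lab in enumerate(labels)}
    rows = [[(c, (label_map[str(v)],), float(label_map[str(v)])) for c, v in lst]
            for lst in view.rows]
    return ItemizedMatrix(list(view.row_nodes), list(view.col_nodes), rows,
                          alphabet=tuple(label_map.values()),
                          delta=1.0 / max(len(labels), 1),
                          labeled=True, label_map=label_map,
                          symmetric=view.symmetric)


def build_transactions(
    mat: ItemizedMatrix,
    annotations: dict[str, list[str]] | None = None,
) -> TransactionalDB:
    """One transaction per non-empty row; multi-items yield one token each.

    Node annotations (e.g. ontology terms) are appended as dedicated tokens
    so the miners can treat them like any other item.
    """
    transactions, row_ids = [], []
    for i, lst in enumerate(mat.rows):
        if not lst:
            continue
        tokens: list[Token] = [(c, it) for c, items, _ in lst for it in items]
        if annotations:
            for term in annotations.get(mat.row_nodes[i], []):
                tokens.append((ANNOTATION, term))
        transactions.append(tokens)
        row_ids.append(i)
    return TransactionalDB(transactions, row_ids, len(mat.rows), len(mat.col_nodes))


def build_sequences(
    source: Union[AdjacencyView, ItemizedMatrix],
    annotations: dict[str, list[str]] | None = None,
    n_bins: int | None = None,
) -> SequentialDB:
    """Per row, sort columns ascending by value; equal values co-occur.

    ``source`` may be a raw weighted view (discretization is optional for
    order-preserving searches) or an itemized matrix, in which case equal
    items form the co-occurrence groups.  ``n_bins`` optionally coarsens raw
    values into overall Gaussian quantile ranks before ordering, trading
    precedence detail for tie robustness.  Annotation tokens are appended as
    a trailing group.
    """
    if isinstance(source, ItemizedMatrix):
        row_nodes = source.row_nodes
        n_cols = len(source.col_nodes)
        keyed = [[(min(items), c) for c, items, _ in lst] for lst in source.rows]
    else:
        if not source.weighted:
            src = itemize_labeled(source)
            return build_sequences(src, annotations=annotations)
        row_nodes = source.row_nodes
        n_cols = len(source.col_nodes)
        if n_bins is not None and n_bins >= 2:
            values = [float(v) for _, _, v in source.iter_cells()]
            cuts = gaussian_cut_points(values, n_bins)
            keyed = [[(int(np.searchsorted(cuts, float(v), side="right")), c)
                      for c, v in lst] for lst in source.rows]
        else:
            keyed = [[(float(v), c) for c, v in lst] for lst in source.rows]

    sequences, row_ids = [], []
    for i, lst in enumerate(keyed):
        if not lst:
            continue
        lst = sorted(lst)
        groups: list[frozenset[Token]] = []
        cur_key: object = object()
        cur: set = set()
        for key, c in lst:
            if key == cur_key:
                cur.add(c)
            else:
                if cur:
                    groups.append(frozenset(cur))
                cur_key, cur = key, {c}
        if cur:
            groups.append(frozenset(cur))
        if annotations:
            terms = annotations.get(row_nodes[i], [])
            if terms:
                groups.append(frozenset((ANNOTATION, t) for t in terms))
        sequences.append(groups)
        row_ids.append(i)
    return SequentialDB(sequences, row_ids, len(keyed), n_cols)
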