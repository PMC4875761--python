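"""Sparse representation of homogeneous and heterogeneous interaction networks.

A biological network is held as typed node sets plus a flat list of
interactions ``(node_a, node_b, value)`` where the value is either a real
weight (e.g. a confidence score from an interaction database) or a symbol
from a finite label alphabet (e.g. ``binding``/``activation``).  For
biclustering, the network is viewed as one or more bipartite adjacency
views stored as an array of lists of ``(column, value)`` pairs, so memory
stays proportional to the number of interactions ``p`` and never to the
full ``n x m`` matrix.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

Value = Union[float, str]

HOMOGENEOUS_TYPE = "node"


class NetworkFormatError(ValueError):
    """Raised when an edge list cannot be parsed into a consistent network."""


@dataclass
class Network:
    """A weighted or labeled network over one or more disjoint node sets.

    Parameters
    ----------
    node_sets:
        Mapping from node-type name to the ordered list of node identifiers
        of that type.  Homogeneous networks use a single type.
    interactions:
        Canonical interaction list ``(node_a, node_b, value)``.  For
        undirected networks each pair is stored once, with endpoints in
        canonical (sorted) order when both belong to the same node set.
    weighted:
        True when values are real weights, False when they are labels.
    directed:
        Directedness flag; the default (False) matches most molecular
        interaction data.
    """

    node_sets: dict[str, list[str]]
    interactions: list[tuple[str, str, Value]]
    weighted: bool = True
    directed: bool = False

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for t, nodes in self.node_sets.items():
            for nd in nodes:
                if nd in seen:
                    raise NetworkFormatError(
                        f"node {nd!r} appears in node sets {seen[nd]!r} and {t!r}"
                    )
                seen[nd] = t
        self._node_type = seen
        for a, b, _ in self.interactions:
            if a not in seen or b not in seen:
                missing = a if a not in seen else b
                raise NetworkFormatError(f"interaction endpoint {missing!r} is not a declared node")

    @property
    def kappa(self) -> int:
        """Number of distinct node types."""
        return len(self.node_sets)

    @property
    def n_interactions(self) -> int:
        return len(self.interactions)

    def node_type(self, node: str) -> str:
        return self._node_type[node]

    @property
    def label_alphabet(self) -> list[str]:
        if self.weighted:
            return []
        return sorted({v for _, _, v in self.interactions})

    def is_homogeneous(self) -> bool:
        return self.kappa == 1


@dataclass
class AdjacencyView:
    """Sparse bipartite adjacency view: an array of lists of (col, value) pairs.

    ``rows[i]`` holds the sorted ``(column index, value)`` pairs for row node
    ``row_nodes[i]``.  Homogeneous networks yield a symmetric view in which
    both ``a_ij`` and ``a_ji`` carry the interaction value.
    """

    row_nodes: list[str]
    col_nodes: list[str]
    rows: list[list[tuple[int, Value]]]
    weighted: bool = True
    symmetric: bool = False
    orientation: str = "original"
    row_type: str = HOMOGENEOUS_TYPE
    col_type: str = HOMOGENEOUS_TYPE

    def __post_init__(self) -> None:
        for lst in self.rows:
            lst.sort(key=lambda cv: cv[0])

    @property
    def n_stored_pairs(self) -> int:
        return sum(len(r) for r in self.rows)

    @property
    def is_empty(self) -> bool:
        return self.n_stored_pairs == 0

    def shape(self) -> tuple[int, int]:
        return len(self.row_nodes), len(self.col_nodes)

    def iter_cells(self) -> Iterable[tuple[int, int, Value]]:
        for i, lst in enumerate(self.rows):
            for j, v in lst:
                yield i, j, v

    def to_dict_rows(self) -> list[dict[int, Value]]:
        return [dict(lst) for lst in self.rows]


def _parse_value(raw: str) -> Value:
    """Parse a weight, tolerating the unicode minus sign; fall back to a label."""
    txt = raw.strip().replace("−", "-")
    try:
        return float(txt)
    except ValueError:
        return raw.strip()


def _canonical_edge(a: str, b: str, same_set: bool, directed: bool) -> tuple[str, str]:
    if directed or not same_set:
        return a, b
    return (a, b) if a <= b else (b, a)


def load_edge_list(
    path: Union[str, Path],
    schema: dict | None = None,
) -> Network:
    """Load a TSV/CSV edge list ``node_a, node_b, value[, type_a, type_b]``.

    ``schema`` keys (all optional): ``delimiter``, ``mode`` ("weighted" or
    "labeled"), ``directed`` (bool), ``header`` (bool).  Weighted versus
    labeled mode is inferred from the value column unless forced; mixing
    weights and labels is an error.  Malformed rows are reported with their
    line numbers.  Self-loops are dropped with a warning because the
    bipartite mapping has no cell for them.
    """
    schema = dict(schema or {})
    path = Path(path)
    delimiter = schema.get("delimiter")
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    directed = bool(schema.get("directed", False))
    forced_mode = schema.get("mode")

    records: list[tuple[str, str, Value, str, str]] = []
    bad_lines: list[str] = []
    n_self_loops = 0
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for lineno, row in enumerate(reader, start=1):
            if schema.get("header") and lineno == 1:
                continue
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if delimiter == "\t" and len(row) == 1:
                row = row[0].split()
            if len(row) not in (3, 5):
                bad_lines.append(f"line {lineno}: expected 3 or 5 columns, got {len(row)}")
                continue
            a, b, raw = row[0].strip(), row[1].strip(), row[2]
            if not a or not b or not raw.strip():
                bad_lines.append(f"line {lineno}: empty field")
                continue
            if a == b:
                n_self_loops += 1
                continue
            value = _parse_value(raw)
            ta = row[3].strip() if len(row) == 5 else HOMOGENEOUS_TYPE
            tb = row[4].strip() if len(row) == 5 else HOMOGENEOUS_TYPE
            records.append((a, b, value, ta, tb))
    if bad_lines:
        raise NetworkFormatError("malformed edge list rows: " + "; ".join(bad_lines))
    if n_self_loops:
        warnings.warn(
            f"dropped {n_self_loops} self-loop(s); self-interactions are not modeled",
            stacklevel=2,
        )

    n_numeric = sum(1 for r in records if isinstance(r[2], float))
    if forced_mode == "weighted":
        if n_numeric < len(records):
            raise NetworkFormatError("schema forces weighted mode but labels present")
        weighted = True
    elif forced_mode == "labeled":
        weighted = False
        records = [(a, b, str(v), ta, tb) for a, b, v, ta, tb in records]
    else:
        if 0 < n_numeric < len(records):
            raise NetworkFormatError(
                f"mixed weighted/labeled values: {n_numeric} numeric of {len(records)} rows"
            )
        weighted = n_numeric == len(records) and len(records) > 0

    node_type: dict[str, str] = {}
    node_order: dict[str, list[str]] = {}
    for a, b, _, ta, tb in records:
        for nd, t in ((a, ta), (b, tb)):
            prev = node_type.get(nd)
            if prev is None:
                node_type[nd] = t
                node_order.setdefault(t, []).append(nd)
            elif prev != t:
                raise NetworkFormatError(f"node {nd!r} declared with types {prev!r} and {t!r}")

    dedup: dict[tuple[str, str], Value] = {}
    for a, b, v, ta, tb in records:
        key = _canonical_edge(a, b, ta == tb, directed)
        if key in dedup:
            old = dedup[key]
            if old != v:
                if weighted and abs(float(v)) > abs(float(old)):
                    dedup[key] = v
                warnings.warn(
                    f"duplicate edge {key} with conflicting values; kept max magnitude",
                    stacklevel=2,
                )
        else:
            dedup[key] = v

    interactions = [(a, b, v) for (a, b), v in dedup.items()]
    return Network(node_sets=node_order or {HOMOGENEOUS_TYPE: []},
                   interactions=interactions, weighted=weighted, directed=directed)


def write_edge_list(net: Network, path: Union[str, Path], delimiter: str = "\t") -> None:
    """Write the canonical interaction multiset back to disk (same dialect)."""
    heterogeneous = net.kappa > 1
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        for a, b, v in net.interactions:
            row: list = [a, b, v]
            if heterogeneous:
                row += [net.node_type(a), net.node_type(b)]
            writer.writerow(row)


def load_annotations(path: Union[str, Path], delimiter: str = "\t") -> dict[str, list[str]]:
    """Read ``(node, term)`` pairs into a node -> terms mapping."""
    out: dict[str, list[str]] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter=delimiter):
            if len(row) < 2:
                continue
            node, term = row[0].strip(), row[1].strip()
            if term not in out.setdefault(node, []):
                out[node].append(term)
    return out


def _build_view(
    row_nodes: Sequence[str],
    col_nodes: Sequence[str],
    edges: Iterable[tuple[str, str, Value]],
    *,
    weighted: bool,
    symmetric: bool,
    row_type: str,
    col_type: str,
) -> AdjacencyView:
    ridx = {nd: i for i, nd in enumerate(row_nodes)}
    cidx = {nd: j for j, nd in enumerate(col_nodes)}
    rows: list[list[tuple[int, Value]]] = [[] for _ in row_nodes]
    for a, b, v in edges:
        rows[ridx[a]].append((cidx[b], v))
        if symmetric:
            rows[ridx[b]].append((cidx[a], v))
    return AdjacencyView(list(row_nodes), list(col_nodes), rows, weighted=weighted,
                         symmetric=symmetric, row_type=row_type, col_type=col_type)


def to_minimal_bipartite(net: Network) -> AdjacencyView:
    """Map a homogeneous network to its minimal symmetric adjacency view.

    A single node-ID space serves both the row and the column role, and each
    undirected interaction fills both ``a_ij`` and ``a_ji``, so a network of
    ``p`` interactions yields exactly ``2p`` stored pairs.
    """
    if not net.is_homogeneous():
        raise ValueError("to_minimal_bipartite expects a homogeneous network; "
                         "use decompose_heterogeneous instead")
    (tname, nodes), = net.node_sets.items()
    return _build_view(nodes, nodes, net.interactions, weighted=net.weighted,
                       symmetric=True, row_type=tname, col_type=tname)


def decompose_heterogeneous(net: Network) -> list[AdjacencyView]:
    """Split a network with ``kappa`` node types into its bipartite views.

    Returns exactly ``C(max(kappa, 2), 2)`` views, one per unordered pair of
    distinct node types (a homogeneous network yields its single symmetric
    view).  Views with no interactions are retained and flagged empty via
    ``AdjacencyView.is_empty``.  Interactions between nodes of the same
    declared type in a heterogeneous network are routed to extra symmetric
    views appended after the guaranteed cross-type views.
    """
    if net.is_homogeneous():
        return [to_minimal_bipartite(net)]

    types = list(net.node_sets)
    cross: dict[tuple[str, str], list[tuple[str, str, Value]]] = {}
    intra: dict[str, list[tuple[str, str, Value]]] = {}
    for a, b, v in net.interactions:
        ta, tb = net.node_type(a), net.node_type(b)
        if ta == tb:
            intra.setdefault(ta, []).append((a, b, v))
        else:
            if types.index(ta) > types.index(tb):
                a, b, ta, tb = b, a, tb, ta
            cross.setdefault((ta, tb), []).append((a, b, v))

    views = []
    for i, ta in enumerate(types):
        for tb in types[i + 1:]:
            views.append(_build_view(
                net.node_sets[ta], net.node_sets[tb], cross.get((ta, tb), []),
                weighted=net.weighted, symmetric=False, row_type=ta, col_type=tb))
    expected = math.comb(max(net.kappa, 2), 2)
    assert len(views) == expected, (len(views), expected)
    for t, edges in intra.items():
        views.append(_build_view(net.node_sets[t], net.node_sets[t], edges,
                                 weighted=net.weighted, symmetric=True,
                                 row_type=t, col_type=t))
    return views


def transpose(view: AdjacencyView) -> AdjacencyView:
    """Swap row and column roles; an involution on any view."""
    cols: list[list[tuple[int, Value]]] = [[] for _ in view.col_nodes]
    for i, j, v in view.iter_cells():
        cols[j].append((i, v))
    return AdjacencyView(
        list(view.col_nodes), list(view.row_nodes), cols, weighted=view.weighted,
        symmetric=view.symmetric,
        orientation="transposed" if view.orientation == "original" else "original",
        row_type=view.col_type, col_type=view.row_type)
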