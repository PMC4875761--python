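"""The bicluster (network module) container shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

COHERENCIES = ("dense", "constant", "symmetric", "plaid", "order_preserving")

# pattern phi_B: expected item per column (constant-like models) or an
# ordered tuple of co-occurrence groups of columns (order-preserving).
ConstantPattern = dict[int, int]
OrderPattern = tuple[frozenset[int], ...]
PatternType = Union[ConstantPattern, OrderPattern]


@dataclass
class Bicluster:
    """A module ``(I, J)``: two node subsets with coherent interactions.

    ``rows``/``cols`` are integer indexes into the adjacency view the module
    was found in; ``pattern`` holds the expected values ``k_j`` (or the
    column ordering for order-preserving modules); ``signs`` carries the row
    sign vector ``c_i`` of symmetric modules.  ``noise`` records the
    fraction of deviating and missing cells measured against the itemized
    matrix.
    """

    rows: frozenset[int]
    cols: frozenset[int]
    coherency: str
    delta: float
    pattern: Optional[PatternType] = None
    signs: Optional[dict[int, int]] = None
    p_value: Optional[float] = None
    noise: dict = field(default_factory=dict)
    merged_from: int = 1
    mean_weight: Optional[float] = None

    def __post_init__(self) -> None:
        if self.coherency not in COHERENCIES:
            raise ValueError(f"unknown coherency {self.coherency!r}")

    @property
    def n_cells(self) -> int:
        return len(self.rows) * len(self.cols)

    def cells(self) -> set[tuple[int, int]]:
        return {(i, j) for i in self.rows for j in self.cols}

    def area_key(self) -> tuple:
        return (self.n_cells, len(self.rows), sorted(self.rows), sorted(self.cols))

    def to_record(self, row_names: list[str] | None = None,
                  col_names: list[str] | None = None) -> dict:
        rows = sorted(self.rows)
        cols = sorted(self.cols)
        rec = {
            "rows": [row_names[i] for i in rows] if row_names else rows,
            "cols": [col_names[j] for j in cols] if col_names else cols,
            "coherency": self.coherency,
            "delta": self.delta,
            "p_value": self.p_value,
            "noise": self.noise,
            "merged_from": self.merged_from,
        }
        if isinstance(self.pattern, dict):
            rec["pattern"] = {
                (col_names[j] if col_names else j): k
                for j, k in sorted(self.pattern.items())}
        elif self.pattern is not None:
            rec["pattern"] = [
                sorted(col_names[j] if col_names else j for j in grp)
                for grp in self.pattern]
        if self.signs is not None:
            rec["signs"] = {
                (row_names[i] if row_names else i): s
                for i, s in sorted(self.signs.items())}
        if self.mean_weight is not None:
            rec["mean_weight"] = self.mean_weight
        return rec


def cell_jaccard(a: Bicluster, b: Bicluster) -> float:
    """Jaccard similarity over interaction-cell sets; 1 iff identical (I, J)."""
    ri = len(a.rows & b.rows)
    ci = len(a.cols & b.cols)
    inter = ri * ci
    union = a.n_cells + b.n_cells - inter
    return inter / union if union else 1.0
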