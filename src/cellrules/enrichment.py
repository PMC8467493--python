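"""Over-representation analysis of a gene list against user-supplied sets.

One-sided hypergeometric upper-tail test per term: with a universe of N
genes, a term of K genes, a selection of n genes and an overlap of k, the
p-value is P(X >= k) for X ~ Hypergeom(N, K, n). No multiple-testing
correction is applied by default (a raw threshold of 0.001 is the
convention here); Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

DEFAULT_ALPHA = 0.001


@dataclass
class GeneSetCollection:
    """Named gene sets (term_id -> (name, genes)) over an explicit universe."""

    sets: dict = field(default_factory=dict)
    universe: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.universe = set(self.universe)
        for term, (_, genes) in self.sets.items():
            extra = set(genes) - self.universe
            if extra:
                raise ValueError(
                    f"term {term!r} has genes outside the universe: {sorted(extra)[:3]}"
                )

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class EnrichmentRow:
    """Overlap statistics and hypergeometric p-value for one term."""

    term_id: str
    term_name: str
    overlap: int        # k
    term_size: int      # K
    selection_size: int  # n
    universe_size: int  # N
    p_value: float


def read_gmt(path: str, universe=None) -> GeneSetCollection:
    """Read a GMT file (term_id, description, genes...; tab-delimited).

    If no universe is given, the union of all term genes is used.
    """
    sets: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[parts[0]] = (parts[1], set(g for g in parts[2:] if g))
    if universe is None:
        universe = set()
        for _, genes in sets.values():
            universe |= genes
    return GeneSetCollection(sets, set(universe))


def ora(selected, sets: GeneSetCollection, alpha: float = DEFAULT_ALPHA,
        bh_correct: bool = False) -> list[EnrichmentRow]:
    """Significant terms (p < alpha), ascending by p-value.

    Selected genes outside the universe are dropped with a warning.
    """
    if not sets.universe:
        raise ValueError("empty universe")
    selected = set(selected)
    outside = selected - sets.universe
    if outside:
        import warnings

        warnings.warn(
            f"{len(outside)} selected gene(s) outside the universe were dropped",
            stacklevel=2,
        )
        selected &= sets.universe

    N = len(sets.universe)
    n = len(selected)
    rows = []
    for term, (name, genes) in sets.sets.items():
        K = len(genes)
        k = len(selected & genes)
        # P(X >= k) = sf(k - 1)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(EnrichmentRow(term, name, k, K, n, N, p))
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    if bh_correct:
        m = len(rows)
        adj, running_min = [], 1.0
        for i in range(m - 1, -1, -1):
            running_min = min(running_min, rows[i].p_value * m / (i + 1))
            adj.append(running_min)
        for r, q in zip(rows, reversed(adj)):
            r.p_value = q
    return [r for r in rows if r.p_value < alpha]


def enrichment_to_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
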