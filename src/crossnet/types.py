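"""Core domain containers: the background interactome and gene sets.

The interactome is an undirected, untyped simple graph over gene symbols.
Direction and mechanism annotations of curated interaction databases are
deliberately collapsed: the over-connectivity statistic only counts whether
a connection exists between two node sets, so an unordered node pair is the
natural unit. Symbols are whitespace-trimmed and uppercased; no alias or
HGNC resolution is attempted (documented limitation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .errors import EmptyInteractomeError

logger = logging.getLogger(__name__)

#: Valid provenance tags for a GeneSet.
GENESET_SOURCES = ("list", "gmt", "gwas_catalog", "synthetic")


def normalize_symbol(symbol: str) -> Optional[str]:
    """Normalize a gene symbol: trim whitespace, uppercase.

    Returns ``None`` for symbols that are empty after trimming.
    """
    s = symbol.strip().upper()
    return s or None


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (a network "seed" set).

    Parameters
    ----------
    name
        Free-text label, e.g. ``"coagulation"`` or ``"MS_GWAS"``.
    members
        Normalized gene symbols.
    source
        One of :data:`GENESET_SOURCES`.
    """

    name: str
    members: frozenset[str]
    source: str = "list"

    def __post_init__(self) -> None:
        if self.source not in GENESET_SOURCES:
            raise ValueError(f"unknown GeneSet source {self.source!r}")
        object.__setattr__(self, "members", frozenset(self.members))

    @classmethod
    def from_symbols(
        cls, name: str, symbols: Iterable[str], source: str = "list"
    ) -> "GeneSet":
        """Build a GeneSet, normalizing and dropping empty symbols."""
        members = {s for s in (normalize_symbol(x) for x in symbols) if s}
        return cls(name=name, members=frozenset(members), source=source)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(sorted(self.members))


@dataclass
class Interactome:
    """Undirected simple graph over normalized gene symbols.

    Invariants (enforced by :meth:`from_edges`): no self-loops, no duplicate
    unordered pairs, every edge endpoint is a node. Isolated nodes are
    allowed — they still count toward the background universe used by the
    chance expectation.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    name: str = ""
    provenance: str = ""

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] = (),
        name: str = "",
        provenance: str = "",
        allow_empty: bool = False,
    ) -> "Interactome":
        """Build an interactome from raw (source, target) symbol pairs.

        Symbols are normalized; self-loops are dropped (with a logged
        count); duplicate and reversed-duplicate edges collapse into one
        undirected edge. ``nodes`` may add isolated nodes.
        """
        g = nx.Graph()
        n_self = 0
        for u, v in edges:
            nu, nv = normalize_symbol(u), normalize_symbol(v)
            if nu is None or nv is None:
                continue
            if nu == nv:
                n_self += 1
                g.add_node(nu)
                continue
            g.add_edge(nu, nv)
        for n in nodes:
            nn = normalize_symbol(n)
            if nn is not None:
                g.add_node(nn)
        if n_self:
            logger.info("dropped %d self-loop(s) while building %r", n_self, name)
        if g.number_of_edges() == 0 and not allow_empty:
            raise EmptyInteractomeError(
                f"interactome {name!r} has no edges after cleaning"
            )
        return cls(graph=g, name=name, provenance=provenance)

    # -- views -------------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Edges as sorted symbol 2-tuples (canonical unordered form)."""
        return {tuple(sorted((u, v))) for u, v in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, symbol: str) -> int:
        return self.graph.degree[symbol]

    def neighbors(self, symbol: str) -> set[str]:
        return set(self.graph.neighbors(symbol))

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.graph

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def copy(self) -> "Interactome":
        return Interactome(
            graph=self.graph.copy(), name=self.name, provenance=self.provenance
        )


@dataclass(frozen=True)
class GwasCatalogFilter:
    """Row/column filter for a GWAS Catalog associations export.

    ``trait_substring`` is matched case-insensitively against DISEASE/TRAIT;
    ``p_threshold`` is an upper bound on the association p-value (default:
    genome-wide significance, 5e-8); ``gene_field_policy`` selects which
    gene column(s) feed the list: ``mapped``, ``reported`` or ``union``.
    """

    trait_substring: str = "multiple sclerosis"
    p_threshold: float = 5e-8
    gene_field_policy: str = "mapped"

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0, 1]")
        if self.gene_field_policy not in ("mapped", "reported", "union"):
            raise ValueError(
                f"unknown gene_field_policy {self.gene_field_policy!r}"
            )
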