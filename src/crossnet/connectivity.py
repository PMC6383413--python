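"""Over-connectivity test between two gene networks on an interactome.

The analysis follows the two-step connectivity procedure used in pathway
crosstalk studies: (1) identify the genes shared by the two networks;
(2) enrich every network with its interactors (first neighbors, or deeper),
count the interactions observed between the two enriched networks, and
compare that count with what resampling the seed sets on the same graph
would produce by chance. The result is an observed count, a null mean/sd,
a z-score and a one-sided empirical p-value — the same summary shape as the
commercial connectivity reports this package re-implements openly.

Null models
-----------
Two resampling schemes are provided. ``reseeded`` (default) redraws
surrogate *seed* sets of the observed sizes — preserving the observed
overlap count between the two seed sets — and re-expands them, so the
variability of the interactor-enrichment step propagates into the null.
``fixed_expanded`` freezes the expansion and redraws independent node sets
of the *expanded* sizes; its mean has a closed form
(:func:`expected_analytic`) and it is the cross-check against exhaustive
enumeration on tiny graphs.

Both schemes support a ``uniform`` and a ``degree_matched`` sampler; the
latter replaces each seed with a node from the same log-scale degree bin,
guarding against hub-driven false positives on heavy-tailed interactomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import NamedTuple, Optional

import numpy as np

from ._engine import IndexedGraph, sample_group_masks
from .errors import EmptySetError, ParameterError
from .types import GeneSet, Interactome

logger = logging.getLogger(__name__)

NULL_SCHEMES = ("reseeded", "fixed_expanded")
SAMPLERS = ("uniform", "degree_matched")

# stream tag so the null draws never reuse the integer-seeded streams that
# built the synthetic graph / seed sets
_NULL_STREAM = 3


@dataclass(frozen=True)
class NullConfig:
    """Configuration of the chance-expectation (permutation) null.

    Parameters
    ----------
    scheme
        ``reseeded`` re-draws seed sets and re-expands them each replicate;
        ``fixed_expanded`` re-draws node sets of the expanded sizes.
    sampler
        ``uniform`` or ``degree_matched`` (log-bin degree matching).
    n_perm
        Number of permutation replicates (>= 99 so the empirical p-value
        has at least 1% granularity).
    seed
        Seed for the null's random stream.
    degree_bin_base
        Logarithm base of the degree bins used by ``degree_matched``.
    """

    scheme: str = "reseeded"
    sampler: str = "degree_matched"
    n_perm: int = 1000
    seed: int = 17
    degree_bin_base: float = 2.0

    def __post_init__(self) -> None:
        if self.scheme not in NULL_SCHEMES:
            raise ParameterError(f"unknown null scheme {self.scheme!r}")
        if self.sampler not in SAMPLERS:
            raise ParameterError(f"unknown sampler {self.sampler!r}")
        if self.n_perm < 99:
            raise ParameterError("n_perm must be >= 99")
        if not self.degree_bin_base > 1:
            raise ParameterError("degree_bin_base must be > 1")


@dataclass(frozen=True)
class ExpandedSet:
    """A seed gene set unioned with its interactors up to ``depth`` hops.

    ``members`` is restricted to interactome nodes; seed symbols absent
    from the graph are recorded in ``off_graph``.
    """

    seed: GeneSet
    depth: int
    members: frozenset[str]
    off_graph: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


class NullDistribution(NamedTuple):
    mean: float
    sd: float
    samples: np.ndarray


@dataclass
class ConnectivityResult:
    """Complete output of :func:`connectivity_test`.

    ``z`` is ``nan`` (and ``z_defined`` False) when the null is degenerate
    (sd = 0); ``p_empirical`` always carries the add-one Monte-Carlo
    estimate and lies in [1/(n_perm+1), 1].
    """

    set_a: str
    set_b: str
    observed: int
    expected_null: float
    sd_null: float
    z: float
    z_defined: bool
    p_empirical: float
    expected_analytic: float
    shared_genes: list[str]
    shared_gene_interactors: dict[str, list[str]]
    depth: int
    scheme: str
    sampler: str
    n_perm: int
    seed: int
    degree_bin_base: float
    n_nodes: int
    n_edges: int
    size_a: int
    size_b: int
    expanded_size_a: int
    expanded_size_b: int
    off_graph_a: list[str] = field(default_factory=list)
    off_graph_b: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        # JSON has no NaN — encode undefined z as None
        if not self.z_defined:
            d["z"] = None
        return d

    def __eq__(self, other: object) -> bool:
        # NaN-safe: two results with undefined z compare equal
        if not isinstance(other, ConnectivityResult):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    @classmethod
    def from_dict(cls, d: dict) -> "ConnectivityResult":
        d = dict(d)
        if d.get("z") is None:
            d["z"] = float("nan")
        return cls(**d)


# ---------------------------------------------------------------------------
# step 1: shared genes


def shared_nodes(set_a: GeneSet, set_b: GeneSet) -> set[str]:
    """Genes appearing in both networks (exact intersection of members)."""
    return set(set_a.members & set_b.members)


# ---------------------------------------------------------------------------
# step 2: interactor enrichment


def expand_with_interactors(
    interactome: Interactome, seed: GeneSet, depth: int = 1
) -> ExpandedSet:
    """Enrich a seed set with its interactors up to ``depth`` hops.

    depth=0 returns the seed restricted to graph nodes; depth=1 adds first
    neighbors; etc. Seed symbols absent from the interactome are kept in
    ``off_graph`` so reports can surface them.
    """
    if depth < 0:
        raise ParameterError("depth must be >= 0")
    nodes = interactome.nodes
    on_graph = set(seed.members) & nodes
    off_graph = set(seed.members) - nodes
    members = set(on_graph)
    frontier = set(on_graph)
    for _ in range(depth):
        frontier = {
            nbr
            for node in frontier
            for nbr in interactome.graph.neighbors(node)
        } - members
        if not frontier:
            break
        members |= frontier
    return ExpandedSet(
        seed=seed,
        depth=depth,
        members=frozenset(members),
        off_graph=frozenset(off_graph),
    )


def count_inter_edges(
    interactome: Interactome, expanded_a: ExpandedSet, expanded_b: ExpandedSet
) -> int:
    """Distinct interactome edges linking the two enriched networks.

    An edge {u, v} counts when one endpoint lies in A and the other in B;
    edges inside the A∩B overlap count once.
    """
    graph = IndexedGraph(interactome)
    mask_a = graph.mask(expanded_a.members)
    mask_b = graph.mask(expanded_b.members)
    return int(graph.count_cross(mask_a, mask_b))


# ---------------------------------------------------------------------------
# chance expectation


def expected_analytic(interactome: Interactome, a: int, b: int) -> float:
    """First-moment chance expectation for two independent random sets.

    For independent uniform subsets of sizes ``a`` and ``b`` drawn from the
    N nodes, each edge {u, v} spans the two sets with probability

        2ab/N^2  -  [a(a-1)/(N(N-1))] * [b(b-1)/(N(N-1))]

    (inclusion–exclusion over the two orientations); the expectation sums
    this over the |E| edges. It applies to the ``fixed_expanded`` scheme and
    is reported as a cross-check next to the permutation mean.
    """
    n = interactome.n_nodes
    if n < 2:
        raise ParameterError("interactome must have at least 2 nodes")
    if not (0 <= a <= n) or not (0 <= b <= n):
        raise ParameterError("set sizes must be within [0, n_nodes]")
    both = (a * (a - 1) / (n * (n - 1))) * (b * (b - 1) / (n * (n - 1)))
    per_edge = 2 * a * b / n**2 - both
    return interactome.n_edges * per_edge


def permutation_null(
    interactome: Interactome,
    set_a: GeneSet,
    set_b: GeneSet,
    depth: int,
    config: NullConfig,
    *,
    _graph: Optional[IndexedGraph] = None,
) -> NullDistribution:
    """Monte-Carlo null distribution of the inter-network edge count.

    ``reseeded``: each replicate draws surrogate seed sets of the observed
    on-graph sizes — with the observed overlap count preserved, so shared
    seeds are resampled as shared — re-expands them at ``depth`` and counts.
    ``fixed_expanded``: each replicate draws two independent node sets of
    the expanded sizes and counts directly.

    Returns the sample mean, sample sd (n-1 denominator) and the samples;
    bit-reproducible given ``config.seed``.
    """
    graph = _graph if _graph is not None else IndexedGraph(interactome)
    rng = np.random.default_rng((config.seed, _NULL_STREAM))
    p = config.n_perm

    # the inter-set count is symmetric in (A, B); sampling the two sets in a
    # canonical order makes the whole null invariant under swapping them
    def _ordered(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if (len(x), tuple(x)) <= (len(y), tuple(y)):
            return x, y
        return y, x

    if config.scheme == "reseeded":
        a_idx = graph.to_indices(set_a.members)
        b_idx = graph.to_indices(set_b.members)
        if len(a_idx) == 0 or len(b_idx) == 0:
            raise EmptySetError("a seed set has no members on the interactome")
        shared = np.intersect1d(a_idx, b_idx)
        first, second = _ordered(
            np.setdiff1d(a_idx, shared), np.setdiff1d(b_idx, shared)
        )
        m_shared, m_a, m_b = sample_group_masks(
            rng, graph, p, [shared, first, second],
            config.sampler, config.degree_bin_base,
        )
        masks_a = graph.expand(m_shared | m_a, depth)
        masks_b = graph.expand(m_shared | m_b, depth)
    else:  # fixed_expanded
        ea = expand_with_interactors(interactome, set_a, depth)
        eb = expand_with_interactors(interactome, set_b, depth)
        if len(ea) == 0 or len(eb) == 0:
            raise EmptySetError("a seed set has no members on the interactome")
        first, second = _ordered(
            graph.to_indices(ea.members), graph.to_indices(eb.members)
        )
        (masks_a,) = sample_group_masks(
            rng, graph, p, [first], config.sampler, config.degree_bin_base,
        )
        (masks_b,) = sample_group_masks(
            rng, graph, p, [second], config.sampler, config.degree_bin_base,
        )

    samples = np.asarray(graph.count_cross(masks_a, masks_b), dtype=np.int64)
    return NullDistribution(
        mean=float(samples.mean()),
        sd=float(samples.std(ddof=1)),
        samples=samples,
    )


# ---------------------------------------------------------------------------
# full pipeline


def connectivity_test(
    interactome: Interactome,
    set_a: GeneSet,
    set_b: GeneSet,
    depth: int = 1,
    config: NullConfig = NullConfig(),
) -> ConnectivityResult:
    """Run the full over-connectivity analysis between two gene networks.

    Steps: shared-gene identification; interactor enrichment of both seed
    sets at ``depth``; observed inter-network edge count; permutation null
    per ``config``; z = (observed - null mean)/null sd; one-sided add-one
    empirical p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    graph = IndexedGraph(interactome)
    a_on = set(set_a.members) & interactome.nodes
    b_on = set(set_b.members) & interactome.nodes
    if not a_on:
        raise EmptySetError(f"set {set_a.name!r} has no genes on the interactome")
    if not b_on:
        raise EmptySetError(f"set {set_b.name!r} has no genes on the interactome")

    expanded_a = expand_with_interactors(interactome, set_a, depth)
    expanded_b = expand_with_interactors(interactome, set_b, depth)
    mask_a = graph.mask(expanded_a.members)
    mask_b = graph.mask(expanded_b.members)
    observed = int(graph.count_cross(mask_a, mask_b))

    null = permutation_null(
        interactome, set_a, set_b, depth, config, _graph=graph
    )
    if null.sd > 0:
        z = (observed - null.mean) / null.sd
        z_defined = True
    else:
        z = float("nan")
        z_defined = False
        logger.warning("degenerate null (sd = 0); z undefined")
    p_emp = (1 + int(np.sum(null.samples >= observed))) / (config.n_perm + 1)

    shared = shared_nodes(set_a, set_b)
    interactors = {
        gene: sorted(interactome.neighbors(gene))
        for gene in sorted(shared)
        if gene in interactome
    }

    return ConnectivityResult(
        set_a=set_a.name,
        set_b=set_b.name,
        observed=observed,
        expected_null=null.mean,
        sd_null=null.sd,
        z=z,
        z_defined=z_defined,
        p_empirical=p_emp,
        expected_analytic=expected_analytic(
            interactome, len(expanded_a), len(expanded_b)
        ),
        shared_genes=sorted(shared),
        shared_gene_interactors=interactors,
        depth=depth,
        scheme=config.scheme,
        sampler=config.sampler,
        n_perm=config.n_perm,
        seed=config.seed,
        degree_bin_base=config.degree_bin_base,
        n_nodes=interactome.n_nodes,
        n_edges=interactome.n_edges,
        size_a=len(a_on),
        size_b=len(b_on),
        expanded_size_a=len(expanded_a),
        expanded_size_b=len(expanded_b),
        off_graph_a=sorted(expanded_a.off_graph),
        off_graph_b=sorted(expanded_b.off_graph),
    )
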