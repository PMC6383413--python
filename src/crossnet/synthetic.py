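"""Synthetic interactomes, seed sets and planted crosstalk.

Real curated interactomes are proprietary or heavy downloads, so every
stage of the over-connectivity analysis is exercised against generated
graphs with known ground truth: an Erdős–Rényi or configuration-model
background, two seed sets of configurable sizes sharing a configurable
number of genes (emulating a pathway map and a GWAS gene list that overlap
in a couple of genes), and an optional planted excess of cross-set edges
whose realized count is the recovery oracle.

Seed streams: one master seed per :class:`SyntheticSpec`; stages derive
their own stream by fixed offsets (graph +0, seed sets +1, planting +2) so
changing one stage's draw never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
import logging

import networkx as nx
import numpy as np

from .errors import ParameterError
from .types import GeneSet, Interactome

logger = logging.getLogger(__name__)

GRAPH_MODELS = ("er", "config_powerlaw")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study condition.

    Defaults mirror the benchmark condition used throughout the package's
    recovery experiments: a sparse random background (mean degree ~10),
    two 25-gene seed sets sharing 2 genes (the pathway/GWAS overlap being
    a handful of genes, as in real crosstalk reports), and no planted
    signal unless requested.
    """

    n_nodes: int = 500
    graph_model: str = "er"
    er_p: float = 0.02
    powerlaw_exponent: float = 2.3
    size_a: int = 25
    size_b: int = 25
    overlap: int = 2
    planted_q: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.graph_model not in GRAPH_MODELS:
            raise ParameterError(f"unknown graph_model {self.graph_model!r}")
        if self.n_nodes < 2:
            raise ParameterError("n_nodes must be >= 2")
        if self.graph_model == "er" and not (0 < self.er_p <= 1):
            raise ParameterError("er_p must be in (0, 1]")
        if self.graph_model == "config_powerlaw" and not self.powerlaw_exponent > 2:
            raise ParameterError("powerlaw_exponent must be > 2")
        if min(self.size_a, self.size_b) < 1:
            raise ParameterError("seed set sizes must be >= 1")
        if not (0 <= self.overlap <= min(self.size_a, self.size_b)):
            raise ParameterError("overlap must be <= min(size_a, size_b)")
        if self.size_a + self.size_b - self.overlap > self.n_nodes:
            raise ParameterError("seed sets do not fit in n_nodes")
        if self.planted_q < 0:
            raise ParameterError("planted_q must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PlantedTruth:
    """Ground truth of a planted-crosstalk instance."""

    q_requested: int
    q_added: int
    set_a: GeneSet
    set_b: GeneSet
    spec: dict = field(default_factory=dict)


def _node_name(i: int, n: int) -> str:
    width = max(4, len(str(n)))
    return f"G{i + 1:0{width}d}"


def generate_interactome(spec: SyntheticSpec) -> Interactome:
    """Generate the background graph for a spec; deterministic given seed.

    ``er``: G(n, p). ``config_powerlaw``: degrees drawn from a discrete
    power law P(k) ∝ k^(-gamma) truncated at n-1 (minimum degree 1, sum
    forced even), wired with the configuration model; self-loops and
    multi-edges are dropped, so realized edge counts sit slightly below the
    degree-sequence total.
    """
    n = spec.n_nodes
    if spec.graph_model == "er":
        g = nx.fast_gnp_random_graph(n, spec.er_p, seed=spec.seed)
    else:
        rng = np.random.default_rng(spec.seed)
        ks = np.arange(1, n, dtype=np.float64)
        pmf = ks ** (-spec.powerlaw_exponent)
        pmf /= pmf.sum()
        degrees = rng.choice(np.arange(1, n), size=n, p=pmf)
        if degrees.sum() % 2 == 1:
            bump = int(np.argmin(degrees))  # deterministic, stays <= n-1
            degrees[bump] += 1
        mg = nx.configuration_model(degrees.tolist(), seed=spec.seed)
        g = nx.Graph(mg)
        g.remove_edges_from(nx.selfloop_edges(g))
    mapping = {i: _node_name(i, n) for i in g.nodes}
    g = nx.relabel_nodes(g, mapping)
    return Interactome(
        graph=g,
        name=f"synthetic_{spec.graph_model}",
        provenance=f"crossnet.synthetic seed={spec.seed}",
    )


def make_seed_sets(
    interactome: Interactome, spec: SyntheticSpec
) -> tuple[GeneSet, GeneSet, set[str]]:
    """Draw two uniform seed sets with exactly ``spec.overlap`` shared genes.

    Returns (set_a, set_b, shared). Deterministic given ``spec.seed``.
    """
    nodes = sorted(interactome.nodes)
    needed = spec.size_a + spec.size_b - spec.overlap
    if needed > len(nodes):
        raise ParameterError(
            f"need {needed} distinct nodes but the graph has {len(nodes)}"
        )
    rng = np.random.default_rng(spec.seed + 1)
    perm = rng.permutation(len(nodes))
    shared = {nodes[i] for i in perm[: spec.overlap]}
    a_extra = {
        nodes[i] for i in perm[spec.overlap : spec.size_a]
    }
    b_extra = {
        nodes[i]
        for i in perm[spec.size_a : spec.size_a + spec.size_b - spec.overlap]
    }
    set_a = GeneSet("synthetic_A", frozenset(shared | a_extra), source="synthetic")
    set_b = GeneSet("synthetic_B", frozenset(shared | b_extra), source="synthetic")
    return set_a, set_b, shared


def plant_crosstalk(
    interactome: Interactome,
    set_a: GeneSet,
    set_b: GeneSet,
    q: int,
    seed: int,
) -> tuple[Interactome, PlantedTruth]:
    """Add ``q`` random cross edges between A-only and B-only genes.

    Candidate pairs are (u in A\\B, v in B\\A) that are not already edges;
    planted edges never touch shared genes, so the realized count
    ``q_added`` is an unambiguous over-connectivity ground truth. If fewer
    than ``q`` candidates exist, all of them are added (logged warning).
    The input graph is not modified.
    """
    if q < 0:
        raise ParameterError("q must be >= 0")
    a_only = sorted(set(set_a.members) - set(set_b.members))
    b_only = sorted(set(set_b.members) - set(set_a.members))
    g = interactome.graph
    candidates = [
        (u, v)
        for u in a_only
        for v in b_only
        if not g.has_edge(u, v)
    ]
    rng = np.random.default_rng(seed)
    if q > len(candidates):
        logger.warning(
            "requested %d planted edges but only %d candidate pairs exist",
            q, len(candidates),
        )
    k = min(q, len(candidates))
    chosen = (
        [candidates[i] for i in rng.choice(len(candidates), size=k, replace=False)]
        if k
        else []
    )
    planted = interactome.copy()
    planted.graph.add_edges_from(chosen)
    planted.provenance = (
        f"{interactome.provenance} + {k} planted cross edges (seed={seed})"
    )
    truth = PlantedTruth(
        q_requested=q, q_added=k, set_a=set_a, set_b=set_b,
    )
    return planted, truth


def simulate(spec: SyntheticSpec) -> tuple[Interactome, GeneSet, GeneSet, PlantedTruth]:
    """Full pipeline: graph, seed sets, planted crosstalk.

    Stage seeds are spec.seed + 0 / + 1 / + 2 (graph / sets / planting).
    """
    background = generate_interactome(spec)
    set_a, set_b, _ = make_seed_sets(background, spec)
    planted, truth = plant_crosstalk(
        background, set_a, set_b, spec.planted_q, spec.seed + 2
    )
    truth.spec = spec.to_dict()
    return planted, set_a, set_b, truth
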