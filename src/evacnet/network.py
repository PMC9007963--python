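"""Directed networks, tie rewiring, and structural metrics.

Edges point from the *follower* to the *followee*: ``(i, j)`` means player
``i`` listens to (sees the signal display of) player ``j``.  This is the
neighbor set ``N_i`` used by the hazard model: the followees of ``i``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "DirectedNetwork",
    "RewiringOffer",
    "NetworkMetrics",
    "generate_initial_network",
    "sample_rewiring_offers",
    "apply_rewiring",
    "pair_offer_probability",
    "compute_metrics",
    "informant_degree_contrast",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Used for edge and offer counts (e.g. density 0.25 on 15 players gives
    52.5 possible-pair quota -> 53 edges).  Python's built-in ``round``
    uses banker's rounding, which would give 52.
    """
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class DirectedNetwork:
    """A simple directed graph over player identifiers.

    ``edges`` is a frozenset of ordered ``(follower, followee)`` pairs; the
    graph is simple (no duplicates) and loop-free by construction.
    """

    nodes: frozenset
    edges: frozenset

    def __post_init__(self):
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop {u!r}")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown node")

    @classmethod
    def from_edges(cls, nodes: Iterable, edges: Iterable[tuple]) -> "DirectedNetwork":
        return cls(nodes=frozenset(nodes), edges=frozenset((u, v) for u, v in edges))

    @property
    def n(self) -> int:
        return len(self.nodes)

    def has_edge(self, follower, followee) -> bool:
        return (follower, followee) in self.edges

    def followees(self, node) -> list:
        """Players whose displays `node` can see (out-neighbors)."""
        if node not in self.nodes:
            raise KeyError(node)
        return sorted(v for (u, v) in self.edges if u == node)

    def followers(self, node) -> list:
        """Players who can see `node`'s display (in-neighbors)."""
        if node not in self.nodes:
            raise KeyError(node)
        return sorted(u for (u, v) in self.edges if v == node)

    def out_degree(self, node) -> int:
        return sum(1 for (u, _) in self.edges if u == node)

    def in_degree(self, node) -> int:
        return sum(1 for (_, v) in self.edges if v == node)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes, key=str))
        g.add_edges_from(sorted(self.edges, key=str))
        return g

    def sorted_edges(self) -> list:
        return sorted(self.edges, key=lambda e: (str(e[0]), str(e[1])))


@dataclass(frozen=True)
class RewiringOffer:
    """One ordered pair offered to its follower in the tie-rewiring step.

    ``counterpart_info`` summarizes the followee's previous round: whether
    they evacuated, whether their action was correct, and for how long they
    displayed each signal — the feedback subjects saw when deciding.
    """

    follower: object
    followee: object
    tie_exists: bool
    counterpart_info: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if self.follower == self.followee:
            raise ValueError("follower and followee must differ")


@dataclass(frozen=True)
class NetworkMetrics:
    density: float
    mean_path_length: float | None
    fraction_unreachable: float
    clustering_coefficient: float
    in_degree: Mapping
    out_degree: Mapping


def generate_initial_network(n: int, density: float, rng: np.random.Generator) -> DirectedNetwork:
    """Directed random graph with an exact edge count.

    Samples exactly ``round_half_up(density * n*(n-1))`` distinct directed
    edges uniformly without replacement from all non-loop ordered pairs, so
    the realized density is deterministic given ``(n, density)``; only edge
    identity varies with the seed.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    m = round_half_up(density * n * (n - 1))
    if m < 1:
        warnings.warn("requested density yields an empty graph", stacklevel=2)
    idx = rng.choice(len(pairs), size=m, replace=False)
    return DirectedNetwork.from_edges(range(n), (pairs[i] for i in sorted(idx)))


def sample_rewiring_offers(
    network: DirectedNetwork,
    fraction: float,
    rng: np.random.Generator,
    last_round_info: Mapping | None = None,
) -> list[RewiringOffer]:
    """Sample the ordered pairs put up for rewiring between rounds.

    Exactly ``round_half_up(fraction * n*(n-1))`` ordered pairs are chosen
    uniformly without replacement (both directions of a pair count
    separately).  Each offer is annotated with whether the tie currently
    exists and with the followee's last-round performance from
    ``last_round_info`` (player -> info mapping), when given.
    """
    if not (0 <= fraction <= 1):
        raise ValueError("fraction must be in [0, 1]")
    nodes = sorted(network.nodes, key=str)
    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    m = round_half_up(fraction * len(pairs))
    if m == 0:
        return []
    idx = rng.choice(len(pairs), size=m, replace=False)
    info = last_round_info or {}
    offers = []
    for i in sorted(idx):
        u, v = pairs[i]
        offers.append(
            RewiringOffer(
                follower=u,
                followee=v,
                tie_exists=network.has_edge(u, v),
                counterpart_info=dict(info.get(v, {})),
            )
        )
    return offers


def apply_rewiring(
    network: DirectedNetwork, decisions: Iterable[tuple[RewiringOffer, str]]
) -> DirectedNetwork:
    """Apply follower decisions to the graph.

    Each decision is ``(offer, action)`` with action in {"make", "break",
    "keep"}; "make" requires the tie to be absent and "break" requires it to
    be present.  Only offered pairs may change.
    """
    edges = set(network.edges)
    for offer, action in decisions:
        pair = (offer.follower, offer.followee)
        if action == "keep":
            continue
        if action == "make":
            if pair in edges:
                raise ValueError(f"make on existing edge {pair}")
            edges.add(pair)
        elif action == "break":
            if pair not in edges:
                raise ValueError(f"break on absent edge {pair}")
            edges.remove(pair)
        else:
            raise ValueError(f"unknown action {action!r}")
    return DirectedNetwork(nodes=network.nodes, edges=frozenset(edges))


def pair_offer_probability(fraction: float, n_steps: int) -> float:
    """Probability a fixed ordered pair is offered at least once.

    With a fraction ``q`` of ordered pairs offered independently at each of
    ``n_steps`` rewiring steps, this is ``1 - (1 - q)**n_steps``; at the
    experiment's q = 0.4 over the three between-round steps it is 0.784.
    """
    if not (0 <= fraction <= 1):
        raise ValueError("fraction must be in [0, 1]")
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    return 1.0 - (1.0 - fraction) ** n_steps


def compute_metrics(network: DirectedNetwork) -> NetworkMetrics:
    """Density, mean directed path length, clustering, degrees.

    Mean path length averages directed shortest-path lengths over ordered
    pairs with a finite path; the fraction of unreachable ordered pairs is
    reported alongside.  Clustering is global transitivity of the
    undirected projection.
    """
    if not network.nodes:
        raise ValueError("empty node set")
    g = network.to_networkx()
    n = g.number_of_nodes()
    density = g.number_of_edges() / (n * (n - 1)) if n > 1 else 0.0
    total_pairs = n * (n - 1)
    lengths = []
    for _, dists in nx.all_pairs_shortest_path_length(g):
        lengths.extend(d for d in dists.values() if d > 0)
    if lengths:
        mpl = float(np.mean(lengths))
        frac_unreachable = 1.0 - len(lengths) / total_pairs if total_pairs else 0.0
    else:
        mpl = None
        frac_unreachable = 1.0 if total_pairs else 0.0
    clustering = nx.transitivity(g.to_undirected()) if g.number_of_edges() else 0.0
    return NetworkMetrics(
        density=density,
        mean_path_length=mpl,
        fraction_unreachable=frac_unreachable,
        clustering_coefficient=clustering,
        in_degree={v: d for v, d in g.in_degree()},
        out_degree={v: d for v, d in g.out_degree()},
    )


def informant_degree_contrast(network: DirectedNetwork, informant) -> dict:
    """In/out-degree of the informant vs the mean over everyone else."""
    if informant not in network.nodes:
        raise KeyError(informant)
    others = [v for v in network.nodes if v != informant]
    return {
        "informant_in_degree": network.in_degree(informant),
        "mean_noninformant_in_degree": (
            float(np.mean([network.in_degree(v) for v in others])) if others else 0.0
        ),
        "informant_out_degree": network.out_degree(informant),
        "mean_noninformant_out_degree": (
            float(np.mean([network.out_degree(v) for v in others])) if others else 0.0
        ),
    }
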