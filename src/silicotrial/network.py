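"""Signed, weighted, directed protein-interaction networks.

The network is the substrate over which perturbation signals propagate:
nodes are proteins, directed edges are known interactions carrying a sign
(+1 activating, -1 inhibitory) and a weight in (0, 1] expressing interaction
strength.  Knowledge sets (disease proteins with their pathological
direction) and stimuli (perturbation inputs, e.g. drug-target inhibition)
are thin sign-maps resolved against a network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

from .errors import FormatError, ParameterError, StructuralError

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "KnowledgeSet",
    "Stimulus",
    "load_network",
    "load_sign_map",
    "write_sign_map",
    "within_k_links",
    "select_proximal_stimulus",
]


class InteractionNetwork:
    """Directed signed weighted protein graph.

    Invariants enforced at construction: no self-loops, no duplicate
    (source, target) pairs (last write wins, with a warning), every edge
    sign in {+1, -1} and weight in (0, 1].
    """

    def __init__(self, edges: Iterable[tuple[str, str, int, float]],
                 extra_nodes: Iterable[str] = ()) -> None:
        g = nx.DiGraph()
        n_dropped_loops = 0
        n_duplicates = 0
        for source, target, sign, weight in edges:
            if sign not in (1, -1):
                raise FormatError(f"edge {source}->{target}: sign {sign!r} not in {{+1,-1}}")
            if not 0.0 < weight <= 1.0:
                raise FormatError(f"edge {source}->{target}: weight {weight!r} not in (0,1]")
            if source == target:
                n_dropped_loops += 1
                continue
            if g.has_edge(source, target):
                n_duplicates += 1
            g.add_edge(source, target, sign=int(sign), weight=float(weight))
        for node in extra_nodes:
            g.add_node(node)
        if n_dropped_loops:
            logger.warning("dropped %d self-loop edge(s)", n_dropped_loops)
        if n_duplicates:
            logger.warning("%d duplicate edge row(s); last weight kept", n_duplicates)
        self._graph = g
        # cached views derived lazily
        self._undirected: nx.Graph | None = None

    # -- container protocol -------------------------------------------------

    @property
    def graph(self) -> nx.DiGraph:
        return self._graph

    @property
    def nodes(self) -> set[str]:
        return set(self._graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def __contains__(self, node: str) -> bool:
        return node in self._graph

    def edges(self) -> Iterator[tuple[str, str, int, float]]:
        """Iterate edges as ``(source, target, sign, weight)`` tuples."""
        for u, v, data in self._graph.edges(data=True):
            yield u, v, data["sign"], data["weight"]

    def undirected(self) -> nx.Graph:
        """Undirected skeleton (cached view) used for proximity queries."""
        if self._undirected is None:
            self._undirected = self._graph.to_undirected(as_view=True)
        return self._undirected

    def is_weakly_connected(self) -> bool:
        return nx.is_weakly_connected(self._graph)

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write the edge list as ``source  target  sign  weight`` TSV."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write("source\ttarget\tsign\tweight\n")
            for u, v, sign, weight in sorted(self.edges()):
                fh.write(f"{u}\t{v}\t{sign:+d}\t{weight!r}\n")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"InteractionNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


def load_network(path: str | Path) -> InteractionNetwork:
    """Parse an edge-list TSV (``source target sign weight`` with header).

    Malformed rows raise :class:`FormatError` with the 1-based line number.
    Self-loops are dropped and duplicate (source, target) rows collapse to
    the last occurrence, both with a logged warning.
    """
    path = Path(path)
    edges: list[tuple[str, str, int, float]] = []
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}: empty file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            source, target = parts[0], parts[1]
            try:
                sign = int(parts[2])
                weight = float(parts[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if sign not in (1, -1):
                raise FormatError(f"{path}:{lineno}: sign {sign} not in {{+1,-1}}")
            if not 0.0 < weight <= 1.0:
                raise FormatError(f"{path}:{lineno}: weight {weight} not in (0,1]")
            edges.append((source, target, sign, weight))
    return InteractionNetwork(edges)


@dataclass(frozen=True)
class KnowledgeSet:
    """Disease proteins with their pathological direction.

    ``entries[p] = +1`` means p is activation-associated in disease,
    ``-1`` inhibition-associated.  The knowledge set is the response layer
    of every model: disease-state models maintain these signs, treatment
    models are scored on their reversal.
    """

    entries: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ParameterError("knowledge set must be non-empty")
        bad = {p: s for p, s in self.entries.items() if s not in (1, -1)}
        if bad:
            raise ParameterError(f"knowledge-set signs must be +1/-1, got {bad}")

    @property
    def proteins(self) -> set[str]:
        return set(self.entries)

    def reversed(self) -> dict[str, int]:
        """Expected signs under successful treatment (pathology reversed)."""
        return {p: -s for p, s in self.entries.items()}

    def resolve(self, network: InteractionNetwork) -> None:
        missing = sorted(self.proteins - network.nodes)
        if missing:
            raise StructuralError(f"knowledge-set proteins absent from network: {missing}")


@dataclass(frozen=True)
class Stimulus:
    """Perturbation input: protein -> effect in {+1, -1}.

    Drug-target inhibition is encoded -1; the disease-driving proximal
    stimulus uses +1.
    """

    entries: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ParameterError("stimulus must be non-empty")
        bad = {p: s for p, s in self.entries.items() if s not in (1, -1)}
        if bad:
            raise ParameterError(f"stimulus effects must be +1/-1, got {bad}")

    @property
    def proteins(self) -> set[str]:
        return set(self.entries)

    def merged(self, other: "Stimulus") -> "Stimulus":
        """Union of two stimuli; the other stimulus wins on overlap."""
        combined = dict(self.entries)
        combined.update(other.entries)
        return Stimulus(combined)


def load_sign_map(path: str | Path) -> dict[str, int]:
    """Read a two-column ``protein  sign`` TSV (header optional)."""
    path = Path(path)
    out: dict[str, int] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and parts[1].lstrip("+-").isalpha():
                continue  # header row
            try:
                sign = int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if sign not in (1, -1):
                raise FormatError(f"{path}:{lineno}: sign {sign} not in {{+1,-1}}")
            out[parts[0]] = sign
    return out


def write_sign_map(entries: Mapping[str, int], path: str | Path,
                   header: tuple[str, str] = ("protein", "sign")) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for protein in sorted(entries):
            fh.write(f"{protein}\t{entries[protein]:+d}\n")


def within_k_links(network: InteractionNetwork, seed_proteins: Iterable[str],
                   k: int) -> set[str]:
    """Proteins within undirected shortest-path distance ``k`` of any seed.

    Includes the seeds themselves (distance 0).  Proximity ignores edge
    direction: "interaction links" count hops on the undirected skeleton.
    """
    seeds = set(seed_proteins)
    if k < 0:
        raise ParameterError(f"k must be >= 0, got {k}")
    missing = sorted(seeds - network.nodes)
    if missing:
        raise StructuralError(f"seed proteins absent from network: {missing}")
    result: set[str] = set()
    for depth, layer in enumerate(nx.bfs_layers(network.undirected(), sorted(seeds))):
        if depth > k:
            break
        result.update(layer)
    return result


def _neighborhood_distances(network: InteractionNetwork, seeds: set[str],
                            max_k: int) -> dict[str, int]:
    """Undirected distance (1..max_k) to the seed set for non-seed proteins."""
    dist: dict[str, int] = {}
    for depth, layer in enumerate(nx.bfs_layers(network.undirected(), sorted(seeds))):
        if depth > max_k:
            break
        if depth >= 1:
            for node in layer:
                dist[node] = depth
    return dist


def select_proximal_stimulus(network: InteractionNetwork,
                             knowledge_set: KnowledgeSet, n: int) -> Stimulus:
    """Select ``n`` disease-driving stimulus proteins near the knowledge set.

    Candidates come from the 1-link undirected neighborhood of the knowledge
    set (excluding its members), extended to 2 links if fewer than ``n``
    exist.  Ranking: link distance ascending, then number of knowledge-set
    neighbors descending, then identifier ascending.  Effects are +1 (the
    stimulus drives the pathological state).
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    knowledge_set.resolve(network)
    seeds = knowledge_set.proteins
    undirected = network.undirected()

    dist = _neighborhood_distances(network, seeds, max_k=1)
    if len(dist) < n:
        dist = _neighborhood_distances(network, seeds, max_k=2)
    if len(dist) < n:
        raise StructuralError(
            f"knowledge-set neighborhood exhausted: {len(dist)} candidates "
            f"within 2 links, {n} requested")

    def ks_degree(p: str) -> int:
        return sum(1 for q in undirected.neighbors(p) if q in seeds)

    ranked = sorted(dist, key=lambda p: (dist[p], -ks_degree(p), p))
    return Stimulus({p: +1 for p in ranked[:n]})
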