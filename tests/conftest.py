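"""Shared fixtures: small networks, scenarios, and an independent
breadth-first tanh propagation oracle used to cross-check the engine."""

from __future__ import annotations

import numpy as np
import pytest

from silicotrial import (InteractionNetwork, KnowledgeSet, Stimulus,
                         SyntheticScenario, generate_knowledge_set,
                         generate_network)


@pytest.fixture(scope="session")
def small_scenario() -> SyntheticScenario:
    return SyntheticScenario(seed=7, n_proteins=100, mean_out_degree=3.0,
                             knowledge_set_size=12, n_patients=30,
                             n_healthy=100, n_responder_proteins=5)


@pytest.fixture(scope="session")
def small_network(small_scenario) -> InteractionNetwork:
    return generate_network(small_scenario)


@pytest.fixture(scope="session")
def small_knowledge_set(small_network, small_scenario) -> KnowledgeSet:
    return generate_knowledge_set(small_network, small_scenario)


@pytest.fixture
def chain_network() -> InteractionNetwork:
    """A -> B -> C -> D -> E with unit weights, all activating."""
    return InteractionNetwork([
        ("A", "B", 1, 1.0), ("B", "C", 1, 1.0),
        ("C", "D", 1, 1.0), ("D", "E", 1, 1.0)])


def random_signed_network(rng: np.random.Generator, n_nodes: int = 30,
                          p_edge: float = 0.12) -> InteractionNetwork:
    """Erdos-Renyi-style random signed network for oracle comparisons."""
    edges = []
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j and rng.random() < p_edge:
                sign = -1 if rng.random() < 0.4 else 1
                edges.append((f"N{i:02d}", f"N{j:02d}", sign,
                              float(rng.uniform(0.05, 1.0))))
    names = [f"N{i:02d}" for i in range(n_nodes)]
    return InteractionNetwork(edges, extra_nodes=names)


def oracle_propagate(network: InteractionNetwork,
                     stimulus: dict[str, float],
                     n_steps: int = 3) -> dict[str, float]:
    """Independent wave-front tanh propagation, coded dict-by-dict.

    At each step, every unassigned node with an incoming edge from a node
    assigned in the previous wave integrates weight * activity over ALL
    already-assigned upstream neighbors (in sorted source order, matching
    the engine's fixed summation order) and applies tanh.  Stimulus nodes
    stay clamped.
    """
    in_edges: dict[str, list[tuple[str, float]]] = {}
    for u, v, s, w in network.edges():
        in_edges.setdefault(v, []).append((u, s * w))
    for v in in_edges:
        in_edges[v].sort()
    activity = dict(stimulus)
    last_wave = set(stimulus)
    for _ in range(n_steps):
        candidates = sorted(
            v for v in network.nodes
            if v not in activity
            and any(u in last_wave for u, _ in in_edges.get(v, [])))
        new: dict[str, float] = {}
        for v in candidates:
            total = 0.0
            for u, w in in_edges[v]:
                if u in activity:
                    total += w * activity[u]
            new[v] = float(np.tanh(total))
        activity.update(new)
        last_wave = set(new)
        if not last_wave:
            break
    return activity


@pytest.fixture
def toy_stimulus() -> Stimulus:
    return Stimulus({"A": -1})
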