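"""Signal propagation over the signed network.

A stimulus (protein -> input value) is injected at step 0 and spreads in
synchronous wave fronts.  At each step, every not-yet-assigned node that
receives an edge from a node assigned in the previous wave integrates the
inputs from *all* already-assigned upstream neighbors, weighted by the
effective edge weight (sign x strength), and passes the sum through a
hyperbolic tangent.  Assignments freeze once made: a node keeps the
activity of its first wave, which bounds diffusion and handles cycles
without special casing.  Three steps is the default reach — inputs travel
from targets to neighbors, then one layer further, then one more — so the
perturbation arrives at downstream response proteins without flooding the
whole network.

Stimulus nodes are clamped: network input never overwrites them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import ParameterError, StructuralError
from .network import InteractionNetwork, Stimulus

__all__ = ["ActivityState", "PropagationEngine", "propagate"]

DEFAULT_N_STEPS = 3


@dataclass(frozen=True)
class ActivityState:
    """Per-protein activity after propagation.

    ``activities`` maps each *reached* protein to a value in [-1, +1];
    unreached proteins are absent (distinct from an activity of exactly 0,
    which a reached node can legitimately hold).  ``step_assigned`` records
    the wave at which each reached protein froze (stimulus nodes: 0).
    """

    activities: Mapping[str, float]
    step_assigned: Mapping[str, int] = field(default_factory=dict)

    @property
    def reached(self) -> set[str]:
        return set(self.activities)

    def __getitem__(self, protein: str) -> float:
        return self.activities[protein]

    def __contains__(self, protein: str) -> bool:
        return protein in self.activities

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("protein\tactivity\tstep_assigned\n")
            for protein in sorted(self.activities):
                step = self.step_assigned.get(protein, -1)
                fh.write(f"{protein}\t{self.activities[protein]:.10g}\t{step}\n")


class PropagationEngine:
    """Array-backed propagation core bound to one network.

    Nodes are indexed in sorted-identifier order; edges in (target, source)
    index order, which fixes the floating-point summation order and makes
    results reproducible down to the bit.  The engine is reused across many
    weight vectors during annealing.
    """

    def __init__(self, network: InteractionNetwork) -> None:
        self.node_ids: list[str] = sorted(network.nodes)
        self.node_index: dict[str, int] = {p: i for i, p in enumerate(self.node_ids)}
        self.n_nodes = len(self.node_ids)

        rows = sorted(
            ((self.node_index[v], self.node_index[u], s * w)
             for u, v, s, w in network.edges()))
        if rows:
            dst, src, eff = map(np.asarray, zip(*rows))
        else:
            dst = src = np.empty(0, dtype=np.intp)
            eff = np.empty(0, dtype=np.float64)
        self.edge_dst = dst.astype(np.intp)
        self.edge_src = src.astype(np.intp)
        self.base_effective_weights = eff.astype(np.float64)
        self.edge_index: dict[tuple[str, str], int] = {
            (self.node_ids[s], self.node_ids[d]): k
            for k, (s, d) in enumerate(zip(self.edge_src, self.edge_dst))}
        self.n_edges = len(self.edge_dst)

    # -- array API (hot path) ----------------------------------------------

    def stimulus_arrays(self, stimulus: Mapping[str, float]
                        ) -> tuple[np.ndarray, np.ndarray]:
        missing = sorted(set(stimulus) - set(self.node_index))
        if missing:
            raise StructuralError(f"stimulus proteins absent from network: {missing}")
        proteins = sorted(stimulus)
        idx = np.array([self.node_index[p] for p in proteins], dtype=np.intp)
        val = np.array([float(stimulus[p]) for p in proteins], dtype=np.float64)
        return idx, val

    def run(self, effective_weights: np.ndarray, stim_idx: np.ndarray,
            stim_val: np.ndarray, n_steps: int = DEFAULT_N_STEPS
            ) -> tuple[np.ndarray, np.ndarray]:
        """Propagate and return (activity, step_assigned) arrays.

        ``step_assigned`` is -1 for unreached nodes; activity is 0 there and
        must be interpreted together with ``step_assigned``.
        """
        n = self.n_nodes
        activity = np.zeros(n)
        assigned = np.zeros(n, dtype=bool)
        step_assigned = np.full(n, -1, dtype=np.int64)
        activity[stim_idx] = stim_val
        assigned[stim_idx] = True
        step_assigned[stim_idx] = 0
        last_wave = np.zeros(n, dtype=bool)
        last_wave[stim_idx] = True

        src, dst, w = self.edge_src, self.edge_dst, effective_weights
        for step in range(1, n_steps + 1):
            if not last_wave.any():
                break
            # candidacy: an incoming edge from the previous wave
            fed = np.bincount(dst[last_wave[src]], minlength=n) > 0
            candidates = fed & ~assigned
            if not candidates.any():
                break
            # integrate from ALL already-assigned upstream neighbors;
            # unassigned sources contribute exact zeros (activity is 0 there)
            contrib = w * activity[src] * assigned[src]
            incoming = np.bincount(dst, weights=contrib, minlength=n)
            activity[candidates] = np.tanh(incoming[candidates])
            assigned[candidates] = True
            step_assigned[candidates] = step
            last_wave = candidates
        return activity, step_assigned

    # -- convenience --------------------------------------------------------

    def weights_from_mapping(self, weights: Mapping[tuple[str, str], float]
                             ) -> np.ndarray:
        out = self.base_effective_weights.copy()
        for (u, v), w in weights.items():
            if (u, v) not in self.edge_index:
                raise ParameterError(f"edge {u}->{v} not in network")
            if not -1.0 <= w <= 1.0:
                raise ParameterError(f"effective weight {w} for {u}->{v} outside [-1,1]")
            out[self.edge_index[(u, v)]] = w
        return out

    def to_state(self, activity: np.ndarray, step_assigned: np.ndarray
                 ) -> ActivityState:
        reached = np.flatnonzero(step_assigned >= 0)
        return ActivityState(
            activities={self.node_ids[i]: float(activity[i]) for i in reached},
            step_assigned={self.node_ids[i]: int(step_assigned[i]) for i in reached},
        )


def propagate(network: InteractionNetwork,
              stimulus: Stimulus | Mapping[str, float],
              weights: Mapping[tuple[str, str], float] | np.ndarray | None = None,
              n_steps: int = DEFAULT_N_STEPS,
              engine: PropagationEngine | None = None) -> ActivityState:
    """Propagate ``stimulus`` through ``network`` for ``n_steps`` waves.

    Parameters
    ----------
    weights
        Optional effective edge weights in [-1, 1] (sign folded in),
        either a full array in the engine's canonical edge order or a
        mapping ``(source, target) -> weight`` overriding the network's
        stored ``sign * weight``.  Default: the network's own weights.
    engine
        A prebuilt :class:`PropagationEngine` for the same network, to
        amortize setup across repeated calls.
    """
    if n_steps < 0:
        raise ParameterError(f"n_steps must be >= 0, got {n_steps}")
    eng = engine if engine is not None else PropagationEngine(network)
    if weights is None:
        eff = eng.base_effective_weights
    elif isinstance(weights, np.ndarray):
        if weights.shape != (eng.n_edges,):
            raise ParameterError(
                f"weight array has shape {weights.shape}, expected ({eng.n_edges},)")
        eff = weights
    else:
        eff = eng.weights_from_mapping(weights)
    entries = stimulus.entries if isinstance(stimulus, Stimulus) else stimulus
    stim_idx, stim_val = eng.stimulus_arrays(entries)
    activity, step_assigned = eng.run(eff, stim_idx, stim_val, n_steps=n_steps)
    return eng.to_state(activity, step_assigned)
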