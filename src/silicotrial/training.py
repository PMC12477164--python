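"""Training mechanism-of-action models by simulated annealing.

A model is a vector of effective edge weights in [-1, 1] (sign folded into
magnitude, so annealing can adjust both interaction strength and
direction).  The trainer proposes Gaussian perturbations to single edges
and accepts them by the Metropolis rule under geometric cooling, driving
up the fraction of fulfilled constraints:

* IDE constraints — patient proteins that should appear in the propagated
  state with their observed dysregulation sign (enforced during
  disease-state modeling, released during treatment simulation);
* response constraints — the knowledge-set proteins the signal must reach,
  either with their pathological sign (disease state, ``response_objective
  = "sign"``) or merely reached at all (treatment refinement,
  ``response_objective = "reach"``), with the quality of reversal left to
  the response score rather than the objective.

Because the system is underdetermined (far more edges than constraints),
many weight configurations satisfy the same constraints; ensembles of
independently initialized runs capture that population of feasible
mechanisms, and the uncertainty score — mean per-protein Shannon entropy of
the discretized activities across the ensemble, relative to its maximum —
summarizes how much the solutions disagree.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np

from .errors import ParameterError
from .network import InteractionNetwork, Stimulus
from .propagation import DEFAULT_N_STEPS, ActivityState, PropagationEngine

logger = logging.getLogger(__name__)

__all__ = [
    "AnnealSchedule",
    "ConstraintSet",
    "Solution",
    "SolutionEnsemble",
    "fulfillment",
    "is_valid",
    "anneal",
    "sample_ensemble",
    "prior_ensemble",
    "profile_edge_scales",
    "uncertainty",
]

#: |activity| below this counts as unreached for constraint purposes
DEFAULT_ACTIVITY_EPS = 1e-6
#: dead-zone for discretizing activities into {-, 0, +} in the uncertainty score
DEFAULT_ENTROPY_EPS = 0.05
#: weight of the smooth tie-breaker inside the annealing objective
_TIEBREAK_WEIGHT = 1e-3


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling schedule and proposal width.

    ``t0`` initial temperature, ``gamma`` multiplicative decay per
    temperature level, ``steps_per_temp`` Metropolis proposals per level,
    ``n_temps`` levels, ``proposal_sigma`` SD of the Gaussian edge-weight
    step.  Defaults (1.0, 0.95, 50, 40, 0.2) give 2000 proposals per run.
    """

    t0: float = 1.0
    gamma: float = 0.95
    steps_per_temp: int = 50
    n_temps: int = 40
    proposal_sigma: float = 0.2

    def __post_init__(self) -> None:
        if self.t0 <= 0 or self.steps_per_temp <= 0 or self.n_temps <= 0 \
                or self.proposal_sigma <= 0:
            raise ParameterError("schedule fields must be positive")
        if not 0.0 < self.gamma < 1.0:
            raise ParameterError(f"temperature decay must lie in (0,1), got {self.gamma}")


@dataclass(frozen=True)
class ConstraintSet:
    """Training constraints for one patient/condition.

    ``min_ide_sign_agreement`` (0.50) and ``min_response_coverage`` (0.60)
    are the validity thresholds: at least half the IDE proteins present in
    a solution must carry the observed sign, and at least 60% of the
    response proteins must be reached by the propagated signal.
    """

    response_constraints: Mapping[str, int]
    ide_constraints: Mapping[str, int] = field(default_factory=dict)
    min_ide_sign_agreement: float = 0.50
    min_response_coverage: float = 0.60
    enforce_ide: bool = True
    response_objective: Literal["sign", "reach"] = "sign"
    activity_eps: float = DEFAULT_ACTIVITY_EPS

    def __post_init__(self) -> None:
        if not self.response_constraints and not self.ide_constraints:
            raise ParameterError("constraint set must not be empty")
        for thr in (self.min_ide_sign_agreement, self.min_response_coverage):
            if not 0.0 <= thr <= 1.0:
                raise ParameterError(f"threshold {thr} outside [0,1]")

    def compile(self, engine: PropagationEngine) -> "_CompiledConstraints":
        return _CompiledConstraints(self, engine)


class _CompiledConstraints:
    """Index-array view of a ConstraintSet bound to a propagation engine."""

    def __init__(self, cs: ConstraintSet, engine: PropagationEngine) -> None:
        self.cs = cs
        missing = sorted((set(cs.response_constraints) | set(cs.ide_constraints))
                         - set(engine.node_index))
        if missing:
            raise ParameterError(f"constraint proteins absent from network: {missing}")

        def _index(mapping: Mapping[str, int]) -> tuple[np.ndarray, np.ndarray]:
            proteins = sorted(mapping)
            idx = np.array([engine.node_index[p] for p in proteins], dtype=np.intp)
            sgn = np.array([mapping[p] for p in proteins], dtype=np.float64)
            return idx, sgn

        self.resp_idx, self.resp_sign = _index(cs.response_constraints)
        self.ide_idx, self.ide_sign = _index(cs.ide_constraints)

    def _reached(self, activity: np.ndarray, step: np.ndarray,
                 idx: np.ndarray) -> np.ndarray:
        return (step[idx] >= 0) & (np.abs(activity[idx]) >= self.cs.activity_eps)

    def satisfaction(self, activity: np.ndarray, step: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
        """Per-protein satisfaction indicators (response, IDE)."""
        r_reached = self._reached(activity, step, self.resp_idx)
        if self.cs.response_objective == "reach":
            resp_ok = r_reached
        else:
            resp_ok = r_reached & (activity[self.resp_idx] * self.resp_sign > 0)
        if self.cs.enforce_ide and len(self.ide_idx):
            i_reached = self._reached(activity, step, self.ide_idx)
            ide_ok = i_reached & (activity[self.ide_idx] * self.ide_sign > 0)
        else:
            ide_ok = np.empty(0, dtype=bool)
        return resp_ok, ide_ok

    def fulfillment(self, activity: np.ndarray, step: np.ndarray) -> float:
        resp_ok, ide_ok = self.satisfaction(activity, step)
        pooled = np.concatenate([resp_ok, ide_ok]) if len(ide_ok) else resp_ok
        return float(pooled.mean()) if len(pooled) else 0.0

    def objective(self, activity: np.ndarray, step: np.ndarray) -> float:
        """1 - fulfillment, smoothed so equal-count states are ordered.

        The tie-breaker (mean |activity| on satisfied constraint proteins,
        weight 1e-3) gives annealing a gradient across the 0/1 plateaus of
        the raw count.
        """
        resp_ok, ide_ok = self.satisfaction(activity, step)
        pooled_ok = np.concatenate([resp_ok, ide_ok]) if len(ide_ok) else resp_ok
        n = len(pooled_ok)
        if n == 0:
            return 1.0
        frac = pooled_ok.mean()
        idx = np.concatenate([self.resp_idx, self.ide_idx]) if len(ide_ok) \
            else self.resp_idx
        sat_idx = idx[pooled_ok]
        tiebreak = float(np.abs(activity[sat_idx]).mean()) if len(sat_idx) else 0.0
        return 1.0 - (float(frac) + _TIEBREAK_WEIGHT * tiebreak)

    def is_valid(self, activity: np.ndarray, step: np.ndarray) -> bool:
        r_reached = self._reached(activity, step, self.resp_idx)
        coverage = float(r_reached.mean()) if len(self.resp_idx) else 1.0
        if coverage < self.cs.min_response_coverage:
            return False
        if not self.cs.enforce_ide or not len(self.ide_idx):
            return True
        i_reached = self._reached(activity, step, self.ide_idx)
        n_present = int(i_reached.sum())
        if n_present == 0:
            return True  # vacuous: no IDE protein present in the state
        ok = i_reached & (activity[self.ide_idx] * self.ide_sign > 0)
        agreement = ok.sum() / n_present
        return bool(agreement >= self.cs.min_ide_sign_agreement)


def _state_arrays(state: ActivityState, engine: PropagationEngine
                  ) -> tuple[np.ndarray, np.ndarray]:
    activity = np.zeros(engine.n_nodes)
    step = np.full(engine.n_nodes, -1, dtype=np.int64)
    for protein, value in state.activities.items():
        i = engine.node_index[protein]
        activity[i] = value
        step[i] = state.step_assigned.get(protein, 0)
    return activity, step


def fulfillment(activity: ActivityState, constraints: ConstraintSet,
                engine: PropagationEngine | None = None,
                network: InteractionNetwork | None = None) -> float:
    """Fraction of constraint proteins satisfied by an activity state.

    A response constraint is satisfied when the protein is reached
    (|activity| above the dead-zone) and — under the default ``"sign"``
    objective — carries the expected sign; IDE constraints require the
    observed sign and pool with response constraints at equal per-protein
    weight when ``enforce_ide`` is on.
    """
    eng = engine
    if eng is None and network is not None:
        eng = PropagationEngine(network)
    if eng is None:
        # minimal engine over just the constraint/state proteins
        proteins = (set(activity.activities) | set(constraints.response_constraints)
                    | set(constraints.ide_constraints))
        eng = PropagationEngine(InteractionNetwork([], extra_nodes=sorted(proteins)))
    compiled = constraints.compile(eng)
    return compiled.fulfillment(*_state_arrays(activity, eng))


def is_valid(activity: ActivityState, constraints: ConstraintSet,
             engine: PropagationEngine | None = None) -> bool:
    """Validity per the 50% IDE-sign-agreement / 60% coverage rule.

    Both thresholds are inclusive (>=).  Coverage counts reached response
    proteins regardless of sign; IDE agreement is computed only over IDE
    proteins present in the state (vacuously true when none are), and is
    ignored entirely when ``enforce_ide`` is off (treatment condition).
    """
    eng = engine
    if eng is None:
        proteins = (set(activity.activities) | set(constraints.response_constraints)
                    | set(constraints.ide_constraints))
        eng = PropagationEngine(InteractionNetwork([], extra_nodes=sorted(proteins)))
    compiled = constraints.compile(eng)
    return compiled.is_valid(*_state_arrays(activity, eng))


@dataclass(frozen=True)
class Solution:
    """One trained mechanism-of-action solution."""

    effective_weights: np.ndarray
    state: ActivityState
    fulfillment: float
    seed: int = 0

    def weights_mapping(self, engine: PropagationEngine) -> dict[tuple[str, str], float]:
        return {edge: float(self.effective_weights[k])
                for edge, k in engine.edge_index.items()}


@dataclass
class SolutionEnsemble:
    """Valid solutions collected for one patient/condition."""

    solutions: list[Solution]
    patient: str = ""
    condition: Literal["disease", "treatment"] = "disease"
    n_requested: int = 0
    n_attempts: int = 0

    @property
    def complete(self) -> bool:
        return len(self.solutions) >= self.n_requested

    @property
    def unsolvable(self) -> bool:
        return len(self.solutions) == 0

    def __len__(self) -> int:
        return len(self.solutions)


def anneal(network: InteractionNetwork, stimulus: Stimulus,
           constraints: ConstraintSet,
           schedule: AnnealSchedule = AnnealSchedule(),
           seed: int = 0,
           initial_weights: np.ndarray | None = None,
           weight_penalty: np.ndarray | None = None,
           n_steps: int = DEFAULT_N_STEPS,
           engine: PropagationEngine | None = None) -> Solution:
    """Optimize effective edge weights against constraint fulfillment.

    Proposal: a uniformly random edge perturbed by a Gaussian step
    (``schedule.proposal_sigma``), clipped to [-1, 1]; sign flips are
    allowed, so annealing adjusts both strength and direction.  Acceptance:
    Metropolis on the smoothed objective ``1 - fulfillment`` with geometric
    cooling.  Returns the best state visited (never worse than the start).

    ``weight_penalty`` (optional, per edge, >= 0) adds ``penalty @ |w|``
    to the objective: a prior that keeps specific edges quiet unless the
    constraints genuinely need them.  Individualized models use it to
    discourage signal flow through proteins measured normal in a patient;
    without such a restoring force the flat directions of the count-based
    objective random-walk to arbitrary magnitudes.
    """
    eng = engine if engine is not None else PropagationEngine(network)
    if eng.n_edges == 0:
        raise ParameterError("cannot anneal a network without edges")
    compiled = constraints.compile(eng)
    stim_idx, stim_val = eng.stimulus_arrays(
        stimulus.entries if isinstance(stimulus, Stimulus) else stimulus)
    rng = np.random.default_rng(seed)

    weights = (eng.base_effective_weights if initial_weights is None
               else np.asarray(initial_weights, dtype=float)).copy()
    if weights.shape != (eng.n_edges,):
        raise ParameterError("initial_weights shape mismatch")
    penalty = None
    if weight_penalty is not None:
        penalty = np.asarray(weight_penalty, dtype=float)
        if penalty.shape != (eng.n_edges,):
            raise ParameterError("weight_penalty shape mismatch")

    def total_objective(act: np.ndarray, stp: np.ndarray, w: np.ndarray) -> float:
        obj = compiled.objective(act, stp)
        if penalty is not None:
            obj += float(penalty @ np.abs(w))
        return obj

    activity, step = eng.run(weights, stim_idx, stim_val, n_steps=n_steps)
    obj = total_objective(activity, step, weights)
    best_weights = weights.copy()
    best_obj = obj
    best_arrays = (activity, step)

    temperature = schedule.t0
    for _ in range(schedule.n_temps):
        for _ in range(schedule.steps_per_temp):
            k = int(rng.integers(eng.n_edges))
            old_w = weights[k]
            weights[k] = float(np.clip(old_w + rng.normal(0.0, schedule.proposal_sigma),
                                       -1.0, 1.0))
            cand_activity, cand_step = eng.run(weights, stim_idx, stim_val,
                                               n_steps=n_steps)
            cand_obj = total_objective(cand_activity, cand_step, weights)
            delta = cand_obj - obj
            if delta <= 0 or rng.random() < math.exp(-delta / temperature):
                obj = cand_obj
                activity, step = cand_activity, cand_step
                if cand_obj < best_obj:
                    best_obj = cand_obj
                    best_weights = weights.copy()
                    best_arrays = (cand_activity, cand_step)
            else:
                weights[k] = old_w
        temperature *= schedule.gamma

    best_activity, best_step = best_arrays
    return Solution(
        effective_weights=best_weights,
        state=eng.to_state(best_activity, best_step),
        fulfillment=compiled.fulfillment(best_activity, best_step),
        seed=seed,
    )


def profile_edge_scales(engine: PropagationEngine,
                        profile: set[str],
                        damp_factor: float = 0.15) -> np.ndarray:
    """Per-edge initialization scales that bias routing through a profile.

    Edges whose endpoints both belong to ``profile`` (a patient's
    dysregulated proteins plus the stimulus/response layers) keep full
    strength; any edge touching a protein measured *normal* in this
    patient starts damped by ``damp_factor``.  Individualized training
    thereby retrieves connections between the patient's own dysregulated
    proteins and the stimulus and response nodes, instead of inventing
    signal flow through proteins the patient's profile says are quiet —
    the annealer can still strengthen any edge the constraints demand.
    """
    if not 0.0 <= damp_factor <= 1.0:
        raise ParameterError(f"damp_factor {damp_factor} outside [0,1]")
    in_profile = np.array([p in profile for p in engine.node_ids])
    edge_full = in_profile[engine.edge_src] & in_profile[engine.edge_dst]
    return np.where(edge_full, 1.0, damp_factor)


def sample_ensemble(network: InteractionNetwork, stimulus: Stimulus,
                    constraints: ConstraintSet,
                    n_solutions: int = 50,
                    max_attempts: int | None = None,
                    seed: int = 0,
                    schedule: AnnealSchedule = AnnealSchedule(),
                    init_jitter: float = 0.3,
                    base_weights: np.ndarray | None = None,
                    edge_scales: np.ndarray | None = None,
                    weight_penalty: np.ndarray | None = None,
                    n_steps: int = DEFAULT_N_STEPS,
                    engine: PropagationEngine | None = None,
                    patient: str = "",
                    condition: Literal["disease", "treatment"] = "disease",
                    ) -> SolutionEnsemble:
    """Collect up to ``n_solutions`` valid annealed solutions.

    Attempts run with seeds ``seed, seed+1, ...``; each starts from the
    base weights jittered uniformly by ±``init_jitter`` (the source of
    ensemble diversity in an underdetermined system), optionally rescaled
    per edge by ``edge_scales`` (see :func:`profile_edge_scales`).
    Solutions failing the validity rule are discarded.  An ensemble that
    ends empty marks the patient unsolvable; a partial ensemble is
    flagged via ``complete``.
    """
    if n_solutions < 1:
        raise ParameterError(f"n_solutions must be >= 1, got {n_solutions}")
    eng = engine if engine is not None else PropagationEngine(network)
    compiled = constraints.compile(eng)
    base = eng.base_effective_weights if base_weights is None else \
        np.asarray(base_weights, dtype=float)
    scales = np.ones(eng.n_edges) if edge_scales is None else \
        np.asarray(edge_scales, dtype=float)
    if max_attempts is None:
        max_attempts = 4 * n_solutions

    solutions: list[Solution] = []
    attempts = 0
    while len(solutions) < n_solutions and attempts < max_attempts:
        attempt_seed = seed + attempts
        attempts += 1
        rng = np.random.default_rng(attempt_seed)
        init = np.clip(scales * (base + rng.uniform(-init_jitter, init_jitter,
                                                    eng.n_edges)),
                       -1.0, 1.0)
        sol = anneal(network, stimulus, constraints, schedule=schedule,
                     seed=attempt_seed, initial_weights=init,
                     weight_penalty=weight_penalty, n_steps=n_steps,
                     engine=eng)
        act, stp = _state_arrays(sol.state, eng)
        if compiled.is_valid(act, stp):
            solutions.append(sol)
    ensemble = SolutionEnsemble(solutions=solutions, patient=patient,
                                condition=condition, n_requested=n_solutions,
                                n_attempts=attempts)
    if ensemble.unsolvable:
        logger.warning("patient %r: no valid solution in %d attempts (unsolvable)",
                       patient, attempts)
    elif not ensemble.complete:
        logger.info("patient %r: partial ensemble %d/%d after %d attempts",
                    patient, len(solutions), n_solutions, attempts)
    return ensemble


def prior_ensemble(network: InteractionNetwork, stimulus: Stimulus,
                   n_solutions: int = 50, seed: int = 0,
                   init_jitter: float = 0.3,
                   n_steps: int = DEFAULT_N_STEPS,
                   engine: PropagationEngine | None = None,
                   condition: Literal["disease", "treatment"] = "treatment",
                   ) -> SolutionEnsemble:
    """Ensemble of propagations at jittered literature weights, untrained.

    Each solution propagates the stimulus through the network's own
    effective weights perturbed by a uniform ±``init_jitter`` — the prior
    predictive spread of the model before any constraint fitting.  Used
    where the quantity of interest is the network's intrinsic response
    (e.g. scoring a drug's reach for survival-benefit calibration) rather
    than a constrained mechanism fit.
    """
    if n_solutions < 1:
        raise ParameterError(f"n_solutions must be >= 1, got {n_solutions}")
    eng = engine if engine is not None else PropagationEngine(network)
    stim_idx, stim_val = eng.stimulus_arrays(
        stimulus.entries if isinstance(stimulus, Stimulus) else stimulus)
    solutions = []
    for i in range(n_solutions):
        rng = np.random.default_rng(seed + i)
        weights = np.clip(eng.base_effective_weights
                          + rng.uniform(-init_jitter, init_jitter, eng.n_edges),
                          -1.0, 1.0)
        activity, step = eng.run(weights, stim_idx, stim_val, n_steps=n_steps)
        solutions.append(Solution(effective_weights=weights,
                                  state=eng.to_state(activity, step),
                                  fulfillment=math.nan, seed=seed + i))
    return SolutionEnsemble(solutions=solutions, condition=condition,
                            n_requested=n_solutions, n_attempts=n_solutions)


def uncertainty(ensemble: SolutionEnsemble,
                eps: float = DEFAULT_ENTROPY_EPS) -> float:
    """Ensemble disagreement as an entropy ratio, in percent.

    For each protein reached in at least one solution, activities across
    the ensemble are discretized into three states (negative / dead-zone
    or unreached / positive, dead-zone |a| < ``eps``); the observed Shannon
    entropy of that distribution is divided by log 3 (the maximum for three
    states) and averaged over proteins.  0% = all solutions identical,
    100% = every protein uniform over the three states.
    """
    if len(ensemble) < 2:
        raise ParameterError("uncertainty needs an ensemble of >= 2 solutions")
    proteins = sorted(set().union(*(s.state.reached for s in ensemble.solutions)))
    if not proteins:
        return 0.0
    n_sol = len(ensemble)
    ratios = np.empty(len(proteins))
    log3 = math.log(3.0)
    for j, protein in enumerate(proteins):
        counts = np.zeros(3)  # -, 0, +
        for sol in ensemble.solutions:
            a = sol.state.activities.get(protein, 0.0)
            state = 0 if a < -eps else (2 if a > eps else 1)
            counts[state] += 1
        p = counts[counts > 0] / n_sol
        ratios[j] = float(-(p * np.log(p)).sum() / log3)
    return float(ratios.mean() * 100.0)
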