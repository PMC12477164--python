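"""In-silico response scoring (TSignal) and survival-benefit calibration.

TSignal summarizes how well a propagated activity state modulates the
response proteins in their expected direction: each reached response
protein contributes ``activity x expected_sign`` (positive when the
protein moves as expected, negative when it moves against), and the sum is
divided by the number of reached response proteins.  For treatment
simulations the expected sign is the *reversal* of the pathological sign,
so TSignal > 0 means the drug pushes the disease proteins back toward
normal.  A model's TSignal is the mean over its solution ensemble.

Calibration aligns the score with clinical outcome: given one trained
model per drug and each drug's overall-survival benefit (drug-arm OS minus
matched placebo OS, months), response proteins are greedily removed one at
a time whenever their exclusion increases the Pearson correlation between
model TSignal and OS benefit, until no single removal helps (or a floor on
the set size is hit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .propagation import ActivityState
from .training import DEFAULT_ACTIVITY_EPS, SolutionEnsemble

logger = logging.getLogger(__name__)

__all__ = [
    "TSignalResult",
    "OSBenefitTable",
    "CalibrationResult",
    "tsignal",
    "model_tsignal",
    "calibrate",
]


@dataclass(frozen=True)
class TSignalResult:
    """Scalar response score with its per-protein breakdown."""

    value: float
    n_reached: int
    contributions: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class OSBenefitTable:
    """Per-drug overall-survival benefit in months (drug OS - placebo OS)."""

    benefits: Mapping[str, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.benefits.values()), dtype=float)
        if not np.isfinite(vals).all():
            raise ParameterError("OS benefits must be finite")

    @property
    def drugs(self) -> list[str]:
        return sorted(self.benefits)

    def __getitem__(self, drug: str) -> float:
        return self.benefits[drug]

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("drug\tos_benefit_months\n")
            for drug in self.drugs:
                fh.write(f"{drug}\t{self.benefits[drug]:.6g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OSBenefitTable":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float))))


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of greedy backward elimination on the response set."""

    retained: frozenset[str]
    removed: tuple[str, ...]
    trace: tuple[tuple[int, float], ...]  # (step, Pearson r); step 0 = full set

    @property
    def initial_r(self) -> float:
        return self.trace[0][1]

    @property
    def final_r(self) -> float:
        return self.trace[-1][1]


def tsignal(activity: ActivityState, expected: Mapping[str, int],
            eps: float = DEFAULT_ACTIVITY_EPS,
            denominator: Literal["response", "all"] = "response",
            ) -> TSignalResult:
    """Expectation-signed mean activity of reached response proteins.

    ``expected`` maps each response protein to its expected sign (for a
    treatment simulation, the reversal of the pathological sign).  Reached
    means present in the state with |activity| >= ``eps``.  The default
    denominator counts reached *response* proteins; ``denominator="all"``
    divides by every reached protein network-wide instead (alternative
    reading of "total number of proteins reached").
    """
    if not expected:
        raise ParameterError("expected-sign map must be non-empty")
    contributions: dict[str, float] = {}
    for protein, sign in expected.items():
        if protein in activity and abs(activity[protein]) >= eps:
            contributions[protein] = activity[protein] * sign
    n_response_reached = len(contributions)
    if denominator == "all":
        n_denom = sum(1 for a in activity.activities.values() if abs(a) >= eps)
    else:
        n_denom = n_response_reached
    if n_denom == 0:
        logger.warning("no response protein reached; TSignal = 0")
        return TSignalResult(value=0.0, n_reached=0, contributions={})
    value = sum(contributions.values()) / n_denom
    return TSignalResult(value=float(value), n_reached=n_response_reached,
                         contributions=contributions)


def model_tsignal(ensemble: SolutionEnsemble, expected: Mapping[str, int],
                  eps: float = DEFAULT_ACTIVITY_EPS,
                  denominator: Literal["response", "all"] = "response") -> float:
    """Mean per-solution TSignal over an ensemble."""
    if len(ensemble) == 0:
        raise ParameterError("cannot score an empty ensemble")
    values = [tsignal(s.state, expected, eps=eps, denominator=denominator).value
              for s in ensemble.solutions]
    return float(np.mean(values))


class _DrugScoreCache:
    """Per-drug contribution/reach matrices for fast subset re-scoring.

    Row s, column j hold solution s's signed contribution (activity x
    expected sign) and reach indicator for response protein j; restricting
    TSignal to a protein subset is then two masked row sums.
    """

    def __init__(self, ensemble: SolutionEnsemble, proteins: list[str],
                 expected: Mapping[str, int], eps: float) -> None:
        n_sol, n_prot = len(ensemble), len(proteins)
        self.contrib = np.zeros((n_sol, n_prot))
        self.reached = np.zeros((n_sol, n_prot), dtype=bool)
        for s, sol in enumerate(ensemble.solutions):
            acts = sol.state.activities
            for j, p in enumerate(proteins):
                a = acts.get(p)
                if a is not None and abs(a) >= eps:
                    self.reached[s, j] = True
                    self.contrib[s, j] = a * expected[p]

    def score(self, mask: np.ndarray) -> float:
        sums = self.contrib[:, mask].sum(axis=1)
        counts = self.reached[:, mask].sum(axis=1)
        values = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
        return float(values.mean())

    def score_without(self, mask: np.ndarray, j: int) -> float:
        sums = self.contrib[:, mask].sum(axis=1) - self.contrib[:, j] * mask[j]
        counts = self.reached[:, mask].sum(axis=1) - (self.reached[:, j] & mask[j])
        values = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
        return float(values.mean())


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def calibrate(drug_ensembles: Mapping[str, SolutionEnsemble],
              expected: Mapping[str, int],
              os_table: OSBenefitTable,
              min_set_size: int = 5,
              eps: float = DEFAULT_ACTIVITY_EPS) -> CalibrationResult:
    """Greedy backward elimination of response proteins against OS benefit.

    ``expected`` is the full response layer with expected signs under
    treatment (usually ``knowledge_set.reversed()``).  At each step every
    remaining protein is tentatively removed, each drug's model TSignal is
    re-scored on the reduced set (ensembles stay fixed; no re-training),
    and the single removal that most increases the Pearson correlation
    with OS benefit is accepted (ties broken by protein identifier
    ascending).  Stops when no removal strictly increases r or the
    retained set reaches ``min_set_size``.
    """
    drugs = sorted(drug_ensembles)
    if len(drugs) < 3:
        raise ParameterError("need >= 3 drugs for a meaningful correlation")
    missing = set(drugs) - set(os_table.benefits)
    if missing:
        raise ParameterError(f"drugs without OS benefit: {sorted(missing)}")
    proteins = sorted(expected)
    os_vector = np.array([os_table[d] for d in drugs])

    caches = [_DrugScoreCache(drug_ensembles[d], proteins, expected, eps)
              for d in drugs]
    mask = np.ones(len(proteins), dtype=bool)

    def set_r(current_mask: np.ndarray) -> float | None:
        ts = np.array([c.score(current_mask) for c in caches])
        return _pearson(ts, os_vector)

    r = set_r(mask)
    if r is None:
        raise ParameterError("correlation undefined on the full response set "
                             "(zero-variance TSignal or OS)")
    trace: list[tuple[int, float]] = [(0, r)]
    removed: list[str] = []

    step = 0
    while mask.sum() > min_set_size:
        best_j, best_r = -1, r
        for j in np.flatnonzero(mask):  # ascending identifier order
            ts = np.array([c.score_without(mask, j) for c in caches])
            cand_r = _pearson(ts, os_vector)
            if cand_r is None:
                continue  # removal would make r undefined; skip candidate
            if cand_r > best_r:
                best_j, best_r = int(j), cand_r
        if best_j < 0:
            break
        mask[best_j] = False
        removed.append(proteins[best_j])
        r = best_r
        step += 1
        trace.append((step, r))
    retained = frozenset(p for p, keep in zip(proteins, mask) if keep)
    return CalibrationResult(retained=retained, removed=tuple(removed),
                             trace=tuple(trace))
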