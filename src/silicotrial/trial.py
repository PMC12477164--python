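"""The in-silico trial: per-patient two-step modeling, responder
stratification, and biomarker discovery.

Each patient is simulated in two steps.  Step one trains a disease-state
ensemble: a proximal stimulus (20 proteins near the knowledge set, +1)
drives the network toward maintaining the pathological knowledge-set
signs, with the patient's refined IDE signature enforced as constraints.
Step two applies the drug: its targets join the stimulus as clamped
inhibitory inputs (-1), and each disease solution's weights are refined by
a light re-annealing toward reversal of the knowledge-set signs — with the
IDE constraint released and validity requiring only 60% coverage of the
response layer.  The model TSignal (mean reversal-signed activity over the
treatment ensemble) is the patient's predicted response.

Cohort-level: patients strictly above the 90th TSignal percentile are good
responders, strictly below the 10th poor responders.  Mechanistic
biomarkers are proteins whose treatment-model activity separates the two
groups (Welch + BH FDR < 0.05 and |mean difference| > 0.1 in discovery
mode; Mann-Whitney raw p < 0.05 and |median difference| > 0.1 in
validation mode); predictive biomarkers are proteins whose IDE inclusion
frequency/sign differs between groups (two-sided Fisher, raw p < 0.05).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError
from .expression import (ExpressionMatrix, IDESignature, QUANTILE_METHOD,
                         call_ides, healthy_bounds, population_degs, refine_ides)
from .network import (InteractionNetwork, KnowledgeSet, Stimulus,
                      select_proximal_stimulus, within_k_links)
from .propagation import PropagationEngine
from .scoring import model_tsignal
from .training import (AnnealSchedule, ConstraintSet, Solution, SolutionEnsemble,
                       anneal, profile_edge_scales, sample_ensemble)

logger = logging.getLogger(__name__)

__all__ = [
    "TrialConfig",
    "PatientModel",
    "TrialResult",
    "run_patient",
    "run_trial",
    "stratify",
    "mechanistic_biomarkers",
    "predictive_biomarkers",
    "enrichment",
    "predictive_evaluation",
    "read_gmt",
]


@dataclass(frozen=True)
class TrialConfig:
    """Tunable knobs of the per-patient simulation.

    ``n_solutions`` valid solutions are collected per patient and step
    (50 at production scale; small trials use fewer).  The treatment
    schedule is deliberately lighter and colder than the disease schedule:
    it refines an already-trained solution, and the amount of reversal
    achievable under that fixed budget is exactly what TSignal measures.
    """

    n_solutions: int = 50
    max_attempts: int | None = None
    stimulus_size: int = 20
    min_ide: int = 10
    min_ide_sign_agreement: float = 0.50
    min_response_coverage: float = 0.60
    init_jitter: float = 0.3
    profile_damp: float = 0.15
    offprofile_penalty: float = 0.02
    n_steps: int = 3
    treatment_retries: int = 3
    disease_schedule: AnnealSchedule = field(
        default_factory=lambda: AnnealSchedule(
            t0=0.003, gamma=0.90, steps_per_temp=50, n_temps=40,
            proposal_sigma=1.0))
    treatment_schedule: AnnealSchedule = field(
        default_factory=lambda: AnnealSchedule(
            t0=0.001, gamma=0.90, steps_per_temp=15, n_temps=10,
            proposal_sigma=1.0))


@dataclass
class PatientModel:
    """One patient's trained disease/treatment ensembles and response."""

    patient: str
    disease_ensemble: SolutionEnsemble | None
    treatment_ensemble: SolutionEnsemble | None
    tsignal: float
    label: Literal["good", "poor", "intermediate", "excluded"] = "intermediate"

    @property
    def excluded(self) -> bool:
        return self.label == "excluded"


def run_patient(network: InteractionNetwork, knowledge_set: KnowledgeSet,
                ide: IDESignature, drug: Stimulus,
                config: TrialConfig = TrialConfig(), seed: int = 0,
                stimulus: Stimulus | None = None,
                engine: PropagationEngine | None = None) -> PatientModel:
    """Two-step simulation for one patient.

    Step 1 trains the disease-state ensemble (proximal stimulus, knowledge
    set maintained, IDE enforced); step 2 refines each disease solution
    under the combined stimulus (proximal + drug targets at -1) toward
    reversal, with IDE constraints released and coverage-only validity.
    A patient with no valid disease (or treatment) solution is excluded.

    Initial weights are profile-guided: edges touching proteins measured
    normal in this patient start damped (``config.profile_damp``), so the
    individualized model routes signal through the patient's own
    dysregulated proteins, and the drug's input flip transmits into the
    response layer only along channels that patient actually carries.
    """
    eng = engine if engine is not None else PropagationEngine(network)
    stim = stimulus if stimulus is not None else select_proximal_stimulus(
        network, knowledge_set, n=config.stimulus_size)
    profile = (set(ide.entries) | set(knowledge_set.proteins)
               | stim.proteins | drug.proteins)
    scales = profile_edge_scales(eng, profile, damp_factor=config.profile_damp)
    penalty = config.offprofile_penalty * (scales < 1.0)

    disease_constraints = ConstraintSet(
        response_constraints=knowledge_set.entries,
        ide_constraints=ide.entries,
        min_ide_sign_agreement=config.min_ide_sign_agreement,
        min_response_coverage=config.min_response_coverage,
        enforce_ide=True,
        response_objective="sign",
    )
    disease_ens = sample_ensemble(
        network, stim, disease_constraints, n_solutions=config.n_solutions,
        max_attempts=config.max_attempts, seed=seed,
        schedule=config.disease_schedule, init_jitter=config.init_jitter,
        edge_scales=scales, weight_penalty=penalty, n_steps=config.n_steps,
        engine=eng, patient=ide.patient, condition="disease")
    if disease_ens.unsolvable:
        logger.warning("patient %s: disease state unsolvable; excluded", ide.patient)
        return PatientModel(ide.patient, disease_ens, None, math.nan, "excluded")

    treatment_constraints = ConstraintSet(
        response_constraints=knowledge_set.reversed(),
        min_response_coverage=config.min_response_coverage,
        enforce_ide=False,
        response_objective="sign",
    )
    compiled = treatment_constraints.compile(eng)
    combined = stim.merged(drug)
    stim_idx, stim_val = eng.stimulus_arrays(combined.entries)

    treatment_solutions: list[Solution] = []
    treatment_seed_base = seed + 100_000
    for i, disease_sol in enumerate(disease_ens.solutions):
        for retry in range(config.treatment_retries):
            s = treatment_seed_base + i * config.treatment_retries + retry
            sol = anneal(network, combined, treatment_constraints,
                         schedule=config.treatment_schedule, seed=s,
                         initial_weights=disease_sol.effective_weights,
                         weight_penalty=penalty, n_steps=config.n_steps,
                         engine=eng)
            activity = np.zeros(eng.n_nodes)
            step = np.full(eng.n_nodes, -1, dtype=np.int64)
            for p, a in sol.state.activities.items():
                activity[eng.node_index[p]] = a
                step[eng.node_index[p]] = sol.state.step_assigned.get(p, 0)
            if compiled.is_valid(activity, step):
                treatment_solutions.append(sol)
                break
    treatment_ens = SolutionEnsemble(
        solutions=treatment_solutions, patient=ide.patient,
        condition="treatment", n_requested=len(disease_ens.solutions),
        n_attempts=len(disease_ens.solutions))
    if treatment_ens.unsolvable:
        logger.warning("patient %s: treatment state unsolvable; excluded",
                       ide.patient)
        return PatientModel(ide.patient, disease_ens, treatment_ens,
                            math.nan, "excluded")

    ts = model_tsignal(treatment_ens, knowledge_set.reversed())
    return PatientModel(ide.patient, disease_ens, treatment_ens, ts)


def stratify(tsignals: Sequence[float], low_q: float = 0.10,
             high_q: float = 0.90) -> list[str]:
    """Label values strictly above the ``high_q`` percentile "good",
    strictly below the ``low_q`` percentile "poor", else "intermediate".

    Percentiles use the same linear-interpolation convention as the
    healthy-expression bounds.  With heavy ties spanning a threshold the
    group sizes can deviate from ~10% of n; this is logged.
    """
    values = np.asarray(tsignals, dtype=float)
    if len(values) < 10:
        raise ParameterError("stratification needs >= 10 values")
    lo, hi = np.quantile(values, [low_q, high_q], method=QUANTILE_METHOD)
    labels = ["good" if v > hi else "poor" if v < lo else "intermediate"
              for v in values]
    n = len(values)
    n_good, n_poor = labels.count("good"), labels.count("poor")
    expected = math.ceil(min(low_q, 1 - high_q) * n) - 1
    if abs(n_good - n_poor) > 0 or n_good < max(expected, 1):
        logger.info("stratification counts good=%d poor=%d (ties near the "
                    "thresholds can shift these)", n_good, n_poor)
    return labels


def _activity_matrix(models: Sequence[PatientModel]) -> pd.DataFrame:
    """Patient x protein summary: mean treatment-ensemble activity,
    unreached solutions contributing 0."""
    proteins: set[str] = set()
    for m in models:
        for sol in m.treatment_ensemble.solutions:
            proteins.update(sol.state.reached)
    cols = sorted(proteins)
    col_index = {p: i for i, p in enumerate(cols)}
    mat = np.zeros((len(models), len(cols)))
    for r, m in enumerate(models):
        sols = m.treatment_ensemble.solutions
        for sol in sols:
            for p, a in sol.state.activities.items():
                mat[r, col_index[p]] += a
        mat[r] /= max(len(sols), 1)
    return pd.DataFrame(mat, index=[m.patient for m in models], columns=cols)


def mechanistic_biomarkers(models: Sequence[PatientModel],
                           mode: Literal["discovery", "validation"] = "discovery",
                           fdr_alpha: float = 0.05,
                           effect_threshold: float = 0.1) -> pd.DataFrame:
    """Proteins whose treatment-model activity separates good from poor.

    Discovery: Welch's t-test, BH FDR < 0.05 AND |mean difference| > 0.1.
    Validation (small cohorts): Mann-Whitney U, raw p < 0.05 AND |median
    difference| > 0.1.  The unit of analysis is the patient (mean activity
    over that patient's treatment solutions, unreached counted as 0).
    """
    good = [m for m in models if m.label == "good"]
    poor = [m for m in models if m.label == "poor"]
    if len(good) < 2 or len(poor) < 2:
        raise ParameterError("need >= 2 patients per responder group")
    summary = _activity_matrix(list(good) + list(poor))
    g = summary.iloc[:len(good)].to_numpy()
    p_mat = summary.iloc[len(good):].to_numpy()

    var_ok = (g.var(axis=0, ddof=1) > 0) | (p_mat.var(axis=0, ddof=1) > 0)
    n_skipped = int((~var_ok).sum())
    if n_skipped:
        logger.info("skipping %d zero-variance protein(s)", n_skipped)
    proteins = summary.columns[var_ok]
    g, p_mat = g[:, var_ok], p_mat[:, var_ok]

    if mode == "discovery":
        stat, pvals = stats.ttest_ind(g, p_mat, axis=0, equal_var=False)
        effect = g.mean(axis=0) - p_mat.mean(axis=0)
        _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
        significant = (fdr < fdr_alpha) & (np.abs(effect) > effect_threshold)
    elif mode == "validation":
        stat = np.empty(len(proteins))
        pvals = np.empty(len(proteins))
        for j in range(len(proteins)):
            res = stats.mannwhitneyu(g[:, j], p_mat[:, j], alternative="two-sided")
            stat[j], pvals[j] = res.statistic, res.pvalue
        effect = np.median(g, axis=0) - np.median(p_mat, axis=0)
        _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
        significant = (pvals < fdr_alpha) & (np.abs(effect) > effect_threshold)
    else:
        raise ParameterError(f"unknown mode {mode!r}")

    return pd.DataFrame({
        "protein": proteins,
        "statistic": stat,
        "effect_size": effect,
        "p": pvals,
        "fdr": fdr,
        "direction": np.sign(effect).astype(int),
        "significant": significant,
        "type": "mechanistic",
    }).reset_index(drop=True)


def predictive_biomarkers(ides: Sequence[IDESignature],
                          labels: Mapping[str, str],
                          alpha: float = 0.05) -> pd.DataFrame:
    """Proteins whose IDE inclusion frequency/sign differs between groups.

    For each protein and direction d in {+1, -1}: a 2x2 table of
    [good with entry d, good without] x [poor with entry d, poor without],
    two-sided Fisher's exact test.  A protein is significant if its
    smaller-p direction has raw p < 0.05 (no multiplicity adjustment); the
    reported direction is the smaller-p one.
    """
    good = [s for s in ides if labels.get(s.patient) == "good"]
    poor = [s for s in ides if labels.get(s.patient) == "poor"]
    if not good or not poor:
        raise ParameterError("need >= 1 patient per responder group")
    proteins = sorted(set().union(*(s.proteins for s in good + poor)))
    rows = []
    n_good, n_poor = len(good), len(poor)
    for protein in proteins:
        best_p, best_dir, best_or = 1.0, 0, math.nan
        for d in (+1, -1):
            a = sum(1 for s in good if s.entries.get(protein) == d)
            c = sum(1 for s in poor if s.entries.get(protein) == d)
            table = [[a, n_good - a], [c, n_poor - c]]
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            if p < best_p or (p == best_p and best_dir == 0):
                best_p, best_dir, best_or = p, d, odds
        rows.append((protein, best_or, best_p, best_dir, best_p < alpha))
    df = pd.DataFrame(rows, columns=["protein", "statistic", "p",
                                     "direction", "significant"])
    df["effect_size"] = df["statistic"]
    df["fdr"] = df["p"]  # raw p is the decision scale here (no adjustment)
    df["type"] = "predictive"
    return df[["protein", "statistic", "effect_size", "p", "fdr",
               "direction", "significant", "type"]]


def enrichment(proteins: set[str], annotations: Mapping[str, set[str]],
               background: set[str], fdr_alpha: float = 0.05,
               min_coverage: float = 0.10) -> pd.DataFrame:
    """Hypergeometric pathway over-representation of a protein set.

    The background is the set of proteins with predicted activity;
    annotations are clipped to it.  Significant: BH FDR < 0.05 AND the
    overlap covers at least 10% of the input set (rounded up).
    """
    if not background:
        raise ParameterError("empty background")
    stray = proteins - background
    if stray:
        raise ParameterError(f"input proteins outside background: {sorted(stray)[:5]}")
    m_total = len(background)
    n_input = len(proteins)
    min_overlap = math.ceil(min_coverage * n_input)
    rows = []
    for pathway in sorted(annotations):
        members = annotations[pathway] & background
        if not members:
            continue
        overlap = len(proteins & members)
        # P(X >= overlap), X ~ Hypergeom(M=m_total, K=|members|, n=n_input)
        p = float(stats.hypergeom.sf(overlap - 1, m_total, len(members), n_input))
        rows.append((pathway, overlap, len(members), p))
    if not rows:
        return pd.DataFrame(columns=["pathway", "overlap", "pathway_size",
                                     "p", "fdr", "significant"])
    df = pd.DataFrame(rows, columns=["pathway", "overlap", "pathway_size", "p"])
    _, fdr, _, _ = multipletests(df["p"], method="fdr_bh")
    df["fdr"] = fdr
    df["significant"] = (df["fdr"] < fdr_alpha) & (df["overlap"] >= min_overlap)
    return df


def predictive_evaluation(expression: ExpressionMatrix,
                          labels: Mapping[str, str], protein: str,
                          n_splits: int = 10, n_repeats: int = 100,
                          seed: int = 0, auc_threshold: float = 0.7
                          ) -> tuple[float, bool]:
    """Cross-validated AUC of a univariate logistic model for one protein.

    Stratified ``n_splits``-fold CV repeated ``n_repeats`` times with
    seeded shuffles; each repetition scores the pooled out-of-fold
    predictions, and the reported value is the mean AUC over repetitions.
    Returns ``(cv_auc, cv_auc > auc_threshold)``.
    """
    samples = [s for s in expression.samples
               if labels.get(str(s)) in ("good", "poor")]
    if len(samples) < 10:
        raise ParameterError("need >= 10 labeled samples")
    y = np.array([1 if labels[str(s)] == "good" else 0 for s in samples])
    if len(np.unique(y)) < 2:
        raise ParameterError("both labels must be present")
    x = expression.values.loc[protein, samples].to_numpy(dtype=float).reshape(-1, 1)
    min_class = int(np.bincount(y).min())
    splits = min(n_splits, min_class)
    if splits < 2:
        raise ParameterError("smallest class too small for cross-validation")
    if splits < n_splits:
        logger.info("reducing folds from %d to %d (smallest class has %d)",
                    n_splits, splits, min_class)

    aucs = np.empty(n_repeats)
    for rep in range(n_repeats):
        rep_seed = seed + rep
        while True:
            skf = StratifiedKFold(n_splits=splits, shuffle=True,
                                  random_state=rep_seed % (2**32))
            oof = np.empty(len(y))
            ok = True
            for train, test in skf.split(x, y):
                if len(np.unique(y[train])) < 2:
                    ok = False  # defensive; stratified folds keep both classes
                    break
                clf = LogisticRegression(max_iter=1000)
                clf.fit(x[train], y[train])
                oof[test] = clf.predict_proba(x[test])[:, 1]
            if ok:
                break
            rep_seed += n_repeats  # re-draw this repetition with a fresh seed
            logger.info("single-class fold; re-drawing repetition %d", rep)
        aucs[rep] = roc_auc_score(y, oof)
    cv_auc = float(aucs.mean())
    return cv_auc, cv_auc > auc_threshold


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read pathway annotations in GMT format (name, description, members)."""
    out: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            out[parts[0]] = {p for p in parts[2:] if p}
    return out


@dataclass
class TrialResult:
    """Everything the end-to-end synthetic trial computes."""

    models: list[PatientModel]
    labels: dict[str, str]
    tsignals: dict[str, float]
    ides: list[IDESignature]
    excluded_low_ide: list[str]
    excluded_unsolvable: list[str]
    mechanistic: pd.DataFrame | None = None
    predictive: pd.DataFrame | None = None


def run_trial(network: InteractionNetwork, knowledge_set: KnowledgeSet,
              healthy: ExpressionMatrix, disease: ExpressionMatrix,
              drug: Stimulus, config: TrialConfig = TrialConfig(),
              seed: int = 0, compute_biomarkers: bool = True) -> TrialResult:
    """Run the whole pipeline on one cohort.

    Expression -> IDE signatures (percentile calling, DEG + proximity
    refinement) -> per-patient two-step models -> TSignal stratification
    -> mechanistic and predictive biomarker tables.
    """
    bounds = healthy_bounds(healthy)
    raw_ides = call_ides(disease, bounds)
    degs = population_degs(disease, healthy)
    proximal = within_k_links(network, knowledge_set.proteins, 3)
    ides, excluded_low = refine_ides(raw_ides, degs, proximal,
                                     min_ide=config.min_ide)

    engine = PropagationEngine(network)
    stimulus = select_proximal_stimulus(network, knowledge_set,
                                        n=config.stimulus_size)
    models: list[PatientModel] = []
    excluded_unsolvable: list[str] = []
    for i, ide in enumerate(ides):
        model = run_patient(network, knowledge_set, ide, drug, config=config,
                            seed=seed + i * 1_000_000, stimulus=stimulus,
                            engine=engine)
        if model.excluded:
            excluded_unsolvable.append(ide.patient)
        else:
            models.append(model)
        logger.info("patient %s: tsignal=%.4f", ide.patient, model.tsignal)

    labels_list = stratify([m.tsignal for m in models])
    for m, lab in zip(models, labels_list):
        m.label = lab
    labels = {m.patient: m.label for m in models}
    tsignals = {m.patient: m.tsignal for m in models}

    mech = pred = None
    if compute_biomarkers:
        mech = mechanistic_biomarkers(models, mode="discovery")
        kept_ides = [s for s in ides if s.patient in labels]
        pred = predictive_biomarkers(kept_ides, labels)
    return TrialResult(models=models, labels=labels, tsignals=tsignals,
                       ides=ides, excluded_low_ide=excluded_low,
                       excluded_unsolvable=excluded_unsolvable,
                       mechanistic=mech, predictive=pred)
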