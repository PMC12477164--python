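"""Synthetic study generator: networks, cohorts, drugs, survival panels.

Every downstream stage of the pipeline is exercised on data produced here,
with planted structure serving as recoverable ground truth:

* a sparse directed signed network with heavy-tailed out-degree (hubs
  matter for propagation, as in real protein-interaction maps);
* a clustered disease knowledge set embedded in the network, with random
  pathological directions;
* healthy expression as per-protein lognormal baselines; disease samples
  with dysregulation concentrated within three interaction links of the
  knowledge set, shifted in the knowledge-set-concordant direction;
* a planted set of responder-associated proteins — mediators lying on
  directed paths from the trial drug's targets into the knowledge set —
  dysregulated only in a designated fraction of patients;
* a drug panel whose overall-survival benefits carry a planted monotone
  relationship to each drug's propagated reversal signal, so calibration
  has signal to find.

All generators are deterministic functions of their seed: repeated calls
with the same scenario produce identical objects.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParameterError, StructuralError
from .expression import ExpressionMatrix
from .network import (InteractionNetwork, KnowledgeSet, Stimulus,
                      select_proximal_stimulus, within_k_links, write_sign_map)
from .propagation import propagate
from .scoring import OSBenefitTable, model_tsignal
from .training import Solution, SolutionEnsemble

__all__ = [
    "SyntheticScenario",
    "CohortTruth",
    "DrugPanel",
    "StudyBundle",
    "generate_network",
    "generate_knowledge_set",
    "generate_cohort",
    "generate_drug_panel",
    "generate_study",
    "assign_os_benefit",
    "write_study",
]

# substream tags so each generator draws from an independent stream of the
# scenario seed
_SUB_NETWORK, _SUB_KNOWLEDGE, _SUB_COHORT, _SUB_DRUGS = 0, 1, 2, 3


@dataclass(frozen=True)
class SyntheticScenario:
    """Study conditions for one synthetic trial.

    ``effect_size`` is the planted shift in units of the per-protein
    healthy log-scale SD (multiplicative on the natural scale, keeping
    expression positive).  ``dysregulation_rate`` is the per-patient
    fraction of candidate proteins (within three links of the knowledge
    set) that are dysregulated.  ``n_responder_proteins`` mediators of the
    drug effect are dysregulated only in the ``responder_fraction`` of
    patients planted as would-be responders.
    """

    seed: int = 0
    n_proteins: int = 250
    mean_out_degree: float = 2.0
    inhibitory_edge_fraction: float = 0.3
    knowledge_set_size: int = 30
    n_patients: int = 80
    n_healthy: int = 200
    dysregulation_rate: float = 0.3
    effect_size: float = 3.0
    n_responder_proteins: int = 6
    responder_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_proteins < 10:
            raise ParameterError("n_proteins must be >= 10")
        if self.mean_out_degree < 1:
            raise ParameterError("mean_out_degree must be >= 1")
        if self.mean_out_degree >= self.n_proteins:
            raise ParameterError("mean out-degree must be < n_proteins")
        if not 0.0 <= self.inhibitory_edge_fraction <= 1.0:
            raise ParameterError("inhibitory_edge_fraction outside [0,1]")
        if self.knowledge_set_size >= self.n_proteins:
            raise ParameterError("knowledge_set_size must be < n_proteins")
        for name in ("dysregulation_rate", "responder_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} outside [0,1]")
        if self.effect_size < 0:
            raise ParameterError("effect_size must be >= 0")


def _protein_name(i: int, width: int) -> str:
    return f"P{i:0{width}d}"


def generate_network(scenario: SyntheticScenario) -> InteractionNetwork:
    """Directed signed weighted network with heavy-tailed out-degree.

    Out-degrees follow a shifted Pareto scaled to ``mean_out_degree``;
    targets are drawn preferentially toward nodes that already receive
    edges (configuration-style attachment, producing PPI-like hubs).
    Weights are uniform on [0.3, 1]; a ``inhibitory_edge_fraction`` of
    edges carry sign -1.  Components are stitched until the graph is
    weakly connected.
    """
    rng = np.random.default_rng([scenario.seed, _SUB_NETWORK])
    n = scenario.n_proteins
    width = len(str(n - 1))
    names = [_protein_name(i, width) for i in range(n)]

    # heavy-tailed out-degree with the requested mean: 1 + scaled Pareto(2)
    scale = max(scenario.mean_out_degree - 1.0, 1e-9)
    raw = 1.0 + rng.pareto(2.0, size=n) * scale
    out_deg = np.minimum(np.round(raw).astype(int), max(n // 4, 2))
    out_deg = np.maximum(out_deg, 1)

    # configuration-style wiring: heavy-tailed out-degree, near-uniform
    # in-degree (each stub picks a uniform random non-self target)
    edge_set: set[tuple[int, int]] = set()
    for i in rng.permutation(n):
        d = int(out_deg[i])
        targets = rng.choice(n - 1, size=min(d, n - 1), replace=False)
        for j in targets:
            j = int(j) + (int(j) >= i)  # skip self
            edge_set.add((i, j))

    # stitch weakly connected components together
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edge_set)
    components = sorted(nx.weakly_connected_components(g), key=len, reverse=True)
    while len(components) > 1:
        giant, other = components[0], components[1]
        u = int(rng.choice(sorted(giant)))
        v = int(rng.choice(sorted(other)))
        edge_set.add((u, v))
        g.add_edge(u, v)
        components = sorted(nx.weakly_connected_components(g), key=len, reverse=True)

    edges = []
    for (i, j) in sorted(edge_set):
        sign = -1 if rng.random() < scenario.inhibitory_edge_fraction else 1
        weight = float(rng.uniform(0.3, 1.0))
        edges.append((names[i], names[j], sign, weight))
    return InteractionNetwork(edges, extra_nodes=names)


def generate_knowledge_set(network: InteractionNetwork,
                           scenario: SyntheticScenario,
                           min_reach_fraction: float = 0.8,
                           max_tries: int = 50,
                           salt: int = 0) -> KnowledgeSet:
    """Embed a knowledge set with random pathological signs.

    Members are sampled across the whole network (disease proteins are
    scattered, not a single dense ball), and the draw is retried until at
    least ``min_reach_fraction`` of members lie within three directed
    steps of the prospective proximal stimulus — otherwise disease-state
    models could never satisfy the 60% coverage rule for structural
    reasons.
    """
    rng = np.random.default_rng([scenario.seed, _SUB_KNOWLEDGE, salt])
    nodes = sorted(network.nodes)
    size = scenario.knowledge_set_size
    for _ in range(max_tries):
        members = sorted(str(m) for m in rng.choice(nodes, size=size,
                                                    replace=False))
        signs = {m: int(rng.choice([-1, 1])) for m in members}
        ks = KnowledgeSet(signs)
        try:
            stimulus = select_proximal_stimulus(network, ks, n=20)
        except StructuralError:
            continue
        reach: set[str] = set()
        for depth, layer in enumerate(
                nx.bfs_layers(network.graph, sorted(stimulus.proteins))):
            if depth > 3:
                break
            reach.update(layer)
        if len(reach & ks.proteins) >= min_reach_fraction * size:
            return ks
    raise StructuralError(
        f"no knowledge set with >= {min_reach_fraction:.0%} structural reach "
        f"found in {max_tries} tries; network too sparse")


@dataclass(frozen=True)
class CohortTruth:
    """Planted ground truth for one synthetic cohort."""

    responder_patients: frozenset[str]
    responder_proteins: frozenset[str]
    candidate_proteins: frozenset[str]
    directions: dict[str, int]          # protein -> planted shift direction
    carriers: dict[str, frozenset[str]]  # patient -> dysregulated proteins

    def to_json(self, path: str | Path) -> None:
        payload = {
            "responder_patients": sorted(self.responder_patients),
            "responder_proteins": sorted(self.responder_proteins),
            "candidate_proteins": sorted(self.candidate_proteins),
            "directions": dict(sorted(self.directions.items())),
            "carriers": {p: sorted(v) for p, v in sorted(self.carriers.items())},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _concordant_directions(network: InteractionNetwork, ks: KnowledgeSet,
                           candidates: set[str], rng: np.random.Generator
                           ) -> dict[str, int]:
    """Planted shift direction per candidate: knowledge-set members keep
    their pathological sign; neighbors inherit the sign of the member that
    first reaches them in a multi-source undirected BFS."""
    directions: dict[str, int] = dict(ks.entries)
    undirected = network.undirected()
    frontier = sorted(ks.proteins)
    seen = set(frontier)
    while frontier:
        nxt: list[str] = []
        for u in frontier:
            for v in sorted(undirected.neighbors(u)):
                if v not in seen:
                    seen.add(v)
                    directions[v] = directions[u]
                    nxt.append(v)
        frontier = nxt
    return {p: directions[p] for p in candidates if p in directions}


def generate_cohort(scenario: SyntheticScenario, network: InteractionNetwork,
                    knowledge_set: KnowledgeSet,
                    responder_proteins: set[str] | None = None,
                    ) -> tuple[ExpressionMatrix, ExpressionMatrix, CohortTruth]:
    """Healthy and disease expression with planted dysregulation.

    Healthy: per-protein lognormal baselines (log-location ~ N(5, 1),
    log-SD ~ U(0.3, 0.6)) with independent noise per sample.  Disease:
    each patient dysregulates a ``dysregulation_rate`` fraction of the
    candidate proteins (within 3 links of the knowledge set, responder
    proteins excluded from this pool), shifted ``effect_size`` log-SDs in
    the knowledge-set-concordant direction.  The planted responder
    proteins are shifted in responder patients only.
    """
    knowledge_set.resolve(network)
    rng = np.random.default_rng([scenario.seed, _SUB_COHORT])
    proteins = sorted(network.nodes)
    n_prot = len(proteins)

    candidates = within_k_links(network, knowledge_set.proteins, 3)
    if not candidates:
        raise StructuralError("empty 3-link neighborhood of the knowledge set")
    directions = _concordant_directions(network, knowledge_set, candidates, rng)

    if responder_proteins is None:
        pool = sorted(candidates - knowledge_set.proteins)
        if len(pool) < scenario.n_responder_proteins:
            raise StructuralError(
                f"only {len(pool)} non-knowledge-set candidates for "
                f"{scenario.n_responder_proteins} responder proteins")
        responder_proteins = {
            str(p) for p in rng.choice(pool, size=scenario.n_responder_proteins,
                                       replace=False)}
    else:
        stray = responder_proteins - candidates
        if stray:
            raise StructuralError(
                f"responder proteins outside the 3-link neighborhood: {sorted(stray)}")

    mu = rng.normal(5.0, 1.0, size=n_prot)
    sigma = rng.uniform(0.3, 0.6, size=n_prot)

    n_h, n_p = scenario.n_healthy, scenario.n_patients
    healthy_log = mu[:, None] + sigma[:, None] * rng.standard_normal((n_prot, n_h))
    disease_log = mu[:, None] + sigma[:, None] * rng.standard_normal((n_prot, n_p))

    patient_ids = [f"PT{i:03d}" for i in range(n_p)]
    healthy_ids = [f"HC{i:03d}" for i in range(n_h)]

    n_responders = int(round(scenario.responder_fraction * n_p))
    responder_patients = {patient_ids[i]
                          for i in rng.choice(n_p, size=n_responders,
                                              replace=False)}

    prot_index = {p: i for i, p in enumerate(proteins)}
    general_pool = sorted((candidates - responder_proteins))
    carriers: dict[str, frozenset[str]] = {}
    for j, patient in enumerate(patient_ids):
        mask = rng.random(len(general_pool)) < scenario.dysregulation_rate
        dysregulated = {p for p, m in zip(general_pool, mask) if m}
        if patient in responder_patients:
            dysregulated |= responder_proteins
        for p in dysregulated:
            i = prot_index[p]
            disease_log[i, j] += directions[p] * scenario.effect_size * sigma[i]
        carriers[patient] = frozenset(dysregulated)

    healthy = ExpressionMatrix(pd.DataFrame(np.exp(healthy_log), index=proteins,
                                            columns=healthy_ids))
    disease = ExpressionMatrix(pd.DataFrame(np.exp(disease_log), index=proteins,
                                            columns=patient_ids))
    truth = CohortTruth(
        responder_patients=frozenset(responder_patients),
        responder_proteins=frozenset(responder_proteins),
        candidate_proteins=frozenset(candidates),
        directions=directions,
        carriers=carriers,
    )
    return healthy, disease, truth


@dataclass(frozen=True)
class DrugPanel:
    """Synthetic first-line drug panel with an OS-benefit calibration target."""

    stimuli: dict[str, Stimulus]
    os_table: OSBenefitTable
    noise_proteins: frozenset[str]  # response proteins excluded from the
    # OS-generating signal (what calibration should remove)


def generate_drug_panel(network: InteractionNetwork, knowledge_set: KnowledgeSet,
                        n_drugs: int = 5, targets_per_drug: int = 6,
                        seed: int = 0, n_noise_proteins: int = 0,
                        relationship_slope: float = 1.0,
                        noise_sd: float = 0.25,
                        min_coverage: float = 0.5) -> DrugPanel:
    """Drug target sets (inhibition, effect -1) plus a planted OS panel.

    Each drug is a multi-target inhibitor (first-line drugs of this class
    hit a dozen or more kinases): targets are sampled among proteins with
    a directed path of length <= 2 into the knowledge set, re-drawn until
    the target set structurally reaches at least ``min_coverage`` of the
    knowledge set within three steps, so trained drug models can satisfy
    the coverage validity rule.

    OS benefit is a monotone affine function (``relationship_slope``
    scales months per SD of signal) of the drug's propagated reversal
    score over the knowledge set minus ``n_noise_proteins`` designated
    members, plus Gaussian noise (``noise_sd`` months).  The designated
    noise proteins are the members whose per-drug reversal profile is
    most discordant with the full-set consensus — response proteins that
    do not track clinical benefit, which is exactly what calibration is
    meant to strip out.  With ``relationship_slope=0`` the panel carries
    no signal at all.
    """
    if targets_per_drug < 1:
        raise ParameterError("targets_per_drug must be >= 1")
    if n_drugs < 1:
        raise ParameterError("n_drugs must be >= 1")
    knowledge_set.resolve(network)
    rng = np.random.default_rng([seed, _SUB_DRUGS])

    reversed_graph = network.graph.reverse(copy=False)
    upstream: set[str] = set()
    for depth, layer in enumerate(
            nx.bfs_layers(reversed_graph, sorted(knowledge_set.proteins))):
        if depth > 2:
            break
        if depth >= 1:
            upstream.update(layer)
    upstream -= knowledge_set.proteins
    pool = sorted(upstream)
    if len(pool) < targets_per_drug:
        raise StructuralError(
            f"only {len(pool)} proteins upstream of the knowledge set, "
            f"{targets_per_drug} targets per drug requested")

    ks_members = sorted(knowledge_set.proteins)
    if n_noise_proteins > len(ks_members):
        raise ParameterError("more noise proteins than knowledge-set members")

    def structural_coverage(targets: list[str]) -> float:
        reach: set[str] = set()
        for depth, layer in enumerate(nx.bfs_layers(network.graph, targets)):
            if depth > 3:
                break
            reach.update(layer)
        return len(reach & knowledge_set.proteins) / len(ks_members)

    stimuli: dict[str, Stimulus] = {}
    states = []
    for d in range(n_drugs):
        best_targets: list[str] | None = None
        best_cov = -1.0
        for _ in range(100):
            targets = sorted(str(t) for t in
                             rng.choice(pool, size=targets_per_drug,
                                        replace=False))
            cov = structural_coverage(targets)
            if cov > best_cov:
                best_targets, best_cov = targets, cov
            if cov >= min_coverage:
                break
        name = f"drug{d:02d}"
        stimuli[name] = Stimulus({t: -1 for t in best_targets})
        states.append(propagate(network, stimuli[name]))

    # per-drug, per-member reversal contributions at the network's own weights
    reversed_signs = knowledge_set.reversed()
    contrib = np.zeros((n_drugs, len(ks_members)))
    for d, state in enumerate(states):
        for j, member in enumerate(ks_members):
            a = state.activities.get(member)
            if a is not None:
                contrib[d, j] = a * reversed_signs[member]

    single_ensembles = {
        name: SolutionEnsemble(
            solutions=[Solution(effective_weights=np.empty(0), state=state,
                                fulfillment=float("nan"), seed=seed)],
            n_requested=1, n_attempts=1)
        for (name, _), state in zip(stimuli.items(), states)}
    noise, os_table = _plant_os(single_ensembles, reversed_signs,
                                n_noise_proteins, relationship_slope,
                                noise_sd, rng)
    return DrugPanel(stimuli=stimuli, os_table=os_table, noise_proteins=noise)


def _plant_os(ensembles, expected: dict[str, int], n_noise_proteins: int,
              relationship_slope: float, noise_sd: float,
              rng: np.random.Generator, discordance_boost: float = 2.0
              ) -> tuple[frozenset[str], OSBenefitTable]:
    """Designate discordant response proteins and derive OS benefits.

    The designated noise members are the response proteins with the most
    drug-discriminating contribution profiles (largest variance of mean
    reversal-signed activity across drugs).  The OS-generating signal is
    ``(1 + b) * score(clean) - b * score(full)`` where ``score`` is the
    exact ensemble response score later used by calibration: benefit
    tracks what the drugs do to the concordant members and is actively
    pushed away from a score that still contains the noise members, so
    greedy elimination has a decisive gain from stripping each of them.
    """
    drug_names = sorted(ensembles)
    members = sorted(expected)
    contrib = np.zeros((len(drug_names), len(members)))
    for d, name in enumerate(drug_names):
        sols = ensembles[name].solutions
        for j, member in enumerate(members):
            vals = [sol.state.activities.get(member, 0.0) for sol in sols]
            contrib[d, j] = float(np.mean(vals)) * expected[member]

    order = np.argsort(-contrib.std(axis=0), kind="stable")
    noise_idx = list(order[:n_noise_proteins])
    noise = frozenset(members[j] for j in noise_idx)
    clean_expected = {m: s for m, s in expected.items() if m not in noise}

    t_full = np.array([model_tsignal(ensembles[d], expected)
                       for d in drug_names])
    t_clean = np.array([model_tsignal(ensembles[d], clean_expected)
                        for d in drug_names]) if clean_expected else t_full
    b = discordance_boost if noise_idx else 0.0
    signals = (1.0 + b) * t_clean - b * t_full
    spread = signals.std()
    standardized = (signals - signals.mean()) / spread if spread > 0 \
        else np.zeros(len(drug_names))
    benefits = 6.0 + relationship_slope * 3.0 * standardized \
        + rng.normal(0.0, noise_sd, size=len(drug_names))
    return noise, OSBenefitTable(
        {name: float(v) for name, v in zip(drug_names, benefits)})


def assign_os_benefit(panel: DrugPanel, ensembles, knowledge_set: KnowledgeSet,
                      n_noise_proteins: int = 3, seed: int = 0,
                      relationship_slope: float = 1.0,
                      noise_sd: float = 0.25) -> DrugPanel:
    """Re-derive the OS panel from a set of drug model ensembles.

    The clinical benefit of a real drug reflects what the drug actually
    does to the disease machinery; here that role is played by the
    supplied models' own reversal scores, so the planted monotone OS
    relationship (and its designated discordant noise members) lives on
    the same scale calibration later scores.  Takes the stimuli of an
    existing ``panel`` plus one
    :class:`~silicotrial.training.SolutionEnsemble` per drug.
    """
    rng = np.random.default_rng([seed, _SUB_DRUGS, 7])
    noise, os_table = _plant_os(ensembles, knowledge_set.reversed(),
                                n_noise_proteins, relationship_slope,
                                noise_sd, rng)
    return DrugPanel(stimuli=dict(panel.stimuli), os_table=os_table,
                     noise_proteins=noise)


@dataclass(frozen=True)
class StudyBundle:
    """Everything one synthetic trial needs, wired consistently."""

    scenario: SyntheticScenario
    network: InteractionNetwork
    knowledge_set: KnowledgeSet
    drug: Stimulus
    healthy: ExpressionMatrix
    disease: ExpressionMatrix
    truth: CohortTruth


def _wave_steps(network: InteractionNetwork, sources: set[str]) -> dict[str, int]:
    """Directed BFS layer of every node from a source set.

    Because wave-front candidacy is purely topological (a node joins the
    wave after which it first has an assigned in-neighbor, whatever the
    weights), this gives the freeze step of each node for ANY weight
    vector — the geometry the study generator needs to reason about.
    """
    steps: dict[str, int] = {}
    for depth, layer in enumerate(nx.bfs_layers(network.graph, sorted(sources))):
        for node in layer:
            steps[node] = depth
    return steps


def generate_study(scenario: SyntheticScenario,
                   max_targets: int = 18) -> StudyBundle:
    """Generate a coherent trial: network, knowledge set, drug, cohort.

    The trial drug is a multi-target inhibitor whose targets are drawn
    from the proximal stimulus: disease-driving proteins, clamped +1
    during disease-state modeling and overridden to -1 under treatment,
    so the drug acts by flipping inputs the trained models actually use.
    The planted responder proteins are *exclusive mediators* of those
    targets — first-wave nodes whose stimulus inputs all come from drug
    targets (their activity inverts exactly under treatment) and which
    feed knowledge-set members that freeze at wave 2 or later (members
    frozen at wave 1 are set entirely by direct stimulus edges and cannot
    respond to any mediator).  Responder patients carry dysregulation —
    hence IDE training constraints — on exactly those mediator channels,
    which is what makes their trained models transmit the drug's sign
    flip into the response layer.
    """
    network = generate_network(scenario)
    rng = np.random.default_rng([scenario.seed, _SUB_DRUGS, 1])
    graph = network.graph

    best: tuple[KnowledgeSet, set[str], list[str]] | None = None
    for salt in range(60):
        try:
            ks = generate_knowledge_set(network, scenario, salt=salt)
        except StructuralError:
            continue
        stimulus = select_proximal_stimulus(network, ks, n=20)
        steps = _wave_steps(network, stimulus.proteins)
        candidates = within_k_links(network, ks.proteins, 3)
        late_ks = {k for k in ks.proteins if steps.get(k, -1) >= 2}
        if not late_ks:
            continue

        stim_parents = {
            m: set(graph.predecessors(m)) & stimulus.proteins
            for m in candidates - ks.proteins - stimulus.proteins
            if steps.get(m, -1) == 1 and (set(graph.successors(m)) & late_ks)}

        # set-cover greedy: repeatedly absorb the mediator whose stimulus
        # parents add fewest new targets, until the target budget is spent
        targets: set[str] = set()
        pool: set[str] = set()
        while True:
            gains = sorted(
                (len(parents - targets), sorted(parents - targets), m)
                for m, parents in stim_parents.items()
                if m not in pool and parents)
            if not gains:
                break
            need, _, _ = gains[0]
            if len(targets) + need > max_targets:
                break
            targets |= stim_parents[gains[0][2]]
            pool = {m for m, parents in stim_parents.items()
                    if parents and parents <= targets}
        if len(pool) >= scenario.n_responder_proteins:
            best = (ks, targets, sorted(pool))
            break
        if best is None or len(pool) > len(best[2]):
            best = (ks, targets, sorted(pool))
    if best is None or len(best[2]) < scenario.n_responder_proteins:
        found = 0 if best is None else len(best[2])
        raise StructuralError(
            f"only {found} target-exclusive mediators for "
            f"{scenario.n_responder_proteins} responder proteins "
            f"(network too dense around the knowledge set)")
    ks, targets, pool = best
    responder_proteins = set(
        str(p) for p in rng.choice(pool, size=scenario.n_responder_proteins,
                                   replace=False))
    drug = Stimulus({t: -1 for t in sorted(targets)})

    healthy, disease, truth = generate_cohort(
        scenario, network, ks, responder_proteins=responder_proteins)
    return StudyBundle(scenario=scenario, network=network, knowledge_set=ks,
                       drug=drug, healthy=healthy, disease=disease, truth=truth)


def write_study(bundle: StudyBundle, outdir: str | Path) -> None:
    """Dump a study bundle as the pipeline's plain-text interchange files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.network.to_tsv(outdir / "network.tsv")
    write_sign_map(bundle.knowledge_set.entries, outdir / "knowledge_set.tsv")
    write_sign_map(bundle.drug.entries, outdir / "drug.tsv",
                   header=("protein", "effect"))
    bundle.healthy.to_tsv(outdir / "healthy.tsv")
    bundle.disease.to_tsv(outdir / "disease.tsv")
    bundle.truth.to_json(outdir / "truth.json")
    (outdir / "scenario.json").write_text(json.dumps(asdict(bundle.scenario), indent=1))
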