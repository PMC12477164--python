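# Methods

`silicotrial` implements an in-silico clinical-trial pipeline on signed
protein-interaction networks: individualized differential-expression
profiling, constraint-trained network models of disease and treatment,
a calibrated response score, responder stratification, and biomarker
statistics — all exercised end-to-end on synthetic cohorts with planted,
recoverable ground truth.

## The network model

The substrate is a directed graph whose nodes are proteins and whose
edges carry a sign (+1 activating, −1 inhibitory) and a weight in
(0, 1]. Internally every edge is reduced to one *effective weight*
`sign × weight ∈ [−1, 1]`; training operates directly on this quantity,
so an optimizer move can change interaction strength and direction in
one step.

### Signal propagation

A perturbation (stimulus) assigns input values to a set of clamped
nodes. The signal then spreads in synchronous wave fronts: at step *t*,
every not-yet-assigned node with an incoming edge from a node assigned
at step *t − 1* receives

    a_v = tanh( Σ_u  w_uv · a_u )       over ALL already-assigned upstream u,

and freezes at that value. Three steps is the default horizon: the
perturbation reaches downstream response proteins without diffusing over
the whole network, and freezing handles cycles with no special casing.
Stimulus nodes are never overwritten. Two consequences worth noting:

* the *wave structure is purely topological* — which step a node freezes
  at depends only on the graph and the stimulus set, never on the
  weights; the synthetic-study generator exploits this to place planted
  structure where it can matter;
* `tanh` is odd, so negating a stimulus negates every activity exactly.

The engine fixes node order (sorted identifiers) and edge order (target,
then source), which pins the floating-point summation order; results are
reproducible to the bit, and the test suite holds the engine to exact
equality against an independently coded dict-based recursion.

## Constraints, validity, and annealing

A model for one patient/condition is trained against two constraint
layers:

* **response constraints** — the disease knowledge set (protein →
  pathological sign). Disease-state models must hold these signs;
  treatment models are scored on their reversal.
* **IDE constraints** — the patient's individually dysregulated proteins
  with their observed signs; enforced during disease-state modeling,
  released during treatment simulation.

A solution is **valid** when at least 60% of the response proteins are
reached by the propagated signal (sign-free coverage) and — in the
disease state — at least 50% of the IDE proteins present in the solution
carry their observed sign. Both thresholds are inclusive; the IDE rule
is vacuously satisfied when no IDE protein is reached.

**Simulated annealing** proposes a Gaussian perturbation of one uniformly
random effective weight (clipped to [−1, 1]), accepted by the Metropolis
rule under geometric cooling, with the best-visited state returned (the
result is never worse than the start). The objective is
`1 − fulfillment` where fulfillment is the fraction of constraint
proteins reached with the expected sign, plus two refinements:

* a smooth tie-breaker (10⁻³ × mean |activity| over satisfied
  constraints) that orders the plateaus of the count objective;
* an optional per-edge L1 penalty (`weight_penalty`) used by the
  individualized models (below).

The library default schedule is T₀ = 1.0, γ = 0.95, 50 proposals per
temperature, 40 temperatures, proposal σ = 0.2. The per-patient trial
configuration instead uses a *cold, wide* schedule (T₀ = 0.003,
γ = 0.90, 50 × 40, σ = 1.0): with ~100 pooled constraints the objective
granularity is ~0.01, so temperatures of order 1 random-walk instead of
optimizing, while σ = 1.0 lets a single proposal flip an edge's sign —
the move the sign constraints actually need. These are deliberate,
config-exposed choices, validated by the annealing sanity checks in the
test suite.

### Individualized models route through the patient's own profile

The IDE constraints serve two purposes: they reward solutions in which
the patient's dysregulated proteins appear with the observed sign, and
they bias the model toward routing signal through those proteins rather
than through proteins the patient's profile says are normal. The second
purpose is implemented by *profile-guided initialization plus an
off-profile prior*: edges whose endpoints are not both in the patient's
profile (IDE ∪ stimulus ∪ drug targets ∪ knowledge set) start damped by
0.15, and the annealing objective adds 0.02 · |w| for every damped
edge. Without the penalty the damping is useless — the count objective
is flat in most directions, and a long Metropolis run random-walks
damped weights back to arbitrary magnitude; the L1 term is the restoring
force that keeps off-profile channels quiet unless a constraint
genuinely needs them (gaining one constraint, worth ~1/n_constraints, is
always allowed to pay for an edge). Both knobs (`profile_damp`,
`offprofile_penalty`) are `TrialConfig` fields.

This matters because patient identity enters treatment response *only*
through the trained weights. Under the drug, target inputs flip from +1
to −1 and the flip propagates precisely through channels the disease
model actually uses; a patient whose profile contains the target→response
mediators has those channels trained and transmits the flip into the
response layer, a patient without them does not. Development pilots
without the off-profile prior showed no association between planted
responder status and the response score; with it the planted responders
dominate the top TSignal decile and the planted mediators are recovered
as predictive biomarkers, which is exactly what the end-to-end recovery
checks in the test suite and the acceptance script verify.

### Two-step patient simulation

1. **Disease state.** Stimulus = 20 proteins proximal to the knowledge
   set (undirected link distance 1, extended to 2 if needed; ranked by
   distance, then number of knowledge-set neighbors, then identifier),
   clamped +1. Response = knowledge set with pathological signs, IDE
   constraints enforced. Valid solutions are collected from
   independently jittered starts (uniform ±0.3 on the initial weights)
   until the requested ensemble size is reached; a patient with no
   valid solution is excluded, mirroring how unsolvable patients are
   dropped in practice.
2. **Treatment.** The drug's targets join the stimulus as clamped −1
   inputs (overriding their disease value where they coincide with
   stimulus proteins). Each disease solution's weights are refined by a
   short, even colder anneal (T₀ = 0.001, 15 × 10) toward reversal of
   the knowledge-set signs, with the IDE constraint released and
   validity reduced to 60% coverage. Starting from the disease weights
   is essential: the treatment model is that patient's disease
   mechanism with the drug applied, not a fresh fit.

The patient's **TSignal** is the mean over treatment solutions of

    Σ_i a_i · e_i  /  n_reached,

summed over *reached* response proteins, where `e_i` is the expected
sign under treatment (the reversal of the pathological sign). The
denominator counts reached response proteins; a config switch
(`denominator="all"`) divides by all reached proteins instead, since the
defining phrase "total number of proteins reached" admits both readings.

**Uncertainty** of an ensemble is the mean over proteins (reached in at
least one solution) of the Shannon entropy of the discretized activity
(three states: below −ε, within ±ε or unreached, above +ε; ε = 0.05)
divided by log 3, reported as a percentage.

## Expression profiling

* Probe-level matrices collapse to protein level by the arithmetic mean
  of mapped probes.
* The healthy reference band is the per-protein [5th, 95th] percentile
  interval of healthy samples, computed with linear interpolation
  between order statistics (the same convention used for responder
  stratification); values *strictly* outside the band are called +1/−1,
  values on the bound are normal.
* Cohort-level differential expression: two-sided Welch's t-test per
  protein with Benjamini–Hochberg adjustment, FDR < 0.05.
* Refinement intersects each individual signature with (population DEGs
  ∩ proteins within three undirected links of the knowledge set);
  patients with fewer than `min_ide` (default 10) surviving proteins are
  excluded. The threshold is a judgment call — the underlying exclusion
  rule is stated only as "a low number" — and is config-exposed.

## Stratification and biomarkers

Patients strictly above the cohort's 90th TSignal percentile are good
responders, strictly below the 10th poor responders (linear-interpolation
percentiles; with 399 distinct values this yields exactly 40 and 40).
Heavy ties spanning a threshold can shift the counts; this is logged.

* **Mechanistic biomarkers** — unit of analysis is the patient: each
  protein's summary is the mean activity over that patient's treatment
  solutions with unreached solutions contributing 0 (using per-solution
  values would pseudo-replicate). Discovery mode: Welch's t-test across
  good vs poor, BH FDR < 0.05 AND |mean difference| > 0.1. Validation
  mode (small cohorts): Mann–Whitney U, raw p < 0.05 AND |median
  difference| > 0.1.
* **Predictive biomarkers** — per protein and per direction d ∈ {+1, −1},
  a 2×2 table of IDE inclusion (good with entry d / without × poor with
  entry d / without), two-sided Fisher's exact test; a protein is
  significant if its smaller-p direction has raw p < 0.05 (no
  multiplicity adjustment, matching the stated rule; the mechanistic
  test uses FDR because its rule says FDR).
* **Enrichment** — upper-tail hypergeometric per pathway against the
  background of proteins with predicted activity, BH FDR < 0.05 AND
  overlap ≥ 10% of the input set (rounded up).
* **Predictive evaluation** — univariate logistic regression per
  protein; stratified 10-fold cross-validation with seeded shuffles,
  100 repetitions by default; each repetition scores the pooled
  out-of-fold probabilities and the reported CV-AUC is the mean over
  repetitions, flagged when > 0.7.

## The synthetic study generator

The generator's job is to emulate the study inputs with planted,
recoverable structure. Defaults (a `SyntheticScenario`):

| parameter | default | meaning |
|---|---|---|
| n_proteins | 250 | network size |
| mean_out_degree | 2.0 | edge density; out-degrees are 1 + scaled Pareto(2) (heavy-tailed hubs) with uniform target choice |
| inhibitory_edge_fraction | 0.3 | fraction of −1 edges |
| knowledge_set_size | 30 | disease proteins, scattered over the network, random ±1 signs |
| n_patients / n_healthy | 80 / 200 | cohort sizes |
| dysregulation_rate | 0.3 | per-patient fraction of candidate proteins shifted |
| effect_size | 3.0 | shift in units of the healthy log-SD |
| n_responder_proteins | 6 | planted drug-effect mediators |
| responder_fraction | 0.5 | planted would-be responders |

Choices that merit explanation:

* **Healthy expression is lognormal** (log-location ~ N(5, 1), log-SD ~
  U(0.3, 0.6)): intensity-scale data is positive and right-skewed.
  Consequently the planted *effect size acts on the log scale* in units
  of the per-protein log-SD — a natural-scale additive shift of several
  SDs would produce negative expression.
* **Dysregulation is knowledge-set-concordant**: each candidate protein
  (within three links of the knowledge set) inherits the pathological
  sign of the member that first reaches it in a multi-source BFS, and
  carriers shift in that direction.
* **The knowledge set is larger than the stimulus** (30 vs 20), matching
  the real proportions of a curated disease definition versus a compact
  stimulus. This is not cosmetic: knowledge-set members adjacent to a
  stimulus node freeze at wave 1 and are fully determined by direct
  stimulus edges, so only members freezing later can respond to any
  mediator. A compact knowledge set engulfed by its own stimulus has
  almost no late members, and no planted mechanism can exist.
* **Planted responder proteins are target-exclusive mediators**: the
  trial drug is a multi-target inhibitor whose targets are drawn from
  the proximal stimulus (disease-driving proteins, as with multi-kinase
  inhibitors); the planted mediators are wave-1 nodes whose stimulus
  inputs come entirely from drug targets (their activity inverts exactly
  under treatment, by oddness of tanh) and which feed late-freezing
  knowledge-set members. Responder patients carry dysregulation on
  exactly these mediators; non-responders never do, and their general
  dysregulation is drawn from the remaining candidates. The generator
  re-draws the knowledge set (deterministically, up to 60 salted
  attempts) until the geometry hosts the requested number of mediators,
  and raises a structural error otherwise.
* **The drug panel for calibration** consists of five 6-target
  inhibitors whose target sets are re-drawn until they structurally
  reach ≥ 50% of the knowledge set in three steps. The OS benefit
  (months) is an affine function of the drugs' reversal score over the
  *clean* response subset, actively pushed away from the score of the
  full set (signal = 3·score(clean) − 2·score(full) before
  standardization), with Gaussian noise of 0.25 months. The designated
  noise members are the most drug-discriminating members (largest
  cross-drug variance of mean reversal contribution). Calibration is
  demonstrated on *prior ensembles* — propagations at ±0.3-jittered
  literature weights with no annealing — because the calibration step
  re-scores fixed models, and because constraint training drives all
  members toward reversal and thereby erases the cross-drug profile
  heterogeneity the planted panel relies on. With only 5 drugs the
  Pearson correlation saturates quickly and greedy elimination is
  degenerate (many removal paths reach r ≈ 1); the planted-noise
  recovery is therefore a fixed-seed property, while `final r ≥
  initial r` and the strictly increasing trace hold always.

### What the generator does not emulate

Probe chemistry, batch and platform effects, cross-platform
normalization artifacts, missing values, and correlated (co-regulated)
noise across proteins. Passing tests therefore demonstrate that the
pipeline's logic is correct and that planted signal of the stated
magnitude is recovered under clean conditions — not that the statistical
power or calibration would transfer to real microarray/RNA-seq cohorts.
Values reported for the real study (hundreds of biomarkers, calibration
r = 0.87, a ~20% median uncertainty) depend on a proprietary
interaction network and clinical data and are not reproduction targets
here.

## Problem sizes and numerical choices

* Default trial scale: 250-protein network, 80 patients, 10 solutions
  per patient and step — sizes chosen so a complete trial trains in a
  few minutes on one core while leaving every statistical test
  non-degenerate. The production-scale setting (50 solutions per
  patient, 399 patients) is a config change, not a code change.
* Reached-ness uses |activity| ≥ 10⁻⁶ (`activity_eps`); the uncertainty
  dead-zone is 0.05; both config-exposed.
* Percentiles everywhere use numpy's linear interpolation.
* Calibration ties (equal r gain) break by protein identifier ascending;
  candidate removals that would make r undefined are skipped.
* Degenerate inputs raise typed errors (`ParameterError`,
  `FormatError`, `StructuralError`) rather than warnings, except where
  the field convention is to proceed and log (duplicate edges,
  self-loops, unmapped probes, zero-variance proteins).

## Known limitations

* The annealer evaluates a full propagation per proposal; on networks
  beyond ~10⁴ edges an incremental evaluator would be needed.
* TSignal separation between planted responders and non-responders is a
  property of the profile-guided training prior; with unregularized
  training the underdetermined system hides patient identity in flat
  directions of the objective.
* The greedy calibration endpoint is a local optimum of a 5-point
  correlation; it strips planted discordant proteins reliably only when
  the drugs' response profiles are heterogeneous.
* OS values are synthetic months on a plausible scale; no mapping from
  TSignal to survival time is modeled.
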