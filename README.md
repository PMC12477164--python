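# silicotrial

In-silico clinical trials on signed protein-interaction networks.

`silicotrial` is for computational biologists who want to simulate a
drug's effect on individual patients *mechanistically*: each patient's
transcriptomic profile is turned into a personal network model of their
disease, the drug is applied to that model, and the predicted degree of
pathology reversal — a score called **TSignal** — stratifies the cohort
into in-silico good and poor responders, from which mechanistic and
predictive biomarkers are mined. Everything runs end to end on synthetic
data with planted, recoverable ground truth, so the whole pipeline is
testable without any external database.

## The model in brief

A protein network G carries directed edges with effective weights
w<sub>uv</sub> ∈ [−1, 1] (sign = activation/inhibition, magnitude =
strength). A stimulus clamps input values on a set of nodes, and the
signal spreads for three synchronous wave fronts; a node first reached
at step *t* freezes at

&nbsp;&nbsp;&nbsp;&nbsp;a<sub>v</sub> = tanh( Σ<sub>u assigned</sub> w<sub>uv</sub> · a<sub>u</sub> )

Models are trained by simulated annealing on the effective weights
against constraint fulfillment: the disease **knowledge set** (proteins
with pathological direction ±1) must be reached with its signs, and the
patient's **IDE signature** — proteins outside the healthy [5th, 95th]
expression percentile band, refined by population DEGs and 3-link
network proximity — must appear with the observed signs. A solution is
valid when ≥ 60% of the knowledge set is reached and ≥ 50% of the
present IDE proteins carry the right sign; 50 (here: configurable)
valid solutions form a patient's ensemble.

Treatment is simulated by flipping the drug's targets to −1 on each
disease solution and re-annealing briefly toward sign reversal. The
response score of a solution is

&nbsp;&nbsp;&nbsp;&nbsp;TSignal = Σ<sub>i reached</sub> a<sub>i</sub> e<sub>i</sub> / n<sub>reached</sub>,

with e<sub>i</sub> the expected (reversed) sign — positive contributions
mean the drug pushes disease proteins back toward normal — and a model's
TSignal is the mean over its ensemble. Patients above the cohort's 90th
/ below the 10th TSignal percentile are good / poor responders;
mechanistic biomarkers (Welch, FDR < 0.05, |Δmean activity| > 0.1) and
predictive biomarkers (Fisher's exact on IDE inclusion, p < 0.05)
separate the two groups. TSignal can additionally be calibrated against
per-drug overall-survival benefit by greedy backward elimination of
response proteins (maximizing Pearson r).

## Worked example

`examples/05_run_trial.py` generates a 40-patient study (250-protein
network, 30-protein knowledge set, a 5-target inhibitor, 6 planted
mediator proteins carried only by the 20 planted responders) and runs
the full pipeline:

```text
modeled 40 patients (0 unsolvable)
TSignal, planted responders:   +0.063
TSignal, planted non-responders: +0.020
good responders: ['PT007', 'PT009', 'PT019', 'PT020'] (4 planted)
poor responders: ['PT010', 'PT034', 'PT035', 'PT036'] (2 planted)
predictive biomarkers (planted arms): ['P129', 'P165', 'P166', 'P204', 'P242', 'P243'] + 6 other(s)
planted mediators recovered: 6/6
```

Reading this: planted responders score a three-fold higher mean TSignal
(their models transmit the drug's inhibition into the knowledge set,
non-responders' models have no trained channel for it); the top decile
of the cohort is all planted responders; and Fisher's exact test on IDE
inclusion rediscovers all six planted mediator proteins. At the default
80-patient scale the stratified extremes alone recover the mediators
(see the acceptance checks).

The other example scripts each demonstrate one capability: study
generation (`01`), IDE profiling (`02`), propagation + ensemble training
with the entropy-ratio uncertainty score (`03`), and survival-benefit
calibration that strips planted non-tracking response proteins (`04`).

A thin CLI mirrors the pipeline stages for shell use:

```bash
silicotrial generate --outdir study/ --seed 7
silicotrial ide --disease study/disease.tsv --healthy study/healthy.tsv \
    --network study/network.tsv --knowledge study/knowledge_set.tsv --out ides.tsv
silicotrial trial --indir study/ --outdir results/ --seed 7
```

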