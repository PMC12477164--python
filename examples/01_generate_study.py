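"""Generate a synthetic study and look at what was planted.

A study bundles a signed protein network, a disease knowledge set, a
multi-target drug, healthy/disease expression cohorts, and the ground
truth (which patients are would-be responders, and through which
mediator proteins the drug can act).
"""

from silicotrial import SyntheticScenario, generate_study

scenario = SyntheticScenario(seed=7, n_patients=20, n_healthy=60)
study = generate_study(scenario)

print(f"network: {study.network.n_nodes} proteins, "
      f"{study.network.n_edges} signed edges")
print(f"knowledge set: {len(study.knowledge_set.entries)} proteins "
      f"(pathological direction +1/-1)")
print(f"drug: {len(study.drug.entries)} inhibited targets "
      f"-> {sorted(study.drug.proteins)}")
print(f"cohort: {study.disease.n_samples} patients, "
      f"{study.healthy.n_samples} healthy controls")
print(f"planted responder patients: {len(study.truth.responder_patients)}")
print(f"planted mediator proteins: {sorted(study.truth.responder_proteins)}")

# The mediators are what a successful trial should rediscover as
# predictive biomarkers: they sit downstream of the drug's targets and
# upstream of the knowledge set, and only responder patients carry
# dysregulation on them.
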