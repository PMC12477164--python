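"""Stratification, biomarker statistics, enrichment, CV-AUC evaluation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.special import comb

from silicotrial import (ExpressionMatrix, IDESignature, ParameterError,
                         PatientModel, Solution, SolutionEnsemble, enrichment,
                         mechanistic_biomarkers, predictive_biomarkers,
                         predictive_evaluation, read_gmt, stratify)
from silicotrial.propagation import ActivityState


class TestStratify:
    def test_399_distinct_values_give_40_and_40(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=399)
        assert len(set(values)) == 399
        labels = stratify(values)
        assert labels.count("good") == 40
        assert labels.count("poor") == 40

    def test_ten_distinct_values_give_one_and_one(self):
        labels = stratify(list(range(10)))
        assert labels.count("good") == 1 and labels.count("poor") == 1
        assert labels[9] == "good" and labels[0] == "poor"

    def test_all_equal_gives_none(self):
        labels = stratify([1.0] * 20)
        assert set(labels) == {"intermediate"}

    def test_permutation_invariant_per_patient(self):
        rng = np.random.default_rng(1)
        values = list(rng.normal(size=50))
        labels = stratify(values)
        perm = rng.permutation(50)
        permuted_labels = stratify([values[i] for i in perm])
        for rank, i in enumerate(perm):
            assert permuted_labels[rank] == labels[i]

    def test_too_few_values_rejected(self):
        with pytest.raises(ParameterError):
            stratify([1.0] * 9)


def _patient_model(patient, label, per_solution_acts):
    sols = [Solution(effective_weights=np.zeros(1),
                     state=ActivityState(activities=acts,
                                         step_assigned={p: 1 for p in acts}),
                     fulfillment=1.0, seed=i)
            for i, acts in enumerate(per_solution_acts)]
    ens = SolutionEnsemble(solutions=sols, patient=patient,
                           condition="treatment", n_requested=len(sols))
    return PatientModel(patient=patient, disease_ensemble=None,
                        treatment_ensemble=ens, tsignal=0.0, label=label)


class TestMechanisticBiomarkers:
    def _cohort(self, rng, n_per_group, effect, n_proteins=30):
        proteins = [f"P{i:02d}" for i in range(n_proteins)]
        models = []
        for g, label in ((0, "good"), (1, "poor")):
            for i in range(n_per_group):
                shift = effect if g == 0 else 0.0
                acts = {p: float(np.clip(
                    (shift if p == "P00" else 0.0)
                    + 0.1 * rng.standard_normal(), -1, 1)) for p in proteins}
                models.append(_patient_model(f"{label}{i}", label, [acts]))
        return models

    def test_null_groups_no_significant_calls(self):
        rng = np.random.default_rng(6)
        models = self._cohort(rng, n_per_group=20, effect=0.0)
        table = mechanistic_biomarkers(models, mode="discovery")
        assert table.significant.sum() == 0

    def test_large_effect_flagged_in_both_modes(self):
        rng = np.random.default_rng(7)
        models = self._cohort(rng, n_per_group=40, effect=0.7)
        for mode in ("discovery", "validation"):
            table = mechanistic_biomarkers(models, mode=mode)
            row = table.set_index("protein").loc["P00"]
            assert bool(row.significant)
            assert row.effect_size > 0.1
            assert row.direction == 1

    def test_effect_threshold_blocks_tiny_but_significant_difference(self):
        rng = np.random.default_rng(8)
        proteins = ["P00"]
        models = []
        for label, mean in (("good", 0.05), ("poor", 0.0)):
            for i in range(200):
                acts = {"P00": float(mean + 0.01 * rng.standard_normal())}
                models.append(_patient_model(f"{label}{i}", label, [acts]))
        table = mechanistic_biomarkers(models, mode="discovery")
        row = table.iloc[0]
        assert row.p < 0.05 and not row.significant  # |effect| 0.05 <= 0.1

    def test_welch_statistics_match_scipy_on_summary_matrix(self):
        rng = np.random.default_rng(9)
        models = self._cohort(rng, n_per_group=10, effect=0.4)
        table = mechanistic_biomarkers(models, mode="discovery")
        g = np.array([[m.treatment_ensemble.solutions[0].state.activities["P00"]]
                      for m in models if m.label == "good"]).ravel()
        p = np.array([[m.treatment_ensemble.solutions[0].state.activities["P00"]]
                      for m in models if m.label == "poor"]).ravel()
        _, expected_p = sps.ttest_ind(g, p, equal_var=False)
        got = table.set_index("protein").loc["P00", "p"]
        assert got == pytest.approx(expected_p, rel=1e-9)

    def test_fdr_controlled_under_label_permutation(self):
        rng = np.random.default_rng(10)
        n_sig = 0
        n_perm = 30
        for _ in range(n_perm):
            models = self._cohort(rng, n_per_group=15, effect=0.0,
                                  n_proteins=50)
            table = mechanistic_biomarkers(models, mode="discovery")
            n_sig += int(table.significant.sum())
        assert n_sig / (n_perm * 50) <= 0.05 + 0.02


def _fisher_two_sided_oracle(a, b, c, d):
    """Exact two-sided Fisher p by enumerating tables with fixed margins,
    summing probabilities <= observed (scipy's convention)."""
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = (comb(row1, a, exact=True)
             * comb(n - row1, col1 - a, exact=True)) / comb(n, col1, exact=True)
    total = 0.0
    for x in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        p = (comb(row1, x, exact=True)
             * comb(n - row1, col1 - x, exact=True)) / comb(n, col1, exact=True)
        if p <= p_obs * (1 + 1e-10):
            total += p
    return total


class TestPredictiveBiomarkers:
    def _sigs(self, counts, sign=1):
        """counts: (good_with, n_good, poor_with, n_poor)"""
        gw, ng, pw, npr = counts
        sigs, labels = [], {}
        for i in range(ng):
            entries = {"X": sign} if i < gw else {}
            entries["PAD"] = 1  # keep signatures non-degenerate
            sigs.append(IDESignature(f"g{i}", entries))
            labels[f"g{i}"] = "good"
        for i in range(npr):
            entries = {"X": sign} if i < pw else {}
            entries["PAD"] = 1
            sigs.append(IDESignature(f"p{i}", entries))
            labels[f"p{i}"] = "poor"
        return sigs, labels

    def test_equal_frequencies_not_significant(self):
        sigs, labels = self._sigs((10, 20, 10, 20))
        table = predictive_biomarkers(sigs, labels)
        row = table.set_index("protein").loc["X"]
        assert row.p == pytest.approx(1.0)
        assert not row.significant

    def test_matches_hypergeometric_enumeration(self):
        sigs, labels = self._sigs((10, 40, 30, 40))
        table = predictive_biomarkers(sigs, labels)
        row = table.set_index("protein").loc["X"]
        expected = _fisher_two_sided_oracle(10, 30, 30, 10)
        assert row.p == pytest.approx(expected, rel=1e-9)
        assert row.significant

    @pytest.mark.parametrize("a,b,c,d", [(3, 5, 7, 2), (0, 8, 8, 0),
                                         (5, 5, 5, 5), (12, 3, 2, 13)])
    def test_scipy_fisher_equals_enumeration_oracle(self, a, b, c, d):
        _, p_scipy = sps.fisher_exact([[a, b], [c, d]])
        assert p_scipy == pytest.approx(_fisher_two_sided_oracle(a, b, c, d),
                                        rel=1e-9)

    def test_direction_reported_for_smaller_p(self):
        # X present as -1 mostly in poor patients
        sigs, labels = self._sigs((2, 20, 18, 20), sign=-1)
        table = predictive_biomarkers(sigs, labels)
        row = table.set_index("protein").loc["X"]
        assert row.direction == -1
        assert row.significant

    def test_missing_group_rejected(self):
        sigs, _ = self._sigs((1, 5, 1, 5))
        with pytest.raises(ParameterError):
            predictive_biomarkers(sigs, {s.patient: "good" for s in sigs})


class TestEnrichment:
    def test_pathway_equal_to_input_is_top_hit(self):
        background = {f"P{i}" for i in range(100)}
        inputs = {f"P{i}" for i in range(10)}
        annotations = {"match": set(inputs),
                       "other": {f"P{i}" for i in range(50, 80)}}
        table = enrichment(inputs, annotations, background)
        top = table.sort_values("p").iloc[0]
        assert top.pathway == "match"
        assert top.overlap == 10
        assert bool(top.significant)

    def test_p_matches_closed_form_tail_sum(self):
        background = {f"P{i}" for i in range(60)}
        inputs = {f"P{i}" for i in range(12)}
        annotations = {"A": {f"P{i}" for i in range(8, 28)}}  # overlap 4
        table = enrichment(inputs, annotations, background)
        # closed-form upper tail: sum_{x>=4} C(20,x) C(40,12-x) / C(60,12)
        expected = sum(comb(20, x, exact=True) * comb(40, 12 - x, exact=True)
                       for x in range(4, 13)) / comb(60, 12, exact=True)
        assert table.iloc[0].p == pytest.approx(expected, rel=1e-12)

    def test_coverage_floor_blocks_small_overlaps(self):
        background = {f"P{i}" for i in range(200)}
        inputs = {f"P{i}" for i in range(40)}
        # overlap 3 < ceil(0.1*40)=4, even if the p-value is small
        annotations = {"tiny": {"P0", "P1", "P2"}}
        table = enrichment(inputs, annotations, background)
        assert not table.iloc[0].significant

    def test_null_fdr_control(self):
        rng = np.random.default_rng(12)
        background = {f"P{i}" for i in range(200)}
        n_sig = n_total = 0
        for _ in range(20):
            inputs = set(rng.choice(sorted(background), 30, replace=False))
            annotations = {
                f"path{j}": set(rng.choice(sorted(background), 25,
                                           replace=False))
                for j in range(20)}
            table = enrichment(inputs, annotations, background)
            n_sig += int(table.significant.sum())
            n_total += len(table)
        assert n_sig / n_total <= 0.05 + 0.03

    def test_input_outside_background_rejected(self):
        with pytest.raises(ParameterError):
            enrichment({"Z"}, {}, {"A", "B"})


class TestPredictiveEvaluation:
    def _expression(self, rng, labels, shift):
        samples = sorted(labels)
        values = [[(shift if labels[s] == "good" else 0.0) + rng.standard_normal()
                   for s in samples]]
        return ExpressionMatrix(pd.DataFrame(values, index=["X"],
                                             columns=samples))

    def test_null_expression_auc_near_half(self):
        rng = np.random.default_rng(21)
        labels = {f"s{i}": ("good" if i < 40 else "poor") for i in range(80)}
        expr = self._expression(rng, labels, shift=0.0)
        auc, significant = predictive_evaluation(expr, labels, "X",
                                                 n_repeats=20, seed=0)
        assert 0.45 <= auc <= 0.55
        assert not significant

    def test_perfect_separation_auc_one(self):
        labels = {f"s{i}": ("good" if i < 20 else "poor") for i in range(40)}
        samples = sorted(labels)
        values = [[10.0 if labels[s] == "good" else -10.0 for s in samples]]
        expr = ExpressionMatrix(pd.DataFrame(values, index=["X"],
                                             columns=samples))
        auc, significant = predictive_evaluation(expr, labels, "X",
                                                 n_repeats=5, seed=0)
        assert auc == 1.0 and significant

    def test_one_sd_shift_matches_analytic_auc(self):
        # equal-variance Gaussian shift d has AUC = Phi(d / sqrt(2));
        # average over cohort draws (single 40/40 draws scatter by ~0.06)
        rng = np.random.default_rng(22)
        labels = {f"s{i}": ("good" if i < 40 else "poor") for i in range(80)}
        aucs = []
        for draw in range(6):
            expr = self._expression(rng, labels, shift=1.0)
            auc, _ = predictive_evaluation(expr, labels, "X", n_repeats=10,
                                           seed=draw)
            aucs.append(auc)
        analytic = sps.norm.cdf(1.0 / math.sqrt(2.0))
        assert np.mean(aucs) == pytest.approx(analytic, abs=0.05)

    def test_single_label_rejected(self):
        labels = {f"s{i}": "good" for i in range(20)}
        rng = np.random.default_rng(0)
        expr = self._expression(rng, labels, shift=0.0)
        with pytest.raises(ParameterError):
            predictive_evaluation(expr, labels, "X")


class TestReadGmt:
    def test_parses_name_description_members(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("pathA\tdesc\tP1\tP2\tP3\n"
                     "pathB\thttp://x\tP2\tP4\n"
                     "\n")
        out = read_gmt(p)
        assert out == {"pathA": {"P1", "P2", "P3"}, "pathB": {"P2", "P4"}}
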