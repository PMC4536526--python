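"""Risk-gene screening, risk prediction, confusion metrics, panel assembly."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import panconserve as pc
from panconserve.risk import (
    HIGH,
    INDET,
    LOW,
    RiskGene,
    assemble_panel,
    assign_actual_risk,
    common_risk_genes,
    compare_signatures,
    evaluate_prediction,
    identify_risk_genes,
    predict_risk,
)
from panconserve.simulate import ExpressionDataset, SurvivalTable


def _rg(gene, direction=1, p=0.001, cancer="X"):
    return RiskGene(gene=gene, cancer=cancer, direction=direction, p_value=p)


def _expr(mat, samples=None):
    genes = [f"G{i}" for i in range(mat.shape[0])]
    samples = samples or [f"S{j}" for j in range(mat.shape[1])]
    return ExpressionDataset("X", pd.DataFrame(mat, index=genes, columns=samples))


def _surv(times, events, samples):
    return SurvivalTable(
        "X", pd.DataFrame({"sample_id": samples, "time_days": times, "event": events})
    )


class TestIdentifyRiskGenes:
    def test_planted_risk_genes_detected_with_hazardous_direction(self, risk_cohort):
        ds, surv, truth = risk_cohort
        found = identify_risk_genes(ds, surv, p_threshold=0.01)
        by_gene = {r.gene: r for r in found}
        hits = [g for g in truth.true_risk_genes if g in by_gene]
        assert len(hits) >= 0.9 * len(truth.true_risk_genes)
        assert all(by_gene[g].direction == +1 for g in hits)

    def test_null_type_one_error_controlled(self):
        rng = np.random.default_rng(0)
        mat = rng.standard_normal((100, 120))
        samples = [f"S{j}" for j in range(120)]
        ds = _expr(mat, samples)
        surv = _surv(rng.exponential(900, 120), np.ones(120, int), samples)
        found = identify_risk_genes(ds, surv, p_threshold=0.05)
        assert len(found) / 100 <= 0.12

    def test_constant_gene_skipped(self):
        samples = [f"S{j}" for j in range(40)]
        mat = np.vstack([np.ones(40), np.random.default_rng(1).standard_normal(40)])
        ds = _expr(mat, samples)
        surv = _surv(np.arange(1, 41, dtype=float), np.ones(40, int), samples)
        found = identify_risk_genes(ds, surv, p_threshold=1.0)
        assert "G0" not in {r.gene for r in found}

    def test_affine_rescaling_invariance(self, risk_cohort):
        ds, surv, _ = risk_cohort
        sub = ExpressionDataset("C1", ds.expression.iloc[:20].copy())
        scaled = ExpressionDataset("C1", sub.expression * 7.3 + 11.0)
        a = identify_risk_genes(sub, surv, p_threshold=0.05)
        b = identify_risk_genes(scaled, surv, p_threshold=0.05)
        assert [(r.gene, r.direction) for r in a] == [(r.gene, r.direction) for r in b]
        assert np.allclose([r.p_value for r in a], [r.p_value for r in b])


class TestCommonRiskGenes:
    def test_identical_lists_intersect_to_themselves(self):
        lists = {c: [_rg("g1"), _rg("g2")] for c in "ABC"}
        assert common_risk_genes(lists, ("A", "B", "C")) == ["g1", "g2"]

    def test_one_outlier_tolerated_when_allowed(self):
        lists = {
            "A": [_rg("g1"), _rg("g2")],
            "B": [_rg("g1"), _rg("g2")],
            "C": [_rg("g2")],
        }
        assert common_risk_genes(lists, ("A", "B", "C")) == ["g2"]
        assert common_risk_genes(lists, ("A", "B", "C"), allowed_outliers=1) == ["g1", "g2"]

    def test_planted_shared_risk_genes_recovered(self):
        cancers = ("A", "B", "C", "D")
        risk_genes = tuple(f"G{i:04d}" for i in range(1, 10))
        cfg = pc.SimulationConfig(
            n_cancers=4, cancer_names=list(cancers), samples_per_cancer=[200] * 4,
            n_genes=120,
            module_specs=[
                pc.ModuleSpec(size=30, member_cancers=cancers, within_correlation=0.8)
            ],
            n_background_genes=90,
            risk_spec=pc.RiskSpec(
                risk_genes=risk_genes,
                log_hazard_per_unit=float(np.log(2.5)),
                baseline_hazard=1 / 900.0, censoring_rate=0.2,
            ),
            seed=21,
        )
        datasets, survivals, truth = pc.generate_multicancer(cfg)
        surv = {s.cancer: s for s in survivals}
        lists = {
            d.cancer: identify_risk_genes(d, surv[d.cancer], p_threshold=0.01)
            for d in datasets
        }
        common = set(common_risk_genes(lists, cancers))
        assert set(truth.true_risk_genes).issubset(common)


class TestActualRisk:
    def test_death_before_horizon_is_high(self):
        surv = _surv([2 * 365.25], [1], ["s1"])
        assert assign_actual_risk(surv, 3.0).iloc[0] == HIGH

    def test_followup_beyond_horizon_is_low_even_if_censored(self):
        surv = _surv([4 * 365.25], [0], ["s1"])
        assert assign_actual_risk(surv, 1.0).iloc[0] == LOW

    def test_censored_before_horizon_indeterminate(self):
        surv = _surv([0.5 * 365.25], [0], ["s1"])
        assert assign_actual_risk(surv, 2.0).iloc[0] == INDET

    def test_nonpositive_threshold_rejected(self):
        surv = _surv([10.0], [1], ["s1"])
        with pytest.raises(ValueError):
            assign_actual_risk(surv, 0.0)


class TestPredictRisk:
    def test_all_genes_risky_side_predicts_high(self):
        mat = np.array([[0.0, 1.0, 2.0, 9.0]] * 3)
        ds = _expr(mat)
        pred = predict_risk(ds, [_rg("G0"), _rg("G1"), _rg("G2")])
        assert pred.loc["S3"] == HIGH
        assert pred.loc["S0"] == LOW

    def test_protective_direction_flips_vote(self):
        mat = np.array([[0.0, 1.0, 2.0, 9.0]] * 3)
        ds = _expr(mat)
        pred = predict_risk(ds, [_rg("G0", -1), _rg("G1", -1), _rg("G2", -1)])
        assert pred.loc["S0"] == HIGH
        assert pred.loc["S3"] == LOW

    def test_exact_half_tie_is_low(self):
        # 4-gene panel; sample S0 is above the median on exactly 2 genes
        mat = np.array(
            [
                [3.0, 0.0, 1.0, 2.0],
                [3.0, 0.0, 1.0, 2.0],
                [0.0, 3.0, 2.0, 1.0],
                [0.0, 3.0, 2.0, 1.0],
            ]
        )
        ds = _expr(mat)
        pred = predict_risk(ds, [_rg(f"G{i}") for i in range(4)])
        assert pred.loc["S0"] == LOW

    def test_panel_order_invariance(self, risk_cohort):
        ds, _, truth = risk_cohort
        panel = [_rg(g, d, cancer="C1") for g, d in truth.true_risk_genes.items()]
        p1 = predict_risk(ds, panel)
        p2 = predict_risk(ds, panel[::-1])
        assert p1.equals(p2)

    def test_no_panel_genes_rejected(self):
        ds = _expr(np.zeros((2, 3)) + np.arange(3))
        with pytest.raises(ValueError):
            predict_risk(ds, [_rg("NOPE")])


class TestEvaluation:
    def test_formula_sensitivity(self):
        pred = pd.Series([HIGH, HIGH, HIGH, LOW], index=list("abcd"))
        actual = pd.Series([HIGH, HIGH, HIGH, HIGH], index=list("abcd"))
        cs = evaluate_prediction(pred, actual)
        assert (cs.tp, cs.fn) == (3, 1)
        assert cs.sensitivity == 0.75

    def test_perfect_prediction(self):
        actual = pd.Series([HIGH, LOW, HIGH, LOW], index=list("abcd"))
        cs = evaluate_prediction(actual.copy(), actual)
        assert cs.sensitivity == 1.0 and cs.specificity == 1.0

    def test_indeterminate_excluded_and_degenerate_metric_undefined(self):
        pred = pd.Series([HIGH, HIGH, LOW], index=list("abc"))
        actual = pd.Series([HIGH, INDET, HIGH], index=list("abc"))
        cs = evaluate_prediction(pred, actual)
        assert cs.tp + cs.fp + cs.tn + cs.fn == 2
        assert cs.specificity is None  # no true negatives to measure against

    def test_planted_panel_beats_coin_flip(self, risk_cohort):
        ds, surv, truth = risk_cohort
        panel = [_rg(g, d, cancer="C1") for g, d in truth.true_risk_genes.items()]
        pred = predict_risk(ds, panel)
        actual = assign_actual_risk(surv, 2.0)
        cs = evaluate_prediction(pred, actual)
        assert cs.sensitivity > 0.6 and cs.specificity > 0.6


class TestCompareSignatures:
    def test_identical_predictions_p_one(self):
        pred = pd.Series([HIGH, LOW] * 10, index=[f"s{i}" for i in range(20)])
        actual = pd.Series([HIGH] * 20, index=pred.index)
        assert compare_signatures(pred, pred, actual).p_value == 1.0

    def test_asymmetric_discordance_hand_value(self):
        idx = [f"s{i}" for i in range(25)]
        actual = pd.Series([HIGH] * 25, index=idx)
        pred_a = pd.Series([HIGH] * 25, index=idx)  # always right
        pred_b = pd.Series([LOW] * 20 + [HIGH] * 5, index=idx)
        # A right where B wrong on 20; B right where A wrong on 0... adjust:
        pred_a.iloc[20:] = LOW  # A wrong on last 5 where B is right
        res = compare_signatures(pred_a, pred_b, actual)
        assert res.statistic == pytest.approx(7.84)

    def test_both_always_wrong_vacuous(self):
        idx = list("abc")
        actual = pd.Series([HIGH] * 3, index=idx)
        wrong = pd.Series([LOW] * 3, index=idx)
        assert compare_signatures(wrong, wrong, actual).p_value == 1.0


class TestAssemblePanel:
    def _fifteen_gene_inputs(self):
        set1 = [_rg(f"s1_{i}") for i in range(6)]
        set2 = [_rg(f"s2_{i}") for i in range(3)]
        per_cancer = {
            "COAD": [_rg(f"coad_{i}", p=0.001 * (i + 1)) for i in range(3)],
            "LUAD": [_rg(f"luad_{i}", p=0.001 * (i + 1)) for i in range(3)],
        }
        rules = {
            "GBM": "common-set1",
            "BRCA": "common-set2",
            "OVCA": "common-set2",
            "READ": "combined",
            "COAD": "common+individual",
            "LUAD": "common+individual",
        }
        return set1, set2, per_cancer, rules

    def test_composition_rule_union_has_fifteen_genes(self):
        set1, set2, per_cancer, rules = self._fifteen_gene_inputs()
        panel = assemble_panel(set1, set2, per_cancer, rules)
        assert len(panel.union) == 15
        assert len(panel.for_cancer("READ")) == 9
        assert len(panel.for_cancer("GBM")) == 6
        assert len(panel.for_cancer("COAD")) == 9

    def test_individual_genes_ranked_by_significance(self):
        set1, set2, per_cancer, rules = self._fifteen_gene_inputs()
        per_cancer["COAD"].append(_rg("coad_best", p=1e-9))
        panel = assemble_panel(set1, set2, per_cancer, rules)
        coad = [r.gene for r in panel.for_cancer("COAD")]
        assert "coad_best" in coad and "coad_2" not in coad

    def test_overlapping_individual_genes_deduplicated(self):
        set1, set2, per_cancer, rules = self._fifteen_gene_inputs()
        # individual candidates that duplicate common genes are not re-added
        per_cancer["COAD"] = [_rg("s1_0", p=1e-9)] + per_cancer["COAD"]
        panel = assemble_panel(set1, set2, per_cancer, rules)
        coad = [r.gene for r in panel.for_cancer("COAD")]
        assert coad.count("s1_0") == 1
        assert len(coad) == 9

    def test_empty_inputs_give_empty_panel_with_warning(self, caplog):
        panel = assemble_panel([], [], {}, {"GBM": "common-set1"})
        assert panel.union == []

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            assemble_panel([], [], {}, {"GBM": "nonsense"})
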