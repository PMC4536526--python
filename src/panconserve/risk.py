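"""Risk-gene identification, risk prediction, and pan-cancer panel assembly.

Per cohort, candidate genes (usually the conserved-set universe) are
screened one at a time: samples are dichotomized at the gene's median
expression (ties go to the high group) and the two groups compared by
log-rank.  Genes below the p threshold become risk genes; the direction
is +1 when the above-median group fares worse by the survival horizon.

Actual patient risk is defined from follow-up alone with a per-cancer
horizon (death before it = high risk, follow-up beyond it = low risk,
censored before it = indeterminate).  Predicted risk counts, per sample,
how many panel genes sit on their risky side of the cohort median; a
strict majority predicts high risk.  Sensitivity/specificity come from
the confusion of predicted vs actual labels, and McNemar's test on
per-sample correctness compares two signatures.  Panel assembly follows
per-cancer composition rules combining the shared risk genes with each
cancer's most significant individual ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import ExpressionDataset, SurvivalTable
from .survstats import TestResult, km_estimate, logrank_test, mcnemar_test

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

HIGH, LOW, INDET = "high", "low", "indeterminate"


@dataclass
class RiskGene:
    gene: str
    cancer: str
    direction: int  # +1 high expression hazardous, -1 protective
    p_value: float


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None

    @property
    def specificity(self) -> float | None:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else None

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
        }


@dataclass
class RiskPanel:
    """Per-cancer gene lists with directions plus the de-duplicated union."""

    per_cancer: dict[str, list[RiskGene]]
    rules: dict[str, str] = field(default_factory=dict)

    @property
    def union(self) -> list[str]:
        seen: dict[str, None] = {}
        for genes in self.per_cancer.values():
            for rg in genes:
                seen.setdefault(rg.gene, None)
        return list(seen)

    def for_cancer(self, cancer: str) -> list[RiskGene]:
        return self.per_cancer[cancer]


def identify_risk_genes(
    expr: ExpressionDataset,
    survival: SurvivalTable,
    p_threshold: float = 0.01,
    genes: list[str] | None = None,
    horizon_days: float | None = None,
) -> list[RiskGene]:
    """Median-split log-rank screen over candidate genes.

    ``horizon_days`` sets where the two Kaplan-Meier curves are compared
    to call the risk direction; by default the median observed follow-up.
    """
    surv = survival.table.set_index("sample_id")
    samples = [s for s in expr.samples if s in surv.index]
    if not samples:
        raise ValueError("no overlapping samples between expression and survival")
    t = surv.loc[samples, "time_days"].to_numpy(dtype=float)
    e = surv.loc[samples, "event"].to_numpy(dtype=int)
    if horizon_days is None:
        horizon_days = float(np.median(t))
    universe = genes if genes is not None else expr.genes
    mat = expr.expression.loc[
        [g for g in universe if g in expr.expression.index], samples
    ]
    out: list[RiskGene] = []
    for gene, row in mat.iterrows():
        x = row.to_numpy(dtype=float)
        med = np.median(x)
        high = x >= med  # ties at the median go to the high group
        if high.all() or not high.any():
            logger.warning("gene %s constant at median split; skipped", gene)
            continue
        if e[high].sum() + e[~high].sum() == 0:
            continue
        try:
            res = logrank_test([(t[high], e[high]), (t[~high], e[~high])])
        except ValueError:
            continue
        if res.p_value <= p_threshold:
            s_high = km_estimate(t[high], e[high]).survival_at(horizon_days)
            s_low = km_estimate(t[~high], e[~high]).survival_at(horizon_days)
            direction = 1 if s_high < s_low else -1
            out.append(
                RiskGene(gene=gene, cancer=expr.cancer, direction=direction,
                         p_value=res.p_value)
            )
    out.sort(key=lambda rg: (rg.p_value, rg.gene))
    return out


def common_risk_genes(
    per_cancer: dict[str, list[RiskGene]],
    group: tuple[str, ...],
    allowed_outliers: int = 0,
) -> list[str]:
    """Genes flagged as risk genes in all but ``allowed_outliers`` cohorts."""
    if len(group) < 2:
        raise ValueError("group must contain at least 2 cancers")
    counts: dict[str, int] = {}
    for cancer in group:
        for rg in per_cancer.get(cancer, []):
            counts[rg.gene] = counts.get(rg.gene, 0) + 1
    need = len(group) - allowed_outliers
    return sorted(g for g, c in counts.items() if c >= need)


def assign_actual_risk(
    survival: SurvivalTable, threshold_years: float
) -> pd.Series:
    """Survival-horizon label: high / low / indeterminate per sample.

    Death before the horizon is high risk; follow-up (event or censoring)
    reaching the horizon is low risk; censoring before the horizon is
    indeterminate and excluded from confusion counts.
    """
    if threshold_years <= 0:
        raise ValueError("threshold must be positive")
    t = survival.times
    if np.any(t < 0):
        raise ValueError("negative survival times")
    e = survival.events
    cut = threshold_years * DAYS_PER_YEAR
    labels = np.where(
        t >= cut, LOW, np.where(e == 1, HIGH, INDET)
    )
    n_indet = int((labels == INDET).sum())
    if n_indet:
        logger.info("%d sample(s) censored before horizon -> indeterminate", n_indet)
    return pd.Series(labels, index=survival.table["sample_id"].to_numpy())


def predict_risk(
    expr: ExpressionDataset, panel_genes: list[RiskGene]
) -> pd.Series:
    """Majority vote of risky-side exceedances vs the cohort median.

    A gene votes "risky" for a sample when its expression is above the
    cohort median (direction +1) or below it (direction -1).  A strict
    majority of evaluated genes predicts high risk; an exact half is low.
    """
    present = [rg for rg in panel_genes if rg.gene in expr.expression.index]
    if not present:
        raise ValueError("no panel genes present in expression matrix")
    mat = expr.expression.loc[[rg.gene for rg in present]]
    med = mat.median(axis=1)
    above = mat.gt(med, axis=0)
    dirs = pd.Series({rg.gene: rg.direction for rg in present})
    risky = above.where(dirs.reindex(mat.index) == 1, ~above)
    votes = risky.sum(axis=0)
    pred = np.where(votes > len(present) / 2.0, HIGH, LOW)
    return pd.Series(pred, index=mat.columns)


def evaluate_prediction(
    predicted: pd.Series, actual: pd.Series
) -> ConfusionSummary:
    """Confusion counts of predicted vs actual risk; indeterminate excluded."""
    shared = predicted.index.intersection(actual.index)
    a = actual.loc[shared]
    p = predicted.loc[shared]
    keep = a != INDET
    a, p = a[keep], p[keep]
    tp = int(((p == HIGH) & (a == HIGH)).sum())
    fp = int(((p == HIGH) & (a == LOW)).sum())
    tn = int(((p == LOW) & (a == LOW)).sum())
    fn = int(((p == LOW) & (a == HIGH)).sum())
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)


def compare_signatures(
    pred_a: pd.Series, pred_b: pd.Series, actual: pd.Series
) -> TestResult:
    """McNemar on per-sample correctness of two signatures vs actual risk."""
    shared = pred_a.index.intersection(pred_b.index).intersection(actual.index)
    a = actual.loc[shared]
    keep = a != INDET
    a = a[keep]
    ok_a = pred_a.loc[a.index] == a
    ok_b = pred_b.loc[a.index] == a
    b = int((ok_a & ~ok_b).sum())
    c = int((~ok_a & ok_b).sum())
    return mcnemar_test(b, c)


def assemble_panel(
    common_set1: list[RiskGene],
    common_set2: list[RiskGene],
    per_cancer_risk: dict[str, list[RiskGene]],
    cancer_rules: dict[str, str],
    n_individual: int = 3,
) -> RiskPanel:
    """Per-cancer panels from the composition-rule table.

    Rules: ``common-set1`` (shared first-set genes), ``common-set2``,
    ``combined`` (both shared lists), ``common+individual`` (shared
    first-set genes plus that cancer's ``n_individual`` most significant
    risk genes not already included; ties by gene id).  The pan-cancer
    union de-duplicates across cancers.
    """
    per_cancer: dict[str, list[RiskGene]] = {}
    for cancer, rule in cancer_rules.items():
        if rule == "common-set1":
            genes = list(common_set1)
        elif rule == "common-set2":
            genes = list(common_set2)
        elif rule == "combined":
            genes = list(common_set1) + list(common_set2)
        elif rule == "common+individual":
            genes = list(common_set1)
            have = {rg.gene for rg in genes}
            cands = [
                rg for rg in sorted(
                    per_cancer_risk.get(cancer, []), key=lambda r: (r.p_value, r.gene)
                )
                if rg.gene not in have
            ]
            if len(cands) < n_individual:
                logger.warning(
                    "%s: only %d individual risk gene(s) available (wanted %d)",
                    cancer, len(cands), n_individual,
                )
            genes += cands[:n_individual]
        else:
            raise ValueError(f"unknown composition rule {rule!r}")
        # de-duplicate within a cancer, keeping first occurrence
        seen: set[str] = set()
        uniq = []
        for rg in genes:
            if rg.gene not in seen:
                seen.add(rg.gene)
                uniq.append(rg)
        per_cancer[cancer] = uniq
    return RiskPanel(per_cancer=per_cancer, rules=dict(cancer_rules))
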