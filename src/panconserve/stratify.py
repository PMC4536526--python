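"""Tumor stratification from classifier-set expression, with survival tests.

Each sample gets a per-set score: the mean z-score (gene standardized
across the cohort) of the classifier genes.  In two-set mode the sign
pattern of the two scores defines four classes -- class 1 has both sets
up, classes 2 and 3 have only the first or second set up, class 4 has
both down; one-set mode collapses to up (class 1) vs down (class 2).
A score of exactly zero counts as "down".  Class-wise Kaplan-Meier
curves and overall/pairwise log-rank tests quantify the association
between classes and outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .simulate import ExpressionDataset, SurvivalTable
from .survstats import SurvivalCurve, TestResult, km_estimate, logrank_test

logger = logging.getLogger(__name__)


@dataclass
class ClassAssignment:
    classes: pd.Series  # per-sample class label (int)
    scores: pd.DataFrame  # per-sample score per set


def set_score(expr: ExpressionDataset, classifier_genes: list[str]) -> pd.Series:
    """Mean per-gene z-score over the classifier genes, per sample."""
    present = [g for g in classifier_genes if g in expr.expression.index]
    missing = sorted(set(classifier_genes) - set(present))
    if missing:
        logger.warning("%d classifier gene(s) absent from matrix; skipped", len(missing))
    if not present:
        raise ValueError("no classifier genes present in expression matrix")
    mat = expr.expression.loc[present]
    mu = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=1).replace(0.0, np.nan)
    z = mat.sub(mu, axis=0).div(sd, axis=0)
    return z.mean(axis=0, skipna=True)


def classify_samples(
    score_set1: pd.Series, score_set2: pd.Series | None = None
) -> ClassAssignment:
    """Sign-pattern classes: (up, up)->1, (up, down)->2, (down, up)->3, else 4.

    One-set mode (``score_set2`` is None): up -> 1, down -> 2.
    """
    if score_set2 is None:
        classes = pd.Series(
            np.where(score_set1 > 0, 1, 2), index=score_set1.index, dtype=int
        )
        scores = pd.DataFrame({"set1": score_set1})
        return ClassAssignment(classes=classes, scores=scores)
    s2 = score_set2.reindex(score_set1.index)
    up1, up2 = score_set1 > 0, s2 > 0
    classes = pd.Series(4, index=score_set1.index, dtype=int)
    classes[up1 & up2] = 1
    classes[up1 & ~up2] = 2
    classes[~up1 & up2] = 3
    scores = pd.DataFrame({"set1": score_set1, "set2": s2})
    return ClassAssignment(classes=classes, scores=scores)


@dataclass
class ClassSurvival:
    curves: dict[int, SurvivalCurve]
    overall: TestResult | None
    pairwise: dict[tuple[int, int], TestResult]


def class_survival(
    classes: ClassAssignment, survival: SurvivalTable
) -> ClassSurvival:
    """Per-class K-M curves plus overall and pairwise log-rank tests."""
    surv = survival.table.set_index("sample_id")
    shared = classes.classes.index.intersection(surv.index)
    dropped = len(classes.classes) - len(shared)
    if dropped:
        logger.warning("%d sample(s) lack survival records; dropped", dropped)
    labels = classes.classes.loc[shared]
    groups: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for cls in sorted(labels.unique()):
        ids = labels.index[labels == cls]
        groups[int(cls)] = (
            surv.loc[ids, "time_days"].to_numpy(dtype=float),
            surv.loc[ids, "event"].to_numpy(dtype=int),
        )
    curves = {cls: km_estimate(t, e) for cls, (t, e) in groups.items()}
    if len(groups) < 2:
        logger.warning("single non-empty class; log-rank tests skipped")
        return ClassSurvival(curves=curves, overall=None, pairwise={})
    overall = logrank_test(list(groups.values()))
    pairwise = {}
    for a, b in combinations(sorted(groups), 2):
        try:
            pairwise[(a, b)] = logrank_test([groups[a], groups[b]])
        except ValueError:
            logger.warning("pairwise log-rank (%s, %s) undefined; skipped", a, b)
    return ClassSurvival(curves=curves, overall=overall, pairwise=pairwise)
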