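"""Random-dataset (RD) resampling revalidation of a risk panel.

Repeatedly subsample patients from a cohort, re-predict risk from the
panel within each subsample, and test predicted high vs low groups by
log-rank.  The summary is the fraction of RDs reaching significance;
RDs where prediction collapses to a single group count as
non-significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .risk import HIGH, RiskGene, predict_risk
from .simulate import ExpressionDataset, SurvivalTable
from .survstats import logrank_test

logger = logging.getLogger(__name__)


@dataclass
class ResamplingSummary:
    per_rd: pd.DataFrame  # rd_index, n_high, n_low, chi2, p
    fraction_significant: float
    alpha: float
    n_rd: int
    rd_size: int


def resample_validate(
    expr: ExpressionDataset,
    survival: SurvivalTable,
    panel_genes: list[RiskGene],
    n_rd: int = 100,
    rd_size: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    replace: bool = False,
) -> ResamplingSummary:
    """Per-RD log-rank of predicted risk groups; summary fraction with p < alpha.

    Patients are drawn without replacement by default (``replace=True``
    switches to a bootstrap).  Same seed, same memberships and p-values.
    """
    surv = survival.table.set_index("sample_id")
    samples = [s for s in expr.samples if s in surv.index]
    if rd_size > len(samples):
        raise ValueError(f"rd_size {rd_size} exceeds cohort size {len(samples)}")
    if n_rd < 1:
        raise ValueError("n_rd must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    n_sig = 0
    for i in range(n_rd):
        chosen = list(rng.choice(samples, size=rd_size, replace=replace))
        sub = ExpressionDataset(
            cancer=expr.cancer, expression=expr.expression[chosen]
        )
        pred = predict_risk(sub, panel_genes)
        hi = pred.index[pred == HIGH]
        lo = pred.index[pred != HIGH]
        if len(hi) == 0 or len(lo) == 0:
            logger.warning("RD %d: single predicted group; counted non-significant", i)
            rows.append((i, len(hi), len(lo), np.nan, np.nan))
            continue
        t_hi = surv.loc[hi, "time_days"].to_numpy(dtype=float)
        e_hi = surv.loc[hi, "event"].to_numpy(dtype=int)
        t_lo = surv.loc[lo, "time_days"].to_numpy(dtype=float)
        e_lo = surv.loc[lo, "event"].to_numpy(dtype=int)
        try:
            res = logrank_test([(t_hi, e_hi), (t_lo, e_lo)])
        except ValueError:
            rows.append((i, len(hi), len(lo), np.nan, np.nan))
            continue
        if res.p_value < alpha:
            n_sig += 1
        rows.append((i, len(hi), len(lo), res.statistic, res.p_value))
    per_rd = pd.DataFrame(rows, columns=["rd_index", "n_high", "n_low", "chi2", "p"])
    return ResamplingSummary(
        per_rd=per_rd,
        fraction_significant=n_sig / n_rd,
        alpha=alpha,
        n_rd=n_rd,
        rd_size=rd_size,
    )
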