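"""Permutation module-preservation statistics (Zsummary, medianRank).

A reference cohort's module is evaluated in a test cohort through four
observed statistics on the shared gene universe:

* density: mean within-module |correlation| and mean within-module
  adjacency, both measured in the test cohort;
* connectivity: correlation between the two cohorts' intramodular
  connectivity vectors (kIM), and correlation between the off-diagonal
  entries of the two cohorts' within-module correlation matrices.

Each statistic is standardized against a null built from random gene sets
of the same size drawn from the shared universe (random-gene null, which
preserves the test cohort's correlation structure).  Zsummary is the mean
of the density and connectivity composite Z scores; medianRank is the
median of the module's ranks (1 = best) on the four observed statistics
across all evaluated modules.

Classification: strong iff Zsummary > 10 and medianRank < 10; moderate iff
2 < Zsummary <= 10 and medianRank < 10; otherwise none (boundary values go
to the lower class).  The percentage-preservation matrix counts, for each
ordered cohort pair (A, B), the fraction of A's modules preserved in B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import ModuleAssignment, correlation_matrix
from .simulate import ExpressionDataset

STAT_NAMES = ("mean_abs_cor", "mean_adj", "cor_kim", "cor_cor")

STRONG = "strong"
MODERATE = "moderate"
NONE = "none"


@dataclass
class ModulePreservation:
    module: str
    z_density: float
    z_connectivity: float
    z_summary: float
    median_rank: int
    preservation_class: str
    observed: dict[str, float]


@dataclass
class PreservationResult:
    reference: str
    test: str
    modules: list[ModulePreservation]

    def by_module(self) -> dict[str, ModulePreservation]:
        return {m.module: m for m in self.modules}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ref_cancer": self.reference,
                "test_cancer": self.test,
                "module": [m.module for m in self.modules],
                "Zsummary": [m.z_summary for m in self.modules],
                "medianRank": [m.median_rank for m in self.modules],
                "class": [m.preservation_class for m in self.modules],
            }
        )


@dataclass
class PreservationMatrix:
    cancers: list[str]
    percent: pd.DataFrame  # ref x test, values in [0, 100]
    counts: pd.DataFrame  # ref x test, (preserved, total) tuples


def classify_preservation(z_summary: float, median_rank: float) -> str:
    """Strong/moderate/none classification from the two statistics."""
    if not (np.isfinite(z_summary) or z_summary == np.inf):
        raise ValueError("non-finite Zsummary")
    if z_summary > 10 and median_rank < 10:
        return STRONG
    if 2 < z_summary <= 10 and median_rank < 10:
        return MODERATE
    return NONE


def percent_preservation(n_preserved: int, n_total_modules: int) -> float:
    """preserved / total * 100, reported to 2 decimals."""
    if n_total_modules < 1:
        raise ValueError("total module count must be >= 1")
    if n_preserved > n_total_modules:
        raise ValueError("preserved count exceeds total")
    return round(n_preserved / n_total_modules * 100.0, 2)


def _module_stats(
    idx: np.ndarray,
    cor_ref: np.ndarray,
    cor_test: np.ndarray,
    adj_ref: np.ndarray,
    adj_test: np.ndarray,
) -> np.ndarray:
    """The four observed statistics for one gene-index set."""
    ct = cor_test[np.ix_(idx, idx)]
    cr = cor_ref[np.ix_(idx, idx)]
    at = adj_test[np.ix_(idx, idx)]
    m = idx.size
    off = ~np.eye(m, dtype=bool)
    mean_abs_cor = float(np.abs(ct[off]).mean())
    mean_adj = float(at[off].mean())
    # intramodular connectivity agreement between cohorts
    ar = adj_ref[np.ix_(idx, idx)]
    kim_ref = ar.sum(axis=1) - np.diag(ar)
    kim_test = at.sum(axis=1) - np.diag(at)
    cor_kim = _safe_corr(kim_ref, kim_test)
    cor_cor = _safe_corr(cr[off], ct[off])
    return np.array([mean_abs_cor, mean_adj, cor_kim, cor_cor])


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def module_preservation_stats(
    ref_assign: ModuleAssignment,
    ref_expr: ExpressionDataset,
    test_expr: ExpressionDataset,
    n_perm: int = 200,
    seed: int = 0,
    power: int = 6,
    min_shared: int = 3,
) -> PreservationResult:
    """Zsummary / medianRank for each reference module in the test cohort."""
    if n_perm < 50:
        raise ValueError("n_perm must be >= 50")
    ref_genes, cor_ref_full = correlation_matrix(ref_expr)
    test_genes, cor_test_full = correlation_matrix(test_expr)
    shared = sorted(set(ref_genes) & set(test_genes))
    if not shared:
        raise ValueError("no shared genes between cohorts")
    ridx = {g: i for i, g in enumerate(ref_genes)}
    tidx = {g: i for i, g in enumerate(test_genes)}
    r_sel = np.array([ridx[g] for g in shared])
    t_sel = np.array([tidx[g] for g in shared])
    cor_ref = cor_ref_full[np.ix_(r_sel, r_sel)]
    cor_test = cor_test_full[np.ix_(t_sel, t_sel)]
    adj_ref = np.abs(cor_ref) ** power
    adj_test = np.abs(cor_test) ** power
    shared_pos = {g: i for i, g in enumerate(shared)}

    rng = np.random.default_rng(seed)
    null_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    n_univ = len(shared)

    modules = []
    observed: dict[str, np.ndarray] = {}
    for mod in ref_assign.module_names:
        members = [g for g in ref_assign.members(mod) if g in shared_pos]
        if len(members) < min_shared:
            warnings.warn(
                f"module {mod}: only {len(members)} shared gene(s); skipped",
                stacklevel=2,
            )
            continue
        idx = np.array(sorted(shared_pos[g] for g in members))
        observed[mod] = _module_stats(idx, cor_ref, cor_test, adj_ref, adj_test)
        modules.append((mod, idx.size))

    if not modules:
        return PreservationResult(ref_expr.cancer, test_expr.cancer, [])

    # null per module size, shared across same-size modules
    for _, size in modules:
        if size in null_cache:
            continue
        draws = np.empty((n_perm, 4))
        for p in range(n_perm):
            ridx_p = rng.choice(n_univ, size=size, replace=False)
            draws[p] = _module_stats(
                np.sort(ridx_p), cor_ref, cor_test, adj_ref, adj_test
            )
        null_cache[size] = (draws.mean(axis=0), draws.std(axis=0, ddof=1))

    # ranks: 1 = best (largest observed statistic), per statistic
    obs_matrix = np.vstack([observed[m] for m, _ in modules])
    ranks = np.empty_like(obs_matrix)
    for j in range(4):
        order = (-obs_matrix[:, j]).argsort(kind="stable")
        ranks[order, j] = np.arange(1, len(modules) + 1)

    results = []
    for i, (mod, size) in enumerate(modules):
        mu, sd = null_cache[size]
        z = np.empty(4)
        for j in range(4):
            if sd[j] == 0:
                warnings.warn(
                    f"module {mod}: zero null sd for {STAT_NAMES[j]}; Z set to +inf",
                    stacklevel=2,
                )
                z[j] = np.inf
            else:
                z[j] = (obs_matrix[i, j] - mu[j]) / sd[j]
        z_density = float(np.mean(z[:2]))
        z_conn = float(np.mean(z[2:]))
        z_summary = (z_density + z_conn) / 2.0
        median_rank = int(np.median(ranks[i]))
        results.append(
            ModulePreservation(
                module=mod,
                z_density=z_density,
                z_connectivity=z_conn,
                z_summary=z_summary,
                median_rank=median_rank,
                preservation_class=classify_preservation(z_summary, median_rank),
                observed=dict(zip(STAT_NAMES, obs_matrix[i])),
            )
        )
    return PreservationResult(ref_expr.cancer, test_expr.cancer, results)


def preservation_matrix(
    datasets: list[ExpressionDataset],
    assignments: dict[str, ModuleAssignment],
    n_perm: int = 200,
    seed: int = 0,
    power: int = 6,
    count_classes: tuple[str, ...] = (STRONG, MODERATE),
) -> tuple[PreservationMatrix, dict[tuple[str, str], PreservationResult]]:
    """Asymmetric percent-preservation grid over all ordered cohort pairs.

    Cell (A, B) is the percentage of A's modules classified in one of
    ``count_classes`` when evaluated in B.  The diagonal evaluates a
    cohort against itself.  Per-pair results are returned alongside.
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 cohorts")
    cancers = [d.cancer for d in datasets]
    by_cancer = {d.cancer: d for d in datasets}
    root = np.random.SeedSequence(seed)
    pair_seeds = root.spawn(len(cancers) ** 2)
    percent = pd.DataFrame(np.nan, index=cancers, columns=cancers)
    counts = pd.DataFrame(index=cancers, columns=cancers, dtype=object)
    pair_results: dict[tuple[str, str], PreservationResult] = {}
    k = 0
    for ref in cancers:
        total = len(assignments[ref].module_names)
        for test in cancers:
            ps = int(np.random.default_rng(pair_seeds[k]).integers(2**31))
            k += 1
            res = module_preservation_stats(
                assignments[ref], by_cancer[ref], by_cancer[test],
                n_perm=n_perm, seed=ps, power=power,
            )
            pair_results[(ref, test)] = res
            n_pres = sum(
                1 for m in res.modules if m.preservation_class in count_classes
            )
            if total >= 1:
                percent.loc[ref, test] = percent_preservation(n_pres, total)
            counts.loc[ref, test] = (n_pres, total)
    return PreservationMatrix(cancers, percent, counts), pair_results
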