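"""Weighted co-expression network construction and module detection.

Per cohort: soft-thresholded correlation adjacency, topological overlap
similarity, and average-linkage clustering of 1 - TOM with a static cut
approximating the dynamic tree cut used in the field.  The unsigned
network (adjacency |cor|^beta) is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .simulate import ExpressionDataset

UNASSIGNED = "unassigned"


@dataclass
class NetworkModel:
    """Soft-thresholded network for one cohort.

    ``adjacency`` has a unit diagonal by convention; ``connectivity``
    (row sums excluding self) and ``tom`` are filled by
    :func:`tom_similarity`.
    """

    genes: list[str]
    power: int
    adjacency: np.ndarray
    tom: np.ndarray | None = None

    @property
    def connectivity(self) -> np.ndarray:
        return self.adjacency.sum(axis=1) - np.diag(self.adjacency)


@dataclass
class ModuleAssignment:
    """Gene -> module label map; ``unassigned`` is the reserved grey label."""

    labels: dict[str, str]

    @property
    def module_names(self) -> list[str]:
        return sorted({m for m in self.labels.values() if m != UNASSIGNED})

    def members(self, module: str) -> list[str]:
        return [g for g, m in self.labels.items() if m == module]

    @property
    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.labels.values():
            if m != UNASSIGNED:
                out[m] = out.get(m, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.labels), "module_label": list(self.labels.values())}
        )


def _clean_expression(expr: ExpressionDataset) -> pd.DataFrame:
    """Drop zero-variance genes (they carry no correlation signal)."""
    mat = expr.expression
    sd = mat.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant gene(s) before network "
            f"construction in {expr.cancer or 'cohort'}",
            stacklevel=3,
        )
        mat = mat.loc[~constant]
    return mat


def correlation_matrix(expr: ExpressionDataset) -> tuple[list[str], np.ndarray]:
    """Pearson correlation across samples, constant genes dropped."""
    mat = _clean_expression(expr)
    corr = np.corrcoef(mat.to_numpy())
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return list(mat.index), corr


def adjacency(
    expr: ExpressionDataset, power: int, mode: str = "unsigned"
) -> NetworkModel:
    """Soft-threshold adjacency a_ij = |cor|^beta (unsigned) or ((1+cor)/2)^beta."""
    if power < 1:
        raise ValueError("power must be >= 1")
    genes, corr = correlation_matrix(expr)
    if mode == "unsigned":
        adj = np.abs(corr) ** power
    elif mode == "signed":
        adj = ((1.0 + corr) / 2.0) ** power
    else:
        raise ValueError(f"unknown network mode {mode!r}")
    np.fill_diagonal(adj, 1.0)
    return NetworkModel(genes=genes, power=power, adjacency=adj)


def select_soft_threshold(
    expr: ExpressionDataset,
    candidate_powers: list[int] | None = None,
    r2_threshold: float = 0.8,
    mode: str = "unsigned",
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Pick the soft-threshold power by the scale-free topology criterion.

    For each candidate beta the connectivity distribution is binned and
    log10(frequency) regressed on log10(mean connectivity); the fit index
    is sign(-slope) * R^2.  The chosen power is the smallest candidate
    reaching ``r2_threshold``; if none does, the candidate maximizing the
    index (standard pick-soft-threshold behavior).
    """
    if candidate_powers is None:
        candidate_powers = list(range(1, 21))
    mat = _clean_expression(expr)
    if mat.shape[0] < 2 or mat.shape[1] < 3:
        raise ValueError("need at least 2 genes and 3 samples")
    corr = np.clip(np.abs(np.corrcoef(mat.to_numpy())), 0.0, 1.0)
    np.fill_diagonal(corr, 0.0)

    rows = []
    for beta in candidate_powers:
        k = (corr**beta).sum(axis=1)
        rows.append((beta, _scale_free_fit(k, n_bins), float(k.mean())))
    fit = pd.DataFrame(rows, columns=["power", "sft_r2", "mean_connectivity"])

    ok = fit[fit["sft_r2"] >= r2_threshold]
    if len(ok):
        chosen = int(ok["power"].iloc[0])
    else:
        chosen = int(fit.loc[fit["sft_r2"].idxmax(), "power"])
        if not np.isfinite(fit["sft_r2"]).any() or fit["sft_r2"].max() <= -np.inf:
            chosen = candidate_powers[0]
    return chosen, fit


def _scale_free_fit(k: np.ndarray, n_bins: int) -> float:
    """Signed R^2 of log-log frequency vs binned connectivity."""
    k = k[np.isfinite(k)]
    if k.size < 4 or np.allclose(k, k[0]):
        warnings.warn("scale-free fit undefined for degenerate connectivity", stacklevel=3)
        return -np.inf
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = np.array(
        [k[(k >= edges[i]) & (k <= edges[i + 1])].mean() if counts[i] else np.nan
         for i in range(n_bins)]
    )
    keep = (counts > 0) & (centers > 0)
    if keep.sum() < 3:
        return -np.inf
    x = np.log10(centers[keep])
    y = np.log10(counts[keep] / counts.sum())
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2)


def tom_similarity(net: NetworkModel) -> NetworkModel:
    """Topological overlap: TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    The shared-neighbor sum excludes u in {i, j}; the diagonal is 1.
    """
    a = net.adjacency
    k = a.sum(axis=1) - np.diag(a)
    shared = a @ a
    # remove u = i and u = j contributions (diagonal of a is 1)
    shared = shared - a * np.diag(a)[:, None] - a * np.diag(a)[None, :]
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = num / den
    tom = np.clip(tom, 0.0, 1.0)
    tom = (tom + tom.T) / 2.0
    np.fill_diagonal(tom, 1.0)
    net.tom = tom
    return net


def detect_modules(
    net: NetworkModel,
    min_module_size: int = 30,
    cut_height: float | str = "auto",
) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with a static branch cut.

    ``cut_height="auto"`` cuts at dissimilarity 0.99: at the default
    soft-threshold power, uncorrelated genes merge at 1 - TOM ~ 1 and
    stay singletons, while correlated blocks merge far below the cut and
    survive intact (the static-cut convention, a deterministic
    approximation of the dynamic tree cut).  Branches smaller than
    ``min_module_size`` fall into the unassigned label.  Named modules
    are numbered by decreasing size (ties by smallest member id).
    """
    if net.tom is None:
        raise ValueError("TOM not computed; call tom_similarity first")
    if min_module_size < 3:
        raise ValueError("min_module_size must be >= 3")
    genes = net.genes
    diss = 1.0 - net.tom
    np.fill_diagonal(diss, 0.0)
    z = linkage(squareform(diss, checks=False), method="average")
    height = 0.99 if cut_height == "auto" else float(cut_height)
    raw = fcluster(z, t=height, criterion="distance")

    # keep clusters of sufficient size, order by (size desc, member id asc)
    clusters: dict[int, list[str]] = {}
    for g, c in zip(genes, raw):
        clusters.setdefault(int(c), []).append(g)
    named = sorted(
        (c for c, mem in clusters.items() if len(mem) >= min_module_size),
        key=lambda c: (-len(clusters[c]), min(clusters[c])),
    )
    rename = {c: f"M{i + 1}" for i, c in enumerate(named)}
    labels = {
        g: rename.get(int(c), UNASSIGNED) for g, c in zip(genes, raw)
    }
    return ModuleAssignment(labels=labels)


def build_cohort_network(
    expr: ExpressionDataset,
    power: int | None = 6,
    mode: str = "unsigned",
    min_module_size: int = 30,
    cut_height: float | str = "auto",
    candidate_powers: list[int] | None = None,
) -> tuple[NetworkModel, ModuleAssignment, pd.DataFrame | None]:
    """Convenience: adjacency, TOM and module detection for one cohort.

    ``power=6`` is the unsigned-network default; ``power=None`` selects
    the soft threshold by the scale-free fit instead.
    """
    fit = None
    if power is None:
        power, fit = select_soft_threshold(expr, candidate_powers, mode=mode)
    net = adjacency(expr, power, mode=mode)
    net = tom_similarity(net)
    assign = detect_modules(net, min_module_size=min_module_size, cut_height=cut_height)
    return net, assign, fit
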