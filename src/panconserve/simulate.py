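"""Synthetic multi-cancer expression and survival data with known truth.

Emulates the structure the downstream analysis assumes: several tumor
cohorts on a common gene universe, each carrying a subset of planted
co-expression modules (single latent factor per module, so within-module
pairwise correlation is controlled exactly in expectation), background
noise genes, and survival times from a proportional-hazards model driven
by a planted risk score with independent administrative censoring.

Expression values are on a log2-like scale with standard-normal marginals,
mimicking normalized two-color microarray intensities.  The generator
returns full ground truth so module recovery, conserved-set extraction and
risk-gene detection can all be scored against the planted structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class ModuleSpec:
    """One planted co-expression module.

    ``member_cancers`` lists the cohorts in which the module's genes load
    on a shared latent factor; elsewhere the same genes are plain noise.
    ``within_correlation`` is the expected pairwise Pearson correlation
    between two same-sign module genes.
    """

    size: int
    member_cancers: tuple[str, ...]
    within_correlation: float
    name: str | None = None


@dataclass
class RiskSpec:
    """Survival model driven by a subset of planted genes.

    Hazard for a sample with latent risk score s is
    ``baseline_hazard * exp(log_hazard_per_unit * s)`` (per day).
    ``directions`` maps each risk gene to +1 (high expression hazardous)
    or -1 (protective); unlisted risk genes default to +1.
    """

    risk_genes: tuple[str, ...]
    log_hazard_per_unit: float
    baseline_hazard: float  # events per day at score 0
    censoring_rate: float  # expected censored fraction at score 0, in [0, 1)
    directions: dict[str, int] = field(default_factory=dict)

    def direction(self, gene: str) -> int:
        return int(self.directions.get(gene, 1))


@dataclass
class SimulationConfig:
    n_cancers: int
    samples_per_cancer: list[int]
    n_genes: int
    module_specs: list[ModuleSpec]
    n_background_genes: int
    risk_spec: RiskSpec | None
    seed: int
    cancer_names: list[str] | None = None
    mixed_signs: bool = False  # flip half of each module's loadings to -1
    loading_spread: float = 0.1  # per-gene spread around sqrt(within_correlation)
    missing_rate: float = 0.0  # missing-at-random NaN fraction

    def __post_init__(self) -> None:
        if self.cancer_names is None:
            self.cancer_names = [f"C{i + 1}" for i in range(self.n_cancers)]
        if len(self.cancer_names) != self.n_cancers:
            raise ConfigurationError("cancer_names length must equal n_cancers")
        if len(self.samples_per_cancer) != self.n_cancers:
            raise ConfigurationError("samples_per_cancer length must equal n_cancers")
        total_module = sum(m.size for m in self.module_specs)
        if total_module + self.n_background_genes > self.n_genes:
            raise ConfigurationError(
                f"module sizes ({total_module}) + background ({self.n_background_genes}) "
                f"exceed n_genes ({self.n_genes})"
            )
        for m in self.module_specs:
            if not (0.0 < m.within_correlation < 1.0):
                raise ConfigurationError("within_correlation must lie strictly in (0, 1)")
            unknown = set(m.member_cancers) - set(self.cancer_names)
            if unknown:
                raise ConfigurationError(f"unknown member cancers {sorted(unknown)}")
        for i, m in enumerate(self.module_specs):
            if m.name is None:
                m.name = f"mod{i + 1}"


@dataclass
class ExpressionDataset:
    """One cohort: genes x samples expression matrix plus a cohort label."""

    cancer: str
    expression: pd.DataFrame  # index = gene ids, columns = sample ids

    @property
    def genes(self) -> list[str]:
        return list(self.expression.index)

    @property
    def samples(self) -> list[str]:
        return list(self.expression.columns)


@dataclass
class SurvivalTable:
    """Per-sample follow-up: time in days and event indicator (1 = death)."""

    cancer: str
    table: pd.DataFrame  # columns: sample_id, time_days, event

    @property
    def times(self) -> np.ndarray:
        return self.table["time_days"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=int)


@dataclass
class GroundTruth:
    true_module_of_gene: dict[str, str]  # gene -> module name or "background"
    module_members: dict[str, list[str]]
    module_cancers: dict[str, tuple[str, ...]]
    true_risk_genes: dict[str, int]  # gene -> direction
    risk_scores: dict[str, pd.Series]  # cancer -> per-sample latent score
    loadings: dict[str, float] = None  # gene -> signed factor loading

    def shared_modules(self, cancer_a: str, cancer_b: str) -> list[str]:
        return [
            m
            for m, cs in self.module_cancers.items()
            if cancer_a in cs and cancer_b in cs
        ]


def _censor_bound(baseline_hazard: float, censoring_rate: float) -> float:
    """Upper bound C of Uniform(0, C) entry censoring.

    Chosen so the expected censored fraction at score 0 equals
    ``censoring_rate``: with T ~ Exp(lam) and U ~ Unif(0, C),
    P(U < T) = (1 - exp(-lam C)) / (lam C).
    """
    lam = baseline_hazard

    def frac(c: float) -> float:
        return (1.0 - math.exp(-lam * c)) / (lam * c) - censoring_rate

    lo, hi = 1e-9 / lam, 1.0 / lam
    while frac(hi) > 0:
        hi *= 2.0
        if hi > 1e12 / lam:
            break
    return brentq(frac, lo, hi)


def generate_survival(risk_scores, risk_spec: RiskSpec, seed: int) -> SurvivalTable:
    """Exponential event times under proportional hazards, censored independently.

    ``risk_scores`` is a pandas Series (index = sample ids) or array of
    per-sample latent scores.  Recorded time is min(event, censor); the
    event flag marks death observed before censoring.
    """
    if risk_spec.baseline_hazard <= 0:
        raise ConfigurationError("baseline_hazard must be positive")
    if not (0.0 <= risk_spec.censoring_rate < 1.0):
        raise ConfigurationError("censoring_rate must lie in [0, 1)")
    if isinstance(risk_scores, pd.Series):
        sample_ids = list(risk_scores.index)
        scores = risk_scores.to_numpy(dtype=float)
    else:
        scores = np.asarray(risk_scores, dtype=float)
        sample_ids = [f"S{i + 1}" for i in range(scores.size)]
    if not np.all(np.isfinite(scores)):
        raise ConfigurationError("risk scores must be finite")

    rng = np.random.default_rng(seed)
    hazard = risk_spec.baseline_hazard * np.exp(risk_spec.log_hazard_per_unit * scores)
    event_t = rng.exponential(1.0 / hazard)
    if risk_spec.censoring_rate > 0:
        c = _censor_bound(risk_spec.baseline_hazard, risk_spec.censoring_rate)
        censor_t = rng.uniform(0.0, c, size=scores.size)
    else:
        censor_t = np.full(scores.size, np.inf)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    table = pd.DataFrame(
        {"sample_id": sample_ids, "time_days": time, "event": event}
    )
    return SurvivalTable(cancer="", table=table)


def generate_multicancer(
    config: SimulationConfig,
) -> tuple[list[ExpressionDataset], list[SurvivalTable], GroundTruth]:
    """Generate one expression matrix and survival table per cohort.

    Module gene g in a member cohort: x_g = a_g * f + sqrt(1 - a_g^2) * eps,
    with f the per-sample module factor and a_g a signed per-gene loading
    drawn once (shared by all member cohorts) around sqrt(rho), so
    cor(x_g, x_h) = a_g a_h and the expected pairwise within-module
    correlation equals rho.  The small loading spread gives genes a
    reproducible within-module connectivity ranking, as in real
    co-expression data.  Background and non-member module genes are
    independent N(0, 1).  The per-sample latent risk score is the mean of
    direction-aligned risk-gene values; survival follows
    :func:`generate_survival`.
    """
    root = np.random.SeedSequence(config.seed)
    expr_seeds, surv_seeds = root.spawn(2)
    expr_children = expr_seeds.spawn(config.n_cancers)
    surv_children = surv_seeds.spawn(config.n_cancers)

    width = max(4, len(str(config.n_genes)))
    genes = [f"G{str(i + 1).zfill(width)}" for i in range(config.n_genes)]
    module_members: dict[str, list[str]] = {}
    true_module = {g: "background" for g in genes}
    loadings: dict[str, float] = {}
    pos = 0
    loading_rng = np.random.default_rng(root.spawn(1)[0])
    for spec in config.module_specs:
        members = genes[pos : pos + spec.size]
        pos += spec.size
        module_members[spec.name] = members
        for g in members:
            true_module[g] = spec.name
        base = math.sqrt(spec.within_correlation)
        u = loading_rng.uniform(-1.0, 1.0, spec.size)
        u -= u.mean()  # center so the module's mean loading is exactly sqrt(rho)
        mags = np.clip(base + config.loading_spread * u, 0.05, 0.999)
        if config.mixed_signs:
            flips = loading_rng.random(spec.size) < 0.5
            mags = np.where(flips, -mags, mags)
        for g, a in zip(members, mags):
            loadings[g] = float(a)

    risk_genes: dict[str, int] = {}
    if config.risk_spec is not None:
        for g in config.risk_spec.risk_genes:
            if g not in true_module:
                raise ConfigurationError(f"risk gene {g} not in gene universe")
            risk_genes[g] = config.risk_spec.direction(g)

    datasets: list[ExpressionDataset] = []
    survivals: list[SurvivalTable] = []
    risk_scores: dict[str, pd.Series] = {}
    gene_index = {g: i for i, g in enumerate(genes)}

    for ci, cancer in enumerate(config.cancer_names):
        n = config.samples_per_cancer[ci]
        rng = np.random.default_rng(expr_children[ci])
        x = rng.standard_normal((config.n_genes, n))
        for spec in config.module_specs:
            if cancer not in spec.member_cancers:
                continue
            factor = rng.standard_normal(n)
            rows = [gene_index[g] for g in module_members[spec.name]]
            a = np.array([loadings[g] for g in module_members[spec.name]])
            x[rows, :] = (
                a[:, None] * factor[None, :]
                + np.sqrt(1.0 - a**2)[:, None] * x[rows, :]
            )
        if config.missing_rate > 0:
            mask = rng.random(x.shape) < config.missing_rate
            x = np.where(mask, np.nan, x)
        samples = [f"{cancer}_S{str(j + 1).zfill(4)}" for j in range(n)]
        expr = pd.DataFrame(x, index=genes, columns=samples)
        datasets.append(ExpressionDataset(cancer=cancer, expression=expr))

        if config.risk_spec is not None and risk_genes:
            dirs = np.array([risk_genes[g] for g in risk_genes])
            vals = expr.loc[list(risk_genes)].to_numpy()
            score = pd.Series((dirs[:, None] * vals).mean(axis=0), index=samples)
        else:
            score = pd.Series(np.zeros(n), index=samples)
        risk_scores[cancer] = score
        if config.risk_spec is not None:
            surv_seed = int(np.random.default_rng(surv_children[ci]).integers(2**31))
            st = generate_survival(score, config.risk_spec, seed=surv_seed)
            st.cancer = cancer
            survivals.append(st)

    truth = GroundTruth(
        true_module_of_gene=true_module,
        module_members=module_members,
        module_cancers={m.name: tuple(m.member_cancers) for m in config.module_specs},
        true_risk_genes=risk_genes,
        risk_scores=risk_scores,
        loadings=loadings,
    )
    return datasets, survivals, truth
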