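"""Self-contained statistical primitives for the pipeline.

Implements the survival and contingency-table machinery the downstream
stages rely on: the Kaplan-Meier product-limit estimator, the (multi-group)
log-rank test with the standard hypergeometric variance for tied event
times, the exact Fisher test for 2x2 tables, McNemar's test for paired
classifier comparison, and a centered-SVD principal component analysis.

All results are plain dataclasses that serialize naturally to JSON.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate.

    ``event_times`` are the distinct times with at least one event, in
    ascending order; ``survival[i]`` is S(t) immediately after
    ``event_times[i]``.  ``censor_times`` records censoring marks for
    plotting/reporting.  S(0) = 1 and S is constant between event times.
    """

    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    censor_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def survival_at(self, t: float) -> float:
        """S(t) of the step function (right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])

    def to_dict(self) -> dict:
        return {
            "event_times": self.event_times.tolist(),
            "n_at_risk": self.n_at_risk.tolist(),
            "n_events": self.n_events.tolist(),
            "survival": self.survival.tolist(),
        }


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: int | None = None

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "method": self.method,
            "df": self.df,
        }


@dataclass
class PCAResult:
    loadings: np.ndarray  # genes x components, unit-norm columns
    projections: np.ndarray  # samples x components
    variance_fractions: np.ndarray  # descending, in [0, 1]


def _as_surv_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be 1-d and of equal length")
    if t.size == 0:
        raise ValueError("empty survival input")
    if np.any(t < 0):
        raise ValueError("negative survival times")
    if not np.all(np.isin(e, (0, 1))):
        raise ValueError("events must be binary 0/1")
    return t, e


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate S(t) = prod_{t_i<=t} (1 - d_i/n_i)."""
    t, e = _as_surv_arrays(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    ev_times = np.unique(t[e == 1])
    n = t.size
    n_at_risk = np.empty(ev_times.size, dtype=int)
    n_events = np.empty(ev_times.size, dtype=int)
    surv = np.empty(ev_times.size, dtype=float)
    s = 1.0
    for i, ti in enumerate(ev_times):
        at_risk = int(np.sum(t >= ti))
        d = int(np.sum((t == ti) & (e == 1)))
        s *= 1.0 - d / at_risk
        n_at_risk[i], n_events[i], surv[i] = at_risk, d, s
    return SurvivalCurve(
        event_times=ev_times,
        n_at_risk=n_at_risk,
        n_events=n_events,
        survival=surv,
        censor_times=np.sort(t[e == 0]),
    )


def logrank_test(groups) -> TestResult:
    """Multi-group log-rank test.

    ``groups`` is a sequence of (times, events) pairs.  At each distinct
    event time the observed-minus-expected event counts per group are
    accumulated with the multivariate hypergeometric covariance (which
    handles tied event times); the statistic is chi-squared with
    (n_groups - 1) degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("log-rank requires at least two groups")
    parsed = [_as_surv_arrays(t, e) for t, e in groups]
    k = len(parsed)
    all_t = np.concatenate([t for t, _ in parsed])
    all_e = np.concatenate([e for _, e in parsed])
    gid = np.concatenate([np.full(t.size, i) for i, (t, _) in enumerate(parsed)])
    if not np.any(all_e == 1):
        raise ValueError("no events in any group; log-rank undefined")

    ev_times = np.unique(all_t[all_e == 1])
    o_minus_e = np.zeros(k)
    cov = np.zeros((k, k))
    for ti in ev_times:
        at_risk_mask = all_t >= ti
        n_j = np.array([np.sum(at_risk_mask & (gid == j)) for j in range(k)], dtype=float)
        big_n = n_j.sum()
        if big_n <= 1:
            continue
        d_j = np.array(
            [np.sum((all_t == ti) & (all_e == 1) & (gid == j)) for j in range(k)],
            dtype=float,
        )
        big_d = d_j.sum()
        e_j = big_d * n_j / big_n
        o_minus_e += d_j - e_j
        factor = big_d * (big_n - big_d) / (big_n - 1.0) / big_n**2
        cov += factor * (np.diag(n_j * big_n) - np.outer(n_j, n_j))
    z = o_minus_e[:-1]
    v = cov[:-1, :-1]
    chi2 = float(z @ np.linalg.pinv(v) @ z)
    p = float(sps.chi2.sf(chi2, df=k - 1))
    return TestResult(statistic=chi2, p_value=p, method="logrank", df=k - 1)


def fisher_exact_2x2(a: int, b: int, c: int, d: int, alternative: str = "greater") -> TestResult:
    """Exact Fisher test for the 2x2 table [[a, b], [c, d]].

    The cell ``a`` follows a hypergeometric law given the margins;
    ``greater`` sums the upper tail P(X >= a) (enrichment), ``two-sided``
    sums all tables with point probability <= that of the observed one.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cell counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        return TestResult(statistic=float(a), p_value=1.0, method="fisher_exact")
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    if alternative == "greater":
        p = 1.0 if a <= lo else float(pmf[support >= a].sum())
    elif alternative == "two-sided":
        p_obs = float(sps.hypergeom.pmf(a, n, r1, c1))
        p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(statistic=float(a), p_value=min(p, 1.0), method="fisher_exact")


def mcnemar_test(discordant_b: int, discordant_c: int) -> TestResult:
    """McNemar's test on the two discordant-pair counts.

    Continuity-corrected chi-squared (|b-c|-1)^2/(b+c), 1 df, when
    b + c >= 25; exact two-sided binomial(b+c, 1/2) otherwise.  With no
    discordant pairs the test is vacuous and p = 1.
    """
    b, c = int(discordant_b), int(discordant_c)
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return TestResult(statistic=0.0, p_value=1.0, method="mcnemar_exact")
    if n >= 25:
        stat = (abs(b - c) - 1.0) ** 2 / n
        p = float(sps.chi2.sf(stat, df=1))
        return TestResult(statistic=stat, p_value=p, method="mcnemar_cc_chi2", df=1)
    p = min(1.0, 2.0 * float(sps.binom.cdf(min(b, c), n, 0.5)))
    if b == c:
        p = 1.0
    return TestResult(statistic=float(min(b, c)), p_value=p, method="mcnemar_exact")


def pca(matrix, n_components: int | None = None, scale: bool = False) -> PCAResult:
    """Centered (optionally scaled) SVD principal component analysis.

    ``matrix`` is samples x genes.  Loadings are unit-norm gene weights;
    the sign convention makes the largest-magnitude loading of each
    component positive.  Variance fractions are descending.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-d (samples x genes)")
    n_samples, n_genes = x.shape
    max_comp = min(n_samples, n_genes)
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        import warnings

        warnings.warn(
            f"n_components={n_components} exceeds min(dim)={max_comp}; truncating",
            stacklevel=2,
        )
        n_components = max_comp
    xc = x - x.mean(axis=0)
    if scale:
        sd = xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        xc = xc / sd
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    loadings = vt[:n_components].T  # genes x comps
    # sign convention: largest |loading| positive per component
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            u[:, j] *= -1.0
    projections = u[:, :n_components] * s[:n_components]
    total_var = float((s**2).sum())
    var_frac = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    return PCAResult(loadings=loadings, projections=projections, variance_fractions=var_frac)
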