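"""Shared fixtures: small planted multi-cohort datasets with ground truth."""

from __future__ import annotations

import numpy as np
import pytest

import panconserve as pc


@pytest.fixture(scope="session")
def two_cohorts():
    """Two cohorts sharing two planted modules plus background noise."""
    cfg = pc.SimulationConfig(
        n_cancers=2,
        cancer_names=["C1", "C2"],
        samples_per_cancer=[200, 200],
        n_genes=200,
        module_specs=[
            pc.ModuleSpec(size=30, member_cancers=("C1", "C2"), within_correlation=0.8),
            pc.ModuleSpec(size=30, member_cancers=("C1", "C2"), within_correlation=0.7),
        ],
        n_background_genes=140,
        risk_spec=None,
        seed=1,
    )
    return pc.generate_multicancer(cfg)


@pytest.fixture(scope="session")
def risk_cohort():
    """One 400-sample cohort where 9 module genes drive survival (HR 2.5/unit)."""
    risk_genes = tuple(f"G{i:04d}" for i in range(1, 10))
    cfg = pc.SimulationConfig(
        n_cancers=1,
        cancer_names=["C1"],
        samples_per_cancer=[400],
        n_genes=200,
        module_specs=[
            pc.ModuleSpec(size=30, member_cancers=("C1",), within_correlation=0.8)
        ],
        n_background_genes=170,
        risk_spec=pc.RiskSpec(
            risk_genes=risk_genes,
            log_hazard_per_unit=float(np.log(2.5)),
            baseline_hazard=1 / 900.0,
            censoring_rate=0.2,
        ),
        seed=5,
    )
    datasets, survivals, truth = pc.generate_multicancer(cfg)
    return datasets[0], survivals[0], truth


@pytest.fixture(scope="session")
def two_cohort_networks(two_cohorts):
    """Networks + module assignments for the two planted cohorts."""
    from panconserve.network import build_cohort_network

    datasets, _, truth = two_cohorts
    nets, assigns = {}, {}
    for ds in datasets:
        net, assign, _ = build_cohort_network(ds)
        nets[ds.cancer] = net
        assigns[ds.cancer] = assign
    return nets, assigns, truth


def random_survival(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    """A random censored survival sample for cross-check fixtures."""
    t = rng.exponential(100.0, size=n).round(1) + 0.1
    # introduce ties at the day level in about half of the fixtures
    if rng.random() < 0.5:
        t = np.ceil(t)
    e = (rng.random(n) < 0.7).astype(int)
    return t, e
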