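"""Conserved gene sets, thresholded interaction networks, and hub genes.

Across a group of cohorts whose modules are mutually preserved, the
conserved gene set is the intersection of member genes along a chain of
matched modules (one per cohort).  Module matching across cohorts uses
cross-tabulation with a one-sided Fisher exact test.  Within each
cohort's network, edges above a TOM threshold define an interaction
graph whose high-degree nodes are hub genes; hubs common to every cohort
of the group are the classifiers used downstream for stratification.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .network import ModuleAssignment, NetworkModel
from .preservation import STRONG, PreservationResult
from .survstats import fisher_exact_2x2


@dataclass
class OverlapTest:
    module_a: str
    module_b: str
    overlap: int
    p_value: float


@dataclass
class ConservedGeneSet:
    name: str
    genes: list[str]
    group: tuple[str, ...]
    source_modules: dict[str, str]  # cancer -> module label


def module_overlap_test(
    assign_a: ModuleAssignment, assign_b: ModuleAssignment
) -> list[OverlapTest]:
    """Cross-tabulate every module pair over the shared gene universe.

    For modules a and b the 2x2 table over shared genes is
    (in both / a only / b only / neither); the one-sided enrichment p is
    the hypergeometric upper tail.
    """
    universe = set(assign_a.labels) & set(assign_b.labels)
    if not universe:
        raise ValueError("empty shared gene universe")
    out = []
    for ma in assign_a.module_names:
        genes_a = set(assign_a.members(ma)) & universe
        for mb in assign_b.module_names:
            genes_b = set(assign_b.members(mb)) & universe
            both = len(genes_a & genes_b)
            a_only = len(genes_a) - both
            b_only = len(genes_b) - both
            neither = len(universe) - both - a_only - b_only
            res = fisher_exact_2x2(both, a_only, b_only, neither, alternative="greater")
            out.append(OverlapTest(ma, mb, both, res.p_value))
    return out


def extract_conserved_sets(
    group: tuple[str, ...],
    preservation_results: dict[tuple[str, str], PreservationResult],
    assignments: dict[str, ModuleAssignment],
    p_threshold: float = 0.05,
    required_class: str = STRONG,
) -> list[ConservedGeneSet]:
    """Chains of mutually preserved, significantly overlapping modules.

    The lexicographically first cohort of the group anchors the chains
    (this makes the result invariant to the listing order of ``group``).
    For each anchor module: in every other cohort the best-overlap module
    (lowest Fisher p <= threshold) is matched, and the anchor module must
    reach ``required_class`` preservation in both directions of every
    anchor<->member pair.  The conserved set is the intersection of the
    chained modules' genes.
    """
    group = tuple(sorted(group))
    if len(group) == 1:
        only = group[0]
        return [
            ConservedGeneSet(
                name=f"{only}:{m}",
                genes=sorted(assignments[only].members(m)),
                group=group,
                source_modules={only: m},
            )
            for m in assignments[only].module_names
        ]
    anchor = group[0]
    others = group[1:]
    overlap_cache: dict[tuple[str, str], list[OverlapTest]] = {}
    sets: list[ConservedGeneSet] = []
    for mod in assignments[anchor].module_names:
        fwd_ok = all(
            _module_class(preservation_results, anchor, other, mod) == required_class
            for other in others
        )
        if not fwd_ok:
            continue
        chain = {anchor: mod}
        genes = set(assignments[anchor].members(mod))
        ok = True
        for other in others:
            key = (anchor, other)
            if key not in overlap_cache:
                overlap_cache[key] = module_overlap_test(
                    assignments[anchor], assignments[other]
                )
            cands = [
                t
                for t in overlap_cache[key]
                if t.module_a == mod and t.p_value <= p_threshold and t.overlap > 0
            ]
            if not cands:
                ok = False
                break
            best = min(cands, key=lambda t: (t.p_value, -t.overlap, t.module_b))
            # reverse preservation: the matched module must hold up in the anchor
            if (
                _module_class(preservation_results, other, anchor, best.module_b)
                != required_class
            ):
                ok = False
                break
            chain[other] = best.module_b
            genes &= set(assignments[other].members(best.module_b))
        if ok and genes:
            sets.append(
                ConservedGeneSet(
                    name=f"set_{len(sets) + 1}",
                    genes=sorted(genes),
                    group=group,
                    source_modules=chain,
                )
            )
    return sets


def _module_class(
    results: dict[tuple[str, str], PreservationResult],
    ref: str,
    test: str,
    module: str,
) -> str | None:
    res = results.get((ref, test))
    if res is None:
        raise KeyError(f"missing preservation result for pair ({ref}, {test})")
    mp = res.by_module().get(module)
    return None if mp is None else mp.preservation_class


def subset_conserved_set(
    base: ConservedGeneSet,
    extra_cancers: tuple[str, ...],
    assignments: dict[str, ModuleAssignment],
    modules: dict[str, str],
) -> ConservedGeneSet:
    """Restrict a conserved set to genes also in stated modules of extra cohorts.

    This produces the wider-group subset (the "Set 1-s" analogue): the
    base set intersected with one named module per additional cohort.
    """
    genes = set(base.genes)
    chain = dict(base.source_modules)
    for cancer in extra_cancers:
        mod = modules[cancer]
        genes &= set(assignments[cancer].members(mod))
        chain[cancer] = mod
    return ConservedGeneSet(
        name=f"{base.name}-s",
        genes=sorted(genes),
        group=tuple(sorted(set(base.group) | set(extra_cancers))),
        source_modules=chain,
    )


def build_network(
    net: NetworkModel, genes: list[str], edge_threshold: float
) -> nx.Graph:
    """Keep TOM edges >= threshold among the given genes; no self-edges."""
    if not (0.0 <= edge_threshold <= 1.0):
        raise ValueError("edge_threshold must lie in [0, 1]")
    if net.tom is None:
        raise ValueError("TOM not computed")
    pos = {g: i for i, g in enumerate(net.genes)}
    missing = [g for g in genes if g not in pos]
    if missing:
        raise ValueError(f"genes outside network universe: {missing[:5]}")
    g = nx.Graph()
    g.add_nodes_from(genes)
    for i, gi in enumerate(genes):
        for gj in genes[i + 1 :]:
            w = float(net.tom[pos[gi], pos[gj]])
            if w >= edge_threshold:
                g.add_edge(gi, gj, weight=w)
    return g


def find_hubs(network: nx.Graph, min_degree: int = 10) -> list[str]:
    """Genes with degree >= min_degree, by degree descending then gene id."""
    hubs = [(n, d) for n, d in network.degree() if d >= min_degree]
    hubs.sort(key=lambda nd: (-nd[1], nd[0]))
    return [n for n, _ in hubs]


def common_classifiers(
    hub_sets: dict[str, list[str]],
    group: tuple[str, ...],
    source_sets: list[ConservedGeneSet] | None = None,
) -> dict[str, list[str]]:
    """Intersection of per-cohort hub lists, partitioned by conserved set.

    Returns a mapping set-name -> classifier genes; the key "all" holds
    the full intersection when no source sets are given.
    """
    common: set[str] | None = None
    for cancer in group:
        hubs = set(hub_sets.get(cancer, []))
        common = hubs if common is None else (common & hubs)
    common = common or set()
    if not source_sets:
        return {"all": sorted(common)}
    out: dict[str, list[str]] = {}
    for cs in source_sets:
        out[cs.name] = sorted(common & set(cs.genes))
    return out


def hubs_to_frame(network: nx.Graph) -> pd.DataFrame:
    deg = dict(network.degree())
    return pd.DataFrame(
        {"gene": sorted(deg), "degree": [deg[g] for g in sorted(deg)]}
    )
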