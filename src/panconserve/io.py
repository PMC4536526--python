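"""Readers and writers for the pipeline's plain-text formats.

Expression TSV: first column ``gene_id``, remaining columns sample ids.
Survival TSV: columns ``sample_id``, ``time_days``, ``event`` (0/1).
Gene sets are written as GMT, networks as SIF plus a weighted edge list.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .simulate import ExpressionDataset, GroundTruth, SurvivalTable


def read_expression(path: str | Path, cancer: str | None = None) -> ExpressionDataset:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if cancer is None:
        cancer = Path(path).stem
    return ExpressionDataset(cancer=cancer, expression=df)


def write_expression(ds: ExpressionDataset, path: str | Path) -> None:
    ds.expression.to_csv(path, sep="\t", index_label="gene_id")


def read_survival(path: str | Path, cancer: str | None = None) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time_days", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"survival TSV must have columns {sorted(required)}")
    if cancer is None:
        cancer = Path(path).stem
    return SurvivalTable(cancer=cancer, table=df[["sample_id", "time_days", "event"]])


def write_survival(st: SurvivalTable, path: str | Path) -> None:
    st.table.to_csv(path, sep="\t", index=False)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "true_module_of_gene": truth.true_module_of_gene,
        "module_members": truth.module_members,
        "module_cancers": {k: list(v) for k, v in truth.module_cancers.items()},
        "true_risk_genes": truth.true_risk_genes,
        "risk_scores": {c: s.to_dict() for c, s in truth.risk_scores.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "") -> None:
    lines = [
        "\t".join([name, description or name] + list(genes))
        for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        out[parts[0]] = parts[2:]
    return out


def write_sif(network: nx.Graph, path: str | Path, relation: str = "co") -> None:
    lines = [f"{u}\t{relation}\t{v}" for u, v in sorted(network.edges())]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_edge_list(network: nx.Graph, path: str | Path) -> None:
    rows = [
        {"gene_a": u, "gene_b": v, "weight": d.get("weight", 1.0)}
        for u, v, d in sorted(network.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )
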