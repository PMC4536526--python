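"""End-to-end orchestration under one YAML configuration.

Stages run in dependency order: simulate (or ingest) -> per-cohort
networks/modules -> pairwise preservation -> conserved sets -> hub
classifiers -> stratification -> risk genes -> panel assembly ->
resampling validation.  Every output file is recorded with a sha256
checksum in a JSON manifest; a re-run with the same config and seed
reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import conserved, io, network, preservation, resample, risk, stratify
from .simulate import (
    ModuleSpec,
    RiskSpec,
    SimulationConfig,
    generate_multicancer,
)

logger = logging.getLogger(__name__)


DEFAULTS = {
    "min_module_size": 30,
    "network_mode": "unsigned",
    "power": 6,  # unsigned default; null -> auto soft-threshold per cohort
    "preservation_power": 6,
    "n_perm": 200,
    "overlap_p_threshold": 0.05,
    "edge_threshold": 0.02,
    "hub_min_degree": 10,
    "risk_p_threshold": 0.01,
    "risk_threshold_years": 2.0,
    "allowed_outliers": 0,
    "n_rd": 100,
    "rd_size": None,  # default: half the cohort
    "alpha": 0.05,
}


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if "seed" not in cfg:
        raise ValueError("config must set a global seed")
    if "simulation" not in cfg and "cohorts" not in cfg:
        raise ValueError("config needs a 'simulation' block or 'cohorts' paths")
    merged = dict(DEFAULTS)
    merged.update(cfg.get("parameters", {}))
    cfg["parameters"] = merged
    return cfg


def simulation_config_from_dict(block: dict, seed: int) -> SimulationConfig:
    mods = [
        ModuleSpec(
            size=m["size"],
            member_cancers=tuple(m["member_cancers"]),
            within_correlation=m["within_correlation"],
            name=m.get("name"),
        )
        for m in block["modules"]
    ]
    rs = block.get("risk")
    risk_spec = None
    if rs is not None:
        risk_spec = RiskSpec(
            risk_genes=tuple(rs["risk_genes"]),
            log_hazard_per_unit=rs["log_hazard_per_unit"],
            baseline_hazard=rs["baseline_hazard"],
            censoring_rate=rs.get("censoring_rate", 0.2),
            directions=rs.get("directions", {}),
        )
    return SimulationConfig(
        n_cancers=len(block["cancers"]),
        cancer_names=list(block["cancers"]),
        samples_per_cancer=list(block["samples_per_cancer"]),
        n_genes=block["n_genes"],
        module_specs=mods,
        n_background_genes=block.get(
            "n_background_genes", block["n_genes"] - sum(m.size for m in mods)
        ),
        risk_spec=risk_spec,
        seed=seed,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(global_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config_path: str | Path, out_dir: str | Path) -> dict:
    """Run all stages; return (and write) the manifest."""
    cfg = load_config(config_path)
    params = cfg["parameters"]
    seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": str(config_path), "seed": seed, "stages": {}}

    def record(stage: str, files: list[Path], t0: float) -> None:
        manifest["stages"][stage] = {
            "outputs": {str(f.relative_to(out)): _sha256(f) for f in files},
            "seconds": round(time.time() - t0, 3),
        }

    # ---- stage 1: simulate or ingest -------------------------------------
    t0 = time.time()
    files: list[Path] = []
    if "simulation" in cfg:
        sim_cfg = simulation_config_from_dict(
            cfg["simulation"], _stage_seed(seed, "simulate")
        )
        datasets, survivals, truth = generate_multicancer(sim_cfg)
        for ds in datasets:
            f = out / f"expr_{ds.cancer}.tsv"
            io.write_expression(ds, f)
            files.append(f)
        for st in survivals:
            f = out / f"surv_{st.cancer}.tsv"
            io.write_survival(st, f)
            files.append(f)
        f = out / "ground_truth.json"
        io.write_ground_truth(truth, f)
        files.append(f)
    else:
        datasets, survivals = [], []
        for c in cfg["cohorts"]:
            datasets.append(io.read_expression(c["expression"], cancer=c["name"]))
            if "survival" in c:
                survivals.append(io.read_survival(c["survival"], cancer=c["name"]))
    record("simulate", files, t0)
    surv_by_cancer = {s.cancer: s for s in survivals}

    # ---- stage 2: per-cohort networks and modules ------------------------
    t0 = time.time()
    files = []
    nets: dict[str, network.NetworkModel] = {}
    assigns: dict[str, network.ModuleAssignment] = {}
    for ds in datasets:
        net, assign, fit = network.build_cohort_network(
            ds,
            power=params["power"],
            mode=params["network_mode"],
            min_module_size=params["min_module_size"],
        )
        nets[ds.cancer] = net
        assigns[ds.cancer] = assign
        f = out / f"modules_{ds.cancer}.tsv"
        assign.to_frame().to_csv(f, sep="\t", index=False)
        files.append(f)
        if fit is not None:
            f = out / f"sft_{ds.cancer}.tsv"
            fit.to_csv(f, sep="\t", index=False)
            files.append(f)
    record("modules", files, t0)

    # ---- stage 3: preservation matrix ------------------------------------
    t0 = time.time()
    files = []
    pair_results = {}
    if len(datasets) >= 2:
        matrix, pair_results = preservation.preservation_matrix(
            datasets,
            assigns,
            n_perm=params["n_perm"],
            seed=_stage_seed(seed, "preservation"),
            power=params["preservation_power"],
        )
        f = out / "preservation_matrix.tsv"
        matrix.percent.to_csv(f, sep="\t")
        files.append(f)
        f = out / "preservation_pairs.tsv"
        pd.concat([r.to_frame() for r in pair_results.values()]).to_csv(
            f, sep="\t", index=False
        )
        files.append(f)
    else:
        logger.warning("single cohort: preservation stage skipped")
    record("preservation", files, t0)

    # ---- stage 4: conserved sets -----------------------------------------
    t0 = time.time()
    files = []
    group = tuple(cfg.get("group", [d.cancer for d in datasets]))
    sets = []
    if len(datasets) >= 2:
        sets = conserved.extract_conserved_sets(
            group, pair_results, assigns,
            p_threshold=params["overlap_p_threshold"],
        )
        f = out / "conserved_sets.gmt"
        io.write_gmt({s.name: s.genes for s in sets}, f)
        files.append(f)
    record("conserved_sets", files, t0)

    # ---- stage 5: hubs and classifiers -----------------------------------
    t0 = time.time()
    files = []
    classifiers: dict[str, list[str]] = {}
    if sets:
        hub_sets: dict[str, list[str]] = {}
        for cancer in group:
            pool = sorted({g for s in sets for g in s.genes})
            gnet = conserved.build_network(
                nets[cancer], pool, edge_threshold=params["edge_threshold"]
            )
            hub_sets[cancer] = conserved.find_hubs(
                gnet, min_degree=params["hub_min_degree"]
            )
            f = out / f"hubs_{cancer}.tsv"
            conserved.hubs_to_frame(gnet).to_csv(f, sep="\t", index=False)
            files.append(f)
        classifiers = conserved.common_classifiers(hub_sets, group, sets)
        f = out / "classifiers.gmt"
        io.write_gmt(classifiers, f)
        files.append(f)
    record("classifiers", files, t0)

    # ---- stage 6: stratification -----------------------------------------
    t0 = time.time()
    files = []
    set_names = [s.name for s in sets]
    for ds in datasets:
        if not classifiers or ds.cancer not in surv_by_cancer:
            continue
        genes1 = classifiers.get(set_names[0], []) if set_names else []
        genes2 = classifiers.get(set_names[1], []) if len(set_names) > 1 else []
        if not genes1 and not genes2:
            continue
        primary = genes1 or genes2
        s1 = stratify.set_score(ds, primary)
        s2 = stratify.set_score(ds, genes2) if genes1 and genes2 else None
        ca = stratify.classify_samples(s1, s2)
        cs = stratify.class_survival(ca, surv_by_cancer[ds.cancer])
        f = out / f"classes_{ds.cancer}.tsv"
        frame = ca.scores.copy()
        frame.insert(0, "class", ca.classes)
        frame.to_csv(f, sep="\t", index_label="sample_id")
        files.append(f)
        f = out / f"class_survival_{ds.cancer}.json"
        payload = {
            "overall": cs.overall.to_dict() if cs.overall else None,
            "pairwise": {f"{a}v{b}": r.to_dict() for (a, b), r in cs.pairwise.items()},
        }
        f.write_text(json.dumps(payload, indent=1))
        files.append(f)
    record("stratify", files, t0)

    # ---- stage 7: risk genes ---------------------------------------------
    t0 = time.time()
    files = []
    risk_lists: dict[str, list[risk.RiskGene]] = {}
    pool = sorted({g for s in sets for g in s.genes}) if sets else None
    for ds in datasets:
        if ds.cancer not in surv_by_cancer:
            continue
        rl = risk.identify_risk_genes(
            ds,
            surv_by_cancer[ds.cancer],
            p_threshold=params["risk_p_threshold"],
            genes=pool,
        )
        risk_lists[ds.cancer] = rl
        f = out / f"risk_genes_{ds.cancer}.tsv"
        pd.DataFrame(
            [(r.gene, r.direction, r.p_value) for r in rl],
            columns=["gene", "direction", "p_value"],
        ).to_csv(f, sep="\t", index=False)
        files.append(f)
    record("risk_genes", files, t0)

    # ---- stage 8: panel assembly + evaluation -----------------------------
    t0 = time.time()
    files = []
    panel = None
    if risk_lists and len(risk_lists) >= 2:
        common = risk.common_risk_genes(
            risk_lists, tuple(risk_lists), allowed_outliers=params["allowed_outliers"]
        )
        by_gene = {
            rg.gene: rg for rl in risk_lists.values() for rg in rl
        }
        common_rg = [by_gene[g] for g in common]
        rules = cfg.get(
            "panel_rules", {c: "common+individual" for c in risk_lists}
        )
        panel = risk.assemble_panel(common_rg, [], risk_lists, rules)
        f = out / "panel.tsv"
        rows = [
            (c, rg.gene, rg.direction, panel.rules[c])
            for c, lst in panel.per_cancer.items()
            for rg in lst
        ]
        pd.DataFrame(rows, columns=["cancer", "gene", "direction", "rule"]).to_csv(
            f, sep="\t", index=False
        )
        files.append(f)
        evals = {}
        for ds in datasets:
            genes = panel.per_cancer.get(ds.cancer, [])
            if not genes or ds.cancer not in surv_by_cancer:
                continue
            pred = risk.predict_risk(ds, genes)
            actual = risk.assign_actual_risk(
                surv_by_cancer[ds.cancer], params["risk_threshold_years"]
            )
            evals[ds.cancer] = risk.evaluate_prediction(pred, actual).to_dict()
        f = out / "panel_evaluation.json"
        f.write_text(json.dumps(evals, indent=1))
        files.append(f)
    record("panel", files, t0)

    # ---- stage 9: resampling validation -----------------------------------
    t0 = time.time()
    files = []
    if panel is not None:
        summaries = {}
        for ds in datasets:
            genes = panel.per_cancer.get(ds.cancer, [])
            if not genes or ds.cancer not in surv_by_cancer:
                continue
            rd_size = params["rd_size"] or max(10, len(ds.samples) // 2)
            summ = resample.resample_validate(
                ds,
                surv_by_cancer[ds.cancer],
                genes,
                n_rd=params["n_rd"],
                rd_size=min(rd_size, len(ds.samples)),
                seed=_stage_seed(seed, f"resample:{ds.cancer}"),
                alpha=params["alpha"],
            )
            f = out / f"resampling_{ds.cancer}.tsv"
            summ.per_rd.to_csv(f, sep="\t", index=False)
            files.append(f)
            summaries[ds.cancer] = {
                "fraction_significant": summ.fraction_significant,
                "n_rd": summ.n_rd,
                "rd_size": summ.rd_size,
            }
        f = out / "resampling_summary.json"
        f.write_text(json.dumps(summaries, indent=1))
        files.append(f)
    record("resampling", files, t0)

    mf = out / "manifest.json"
    mf.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
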