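"""End-to-end discovery workflow over a config document.

``run_discovery`` executes: generate (or load) inputs -> per-condition ITR
inference -> top-N overlap matrix, common core, core interaction network
and pathway enrichment -> optional signature/survival, screen and peak
stages, writing every table under the output directory together with a
machine-readable ``report.json`` whose provenance block (config hash,
seed, package version) suffices to re-run identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .errors import ItrkitError
from .integration_networks import (
    common_core,
    core_network,
    pathway_enrichment,
    topn_overlap_matrix,
    z_profiles,
)
from .knowledge_io import read_prior_network, write_interactions, write_prior_network
from .omics_contrasts import load_contrast, significant_set, write_contrast
from .regulator_activity import contributions, infer_itrs, write_ranking
from .screen_phenotype import call_hits, gene_log2fc, loess_normalize, well_results
from .signature_survival import (
    build_signature,
    score_cohort,
    stratify_and_test,
)
from .peak_context import classify_peaks, write_labelled_peaks
from . import synthetic_data as synth

log = logging.getLogger("itrkit.pipeline")


def _config_hash(config: Mapping[str, Any]) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _load_config(config: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh) or {}
    return dict(config)


def run_discovery(
    config: str | Path | Mapping[str, Any],
    out_dir: str | Path,
    seed: int | None = None,
) -> dict[str, Any]:
    """Run the full workflow; returns the report dict (also written to
    ``out_dir/report.json``).

    Config keys: ``seed``; either ``scenario`` (synthetic parameters, see
    :mod:`itrkit.synthetic_data`) or ``inputs`` with ``network`` and
    ``contrasts`` (condition -> TSV path); thresholds ``fdr_max``,
    ``min_abs_log2fc``, ``z_threshold``, ``top_n``, ``min_conditions``;
    optional stage blocks ``signature`` (regulator, min_conditions),
    ``cohort`` (bool), ``screen`` (bool or n_plates), ``peaks`` (bool).
    """
    cfg = _load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    cfg.setdefault("seed", 0)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "provenance": {
            "config_hash": _config_hash(cfg),
            "seed": cfg["seed"],
            "itrkit_version": __version__,
            "config": cfg,
        },
        "stages": {},
    }
    failure_marker = out / "FAILED"
    if failure_marker.exists():
        failure_marker.unlink()
    try:
        _run_stages(cfg, out, report)
    except Exception as exc:  # partial outputs retained with a marker
        stage = report.get("current_stage", "unknown")
        failure_marker.write_text(f"stage={stage}\nerror={exc}\n")
        log.error("stage %s failed: %s", stage, exc)
        raise
    finally:
        report.pop("current_stage", None)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report


def _run_stages(cfg: dict[str, Any], out: Path, report: dict[str, Any]) -> None:
    seed = int(cfg["seed"])
    top_n = int(cfg.get("top_n", 100))
    z_threshold = float(cfg.get("z_threshold", 2.0))
    fdr_max = float(cfg.get("fdr_max", 0.05))
    min_abs_log2fc = float(cfg.get("min_abs_log2fc", 0.0))

    # ---- inputs -----------------------------------------------------
    report["current_stage"] = "inputs"
    scenario = None
    if "inputs" in cfg:
        paths = cfg["inputs"]
        log.info("inputs: reading network %s", paths["network"])
        network = read_prior_network(paths["network"])
        tables = {
            cond: load_contrast(path, cond)
            for cond, path in paths["contrasts"].items()
        }
        interactions = None
        pathways = None
    else:
        sc_cfg = cfg.get("scenario") or {}
        if sc_cfg:
            scenario = synth.scenario_from_dict(sc_cfg, seed=seed)
        else:
            scenario = synth.default_scenario(seed=seed)
        log.info("inputs: synthetic scenario, %d conditions", len(scenario.conditions))
        network = synth.generate_prior_network(scenario)
        tables, truth = synth.generate_contrasts(network, scenario)
        interactions = synth.generate_interactions(scenario)
        pathways = synth.generate_pathway_sets(scenario)
        write_prior_network(network, out / "prior_network.tsv")
        write_interactions(interactions, out / "interactions.tsv")
        with open(out / "planted_truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
    for cond, table in tables.items():
        write_contrast(table, out / f"contrast_{cond}.tsv")
    report["stages"]["inputs"] = {
        "n_conditions": len(tables),
        "n_regulators": len(network.regulators),
        "synthetic": scenario is not None,
    }

    # ---- per-condition inference ------------------------------------
    report["current_stage"] = "infer"
    rankings = []
    evidences = {}
    ranking_files = {}
    for cond, table in tables.items():
        evidence = significant_set(table, fdr_max, min_abs_log2fc)
        evidences[cond] = evidence
        ranking = infer_itrs(network, evidence, z_threshold)
        rankings.append(ranking)
        path = out / f"itrs_{cond}.tsv"
        write_ranking(ranking, path)
        ranking_files[cond] = path.name
        log.info("infer: %s — %d evidence genes, %d calls",
                 cond, len(evidence), len(ranking))
    report["stages"]["infer"] = {"ranking_files": ranking_files}

    # ---- integration ------------------------------------------------
    report["current_stage"] = "integrate"
    matrix = topn_overlap_matrix(rankings, n=top_n)
    matrix.to_tsv(out / "overlap_matrix.tsv")
    min_conditions = int(cfg.get("min_conditions", len(rankings)))
    core = common_core(rankings, n=top_n, min_conditions=min_conditions)
    pd.DataFrame(
        sorted((r, len(core.membership[r])) for r in core.regulators),
        columns=["regulator", "n_conditions"],
    ).to_csv(out / "core_set.tsv", sep="\t", index=False)
    integrate_report: dict[str, Any] = {
        "overlap_matrix": "overlap_matrix.tsv",
        "core_size_raw": len(core),
    }
    if interactions is not None:
        regulator_types = cfg.get("regulator_types")
        subgraph, summary = core_network(core, interactions, regulator_types)
        write_interactions(subgraph, out / "core_network.tsv")
        integrate_report["core_network"] = asdict(summary)
        integrate_report["core_size_filtered"] = summary.n_nodes
        if pathways is not None:
            enrich = pathway_enrichment(
                subgraph.nodes, pathways, universe=interactions.nodes
            )
            enrich.to_csv(out / "core_enrichment.tsv", sep="\t", index=False)
            integrate_report["enrichment_file"] = "core_enrichment.tsv"
    profiles = z_profiles(rankings, set().union(*(r.top(10) for r in rankings)))
    profiles.to_csv(out / "z_profiles.tsv", sep="\t", index=False, na_rep="NA")
    report["stages"]["integrate"] = integrate_report

    # ---- signature + survival (optional) ----------------------------
    sig_cfg = cfg.get("signature")
    if sig_cfg is None and scenario is not None and cfg.get("cohort", True):
        # default: signature for the first shared planted regulator
        shared = set.intersection(
            *(set(spec.planted) for spec in scenario.conditions[:-1])
        ) if len(scenario.conditions) > 1 else set(scenario.conditions[0].planted)
        if shared:
            sig_cfg = {"regulator": sorted(shared)[0], "min_conditions": 2}
    if sig_cfg:
        report["current_stage"] = "signature"
        regulator = sig_cfg["regulator"]
        min_sig = int(sig_cfg.get("min_conditions", 2))
        contrib = {
            cond: contributions(network, ev, regulator)
            for cond, ev in evidences.items()
            if ev.directional
        }
        signature = build_signature(regulator, contrib, min_conditions=min_sig)
        signature.to_tsv(out / f"signature_{signature.regulator}.tsv")
        sig_report: dict[str, Any] = {
            "regulator": signature.regulator,
            "n_genes": len(signature),
        }
        if cfg.get("cohort", True) and scenario is not None:
            report["current_stage"] = "survival"
            cohort, _latent = synth.generate_cohort(signature, scenario)
            scores = score_cohort(signature, cohort)
            strat = stratify_and_test(scores, cohort)
            scores.to_frame().to_csv(out / "cohort_scores.tsv", sep="\t")
            for group, curve in strat.km_curves.items():
                curve.to_csv(out / f"km_{group}.tsv", sep="\t", index=False)
            sig_report["logrank_statistic"] = strat.statistic
            sig_report["logrank_p"] = strat.p
        report["stages"]["signature"] = sig_report

    # ---- screen (optional) ------------------------------------------
    if cfg.get("screen", scenario is not None):
        report["current_stage"] = "screen"
        assert scenario is not None, "screen stage needs a synthetic scenario"
        plate, plate_truth = synth.generate_plate(scenario)
        corrected = loess_normalize(plate, span=float(cfg.get("loess_span", 0.5)))
        well_results(corrected).to_csv(out / "screen_wells.tsv", sep="\t", index=False)
        genes = call_hits(gene_log2fc([corrected]))
        genes.to_csv(out / "screen_hits.tsv", sep="\t", index=False)
        plate_truth.to_csv(out / "screen_truth.tsv", sep="\t", index=False)
        n_hits = int((genes["hit"] != "none").sum())
        report["stages"]["screen"] = {
            "n_hit_genes": n_hits,
            "n_planted": len(plate_truth),
        }

    # ---- peaks (optional) -------------------------------------------
    if cfg.get("peaks", scenario is not None):
        report["current_stage"] = "peaks"
        assert scenario is not None, "peaks stage needs a synthetic scenario"
        genes_m, peaks, peak_truth = synth.generate_genome_fixture(scenario)
        summary, labels = classify_peaks(peaks, genes_m)
        summary.as_frame().to_csv(out / "peak_context.tsv", sep="\t", index=False)
        write_labelled_peaks(labels, out / "peaks_labelled.bed")
        merged = labels.merge(peak_truth, on="name", suffixes=("", "_truth"))
        accuracy = float((merged["category"] == merged["category_truth"]).mean())
        report["stages"]["peaks"] = {
            "n_peaks": len(peaks),
            "label_accuracy": accuracy,
        }

    report["current_stage"] = "done"
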