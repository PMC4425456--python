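"""End-to-end orchestration: simulate -> consensus -> annotate -> coloc ->
chiapet -> gsea, from one config, with a manifest and a summary report.

All randomness flows from one root seed through named substreams, so each
stage is independently reproducible; rerunning an identical config yields an
identical manifest hash and byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import GeneAnnotation, annotate_peaks, read_gtf, tss_distance_summary
from .chiapet import direct_target_table, intra_distance_summary, map_interactions, read_interactions
from .colocalization import coloc_panel
from .consensus import call_consensus
from .expression import ExpressionMatrix, gsea
from .intervals import read_genome, read_intervals
from .simulate import SimulationConfig, simulate_all

logger = logging.getLogger(__name__)

__all__ = ["load_config", "run_pipeline"]

STAGES = ["simulate", "consensus", "annotate", "coloc", "chiapet", "gsea"]


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load a YAML pipeline config; absent keys fall back to defaults.

    Schema (all optional)::

        seed: 0
        stages: [simulate, consensus, annotate, coloc, chiapet, gsea]
        simulation: {<SimulationConfig field>: value, ...}
        consensus: {min_support: 2, control_order: per-replicate}
        coloc: {window_bp: 100, n_random: null, half_window: 20000, bin_size: 500}
        chiapet: {anchor_window_bp: 0, fdr_threshold: 0.05}
        gsea: {n_permutations: 1000, weight_exponent: 1.0, gene_set: direct_targets}
    """
    cfg: dict = {}
    if path is not None:
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
    if overrides:
        cfg.update(overrides)
    cfg.setdefault("seed", 0)
    cfg.setdefault("stages", list(STAGES))
    cfg.setdefault("simulation", {})
    cfg.setdefault("consensus", {})
    cfg.setdefault("coloc", {})
    cfg.setdefault("chiapet", {})
    cfg.setdefault("gsea", {})
    unknown = set(cfg) - {"seed", "stages", "simulation", "consensus", "coloc", "chiapet", "gsea"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    bad = [s for s in cfg["stages"] if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: dict | str | Path | None, out_dir: str | Path, seed: int | None = None) -> dict:
    """Run the configured stages, writing per-stage outputs under ``out_dir``.

    Returns the run manifest (config hash, seed, per-stage paths and row
    counts, package version).  A stage failure raises with the failing stage
    named; outputs of completed stages are retained on disk.
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    if seed is not None:
        cfg = {**cfg, "seed": seed}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": _config_hash(cfg),
        "seed": cfg["seed"],
        "version": __version__,
        "stages": {},
    }
    report: dict = {}
    state: dict = {}
    for stage in cfg["stages"]:
        logger.info("stage %s", stage)
        try:
            counts = _STAGE_FUNCS[stage](cfg, out, state, report)
        except Exception as exc:
            _write_json(manifest, out / "manifest.json")
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = counts
        logger.info("stage %s: %s", stage, counts)
    _write_json(manifest, out / "manifest.json")
    _write_json(report, out / "report.json")
    return manifest


def _write_json(obj: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)


def _stage_simulate(cfg, out, state, report):
    sim_dir = out / "simulated"
    sim_cfg = SimulationConfig(**{"seed": cfg["seed"], **cfg["simulation"]})
    result = simulate_all(sim_cfg, out_dir=sim_dir)
    state.update(result)
    return {
        "out": str(sim_dir),
        "n_true_sites": len(result["truth"].sites),
        "n_replicates": len(result["replicates"]),
        "n_genes": len(result["annotation"]),
        "n_interactions": len(result["interactions"]),
    }


def _require(state, key, stage):
    if key not in state:
        raise ValueError(f"stage needs {key!r}; run the 'simulate' stage or provide inputs")
    return state[key]


def _stage_consensus(cfg, out, state, report):
    from .intervals import write_intervals

    reps = _require(state, "replicates", "consensus")
    peaks = call_consensus(
        reps,
        control=state.get("control"),
        min_support=cfg["consensus"].get("min_support", 2),
        control_order=cfg["consensus"].get("control_order", "per-replicate"),
        genome=state.get("genome"),
    )
    state["consensus"] = peaks
    write_intervals(peaks, out / "consensus.bed")
    return {"out": str(out / "consensus.bed"),
            "peaks_in": sum(len(r) for r in reps), "consensus_sites": len(peaks)}


def _stage_annotate(cfg, out, state, report):
    peaks = _require(state, "consensus", "annotate")
    ann = _require(state, "annotation", "annotate")
    table = annotate_peaks(peaks, ann)
    table.to_csv(out / "annotation.tsv", sep="\t", index=False)
    state["peak_annotation"] = table
    ctx = (
        table.drop_duplicates("peak")["context"].value_counts().to_dict()
    )
    summary = tss_distance_summary(peaks, ann)
    report["context_counts"] = ctx
    report["fraction_within_100kb_of_tss"] = summary["fraction_within_threshold"]
    return {"out": str(out / "annotation.tsv"), "peaks": len(peaks),
            "assignments": int(table["gene"].notna().sum())}


def _stage_coloc(cfg, out, state, report):
    from .colocalization import cooccupancy_profile

    peaks = _require(state, "consensus", "coloc")
    cofactors = _require(state, "cofactors", "coloc")
    c = cfg["coloc"]
    panel = coloc_panel(
        peaks, cofactors, genome=state.get("genome"),
        window_bp=c.get("window_bp", 100), n_random=c.get("n_random"),
        seed=cfg["seed"],
    )
    panel.to_csv(out / "coloc_panel.tsv", sep="\t", index=False)
    for factor, features in cofactors.items():
        prof = cooccupancy_profile(
            peaks, features, genome=state.get("genome"),
            half_window=c.get("half_window", 20_000), bin_size=c.get("bin_size", 500),
        )
        prof.to_frame().to_csv(out / f"profile_{factor}.tsv", sep="\t", index=False)
    report["coloc"] = {
        row["feature"]: {"fraction": row["fraction"], "p_value": row["p_value"],
                         "f_score": row["f_score"]}
        for _, row in panel.iterrows()
    }
    return {"out": str(out / "coloc_panel.tsv"), "features": len(panel)}


def _stage_chiapet(cfg, out, state, report):
    peaks = _require(state, "consensus", "chiapet")
    ann = _require(state, "annotation", "chiapet")
    pairs = _require(state, "interactions", "chiapet")
    de = _require(state, "de_table", "chiapet")
    c = cfg["chiapet"]
    links = map_interactions(pairs, peaks, ann,
                             anchor_window_bp=c.get("anchor_window_bp", 0))
    targets = direct_target_table(links, de, fdr_threshold=c.get("fdr_threshold", 0.05))
    targets.to_csv(out / "direct_targets.tsv", sep="\t", index=False)
    state["links"] = links
    state["direct_targets"] = targets
    report["chiapet"] = intra_distance_summary(links)
    report["n_direct_target_genes"] = int(targets["gene"].nunique())
    return {"out": str(out / "direct_targets.tsv"), "interactions": len(pairs),
            "links": len(links), "target_rows": len(targets)}


def _stage_gsea(cfg, out, state, report):
    counts = _require(state, "counts", "gsea")
    lengths = _require(state, "gene_lengths", "gsea")
    c = cfg["gsea"]
    k = counts.shape[1] // 2
    groups = {
        "sim2": [s for s in counts.columns if s.startswith("sim2_")],
        "ctrl": [s for s in counts.columns if s.startswith("ctrl_")],
    }
    expr = ExpressionMatrix(counts, lengths, groups)
    gene_set = c.get("gene_set", "direct_targets")
    if gene_set == "direct_targets":
        if "direct_targets" in state and len(state["direct_targets"]):
            members = sorted(set(state["direct_targets"]["gene"]))
        else:
            members = sorted({l["gene"] for l in state["truth"].loops})
    else:
        members = list(gene_set)
    res = gsea(expr, "sim2", "ctrl", members,
               n_permutations=c.get("n_permutations", 1000),
               weight_exponent=c.get("weight_exponent", 1.0),
               seed=cfg["seed"])
    report["gsea"] = {"es": res.es, "fdr_p": res.fdr_p,
                      "n_set": len(members), "n_permutations": res.n_permutations}
    return {"gene_set_size": len(members), "es": res.es, "fdr_p": res.fdr_p}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "consensus": _stage_consensus,
    "annotate": _stage_annotate,
    "coloc": _stage_coloc,
    "chiapet": _stage_chiapet,
    "gsea": _stage_gsea,
}
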