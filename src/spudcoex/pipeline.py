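"""End-to-end orchestration: simulate -> validate -> normalize -> score ->
select queries -> co-express -> consensus -> qPCR, with a run manifest.

:func:`analyze` performs the full analysis on in-memory objects and is
what the tests and the acceptance script drive; :func:`run_all` wraps it
with file output, stage toggles and a manifest of SHA-256 digests so a
re-run with the same configuration and seed can be verified
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import ARRAY_PLATFORMS, FPKM_PLATFORM, ParamSet, SimConfig
from .coexpression import (
    cross_platform_consensus,
    evaluate_recovery,
    run_platform_coexpression,
)
from .differential import (
    developmental_log2fc,
    gene_profiles,
    select_query_genes,
    tissue_fold_change,
)
from .preprocess import ExpressionMatrix, detection_filter, normalize_chain
from .probe_validation import build_probe_table
from .qpcr import qpcr_correlation_matrix, stage_profiles
from .simulate import SimResult, generate, simulate_qpcr

logger = logging.getLogger("spudcoex")

#: FPKM detection threshold: a gene must reach 1 FPKM in at least one
#: sample to count as detected on the RNA-Seq platform.
FPKM_DETECTION_MIN = 1.0

__version__ = "0.1.0"


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    version: str
    seed: int
    simulation: dict
    params: dict
    stages: dict
    digests: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def analyze(sim: SimResult, params: ParamSet, queries: list[str] | None = None
            ) -> dict:
    """Run the full analysis on a simulation bundle.

    Returns a dict with the probe table, normalized matrices, gene
    profiles, tissue-specificity and developmental tables, the selected
    (or supplied) query genes, per-platform co-expression results, the
    cross-platform consensus and recovery metrics against the planted
    module.
    """
    models = {m.gene_id: m for m in sim.models}
    logger.info("validate-probes: %d platforms", len(sim.probes))
    probe_table, valid_map, exclusions = build_probe_table(
        sim.probes, models, sim.transcripts, sim.premrnas, params.min_identity)

    logger.info("normalize: detection >= %.3g, q = %g",
                params.min_signal, params.percentile_q)
    normalized: dict[str, ExpressionMatrix] = {}
    for plat in ARRAY_PLATFORMS:
        normalized[plat] = normalize_chain(
            sim.matrices[plat], params.min_signal, params.min_samples,
            params.percentile_q, params.log2_floor)
    fpkm = detection_filter(sim.matrices[FPKM_PLATFORM], FPKM_DETECTION_MIN)

    profiles: dict[str, pd.DataFrame] = {}
    ts: dict[str, pd.DataFrame] = {}
    dev: dict[str, pd.DataFrame] = {}
    for plat in ARRAY_PLATFORMS:
        prof = gene_profiles(normalized[plat], valid_map[plat], probe_table)
        profiles[plat] = prof.values
        ts[plat] = tissue_fold_change(prof.values, sim.sample_sheet, plat,
                                      "log2_norm", params)
        dev[plat] = developmental_log2fc(prof.values, sim.sample_sheet, plat)
    profiles[FPKM_PLATFORM] = gene_profiles(fpkm, None).values
    ts[FPKM_PLATFORM] = tissue_fold_change(profiles[FPKM_PLATFORM],
                                           sim.sample_sheet, FPKM_PLATFORM,
                                           "fpkm", params)

    if queries is None:
        logger.info("select-queries: n = %d", params.n_queries)
        queries = select_query_genes(ts, dev, params)
    logger.info("coexpress: queries = %s", ",".join(queries))

    platform_results: dict[str, dict] = {}
    gene_sets: dict[str, set[str]] = {}
    support: dict[str, dict[str, set[str]]] = {}
    for plat in ARRAY_PLATFORMS:
        features = {q: sorted(valid_map[plat].get(q, [])) for q in queries}
        res = run_platform_coexpression(normalized[plat], features, params,
                                        probe_table)
        platform_results[plat] = res
        gene_sets[plat] = res["genes"]
        support[plat] = res["support"]
    if params.fpkm_log:
        corr_matrix = ExpressionMatrix(
            FPKM_PLATFORM, "log2",
            np.log2(fpkm.values + 1.0))
    else:
        corr_matrix = fpkm
    features = {q: [q] for q in queries}
    res = run_platform_coexpression(corr_matrix, features, params, None)
    platform_results[FPKM_PLATFORM] = res
    gene_sets[FPKM_PLATFORM] = res["genes"]
    support[FPKM_PLATFORM] = res["support"]

    consensus = cross_platform_consensus(gene_sets, support)
    consensus.venn_regions = {p: platform_results[p]["venn_regions"]
                              for p in platform_results}
    consensus.ambiguous_genes = set().union(
        *(platform_results[p]["ambiguous_genes"] for p in platform_results))
    recovery = evaluate_recovery(consensus.genes, sim.truth.module_genes,
                                 sim.truth.query_genes)
    logger.info("consensus: %d genes, recall %.2f, precision %.2f",
                len(consensus.genes), recovery["recall"], recovery["precision"])
    return {
        "probe_table": probe_table,
        "valid_map": valid_map,
        "exclusions": exclusions,
        "normalized": normalized,
        "fpkm_detected": fpkm,
        "profiles": profiles,
        "tissue_specificity": ts,
        "developmental": dev,
        "queries": queries,
        "platform_results": platform_results,
        "consensus": consensus,
        "recovery": recovery,
    }


def run_qpcr_stage(sim: SimResult, params: ParamSet, queries: list[str]) -> dict:
    """qPCR validation on an independent synthetic sample set: the query
    genes, two further module genes and two background genes."""
    extra_module = [g for g in sim.truth.module_genes if g not in queries][:2]
    background = sim.truth.genes_with_role("background")[:2]
    genes = list(queries) + extra_module + background
    ct = simulate_qpcr(sim.config, sim.truth, genes)
    profiles = stage_profiles(ct)
    matrix = qpcr_correlation_matrix(profiles, params.p_threshold)
    return {"ct_table": ct, "profiles": profiles, "matrix": matrix}


def run_all(sim_cfg: SimConfig, params: ParamSet, outdir,
            stages: dict[str, bool] | None = None,
            seed: int | None = None) -> tuple[RunManifest, dict]:
    """Full pipeline with file outputs and a digest manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = dict(stages or {})
    used_seed = sim_cfg.seed if seed is None else seed

    manifest = RunManifest(
        version=__version__, seed=used_seed,
        simulation=_jsonable(dataclasses.asdict(sim_cfg)),
        params=dataclasses.asdict(params),
        stages=stages or {"all": True})

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        logger.info("simulate: %d genes, seed %d", sim_cfg.n_genes, used_seed)
        sim = generate(sim_cfg, seed=used_seed)
        _write_sim(sim, outdir)

        results: dict = {"sim": sim}
        if stages.get("validate_probes", True):
            results.update(analyze(sim, params))
            _write_analysis(results, outdir)
            if stages.get("qpcr", True):
                qpcr_res = run_qpcr_stage(sim, params, results["queries"])
                results["qpcr"] = qpcr_res
                io.write_table(qpcr_res["ct_table"], outdir / "qpcr_ct.tsv")
                io.write_table(qpcr_res["profiles"], outdir / "qpcr_profiles.tsv",
                               index=True)
                io.write_table(qpcr_res["matrix"].r, outdir / "qpcr_correlation.tsv",
                               index=True)
                io.write_table(qpcr_res["matrix"].significant.astype(int),
                               outdir / "qpcr_flags.tsv", index=True)
        manifest.warnings = sorted({str(w.message) for w in caught})

    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest.digests[f.name] = io.sha256_file(f)
    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest, results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_sim(sim: SimResult, outdir: Path) -> None:
    io.write_fasta(sim.chromosomes, outdir / "genome.fasta")
    io.write_gff3(sim.models, outdir / "genes.gff3")
    for plat, probes in sim.probes.items():
        io.write_fasta(probes, outdir / f"probes_{plat}.fasta")
    for plat, m in sim.matrices.items():
        io.write_matrix(m, outdir / f"expression_{plat}.tsv")
    io.write_table(sim.sample_sheet, outdir / "samples.tsv")
    (outdir / "truth.json").write_text(sim.truth.to_json() + "\n")


def _write_analysis(results: dict, outdir: Path) -> None:
    io.write_table(results["probe_table"], outdir / "probe_table.tsv")
    (outdir / "excluded_genes.json").write_text(
        json.dumps(results["exclusions"], indent=1, sort_keys=True) + "\n")
    for plat, m in results["normalized"].items():
        io.write_matrix(m, outdir / f"normalized_{plat}.tsv")
    ts_all = pd.concat([df.reset_index() for df in
                        results["tissue_specificity"].values()],
                       ignore_index=True)
    io.write_table(ts_all, outdir / "tissue_specificity.tsv")
    dev_all = pd.concat([df.reset_index() for df in
                         results["developmental"].values()], ignore_index=True)
    io.write_table(dev_all, outdir / "developmental_log2fc.tsv")
    (outdir / "queries.txt").write_text("\n".join(results["queries"]) + "\n")
    hits = pd.concat([r["hits"] for r in results["platform_results"].values()],
                     ignore_index=True)
    io.write_table(hits, outdir / "coexpression_hits.tsv")
    (outdir / "venn_regions.json").write_text(json.dumps(
        results["consensus"].venn_regions, indent=1, sort_keys=True) + "\n")
    cons = results["consensus"]
    rows = [{"gene_id": g,
             **{f"queries_{p}": ",".join(sorted(cons.support[g].get(p, set())))
                for p in sorted(cons.platform_gene_sets)},
             "ambiguous": g in cons.ambiguous_genes}
            for g in cons.genes]
    io.write_table(pd.DataFrame(rows), outdir / "consensus.tsv")
    (outdir / "recovery.json").write_text(
        json.dumps(_jsonable(results["recovery"]), indent=1, sort_keys=True) + "\n")
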