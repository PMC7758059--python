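"""End-to-end pipeline driver: simulate -> score -> GWA -> annotate -> GSEA /
ERC -> overlap enrichment, with per-stage provenance."""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

import modscreen
from modscreen import annotate, enrichment, erc, gsea, io, lmm, relatedness, screen, simulate
from modscreen.config import PipelineConfig

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def causal_indices_in_genes(
    panel, models, n_causal: int, rng: np.random.Generator
) -> tuple[np.ndarray, list[str]]:
    """Pick causal variants inside gene bodies so annotation can recover them."""
    intervals = [(g.start, g.end, g.gene_id) for g in models]
    pos = panel.variants["pos"].to_numpy()
    chrom = panel.variants["chrom"].to_numpy()
    candidates = []
    host = {}
    for j in range(panel.n_variants):
        for lo, hi, gid in intervals:
            if lo <= pos[j] <= hi and chrom[j] == models.genes[0].chrom:
                candidates.append(j)
                host[j] = gid
                break
    if len(candidates) < n_causal:
        raise ValueError(f"only {len(candidates)} in-gene variants for {n_causal} causal")
    idx = rng.choice(candidates, size=n_causal, replace=False)
    return np.sort(idx), [host[j] for j in np.sort(idx)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the synthetic screen pipeline end to end.

    Deterministic given ``config.seed`` / ``config.sim.seed``; every stage
    writes TSV outputs under ``outdir`` and a provenance record
    (``provenance.json``) capturing parameters, library versions and output
    hashes.  Returns a result bundle of the in-memory tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg = config.sim
    bundle: dict = {}
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        io.write_tsv(df, path)
        written.append(path)

    # --- simulate -----------------------------------------------------
    stage = "simulate"
    try:
        rng = np.random.default_rng(sim_cfg.seed)
        panel = simulate.simulate_genotype_panel(sim_cfg, rng=rng)
        models = simulate.simulate_gene_models(sim_cfg, rng=rng)
        causal_idx, causal_genes = (
            causal_indices_in_genes(panel, models, sim_cfg.n_causal, rng)
            if sim_cfg.n_causal
            else (np.empty(0, dtype=int), [])
        )
        pheno = simulate.simulate_phenotypes(panel, sim_cfg, rng=rng, causal_indices=causal_idx)
        counts = simulate.simulate_cross_counts(
            pheno.y, config.cross_n_expected, rng=rng, strain_ids=panel.strain_ids
        )
        covarying = sorted(set([config.focal_gene, *causal_genes]))
        sim_cfg_trees = simulate.SimConfig(
            **{**asdict(sim_cfg), "covarying_group": covarying,
               "maf_range": tuple(sim_cfg.maf_range)}
        )
        trees = simulate.simulate_rate_trees(sim_cfg_trees, rng=rng)
        gene_sets = simulate.simulate_gene_sets(
            sim_cfg, models, enriched_genes=sorted(set(causal_genes)) or None, rng=rng
        )
        io.write_vcf(panel, outdir / "genotypes.vcf")
        io.write_gff3(models, outdir / "genes.gff3")
        io.write_gmt(gene_sets, outdir / "gene_sets.gmt")
        io.write_rate_trees(trees, outdir, prefix="rates")
        emit(counts, "cross_counts.tsv")
        emit(
            pd.DataFrame(
                {
                    "variant_index": causal_idx,
                    "variant_id": panel.variants["id"].to_numpy()[causal_idx],
                    "host_gene": causal_genes,
                    "effect": pheno.causal_effects,
                }
            ),
            "causal_provenance.tsv",
        )
        bundle.update(
            panel=panel, models=models, gene_sets=gene_sets, trees=trees,
            counts=counts, pheno=pheno, causal_genes=causal_genes,
        )
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    # --- screen scoring -----------------------------------------------
    if config.run_screen:
        stage = "screen"
        try:
            scored = screen.score_screen(counts)
            summary = screen.screen_summary(scored)
            emit(scored, "survival.tsv")
            logger.info(
                "screen: %d strains, proportions %.3f-%.3f, R^2(count)=%.3f",
                summary.n_strains, summary.min_proportion,
                summary.max_proportion, summary.r_squared,
            )
            bundle.update(scored=scored, screen_summary=summary)
            y = scored["proportion_surviving"].to_numpy(dtype=float)
        except Exception as exc:
            raise StageError(stage, exc) from exc
    else:
        y = pheno.y

    # --- GWA ----------------------------------------------------------
    if config.run_gwa:
        stage = "gwa"
        try:
            fpanel, report = relatedness.filter_variants(
                panel, min_maf=config.min_maf, max_missing=config.max_missing
            )
            K = relatedness.centered_grm(fpanel)
            io.write_grm_tsv(K, outdir / "grm.tsv")
            written.append(outdir / "grm.tsv")
            assoc = lmm.run_gwa(
                fpanel, y, K,
                mode=config.lmm_mode, method=config.lmm_method,
                reference=config.wald_reference, p_threshold=config.assoc_p_threshold,
            )
            emit(assoc, "assoc.tsv")
            bundle.update(filtered_panel=fpanel, filter_report=report, K=K, assoc=assoc)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    # --- annotation ---------------------------------------------------
    if config.run_annotate and config.run_gwa:
        stage = "annotate"
        try:
            assignments = annotate.assign_all(
                bundle["assoc"], models, window=config.gene_window
            )
            uniq = annotate.unique_assign(assignments)
            cand, cand_counts = annotate.candidate_genes(
                bundle["assoc"], models,
                p_threshold=config.assoc_p_threshold, window=config.gene_window,
            )
            emit(cand, "candidate_genes.tsv")
            bundle.update(assignments=assignments, unique_assignments=uniq,
                          candidates=cand, candidate_counts=cand_counts)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    # --- GSEA -----------------------------------------------------------
    if config.run_gsea and config.run_annotate and config.run_gwa:
        stage = "gsea"
        try:
            ranked = gsea.gene_scores(bundle["assoc"], bundle["unique_assignments"])
            results = gsea.analyse_sets(
                ranked, gene_sets, n_perm=config.gsea_n_perm, seed=config.seed
            )
            kept = gsea.filter_sets(
                results, min_size=config.gsea_min_size,
                min_es=config.gsea_min_es, max_p=config.gsea_max_p,
            )
            emit(gsea.results_table(results), "gsea_all.tsv")
            emit(gsea.results_table(kept), "gsea_filtered.tsv")
            bundle.update(ranked_genes=ranked, gsea_results=results, gsea_filtered=kept)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    # --- ERC ------------------------------------------------------------
    if config.run_erc:
        stage = "erc"
        try:
            erc_table, erc_hits = erc.erc_against_focal(
                config.focal_gene, trees,
                hit_threshold=config.erc_hit_threshold,
                min_branches=config.erc_min_branches,
            )
            emit(erc_table, "erc.tsv")
            bundle.update(erc_table=erc_table, erc_hits=erc_hits)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    # --- overlap enrichment ---------------------------------------------
    if config.run_enrich and config.run_erc and config.run_annotate and config.run_gwa:
        stage = "enrich"
        try:
            universe = models.gene_ids()
            cand_genes = bundle["candidates"]["gene_id"].tolist() if len(bundle["candidates"]) else []
            overlap_rows = []
            if cand_genes and bundle["erc_hits"]:
                k = len(set(cand_genes) & set(bundle["erc_hits"]))
                t = enrichment.hypergeom_overlap(
                    len(set(cand_genes)), len(set(bundle["erc_hits"])), k, len(universe)
                )
                overlap_rows.append({"test": "candidates_vs_erc", **t.__dict__})
            emit(pd.DataFrame(overlap_rows), "overlap_tests.tsv")
            if cand_genes:
                enr = enrichment.set_enrichment(set(cand_genes), gene_sets, universe)
                emit(enr, "candidate_set_enrichment.tsv")
                bundle["candidate_enrichment"] = enr
            bundle["overlap_tests"] = overlap_rows
        except Exception as exc:
            raise StageError(stage, exc) from exc

    # --- provenance -----------------------------------------------------
    prov = {
        "package_version": modscreen.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "sim"},
            "sim": {**asdict(sim_cfg), "maf_range": list(sim_cfg.maf_range)},
        },
        "outputs": {p.name: _sha256(p) for p in sorted(set(written))},
    }
    with (outdir / "provenance.json").open("w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True)
    bundle["provenance"] = prov
    return bundle
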