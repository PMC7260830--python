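"""End-to-end orchestration of the signature-association analysis.

Stages: mutation table -> cloud/dispersed split + attribution -> exposure
table -> phenotype vectors for abundant signature-contexts -> (a)
expression correlation modules with enrichment, (b) per-signature
alteration matrices -> connected-module search with permutation
significance, k selection and FDR.  Each stage reads/writes plain TSV and
JSON so stages can be rerun or replaced with external data; all randomness
flows from the config seed.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

from . import alterations, expression, io, module_search, significance, signatures
from .config import PipelineConfig

logger = logging.getLogger(__name__)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage the config provides inputs for; return the report."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "stages": {}}

    t0 = time.time()
    exposures = None
    attributed = None
    if config.exposures:
        exposures = io.read_exposures(config.exposures)
    elif config.mutations and config.signature_catalog:
        mut = io.read_mutations(config.mutations)
        catalog = io.read_signature_catalog(config.signature_catalog)
        mut = mut.sort_values(["sample", "chrom", "pos"], kind="stable").reset_index(drop=True)
        mut["context_group"] = signatures.split_cloud_dispersed(
            mut, distance_bp=config.cloud_distance_bp)
        attributed, _weights = signatures.attribute_mutations(
            mut, catalog, n_restarts=config.n_attribution_restarts, seed=config.seed)
        exposures = signatures.build_exposure_table(attributed)
        exposures.to_csv(out / "exposures.tsv", sep="\t")
        io.write_mutations(attributed, out / "attributed_mutations.tsv")
    if exposures is None:
        raise ValueError("config must provide either exposures or mutations + signature_catalog")

    retained = signatures.filter_abundant(exposures, threshold=config.exposure_threshold)
    phenotypes = {}
    for label in retained:
        try:
            phenotypes[label] = signatures.make_phenotype(
                exposures, label, pseudocount=config.pseudocount)
        except ValueError:
            logger.warning("skipping %s: constant counts", label)
    logger.info("phenotype stage finished in %.2f s", time.time() - t0)
    report["stages"]["phenotypes"] = {"retained_labels": retained}

    if config.expression and phenotypes:
        t = time.time()
        expr = io.read_expression(config.expression)
        shared = [s for s in expr.columns if s in exposures.index]
        logger.info("expression analysis on %d/%d shared samples", len(shared), expr.shape[1])
        profile = expression.correlate(expr, list(phenotypes.values()))
        selected = expression.select_genes(profile, rho_min=config.rho_min,
                                           p_adj_max=config.p_adj_max)
        stage = {"n_selected": len(selected), "selected": selected}
        if len(selected) >= 2:
            final_k = min(config.final_k, len(selected))
            consensus, clusters = expression.consensus_cluster(
                profile.loc[selected], n_runs=config.consensus_runs,
                k_range=(min(config.k_range[0], len(selected) - 1),
                         min(config.k_range[1], len(selected) - 1)),
                final_k=final_k, seed=config.seed)
            consensus.to_csv(out / "consensus_matrix.tsv", sep="\t")
            clusters.assignments.to_csv(out / "clusters.tsv", sep="\t")
            clusters.mean_correlation.to_csv(out / "cluster_mean_correlation.tsv", sep="\t")
            stage["n_clusters"] = int(clusters.assignments.nunique())
            if config.gene_sets:
                gene_sets = io.read_gmt(config.gene_sets)
                background = set(expr.index)
                table = expression.enrich_clusters(
                    clusters, gene_sets, background, p_max=config.enrichment_p_max)
                table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
                stage["n_enriched_terms"] = int(len(table))
        profile.to_csv(out / "correlations.tsv", sep="\t")
        logger.info("expression stage finished in %.2f s", time.time() - t)
        report["stages"]["expression_modules"] = stage

    if config.network and attributed is not None and phenotypes:
        t = time.time()
        edges = io.read_edge_list(config.network)
        network = module_search.load_network(edges, threshold=config.edge_score_min)
        biallelic = io.read_biallelic(config.biallelic) if config.biallelic else None
        modules = {}
        for label, phen in phenotypes.items():
            matrix = alterations.build_matrix(
                attributed, biallelic, target=label,
                frequency_min=config.frequency_min,
                patients=list(exposures.index))
            genes = sorted(set(matrix.index) & set(network.nodes))
            if not genes:
                logger.warning("no network genes altered for %s", label)
                continue
            chosen_k, table, sols = significance.k_selection_scan(
                matrix, phen.values, network, k_max=config.k_max,
                density_min=config.density_min,
                exclusivity_weight=config.exclusivity_weight,
                n_permutations=config.n_permutations,
                seed=config.seed)
            sol = sols[chosen_k]
            modules[label] = {
                "k": chosen_k,
                "genes": list(sol.genes),
                "objective": sol.objective,
                "density": sol.density,
                "p": float(table.loc[chosen_k, "p"]),
                "per_k": table.reset_index().to_dict(orient="records"),
            }
        if modules:
            fdr = significance.fdr_significance(
                {l: m["p"] for l, m in modules.items()}, q_max=config.q_max)
            for l in modules:
                modules[l]["q"] = float(fdr.loc[l, "q"])
                modules[l]["significant"] = bool(fdr.loc[l, "significant"])
        logger.info("alteration-module stage finished in %.2f s", time.time() - t)
        report["stages"]["alteration_modules"] = {"modules": modules}

    io.write_json(report, out / "report.json")
    return report
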