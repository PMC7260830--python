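"""Synthetic data with the statistical structure the pipeline assumes.

Every generator returns its ground truth alongside the data, so each
downstream stage (attribution, expression clustering, module search) can be
tested for recovery without any external cohort.  All generators are
deterministic given their seed.

What is emulated, and what is not: mutation catalogs are multinomial draws
from signature channel distributions, with a configurable fraction placed
in tight "cloud" runs (2-10 mutations closer than the cloud spacing) and
the rest widely dispersed — there is no real reference genome, replication
timing, or trinucleotide-content model.  Expression is rank-coupled
Gaussian noise; alteration matrices are Bernoulli background plus a planted
connected module whose coverage shifts a Gaussian log-scale phenotype.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .contexts import N_CHANNELS, CHANNELS


@dataclass
class SimulationConfig:
    """Shared knobs for all generators; see field comments for units.

    ``module_coverage`` (fraction of patients whose phenotype the planted
    alteration module drives) is needed to plant an association of a chosen
    strength and has no counterpart in real data preprocessing.
    """

    n_patients: int = 100
    n_genes: int = 50
    signature_catalog: pd.DataFrame | None = None   # 96 channels x signatures
    exposure_means: dict[str, float] = field(default_factory=dict)  # mean SNVs per signature
    cloud_fraction: float = 0.0          # fraction of mutations placed in clouds
    cloud_spacing_bp: int = 1000         # max intra-cloud inter-mutation distance
    planted_module: tuple[str, ...] = ()  # genes of the planted alteration module
    module_effect: float = 2.0           # log-scale phenotype shift per covered patient
    module_coverage: float = 0.3         # fraction of patients covered by the module
    exclusivity: float = 0.9             # P(covered patient has exactly one module gene altered)
    background_alteration_rate: float = 0.02
    expr_module_genes: tuple[str, ...] = ()
    expr_module_rho: float = 0.6         # target Spearman with the tied exposure
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cloud_fraction", "module_coverage", "exclusivity",
                     "background_alteration_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not -1.0 < self.expr_module_rho < 1.0:
            raise ValueError("expr_module_rho must be in (-1, 1)")
        if any(v < 0 for v in self.exposure_means.values()):
            raise ValueError("exposure_means must be nonnegative")
        if self.n_patients < 1 or self.n_genes < 1:
            raise ValueError("n_patients and n_genes must be positive")


def gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def patient_names(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(n)]


def generate_network(n_genes: int, edge_density: float, planted_module,
                     seed: int = 0, score_threshold: float = 900.0) -> nx.Graph:
    """Random scored interaction network with a connected planted module.

    Edges appear independently with probability ``edge_density``; a random
    spanning tree over the planted module is added so its induced subgraph
    is connected (verified before returning).  Edge scores are uniform in
    [score_threshold, 1000], i.e. all pass the confidence filter.
    """
    planted = list(planted_module)
    genes = gene_names(n_genes)
    if not set(planted) <= set(genes):
        raise ValueError("planted module genes must be among the generated genes")
    if len(planted) > n_genes:
        raise ValueError("planted module larger than the gene universe")
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(genes)
    idx = np.triu_indices(n_genes, k=1)
    keep = rng.random(len(idx[0])) < edge_density
    for a, b in zip(idx[0][keep], idx[1][keep]):
        g.add_edge(genes[a], genes[b])
    # random spanning tree over the module: connect each gene to a random earlier one
    order = list(planted)
    rng.shuffle(order)
    for i in range(1, len(order)):
        g.add_edge(order[i], order[rng.integers(0, i)])
    for u, v in g.edges:
        g.edges[u, v]["score"] = float(rng.uniform(score_threshold, 1000.0))
    if planted and not nx.is_connected(g.subgraph(planted)):
        raise AssertionError("planted module not connected after generation")
    return g


def generate_mutation_catalog(cfg: SimulationConfig) -> pd.DataFrame:
    """Simulate per-patient mutations from the signature catalog.

    For each patient and signature, the mutation count is Poisson with the
    configured mean, and each mutation's channel is a draw from that
    signature's 96-channel distribution.  A ``cloud_fraction`` of each
    patient's mutations is laid out in runs of 2-10 mutations with uniform
    spacing below ``cloud_spacing_bp``; the remainder are spaced at least
    10x the cloud spacing apart.  True signature labels are kept in the
    ``true_signature`` column.
    """
    if cfg.signature_catalog is None or not cfg.exposure_means:
        raise ValueError("signature_catalog and exposure_means are required")
    from .contexts import validate_catalog

    cat = validate_catalog(cfg.signature_catalog)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for patient in patient_names(cfg.n_patients):
        chans, sigs = [], []
        for sig, mean in cfg.exposure_means.items():
            n = int(rng.poisson(mean))
            if n == 0:
                continue
            p = cat[sig].to_numpy()
            chans.extend(rng.choice(N_CHANNELS, size=n, p=p).tolist())
            sigs.extend([str(sig)] * n)
        n_mut = len(chans)
        if n_mut == 0:
            continue
        perm = rng.permutation(n_mut)
        chans = [chans[i] for i in perm]
        sigs = [sigs[i] for i in perm]
        n_cloud = int(round(cfg.cloud_fraction * n_mut))
        positions = _layout_positions(n_mut, n_cloud, cfg.cloud_spacing_bp, rng)
        for (pos, in_cloud), ch, sg in zip(positions, chans, sigs):
            ref, alt = _ref_alt_for_channel(ch)
            rows.append((patient, "chr1", int(pos), ref, alt, "SNV",
                         "non-silent", "", int(ch), sg, in_cloud))
    df = pd.DataFrame(rows, columns=[
        "sample", "chrom", "pos", "ref", "alt", "variant_type",
        "consequence", "gene", "channel", "true_signature", "true_cloud",
    ])
    return df.sort_values(["sample", "chrom", "pos"], kind="stable").reset_index(drop=True)


def _ref_alt_for_channel(ch: int) -> tuple[str, str]:
    label = CHANNELS[ch]          # e.g. "A[C>A]A"
    return label[2], label[4]


def _layout_positions(n_mut: int, n_cloud: int, spacing: int,
                      rng: np.random.Generator) -> list[tuple[int, bool]]:
    """Positions for one patient: cloud runs first, then dispersed tail.

    Cloud runs hold 2-10 mutations with gaps in [1, spacing); dispersed
    mutations (and the gaps between runs) are >= 10x spacing apart.
    """
    if n_cloud == 1:  # a single mutation cannot form a cloud
        n_cloud = 0
    out: list[tuple[int, bool]] = []
    pos = int(rng.integers(1, 10 * spacing))
    remaining = n_cloud
    while remaining > 0:
        size = int(min(remaining, rng.integers(2, 11)))
        if remaining - size == 1:
            size += 1  # avoid stranding a single "cloud" mutation
            size = min(size, remaining)
        for _ in range(size):
            out.append((pos, True))
            pos += int(rng.integers(1, max(2, spacing)))
        remaining -= size
        pos += 10 * spacing + int(rng.integers(0, 10 * spacing))
    for _ in range(n_mut - n_cloud):
        out.append((pos, False))
        pos += 10 * spacing + int(rng.integers(1, 10 * spacing))
    return out


def generate_alterations_and_phenotype(
    cfg: SimulationConfig, network: nx.Graph,
) -> tuple[pd.DataFrame, "pd.Series", dict]:
    """Plant a phenotype-driving, mutually exclusive alteration module.

    Each patient is covered by the planted module with probability
    ``module_coverage``; a covered patient gets exactly one altered module
    gene with probability ``exclusivity`` and two otherwise.  Background
    genes are altered independently at ``background_alteration_rate``.  The
    phenotype is Gaussian noise (sd ``noise_sd``) on the log scale, shifted
    by ``module_effect`` for covered patients, then z-scored.

    Returns (alteration matrix genes x patients, phenotype z-scores, truth
    record with module genes and covered patients).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    genes = sorted(network.nodes)
    module = [g for g in cfg.planted_module]
    if not set(module) <= set(genes):
        raise ValueError("planted module not contained in network nodes")
    patients = patient_names(cfg.n_patients)
    M = pd.DataFrame(0, index=genes, columns=patients, dtype=np.int8)
    background = [g for g in genes if g not in module]
    noise = rng.random((len(background), cfg.n_patients)) < cfg.background_alteration_rate
    M.loc[background, :] = noise.astype(np.int8)

    covered = rng.random(cfg.n_patients) < cfg.module_coverage
    for j, patient in enumerate(patients):
        if not covered[j] or not module:
            continue
        if rng.random() < cfg.exclusivity or len(module) == 1:
            hit = rng.choice(len(module), size=1)
        else:
            hit = rng.choice(len(module), size=2, replace=False)
        for h in hit:
            M.loc[module[h], patient] = 1

    raw = rng.normal(0.0, cfg.noise_sd, cfg.n_patients) + cfg.module_effect * covered
    z = (raw - raw.mean()) / raw.std(ddof=1)
    phen = pd.Series(z, index=patients, name="phenotype")
    truth = {
        "module": sorted(module),
        "covered_patients": [p for p, c in zip(patients, covered) if c],
        "module_effect": cfg.module_effect,
    }
    return M, phen, truth


def generate_expression(cfg: SimulationConfig, exposures: pd.DataFrame,
                        module_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Expression matrix with planted exposure-correlated gene modules.

    ``module_map`` assigns gene -> exposure column; by default every gene
    in ``cfg.expr_module_genes`` tracks the first exposure column.  Module
    genes get expression rho * standardized-rank(exposure) +
    sqrt(1-rho^2) * noise, so their Spearman correlation with the exposure
    is approximately ``expr_module_rho``; all other genes are pure noise.
    Rows are genes, columns patients (matching the exposure table rows).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    patients = list(exposures.index)
    n = len(patients)
    genes = gene_names(cfg.n_genes)
    if module_map is None:
        first = exposures.columns[0]
        module_map = {g: first for g in cfg.expr_module_genes}
    rho = cfg.expr_module_rho
    X = rng.normal(0.0, 1.0, (cfg.n_genes, n))
    for i, g in enumerate(genes):
        if g in module_map:
            r = rankdata(exposures[module_map[g]].to_numpy())
            r = (r - r.mean()) / r.std()
            X[i] = rho * r + np.sqrt(1.0 - rho ** 2) * rng.normal(0.0, 1.0, n)
    X *= cfg.noise_sd if cfg.noise_sd > 0 else 1.0
    return pd.DataFrame(X, index=genes, columns=patients)


def write_simulation(outdir, mutations=None, expression=None, edges=None,
                     exposures=None, alterations=None, phenotype=None, truth=None) -> None:
    """Write generated inputs in the pipeline's TSV formats plus truth JSON."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if mutations is not None:
        mutations.to_csv(out / "mutations.tsv", sep="\t", index=False)
    if expression is not None:
        expression.to_csv(out / "expression.tsv", sep="\t")
    if edges is not None:
        rows = [(u, v, d.get("score", 1000.0)) for u, v, d in edges.edges(data=True)]
        pd.DataFrame(rows, columns=["gene1", "gene2", "score"]).to_csv(
            out / "network.tsv", sep="\t", index=False)
    if exposures is not None:
        exposures.to_csv(out / "exposures.tsv", sep="\t")
    if alterations is not None:
        alterations.to_csv(out / "alterations.tsv", sep="\t")
    if phenotype is not None:
        phenotype.to_csv(out / "phenotype.tsv", sep="\t", header=True)
    if truth is not None:
        (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
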