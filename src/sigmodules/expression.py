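"""Expression modules correlated with signature exposure phenotypes.

Pipeline: Spearman-correlate every gene's expression with every
signature-context phenotype; keep genes significantly correlated with at
least one (|rho| >= 0.3 and BH-adjusted p <= 0.005 by default); cluster the
retained genes' correlation profiles by consensus K-means (repeated
random-start K-means with the cluster number cycling over a range, then
average-linkage hierarchical clustering of the co-clustering frequencies);
annotate clusters by hypergeometric gene-set enrichment, optionally against
a restricted background with an overlap filter on the terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom, rankdata
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .signatures import PhenotypeVector

logger = logging.getLogger(__name__)


def correlate(expr: pd.DataFrame, phenotypes: list[PhenotypeVector]) -> pd.DataFrame:
    """Spearman correlation of every gene with every phenotype.

    ``expr`` is genes x samples.  Correlations are computed on the samples
    shared between the expression matrix and each phenotype (at least 3
    required).  Constant-expression genes are excluded (logged).  Raw
    two-sided p-values are BH-adjusted jointly over all gene x phenotype
    pairs.

    Returns a frame indexed by gene with column pairs
    ``(label, "rho")`` and ``(label, "p_adj")``.
    """
    const = expr.std(axis=1, ddof=0) == 0
    if const.any():
        logger.info("excluding %d constant-expression genes", int(const.sum()))
        expr = expr.loc[~const]
    genes = expr.index
    rho_cols: dict[str, np.ndarray] = {}
    praw_cols: dict[str, np.ndarray] = {}
    for ph in phenotypes:
        shared = [s for s in expr.columns if s in ph.values.index]
        if len(shared) < 3:
            raise ValueError(f"fewer than 3 shared samples for phenotype {ph.label}")
        X = expr[shared].to_numpy(dtype=float)
        y = ph.values.reindex(shared).to_numpy(dtype=float)
        rho, p = _spearman_vector(X, y)
        rho_cols[ph.label] = rho
        praw_cols[ph.label] = p
    labels = [ph.label for ph in phenotypes]
    praw = np.column_stack([praw_cols[l] for l in labels])
    padj = multipletests(praw.ravel(), method="fdr_bh")[1].reshape(praw.shape)
    out = {}
    for i, l in enumerate(labels):
        out[(l, "rho")] = rho_cols[l]
        out[(l, "p_adj")] = padj[:, i]
    return pd.DataFrame(out, index=genes)


def _spearman_vector(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman rho of X (genes x n) against y (n,), with p-values.

    Ranks (average ties) then Pearson; p from the t approximation, the same
    large-sample form scipy uses.
    """
    from scipy.stats import t as tdist

    n = X.shape[1]
    Rx = np.apply_along_axis(rankdata, 1, X)
    ry = rankdata(y)
    Rx = Rx - Rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean()
    denom = np.sqrt((Rx ** 2).sum(axis=1) * (ry ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (Rx @ ry) / denom
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * tdist.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return rho, p


def select_genes(profile: pd.DataFrame, rho_min: float = 0.3,
                 p_adj_max: float = 0.005) -> list[str]:
    """Genes significantly correlated with at least one phenotype."""
    labels = sorted({l for l, _ in profile.columns})
    keep = np.zeros(len(profile), dtype=bool)
    for l in labels:
        keep |= (
            (profile[(l, "rho")].abs().to_numpy() >= rho_min)
            & (profile[(l, "p_adj")].to_numpy() <= p_adj_max)
        )
    return [g for g, k in zip(profile.index, keep) if k]


@dataclass
class GeneClusterSet:
    assignments: pd.Series              # gene -> cluster id (1..final_k)
    mean_correlation: pd.DataFrame      # cluster x phenotype label

    @property
    def clusters(self) -> dict[int, list[str]]:
        return {int(c): sorted(g.index) for c, g in self.assignments.groupby(self.assignments)}


def consensus_cluster(profile: pd.DataFrame, n_runs: int = 100,
                      k_range: tuple[int, int] = (5, 50), final_k: int = 7,
                      seed: int = 0) -> tuple[pd.DataFrame, GeneClusterSet]:
    """Consensus K-means of gene correlation profiles.

    Runs K-means ``n_runs`` times on the rho columns of ``profile`` with a
    fresh random start each run and k cycling round-robin through
    ``k_range`` (clipped below the number of genes).  The consensus matrix
    holds the fraction of runs in which two genes share a cluster; it is
    clustered by average-linkage on (1 - consensus) and cut into
    ``final_k`` clusters.
    """
    labels = sorted({l for l, _ in profile.columns})
    X = profile[[(l, "rho") for l in labels]].to_numpy(dtype=float)
    genes = list(profile.index)
    n = len(genes)
    if n < 2:
        raise ValueError("need at least 2 genes to cluster")
    if final_k > n:
        raise ValueError("final_k exceeds the number of genes")
    lo, hi = k_range
    ks = [lo + (r % (hi - lo + 1)) for r in range(n_runs)]
    ks = [min(k, n) for k in ks]
    rng = np.random.default_rng(seed)
    co = np.zeros((n, n))
    for k in ks:
        km = KMeans(n_clusters=k, n_init=1, init="random",
                    random_state=int(rng.integers(0, 2 ** 31 - 1)))
        lab = km.fit_predict(X)
        co += (lab[:, None] == lab[None, :])
    consensus = co / n_runs
    np.fill_diagonal(consensus, 1.0)
    dist = squareform(1.0 - consensus, checks=False)
    Z = linkage(dist, method="average")
    assign = fcluster(Z, t=final_k, criterion="maxclust")
    assignments = pd.Series(assign, index=genes, name="cluster")
    means = pd.DataFrame(
        {l: [X[assign == c, labels.index(l)].mean() for c in sorted(set(assign))]
         for l in labels},
        index=sorted(set(assign)),
    )
    cons = pd.DataFrame(consensus, index=genes, columns=genes)
    return cons, GeneClusterSet(assignments=assignments, mean_correlation=means)


@dataclass
class EnrichmentResult:
    cluster: object
    term: str
    overlap: int
    universe: int
    term_size: int
    cluster_size: int
    p: float


def enrich(cluster: set[str], term: set[str], background: set[str],
           term_name: str = "", cluster_name: object = None) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of a term in a cluster.

    Draws |cluster| genes from the background, with |term & background|
    successes; p = P(X >= observed overlap).  The cluster must be contained
    in the background; the term is intersected with the background first.
    """
    if not background:
        raise ValueError("empty background")
    if not cluster <= background:
        raise ValueError("cluster must be a subset of the background")
    term_in = term & background
    overlap = len(cluster & term_in)
    M, n, N = len(background), len(term_in), len(cluster)
    p = float(hypergeom.sf(overlap - 1, M, n, N))
    return EnrichmentResult(cluster=cluster_name, term=term_name, overlap=overlap,
                            universe=M, term_size=n, cluster_size=N, p=p)


def restricted_term_filter(term: set[str], focus_set: set[str],
                           universe: set[str], min_overlap: int = 2,
                           p_max: float = 0.05) -> bool:
    """Should a term enter the restricted-background enrichment analysis?

    True iff the term shares at least ``min_overlap`` genes with the focus
    set and the hypergeometric p of that intersection, against the full
    gene universe, is below ``p_max``.
    """
    term_u = term & universe
    focus_u = focus_set & universe
    overlap = len(term_u & focus_u)
    if overlap < min_overlap:
        return False
    p = float(hypergeom.sf(overlap - 1, len(universe), len(term_u), len(focus_u)))
    return p < p_max


def enrich_clusters(clusters: GeneClusterSet, gene_sets: dict[str, set[str]],
                    background: set[str], p_max: float = 0.05,
                    focus_set: set[str] | None = None) -> pd.DataFrame:
    """Enrichment table over all clusters and terms (nominal p < p_max kept).

    With ``focus_set`` given, runs the restricted variant: terms must pass
    ``restricted_term_filter`` against the full background before testing,
    and the test background becomes the focus set.
    """
    rows = []
    test_bg = background if focus_set is None else (focus_set & background)
    for cid, genes in clusters.clusters.items():
        cset = set(genes) & test_bg
        for name, term in gene_sets.items():
            if focus_set is not None and not restricted_term_filter(
                    term, focus_set, background):
                continue
            r = enrich(cset, term, test_bg, term_name=name, cluster_name=cid)
            if r.overlap > 0 and r.p < p_max:
                rows.append((cid, name, r.overlap, r.term_size, r.cluster_size,
                             r.universe, r.p))
    return pd.DataFrame(rows, columns=[
        "cluster", "term", "overlap", "term_size", "cluster_size", "universe", "p",
    ]).sort_values(["cluster", "p"]).reset_index(drop=True)
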