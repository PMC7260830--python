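"""Permutation significance, module-size selection, FDR and robustness.

The observed module objective is compared against re-optimized objectives
under random permutations of the phenotype across patients; the empirical
p-value uses the add-one correction p = (1 + #{permuted >= observed}) /
(1 + N), so it is never zero.  The module size k is chosen as the largest
k whose objective improved by more than 5% over k-1 with a non-increasing
permutation p, the condition holding for every smaller size; BH-FDR is
applied across the signature-contexts tested in one run; per-gene
robustness is the fraction of attribution reruns whose selected module
contains the gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .module_search import ModuleSolution, ObjectiveConfig, find_best_module, score_module


@dataclass
class PermutationResult:
    observed: float
    permuted: np.ndarray
    p: float


def permutation_test(matrix: pd.DataFrame, phen: pd.Series, network,
                     cfg: ObjectiveConfig, n_permutations: int = 100,
                     seed: int = 0,
                     observed: ModuleSolution | None = None) -> PermutationResult:
    """Empirical p of the optimal module objective under phenotype permutation.

    Each permutation shuffles the phenotype values across patients and
    re-runs the full module optimization.  ``observed`` may carry a
    previously computed solution to avoid re-solving the unpermuted
    instance.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if observed is None:
        observed = find_best_module(matrix, phen, network, cfg, tie_break=False)
    rng = np.random.default_rng(seed)
    vals = np.empty(n_permutations)
    base = phen.to_numpy(dtype=float)
    for i in range(n_permutations):
        perm = pd.Series(rng.permutation(base), index=phen.index)
        sol = find_best_module(matrix, perm, network, cfg, tie_break=False)
        vals[i] = sol.objective if sol.feasible else -np.inf
    p = (1.0 + np.sum(vals >= observed.objective)) / (1.0 + n_permutations)
    return PermutationResult(observed=observed.objective, permuted=vals, p=float(p))


def select_k(objectives: dict[int, float], p_values: dict[int, float],
             min_increase: float = 0.05) -> int:
    """Choose the module size from per-k objectives and permutation p-values.

    chosen k = max k such that for every k' with 2 <= k' <= k,
    objective(k') > (1 + min_increase) * objective(k'-1) and
    p(k') <= p(k'-1); k = 1 when no k >= 2 qualifies.
    """
    ks = sorted(objectives)
    if ks != sorted(p_values) or ks[0] != 1 or ks != list(range(1, ks[-1] + 1)):
        raise ValueError("need objectives and p-values for k = 1..k_max")
    if any(not np.isfinite(objectives[k]) for k in ks):
        raise ValueError("non-finite objective")
    chosen = 1
    for k in ks[1:]:
        if (objectives[k] > (1.0 + min_increase) * objectives[k - 1]
                and p_values[k] <= p_values[k - 1]):
            chosen = k
        else:
            break
    return chosen


def fdr_significance(p_values: dict[str, float], q_max: float = 0.1) -> pd.DataFrame:
    """BH adjustment across the tested signature-contexts.

    Returns a frame with raw p, adjusted q and a significance flag
    (q < q_max) per label.
    """
    labels = list(p_values)
    praw = np.array([p_values[l] for l in labels], dtype=float)
    q = multipletests(praw, method="fdr_bh")[1]
    return pd.DataFrame(
        {"p": praw, "q": q, "significant": q < q_max}, index=labels
    )


def robustness(reruns: list) -> pd.Series:
    """Per-gene fraction of attribution reruns selecting the gene.

    ``reruns`` is a list of gene collections (one selected module per
    attribution seed).
    """
    if not reruns:
        raise ValueError("no reruns given")
    genes = sorted({g for module in reruns for g in module})
    counts = {g: sum(g in set(m) for m in reruns) for g in genes}
    return pd.Series({g: counts[g] / len(reruns) for g in genes}, dtype=float)


def per_gene_association(module, matrix: pd.DataFrame, phen: pd.Series,
                         cfg: ObjectiveConfig, n_permutations: int = 100,
                         seed: int = 0) -> pd.Series:
    """Single-gene empirical association p for each gene of a module.

    For each gene g, compares score_module({g}) against its value under
    phenotype permutations (no re-optimization: the module is fixed at
    {g}), with the add-one correction.
    """
    rng = np.random.default_rng(seed)
    base = phen.to_numpy(dtype=float)
    perms = [pd.Series(rng.permutation(base), index=phen.index)
             for _ in range(n_permutations)]
    out = {}
    for g in module:
        obs = score_module([g], matrix, phen, cfg)
        null = np.array([score_module([g], matrix, pp, cfg) for pp in perms])
        out[g] = (1.0 + np.sum(null >= obs)) / (1.0 + n_permutations)
    return pd.Series(out, dtype=float)


def k_selection_scan(matrix: pd.DataFrame, phen: pd.Series, network,
                     k_max: int = 7, density_min: float = 0.5,
                     exclusivity_weight: float = 1.0,
                     n_permutations: int = 100, seed: int = 0,
                     min_increase: float = 0.05) -> tuple[int, pd.DataFrame, dict[int, ModuleSolution]]:
    """Run the search for k = 1..k_max and apply the selection rule.

    Returns (chosen k, per-k table with objective and permutation p,
    solutions by k).  Infeasible sizes truncate the scan.
    """
    objectives: dict[int, float] = {}
    pvals: dict[int, float] = {}
    sols: dict[int, ModuleSolution] = {}
    for k in range(1, k_max + 1):
        cfg = ObjectiveConfig(k=k, density_min=density_min,
                              exclusivity_weight=exclusivity_weight)
        sol = find_best_module(matrix, phen, network, cfg)
        if not sol.feasible:
            break
        res = permutation_test(matrix, phen, network, cfg,
                               n_permutations=n_permutations,
                               seed=seed + k, observed=sol)
        objectives[k] = sol.objective
        pvals[k] = res.p
        sols[k] = sol
    if not objectives:
        raise ValueError("no feasible module size")
    chosen = select_k(objectives, pvals, min_increase=min_increase)
    table = pd.DataFrame({
        "k": sorted(objectives),
        "objective": [objectives[k] for k in sorted(objectives)],
        "p": [pvals[k] for k in sorted(objectives)],
    }).set_index("k")
    return chosen, table, sols
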