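"""Self-validation experiments on generated data.

Each function builds synthetic inputs at stated conditions, runs the
corresponding stage of the pipeline, and returns a summary statistic:

* exact agreement between the MILP search and exhaustive enumeration on
  random instances;
* exact recovery of a planted alteration module across seeds;
* type-I calibration of the permutation test under a null generator;
* recovery (adjusted Rand index) of planted expression modules by the
  consensus clustering;
* accuracy of the EM signature attribution against generator truth.

These back both the test suite and the reproduction script; problem sizes
are chosen so the full battery runs in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from sklearn.metrics import adjusted_rand_score

from . import simulate as sim
from .expression import consensus_cluster, correlate
from .module_search import ObjectiveConfig, enumerate_oracle, find_best_module
from .significance import permutation_test
from .signatures import attribute_mutations, make_phenotype


def oracle_agreement(n_instances: int = 100, seed: int = 0,
                     max_genes: int = 15, max_patients: int = 30,
                     max_k: int = 4) -> dict:
    """Fraction of random instances where MILP and enumeration agree exactly.

    Instances draw gene count, patient count, module size k, a random
    interaction graph and a Bernoulli alteration matrix with Gaussian
    phenotype; agreement requires matching feasibility and, when feasible,
    identical objective (to 1e-8) and identical tie-broken gene sets.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        n = int(rng.integers(5, max_genes + 1))
        m = int(rng.integers(5, max_patients + 1))
        k = int(rng.integers(1, max_k + 1))
        genes = [f"G{i:02d}" for i in range(n)]
        G = nx.relabel_nodes(
            nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(2 ** 31 - 1))),
            dict(enumerate(genes)))
        M = pd.DataFrame((rng.random((n, m)) < 0.25).astype(int),
                         index=genes, columns=[f"P{j}" for j in range(m)])
        w = pd.Series(rng.normal(size=m), index=M.columns)
        cfg = ObjectiveConfig(k=k)
        a = find_best_module(M, w, G, cfg)
        b = enumerate_oracle(M, w, G, cfg)
        ok = a.feasible == b.feasible
        if ok and a.feasible:
            ok = abs(a.objective - b.objective) <= 1e-8 and a.genes == b.genes
        agree += ok
    return {"agreement": agree / n_instances, "n": n_instances}


def planted_recovery(n_seeds: int = 20, seed: int = 0, n_patients: int = 200,
                     n_genes: int = 50, module_size: int = 4,
                     module_effect: float = 2.0, exclusivity: float = 0.9,
                     background_rate: float = 0.02) -> dict:
    """Fraction of seeds where the search returns exactly the planted module."""
    hits = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        genes = sim.gene_names(n_genes)
        module = tuple(sorted(rng.choice(genes, module_size, replace=False)))
        cfg = sim.SimulationConfig(
            n_patients=n_patients, n_genes=n_genes, planted_module=module,
            module_effect=module_effect, exclusivity=exclusivity,
            background_alteration_rate=background_rate, seed=seed + s)
        net = sim.generate_network(n_genes, 0.05, module, seed=seed + s)
        M, phen, _ = sim.generate_alterations_and_phenotype(cfg, net)
        sol = find_best_module(M, phen, net,
                               ObjectiveConfig(k=module_size), tie_break=False)
        hits += sol.genes == module
    return {"recovery_rate": hits / n_seeds, "n": n_seeds}


def permutation_calibration(n_replicates: int = 50, seed: int = 0,
                            n_permutations: int = 99, n_patients: int = 40,
                            n_genes: int = 10, k: int = 2,
                            alpha: float = 0.05) -> dict:
    """Empirical P(p <= alpha) of the permutation test under the null.

    The generator plants a connected module but gives it zero phenotype
    effect, so the optimized objective is exchangeable with its permuted
    counterparts and p should be uniform.
    """
    low = 0
    ps = []
    for s in range(n_replicates):
        genes = sim.gene_names(n_genes)
        module = tuple(genes[:3])
        cfg = sim.SimulationConfig(
            n_patients=n_patients, n_genes=n_genes, planted_module=module,
            module_effect=0.0, background_alteration_rate=0.1,
            module_coverage=0.3, seed=seed + s)
        net = sim.generate_network(n_genes, 0.3, module, seed=seed + s)
        M, phen, _ = sim.generate_alterations_and_phenotype(cfg, net)
        res = permutation_test(M, phen, net, ObjectiveConfig(k=k),
                               n_permutations=n_permutations, seed=seed + s)
        ps.append(res.p)
        low += res.p <= alpha
    return {"p_low_rate": low / n_replicates, "n": n_replicates,
            "mean_p": float(np.mean(ps))}


def consensus_recovery(n_seeds: int = 10, seed: int = 0, n_patients: int = 120,
                       genes_per_module: int = 20, n_noise_genes: int = 60,
                       rho: float = 0.6) -> dict:
    """Mean ARI of consensus clustering against three planted modules."""
    aris = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        labels = ["1D", "2C", "5D"]
        patients = sim.patient_names(n_patients)
        expos = pd.DataFrame(rng.poisson(100, (n_patients, 3)),
                             index=patients, columns=labels)
        n_genes = 3 * genes_per_module + n_noise_genes
        genes = sim.gene_names(n_genes)
        module_map, truth = {}, {}
        for mi, col in enumerate(labels):
            for g in genes[mi * genes_per_module:(mi + 1) * genes_per_module]:
                module_map[g] = col
                truth[g] = mi
        cfg = sim.SimulationConfig(n_patients=n_patients, n_genes=n_genes,
                                   expr_module_rho=rho, seed=seed + s)
        expr = sim.generate_expression(cfg, expos, module_map=module_map)
        phens = [make_phenotype(expos, c) for c in labels]
        prof = correlate(expr, phens)
        module_genes = [g for g in prof.index if g in truth]
        _, clusters = consensus_cluster(prof.loc[module_genes], n_runs=100,
                                        k_range=(5, 20), final_k=3,
                                        seed=seed + s)
        aris.append(adjusted_rand_score(
            [truth[g] for g in module_genes],
            [clusters.assignments[g] for g in module_genes]))
    return {"mean_ari": float(np.mean(aris)), "min_ari": float(np.min(aris)),
            "n": n_seeds}


def em_recovery(seed: int = 0, n_mutations: int = 1000,
                mixture: tuple[float, float] = (0.7, 0.3)) -> dict:
    """EM attribution: weight error on a 70/30 mixture and accuracy at
    disjoint support."""
    from .contexts import CHANNELS

    rng = np.random.default_rng(seed)
    p1 = rng.dirichlet(np.full(96, 0.3))
    p2 = rng.dirichlet(np.full(96, 0.3))
    overlap_cat = pd.DataFrame({"A": p1, "B": p2}, index=list(CHANNELS))
    cfg = sim.SimulationConfig(
        n_patients=1, signature_catalog=overlap_cat,
        exposure_means={"A": mixture[0] * n_mutations,
                        "B": mixture[1] * n_mutations},
        seed=seed + 1)
    mut = sim.generate_mutation_catalog(cfg)
    _, weights = attribute_mutations(mut, overlap_cat, n_restarts=7, seed=seed)
    truth = mut["true_signature"].value_counts(normalize=True)
    weight_error = float(max(abs(weights.iloc[0]["A"] - truth["A"]),
                             abs(weights.iloc[0]["B"] - truth["B"])))

    q1 = np.zeros(96); q1[:48] = 1 / 48
    q2 = np.zeros(96); q2[48:] = 1 / 48
    disjoint = pd.DataFrame({"A": q1, "B": q2}, index=list(CHANNELS))
    cfg2 = sim.SimulationConfig(
        n_patients=3, signature_catalog=disjoint,
        exposure_means={"A": 200, "B": 150}, seed=seed + 2)
    mut2 = sim.generate_mutation_catalog(cfg2)
    att, _ = attribute_mutations(mut2, disjoint, n_restarts=5, seed=seed)
    accuracy = float((att["assigned_signature"] == att["true_signature"]).mean())
    return {"weight_error": weight_error, "disjoint_accuracy": accuracy,
            "n": int(len(mut))}
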