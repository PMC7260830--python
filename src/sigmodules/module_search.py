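"""Connected-subnetwork search for phenotype-associated alteration modules.

Given a binary gene x patient alteration matrix, a per-patient continuous
phenotype w (z-scored signature exposure) and an undirected gene interaction
network, find the connected gene set S of fixed size k, with induced edge
density at least ``density_min``, maximizing the mutual-exclusivity-aware
association objective

    score(S) = sum_{j : c_j >= 1} w_j  -  lambda * sum_j max(0, c_j - 1) * |w_j|

where c_j is the number of genes of S altered in patient j.  Covered
patients contribute their phenotype; redundant coverage (a patient hit by
more than one module gene) is penalized in proportion to the phenotype
magnitude, rewarding mutually exclusive alteration patterns.

The search is an exact mixed-integer linear program (HiGHS via
``scipy.optimize.milp``):

* binary x_g selects genes, with sum x = k;
* binary z_j marks covered patients (z_j <= c_j and k*z_j >= c_j);
* continuous e_j >= max(0, c_j - 1) carries the exclusivity penalty;
* continuous edge variables y_uv <= x_u, x_v enforce the density floor
  sum y >= density_min * C(k,2);
* connectivity is enforced by single-commodity flow: a selected root sends
  k-1 units of flow, every other selected gene consumes one, and flow is
  capped at (k-1) on arcs into selected genes only.  Density 0.5 alone does
  not imply connectivity for k >= 4, so both constraint families are needed.

``enumerate_oracle`` provides an independent exhaustive search over
connected size-k subsets for verification on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp


@dataclass
class ObjectiveConfig:
    """Module-search parameters.

    k: exact module size (1..7 in the study design).
    density_min: minimum induced-subgraph edge density (default 0.5).
    exclusivity_weight: lambda of the redundancy penalty (default 1.0).
    time_limit: solver wall-clock limit in seconds.
    """

    k: int = 3
    density_min: float = 0.5
    exclusivity_weight: float = 1.0
    time_limit: float = 600.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 <= self.density_min <= 1.0:
            raise ValueError("density_min must be in [0, 1]")
        if self.exclusivity_weight < 0:
            raise ValueError("exclusivity_weight must be >= 0")


@dataclass
class ModuleSolution:
    genes: tuple[str, ...]
    objective: float
    density: float
    connected: bool
    coverage: pd.Series            # per-patient count of altered module genes
    optimal: bool = True           # proven optimal by the solver
    feasible: bool = True

    def __iter__(self):
        return iter(self.genes)


INFEASIBLE = ModuleSolution(genes=(), objective=-np.inf, density=0.0,
                            connected=False, coverage=pd.Series(dtype=float),
                            optimal=True, feasible=False)


def load_network(edges: pd.DataFrame, threshold: float = 900.0) -> nx.Graph:
    """Build the thresholded interaction graph from a scored edge list.

    ``edges`` has columns (gene1, gene2, score); only edges with
    score >= threshold are kept, self-loops dropped.
    """
    g = nx.Graph()
    kept = edges[edges.iloc[:, 2].astype(float) >= threshold]
    for a, b, s in kept.itertuples(index=False):
        if a != b:
            g.add_edge(str(a), str(b), score=float(s))
    return g


def density(S, network: nx.Graph) -> float:
    """Induced edge density of gene set S; singletons have density 1."""
    S = list(S)
    if len(S) <= 1:
        return 1.0
    m = network.subgraph(S).number_of_edges()
    return m / comb(len(S), 2)


def score_module(S, matrix: pd.DataFrame, phen: pd.Series,
                 cfg: ObjectiveConfig | None = None) -> float:
    """Evaluate the association objective for gene set S.

    ``matrix`` is genes x patients (0/1); ``phen`` must be aligned to the
    matrix columns (same patients, any order).
    """
    lam = 1.0 if cfg is None else cfg.exclusivity_weight
    S = [g for g in S]
    if not S:
        return 0.0
    missing = set(S) - set(matrix.index)
    if missing:
        raise KeyError(f"genes not in alteration matrix: {sorted(missing)}")
    if set(phen.index) != set(matrix.columns):
        raise ValueError("phenotype patients do not match alteration matrix patients")
    w = phen.reindex(matrix.columns).to_numpy(dtype=float)
    c = matrix.loc[S].to_numpy(dtype=float).sum(axis=0)
    covered = c >= 1
    return float(w[covered].sum() - lam * np.sum(np.maximum(0.0, c - 1.0) * np.abs(w)))


def _coverage(S, matrix: pd.DataFrame) -> pd.Series:
    if not len(S):
        return pd.Series(0, index=matrix.columns, dtype=int)
    return matrix.loc[list(S)].sum(axis=0).astype(int)


def _solution(S, matrix, phen, network, cfg, optimal=True) -> ModuleSolution:
    S = tuple(sorted(S))
    return ModuleSolution(
        genes=S,
        objective=score_module(S, matrix, phen, cfg),
        density=density(S, network),
        connected=len(S) <= 1 or nx.is_connected(network.subgraph(S)),
        coverage=_coverage(S, matrix),
        optimal=optimal,
        feasible=True,
    )


def _candidate_genes(matrix: pd.DataFrame, network: nx.Graph) -> list[str]:
    return sorted(set(matrix.index) & set(network.nodes))


def find_best_module(matrix: pd.DataFrame, phen: pd.Series, network: nx.Graph,
                     cfg: ObjectiveConfig, *, tie_break: bool = True) -> ModuleSolution:
    """Exact MILP search for the best connected size-k module.

    Returns an infeasibility marker (``feasible=False``) when no connected,
    density-feasible set of size k exists.  With ``tie_break`` (default) the
    lexicographically smallest gene set among equal-objective optima is
    returned, by iterative variable fixing.
    """
    genes = _candidate_genes(matrix, network)
    if cfg.k > len(genes):
        return INFEASIBLE
    if cfg.k == 1:
        # no connectivity or density constraint binds: argmax over single genes
        scores = {g: score_module([g], matrix, phen, cfg) for g in genes}
        top = max(scores.values())
        best = min(g for g, s in scores.items() if s >= top - 1e-12)
        return _solution([best], matrix, phen, network, cfg)

    val, sol, proven = _solve_milp(matrix, phen, network, cfg, genes, forced={})
    if sol is None:
        return INFEASIBLE
    if tie_break and proven:
        sol = _lex_refine(matrix, phen, network, cfg, genes, val, sol)
    return _validate(sol, val, matrix, phen, network, cfg, optimal=proven)


def _validate(S, val, matrix, phen, network, cfg, optimal=True) -> ModuleSolution:
    out = _solution(S, matrix, phen, network, cfg, optimal=optimal)
    # re-validate independently of the solver
    assert len(out.genes) == cfg.k, "solver returned wrong module size"
    assert out.connected, "solver returned a disconnected module"
    assert out.density >= cfg.density_min - 1e-9, "solver violated the density floor"
    assert abs(out.objective - val) < 1e-6 * max(1.0, abs(val)), \
        "solver objective does not match independent recomputation"
    return out


def _lex_refine(matrix, phen, network, cfg, genes, best_val, sol) -> list[str]:
    """Find the lexicographically smallest optimum by iterative fixing.

    Genes are visited in sorted order; a gene already in the incumbent
    optimum needs no solve (the incumbent witnesses an optimum containing
    it, and the smallest such gene is always part of the lex-min optimum).
    """
    tol = 1e-9 * max(1.0, abs(best_val))
    forced: dict[str, int] = {}
    chosen: list[str] = []
    solset = set(sol)
    for g in genes:
        if len(chosen) == cfg.k:
            break
        if g in solset:
            forced[g] = 1
            chosen.append(g)
            continue
        trial = dict(forced)
        trial[g] = 1
        val, s2, proven = _solve_milp(matrix, phen, network, cfg, genes, forced=trial)
        if s2 is not None and proven and val >= best_val - tol:
            forced = trial
            chosen.append(g)
            sol, solset = s2, set(s2)
        else:
            forced[g] = 0
    return sol


def _solve_milp(matrix, phen, network, cfg, genes, forced):
    """Single MILP solve; returns (objective, gene list, proven-optimal)."""
    k = cfg.k
    lam = cfg.exclusivity_weight
    n = len(genes)
    gi = {g: i for i, g in enumerate(genes)}
    patients = list(matrix.columns)
    m = len(patients)
    w = phen.reindex(patients).to_numpy(dtype=float)
    A = matrix.loc[genes, patients].to_numpy(dtype=float)  # n x m

    edges = [(gi[u], gi[v]) for u, v in network.edges
             if u in gi and v in gi]
    edges = [(min(a, b), max(a, b)) for a, b in edges if a != b]
    edges = sorted(set(edges))
    ne = len(edges)
    # arcs for flow: both directions of each edge
    arcs = [(a, b) for a, b in edges] + [(b, a) for a, b in edges]
    na = len(arcs)

    # variable layout: x (n) | z (m) | e (m) | y (ne) | r (n) | f (na)
    ofs_x, ofs_z, ofs_e = 0, n, n + m
    ofs_y, ofs_r, ofs_f = n + 2 * m, n + 2 * m + ne, n + 2 * m + ne + n
    nv = ofs_f + na

    c = np.zeros(nv)
    c[ofs_z:ofs_z + m] = -w              # maximize -> minimize negative
    c[ofs_e:ofs_e + m] = lam * np.abs(w)

    lb = np.zeros(nv)
    ub = np.ones(nv)
    ub[ofs_e:ofs_e + m] = max(k - 1, 0)
    ub[ofs_f:ofs_f + na] = max(k - 1, 0)
    integrality = np.zeros(nv)
    integrality[ofs_x:ofs_x + n] = 1
    integrality[ofs_z:ofs_z + m] = 1
    integrality[ofs_r:ofs_r + n] = 1
    for g, v in forced.items():
        lb[ofs_x + gi[g]] = v
        ub[ofs_x + gi[g]] = v

    rows, cols, vals, cl, cu = [], [], [], [], []
    ncon = 0

    def add_row(entries, lo, hi):
        nonlocal ncon
        for col, val in entries:
            rows.append(ncon); cols.append(col); vals.append(val)
        cl.append(lo); cu.append(hi)
        ncon += 1

    # sum x = k
    add_row([(ofs_x + i, 1.0) for i in range(n)], k, k)
    # coverage links: c_j = sum_g A[g,j] x_g
    #   z_j <= c_j           ->  c_j - z_j >= 0
    #   k z_j >= c_j         ->  k z_j - c_j >= 0
    #   e_j >= c_j - 1       ->  e_j - c_j >= -1
    for j in range(m):
        hit = np.flatnonzero(A[:, j])
        ent = [(ofs_x + int(i), 1.0) for i in hit]
        if not len(hit):
            continue
        add_row(ent + [(ofs_z + j, -1.0)], 0, np.inf)
        add_row([(ofs_z + j, float(k))] + [(ofs_x + int(i), -1.0) for i in hit], 0, np.inf)
        add_row([(ofs_e + j, 1.0)] + [(ofs_x + int(i), -1.0) for i in hit], -1.0, np.inf)
    # patients hit by no candidate gene: z_j = 0 (fix via bounds)
    for j in range(m):
        if not A[:, j].any():
            ub[ofs_z + j] = 0
            ub[ofs_e + j] = 0
    # density: y_uv <= x_u, y_uv <= x_v; sum y >= density_min * C(k,2)
    need = cfg.density_min * comb(k, 2)
    for t, (a, b) in enumerate(edges):
        add_row([(ofs_y + t, 1.0), (ofs_x + a, -1.0)], -np.inf, 0)
        add_row([(ofs_y + t, 1.0), (ofs_x + b, -1.0)], -np.inf, 0)
    if ne:
        add_row([(ofs_y + t, 1.0) for t in range(ne)], need, np.inf)
    elif need > 0:
        return -np.inf, None, True
    # root: exactly one, and root is selected
    add_row([(ofs_r + i, 1.0) for i in range(n)], 1, 1)
    for i in range(n):
        add_row([(ofs_r + i, 1.0), (ofs_x + i, -1.0)], -np.inf, 0)
    # flow conservation: inflow - outflow = x_i - k * r_i
    in_arcs: list[list[int]] = [[] for _ in range(n)]
    out_arcs: list[list[int]] = [[] for _ in range(n)]
    for t, (a, b) in enumerate(arcs):
        out_arcs[a].append(t)
        in_arcs[b].append(t)
    for i in range(n):
        ent = [(ofs_f + t, 1.0) for t in in_arcs[i]]
        ent += [(ofs_f + t, -1.0) for t in out_arcs[i]]
        ent += [(ofs_x + i, -1.0), (ofs_r + i, float(k))]
        add_row(ent, 0, 0)
    # capacity: f_ab <= (k-1) * x_a and <= (k-1) * x_b
    for t, (a, b) in enumerate(arcs):
        add_row([(ofs_f + t, 1.0), (ofs_x + a, -(k - 1.0))], -np.inf, 0)
        add_row([(ofs_f + t, 1.0), (ofs_x + b, -(k - 1.0))], -np.inf, 0)

    Acon = sp.csr_matrix((vals, (rows, cols)), shape=(ncon, nv))
    res = milp(
        c=c,
        constraints=LinearConstraint(Acon, np.array(cl), np.array(cu)),
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options={"time_limit": cfg.time_limit, "mip_rel_gap": 0.0},
    )
    if res.x is None:  # infeasible or no incumbent within the time limit
        return -np.inf, None, res.status == 2
    x = res.x[ofs_x:ofs_x + n]
    S = [genes[i] for i in range(n) if x[i] > 0.5]
    return -res.fun, S, res.status == 0


def enumerate_oracle(matrix: pd.DataFrame, phen: pd.Series, network: nx.Graph,
                     cfg: ObjectiveConfig, max_subsets: int = 10 ** 6) -> ModuleSolution:
    """Exhaustive search over connected, density-feasible size-k gene sets.

    Independent verification oracle: grows connected subsets by neighbour
    expansion, checks the density floor, and evaluates ``score_module`` for
    each.  Ties break to the lexicographically smallest set.  Raises if the
    number of enumerated subsets exceeds ``max_subsets``.
    """
    genes = _candidate_genes(matrix, network)
    G = network.subgraph(genes)
    k = cfg.k
    if k > len(genes):
        return INFEASIBLE
    if k == 1:
        candidates = ([g] for g in genes)
    else:
        candidates = _connected_subsets(G, k, max_subsets)
    best: tuple[float, tuple[str, ...]] | None = None
    for S in candidates:
        if density(S, G) < cfg.density_min - 1e-12:
            continue
        val = score_module(S, matrix, phen, cfg)
        key = (val, tuple(sorted(S)))
        if best is None or val > best[0] + 1e-12 or (
            abs(val - best[0]) <= 1e-12 and key[1] < best[1]
        ):
            best = (val, tuple(sorted(S)))
    if best is None:
        return INFEASIBLE
    return _solution(best[1], matrix, phen, network, cfg)


def _connected_subsets(G: nx.Graph, k: int, max_subsets: int):
    """Yield every connected k-subset of G exactly once.

    Standard rooted enumeration: for each start node v (in sorted order),
    grow subsets containing v using only neighbours, never adding a node
    smaller than v, so each subset is produced from its smallest member.
    """
    nodes = sorted(G.nodes)
    count = 0
    for v in nodes:
        init = sorted(n for n in G[v] if n > v)
        stack = [(frozenset([v]), init, frozenset(init) | {v})]
        while stack:
            S, frontier, seen = stack.pop()
            if len(S) == k:
                count += 1
                if count > max_subsets:
                    raise RuntimeError(f"more than {max_subsets} connected subsets")
                yield sorted(S)
                continue
            for i, u in enumerate(frontier):
                new = sorted(x for x in G[u] if x > v and x not in seen)
                stack.append((S | {u}, frontier[i + 1:] + new, seen | frozenset(new)))
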