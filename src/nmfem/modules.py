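"""Seeded detection of differentially expressed modules on a PPI network.

Each gene (vertex) is weighted by the Welch t-statistic of its expression
change between two sample groups.  Starting from a seed gene, a module is
grown greedily: at each step the boundary vertex that most increases the
size-normalized module score

    s(M) = (sum_{i in M} |t_i|) / sqrt(|M|)

is added, stopping when no addition strictly increases the score or the
module reaches ``max_size``.  Module significance comes from a Monte Carlo
null: the t-statistics are permuted across all vertices and the module is
re-grown from the same seed, giving the add-one estimator

    p = (1 + #{null scores >= observed}) / (n_perm + 1).
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

__all__ = [
    "node_statistics",
    "ModuleResult",
    "seeded_module_search",
    "module_score",
    "module_pvalue",
    "detect_modules",
]


def node_statistics(m: pd.DataFrame, labels) -> pd.Series:
    """Per-gene Welch t-statistics on log2(x+1), second group minus first.

    ``labels`` must define exactly two groups (ordered by sorted label
    value), each with at least 2 samples.  A positive t means higher
    expression in the second group.  Genes with zero variance in both groups
    get t = 0.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != m.shape[1]:
        raise ValueError("labels length must equal the number of samples")
    groups = sorted(pd.unique(labels).tolist(), key=str)
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(groups)}")
    masks = [labels == g for g in groups]
    if any(mask.sum() < 2 for mask in masks):
        raise ValueError("each group needs at least 2 samples for a t-statistic")
    log = np.log2(m.to_numpy(dtype=float) + 1.0)
    x1 = log[:, masks[0]]
    x2 = log[:, masks[1]]
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t = ttest_ind(x2, x1, axis=1, equal_var=False).statistic
    return pd.Series(np.nan_to_num(t, nan=0.0), index=m.index, name="t")


def module_score(abs_t_sum: float, size: int) -> float:
    """s(M) = (sum of |t| over members) / sqrt(|M|)."""
    return abs_t_sum / np.sqrt(size)


@dataclass
class ModuleResult:
    """A connected module grown around one seed gene."""

    seed_gene: str
    members: list[str]
    score: float
    p_value: float | None = None
    hub: str | None = None
    t_stats: dict = field(default_factory=dict)


def _grow(adj: dict, weights: dict, seed_gene: str, max_size: int) -> tuple[list, float]:
    members = {seed_gene}
    total = abs(weights.get(seed_gene, 0.0))
    score = module_score(total, 1)
    boundary = set(adj[seed_gene]) - members
    while len(members) < max_size and boundary:
        # strict improvement required; ties resolved toward the smaller gene id
        best, best_score = None, score
        for v in sorted(boundary):
            cand = module_score(total + abs(weights.get(v, 0.0)), len(members) + 1)
            if cand > best_score:
                best, best_score = v, cand
        if best is None:
            break
        members.add(best)
        total += abs(weights.get(best, 0.0))
        score = best_score
        boundary |= set(adj[best])
        boundary -= members
    return sorted(members), score


def _check_graph(g: nx.Graph):
    if g.number_of_nodes() == 0:
        raise ValueError("empty interaction network")
    if any(u == v for u, v in g.edges):
        raise ValueError("interaction network must have no self-loops")


def seeded_module_search(g: nx.Graph, stats, seed_gene: str,
                         max_size: int = 50) -> ModuleResult:
    """Greedy seed-anchored module growth maximizing s(M); no p-value attached.

    ``stats`` maps gene id -> t-statistic; vertices without a statistic get
    weight 0.  The returned module is connected by construction and contains
    the seed.
    """
    _check_graph(g)
    if seed_gene not in g:
        near = difflib.get_close_matches(str(seed_gene), [str(n) for n in g.nodes], n=3)
        raise ValueError(f"seed gene {seed_gene!r} not in the network"
                         + (f"; nearest matches: {near}" if near else ""))
    weights = dict(stats.items() if hasattr(stats, "items") else stats)
    adj = {n: list(g.neighbors(n)) for n in g.nodes}
    members, score = _grow(adj, weights, seed_gene, max_size)
    member_set = set(members)
    sub_deg = {v: sum(1 for w in adj[v] if w in member_set) for v in members}
    # hub tie-break: highest within-module degree, then gene id
    hub = sorted(members, key=lambda v: (-sub_deg[v], v))[0]
    return ModuleResult(seed_gene=seed_gene, members=members, score=score, hub=hub,
                        t_stats={v: weights.get(v, 0.0) for v in members})


def module_pvalue(g: nx.Graph, stats, module: ModuleResult,
                  n_perm: int = 1000, seed: int = 0, max_size: int = 50) -> float:
    """Monte Carlo p-value: permute t across vertices, re-grow from the seed.

    Uses the add-one estimator, so p >= 1/(n_perm+1) always.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable Monte Carlo p-value")
    _check_graph(g)
    weights = dict(stats.items() if hasattr(stats, "items") else stats)
    nodes = sorted(g.nodes)
    values = np.array([weights.get(n, 0.0) for n in nodes], dtype=float)
    adj = {n: list(g.neighbors(n)) for n in g.nodes}
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = values[rng.permutation(len(nodes))]
        null_weights = dict(zip(nodes, perm))
        _, null_score = _grow(adj, null_weights, module.seed_gene, max_size)
        if null_score >= module.score:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


def detect_modules(g: nx.Graph, stats, seed_genes, n_top: int = 5,
                   n_perm: int = 1000, seed: int = 0, max_size: int = 50,
                   overlap_threshold: float = 0.5) -> list[ModuleResult]:
    """Grow one module per seed gene, score by Monte Carlo p, return the top ``n_top``.

    Seed genes absent from the network are skipped (an error is raised only
    if none is present).  Modules sharing more than ``overlap_threshold`` of
    the smaller module's members are deduplicated, keeping the lower p-value
    (ties: higher score, then seed id).  Results are sorted by ascending
    p-value, ties by descending score, and each module reports its hub (the
    member with the highest within-module degree).
    """
    _check_graph(g)
    seeds_present = [s for s in seed_genes if s in g]
    if not seeds_present:
        raise ValueError("no seed gene is present in the interaction network")
    rng = np.random.default_rng(seed)
    perm_seeds = rng.integers(0, 2**31, size=len(seeds_present))

    candidates = []
    for sg, ps in zip(seeds_present, perm_seeds):
        mod = seeded_module_search(g, stats, sg, max_size=max_size)
        mod.p_value = module_pvalue(g, stats, mod, n_perm=n_perm, seed=int(ps),
                                    max_size=max_size)
        candidates.append(mod)

    candidates.sort(key=lambda mod: (mod.p_value, -mod.score, mod.seed_gene))
    kept: list[ModuleResult] = []
    for mod in candidates:
        mem = set(mod.members)
        dup = any(
            len(mem & set(other.members)) > overlap_threshold * min(len(mem), len(other.members))
            for other in kept)
        if not dup:
            kept.append(mod)
    return kept[:n_top]
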