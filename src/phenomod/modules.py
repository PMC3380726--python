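"""Functional-module extraction: connected components, density, and the
Monte Carlo density null.

A retained bicluster's COG-pair set need not be connected, so it is split
into connected components; each component S = (V, E) is a candidate module
with density beta(S) = 2|E| / (|V| (|V| - 1)).  Significance is assessed
empirically: draw W random COG subsets of size |V| from the background
universe M, measure the density each induces in the background graph, and
report p = R / W where R counts draws at least as dense as the observed
module (ties included).  Modules with p <= alpha are the reported
phenotype-biased functional modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from math import comb

import networkx as nx
import numpy as np

from .io import CogPair, canonical_pair

logger = logging.getLogger(__name__)

SUBSET_BY_NODES = "nodes"
SUBSET_BY_EDGES = "edges"

# densities are exact multiples of 2/(k(k-1)); the epsilon only guards float
# representation of those rationals in the >= tie rule
_TIE_EPS = 1e-12


@dataclass(frozen=True)
class BackgroundGraph:
    """The null universe: all eligible COGs M and the background edge set."""

    cogs: frozenset[str]
    edges: frozenset[CogPair]

    def __post_init__(self) -> None:
        loose = {n for e in self.edges for n in e} - self.cogs
        if loose:
            raise ValueError(f"background edges touch COGs outside M: {sorted(loose)[:5]}")


@dataclass
class FunctionalModule:
    """One connected COG subgraph with its statistics and provenance."""

    cogs: frozenset[str]
    edges: frozenset[CogPair]
    density: float
    bias_p: float | None = None
    mc_p: float | None = None
    source_bicluster_ids: frozenset[str] = frozenset()
    organisms: frozenset[str] = frozenset()

    def sort_key(self):
        return (-len(self.cogs), -len(self.edges), sorted(self.cogs))


def density(nodes, edges) -> float:
    """beta(S) = 2|E| / (|V| (|V| - 1)); undefined below two nodes."""
    n = len(nodes)
    if n < 2:
        raise ValueError(f"density undefined for |V| = {n} < 2")
    return 2.0 * len(edges) / (n * (n - 1))


def connected_components(cog_pairs) -> list[tuple[frozenset[str], frozenset[CogPair]]]:
    """Partition a COG edge set into connected components.

    Returns (node set, edge set) per component, ordered by descending node
    count then lexicographically smallest node.  Empty input -> empty list.
    """
    if not cog_pairs:
        return []
    G = nx.Graph()
    G.add_edges_from(cog_pairs)
    comps = []
    for nodes in nx.connected_components(G):
        edges = frozenset(
            canonical_pair(u, v) for u, v in G.subgraph(nodes).edges()
        )
        comps.append((frozenset(nodes), edges))
    comps.sort(key=lambda c: (-len(c[0]), min(c[0])))
    return comps


def _adjacency(bg: BackgroundGraph) -> tuple[list[str], np.ndarray]:
    nodes = sorted(bg.cogs)
    idx = {n: i for i, n in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)), dtype=bool)
    for u, v in bg.edges:
        A[idx[u], idx[v]] = True
        A[idx[v], idx[u]] = True
    return nodes, A


def _subset_size(module: FunctionalModule, rule: str) -> int:
    if rule == SUBSET_BY_NODES:
        return len(module.cogs)
    if rule == SUBSET_BY_EDGES:
        return len(module.edges)
    raise ValueError(f"subset size rule must be 'nodes' or 'edges', got {rule!r}")


def monte_carlo_p(
    module: FunctionalModule,
    bg: BackgroundGraph,
    W: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    subset_size_rule: str = SUBSET_BY_NODES,
) -> float:
    """Empirical p-value R/W of the module's density under the random-subset
    null.

    Draws W uniform COG subsets (without replacement within a draw) of the
    module's size from ``bg.cogs``, takes the density of the subgraph each
    induces in ``bg`` (a subset with < 2 nodes or no induced edges scores
    0), and counts draws with density >= the observed density (ties count).
    Fully reproducible given ``seed``; p = 0 is possible at finite W and is
    reported as-is (rendered "< 1/W" in output files).
    """
    if W < 1:
        raise ValueError("W must be >= 1")
    k = _subset_size(module, subset_size_rule)
    if k > len(bg.cogs):
        raise ValueError(
            f"subset size {k} exceeds background universe |M| = {len(bg.cogs)}"
        )
    observed = module.density
    _, A = _adjacency(bg)
    m = len(bg.cogs)
    rng = np.random.default_rng(seed)
    # uniform k-subsets: first k entries of a uniform random permutation
    draws = np.argsort(rng.random((W, m)), axis=1)[:, :k]
    if k < 2:
        sampled = np.zeros(W)
    else:
        counts = np.zeros(W, dtype=np.int64)
        for a in range(k):
            for b in range(a + 1, k):
                counts += A[draws[:, a], draws[:, b]]
        sampled = 2.0 * counts / (k * (k - 1))
    R = int(np.count_nonzero(sampled >= observed - _TIE_EPS))
    return R / W


def exhaustive_p(
    module: FunctionalModule,
    bg: BackgroundGraph,
    subset_size_rule: str = SUBSET_BY_NODES,
) -> float:
    """Exact version of the random-subset null: enumerate all C(|M|, k)
    subsets instead of sampling.  Only feasible for small universes; used as
    the calibration reference for :func:`monte_carlo_p`."""
    k = _subset_size(module, subset_size_rule)
    m = len(bg.cogs)
    if k > m:
        raise ValueError(f"subset size {k} exceeds |M| = {m}")
    if comb(m, k) > 2_000_000:
        raise ValueError(f"C({m}, {k}) too large for exhaustive enumeration")
    adj: dict[str, set[str]] = {c: set() for c in bg.cogs}
    for u, v in bg.edges:
        adj[u].add(v)
        adj[v].add(u)
    observed = module.density
    hits = 0
    total = 0
    for subset in combinations(sorted(bg.cogs), k):
        total += 1
        if k < 2:
            d = 0.0
        else:
            e = sum(1 for a, b in combinations(subset, 2) if b in adj[a])
            d = 2.0 * e / (k * (k - 1))
        if d >= observed - _TIE_EPS:
            hits += 1
    return hits / total


def merge_duplicate_modules(modules: list[FunctionalModule]) -> list[FunctionalModule]:
    """Collapse modules with identical (cogs, edges) into one record,
    merging provenance; the smallest bias p-value among sources is kept."""
    merged: dict[tuple, FunctionalModule] = {}
    for mod in modules:
        key = (mod.cogs, mod.edges)
        prev = merged.get(key)
        if prev is None:
            merged[key] = replace(mod)
        else:
            bias_ps = [p for p in (prev.bias_p, mod.bias_p) if p is not None]
            merged[key] = replace(
                prev,
                source_bicluster_ids=prev.source_bicluster_ids | mod.source_bicluster_ids,
                organisms=prev.organisms | mod.organisms,
                bias_p=min(bias_ps) if bias_ps else None,
                mc_p=min(p for p in (prev.mc_p, mod.mc_p) if p is not None)
                if (prev.mc_p is not None or mod.mc_p is not None)
                else None,
            )
    out = list(merged.values())
    out.sort(key=FunctionalModule.sort_key)
    return out


def filter_significant(
    modules: list[FunctionalModule], alpha: float = 0.05
) -> list[FunctionalModule]:
    """Keep density-significant modules (mc_p <= alpha), deduplicated."""
    for mod in modules:
        if mod.mc_p is None:
            raise ValueError("filter_significant requires mc_p on every module")
    kept = merge_duplicate_modules([m for m in modules if m.mc_p <= alpha])
    logger.info(
        "filter_significant: %d/%d modules significant at alpha=%g",
        len(kept), len(modules), alpha,
    )
    return kept
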