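"""Seeded subnetwork extraction from a globally ranked MI edge list.

The curation runs in three steps: (1) keep, in rank order, the edges that
touch at least one seed gene and truncate to the top k; (2) collect the
union of endpoint genes (seeds plus first neighbors); (3) go back to the
full ranked list and take the top k edges whose *both* endpoints lie in
that gene list.  Step 3 may therefore include neighbor-neighbor edges that
step 1 never saw, and may drop seed genes whose interactions are weak.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "select_seed_edges",
    "neighbor_gene_set",
    "induced_top_k",
    "connected_components",
    "extract_network",
]


def select_seed_edges(ranked: pd.DataFrame, seed_genes: Iterable[str], k: int) -> pd.DataFrame:
    """First k ranked edges with at least one endpoint in the seed list."""
    seeds = set(seed_genes)
    if not seeds:
        raise ValueError("seed gene set is empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    hit = ranked["gene_a"].isin(seeds) | ranked["gene_b"].isin(seeds)
    if not hit.any():
        endpoints = set(ranked["gene_a"]).union(ranked["gene_b"])
        sample = sorted(seeds - endpoints)[:10]
        raise ValueError(
            f"no edge touches any seed gene; unmatched seed symbols include {sample}"
        )
    out = ranked.loc[hit].head(k).reset_index(drop=True)
    if len(out) < k:
        warnings.warn(f"only {len(out)} seed-touching edges available (k={k})")
    return out


def neighbor_gene_set(edges: pd.DataFrame) -> list[str]:
    """Deduplicated, lexicographically sorted union of edge endpoints."""
    if edges.empty:
        raise ValueError("empty edge list")
    return sorted(set(edges["gene_a"]).union(edges["gene_b"]))


def induced_top_k(ranked: pd.DataFrame, genes: Iterable[str], k: int) -> nx.Graph:
    """Top k ranked edges with both endpoints in ``genes``, as a network.

    Nodes are only the genes incident to a retained edge; node attribute
    ``seed`` / ``status`` annotation happens downstream.
    """
    allowed = set(genes)
    if not allowed:
        raise ValueError("gene list is empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    both = ranked["gene_a"].isin(allowed) & ranked["gene_b"].isin(allowed)
    kept = ranked.loc[both].head(k)
    if len(kept) < k:
        warnings.warn(f"only {len(kept)} qualifying edges available (k={k})")
    g = nx.Graph()
    for a, b, w in kept[["gene_a", "gene_b", "mi"]].itertuples(index=False):
        g.add_edge(a, b, weight=float(w))
    return g


def connected_components(net: nx.Graph) -> list[list[str]]:
    """Components as sorted node lists, largest first, ties by smallest member."""
    comps = [sorted(c) for c in nx.connected_components(net)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def extract_network(
    ranked: pd.DataFrame,
    seed_genes: Iterable[str],
    k_seed: int = 10000,
    k_final: int | None = None,
) -> nx.Graph:
    """Run the full three-step curation; seed membership marked on nodes.

    Seed symbols that never appear among the ranked-edge endpoints are
    dropped with a logged count (annotation lists always exceed any one
    expression platform).
    """
    seeds = set(seed_genes)
    endpoints = set(ranked["gene_a"]).union(ranked["gene_b"])
    present = seeds & endpoints
    if len(present) < len(seeds):
        log.info("dropping %d seed symbols absent from the matrix", len(seeds) - len(present))
    step1 = select_seed_edges(ranked, present, k_seed)
    gene_list = neighbor_gene_set(step1)
    net = induced_top_k(ranked, gene_list, k_final if k_final is not None else k_seed)
    for v in net.nodes:
        net.nodes[v]["seed"] = v in present
    return net
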