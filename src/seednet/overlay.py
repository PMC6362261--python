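"""Differential-expression overlay and inter-module flow summaries.

Node DE status is mapped onto the network, and edges are classified the way
the module maps are drawn: inter-module edges joining two overexpressed
genes are red, two underexpressed genes blue, and everything else —
intra-module edges, mixed pairs and unchanged pairs — gray.  Inter-module
"flow" is summarized per module pair both as the number of links and as the
summed MI weight.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from .community import ModuleTree

log = logging.getLogger(__name__)

__all__ = ["annotate_nodes", "classify_edges", "module_flow"]


def annotate_nodes(net: nx.Graph, de: pd.DataFrame) -> nx.Graph:
    """Attach DE ``status`` to every node; genes absent from the DE table
    default to ``nochange`` with a logged count."""
    status = dict(zip(de["gene"], de["status"]))
    defaulted = 0
    for v in net.nodes:
        s = status.get(v)
        if s is None:
            s = "nochange"
            defaulted += 1
        elif s not in ("over", "under", "nochange"):
            raise ValueError(f"unknown DE status {s!r} for gene {v!r}")
        net.nodes[v]["status"] = s
    if defaulted:
        log.info("%d network genes missing from DE table; defaulted to nochange", defaulted)
    net.graph["de_defaulted"] = defaulted
    return net


def classify_edges(net: nx.Graph, tree: ModuleTree, level: int = 1) -> pd.DataFrame:
    """Color every edge by scope and endpoint DE status.

    Returns a DataFrame (gene_a, gene_b, mi, scope, color): red for
    inter-module over-over pairs, blue for inter-module under-under pairs,
    gray otherwise.
    """
    paths = tree.leaf_paths()
    missing = [v for v in net.nodes if v not in paths]
    if missing:
        raise KeyError(f"module tree does not cover nodes: {missing[:5]}")
    rows = []
    for u, v, data in net.edges(data=True):
        a, b = sorted((u, v))
        su = net.nodes[a].get("status", "nochange")
        sv = net.nodes[b].get("status", "nochange")
        inter = paths[a][:level] != paths[b][:level]
        if inter and su == sv == "over":
            color = "red"
        elif inter and su == sv == "under":
            color = "blue"
        else:
            color = "gray"
        rows.append((a, b, float(data.get("weight", 1.0)), "inter" if inter else "intra", color))
    out = pd.DataFrame(rows, columns=["gene_a", "gene_b", "mi", "scope", "color"])
    return out.sort_values(["gene_a", "gene_b"], kind="stable").reset_index(drop=True)


def module_flow(
    net: nx.Graph, tree: ModuleTree, level: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric per-module-pair edge counts and summed MI weights.

    The diagonal holds intra-module totals; off-diagonal entries count the
    links between genes of different modules, the quantity the inter-module
    flow is proportional to.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    paths = tree.leaf_paths()
    if level > max((len(p) for p in paths.values()), default=0):
        raise ValueError(f"tree has no level {level}")
    mods = sorted({p[:level] for p in paths.values()})
    names = [":".join(str(x) for x in m) for m in mods]
    idx = {m: i for i, m in enumerate(mods)}
    counts = pd.DataFrame(0, index=names, columns=names, dtype=int)
    weights = pd.DataFrame(0.0, index=names, columns=names)
    for u, v, data in net.edges(data=True):
        try:
            mu, mv = paths[u][:level], paths[v][:level]
        except KeyError as exc:
            raise KeyError(f"module tree does not cover node {exc}") from exc
        i, j = sorted((idx[mu], idx[mv]))
        w = float(data.get("weight", 1.0))
        counts.iat[i, j] += 1
        weights.iat[i, j] += w
        if i != j:
            counts.iat[j, i] += 1
            weights.iat[j, i] += w
    return counts, weights
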