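"""Hierarchical map-equation module detection on weighted undirected networks.

The map equation scores a partition M of a network by the expected per-step
description length of an unconstrained random walk encoded with a two-level
(or hierarchical) codebook:

    L(M) = q * H(Q) + sum_i p_i_circ * H(P_i)

where node visit rates are the stationary distribution of the undirected
walk, p_alpha = strength(alpha) / 2W; module exit rates are
q_i = cut(i) / 2W; q = sum_i q_i; and p_i_circ = q_i + sum_{alpha in i}
p_alpha.  The hierarchical variant replaces the single index codebook with a
recursive stack of them, one per internal module.  Minimizing L over
partitions (and trees) reveals community structure.

The search is a seeded, multi-trial Louvain-style two-phase optimization
(local node moves followed by module aggregation), applied recursively
inside each module while the hierarchical codelength keeps dropping.
Module labels use PageRank purely as a naming heuristic; the clustering
flow model itself has no teleportation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FlowNetwork",
    "ModuleNode",
    "ModuleTree",
    "visit_rates",
    "codelength",
    "hierarchical_codelength",
    "detect_modules",
    "pagerank",
    "label_modules",
    "hierarchy_summary",
]

_EPS = 1e-10


def _plogp(x: float) -> float:
    return x * math.log2(x) if x > 0 else 0.0


# ---------------------------------------------------------------------------
# flow model


@dataclass
class FlowNetwork:
    """Node visit rates and adjacency of a weighted undirected network."""

    nodes: list[str]
    p: np.ndarray  # visit rates, sum to 1
    neighbors: list[dict[int, float]]  # symmetric, no self entries
    total_weight: float  # W = sum of edge weights

    def __post_init__(self) -> None:
        if abs(float(self.p.sum()) - 1.0) > 1e-12:
            raise ValueError("visit rates must sum to 1")
        self.index = {v: i for i, v in enumerate(self.nodes)}

    @property
    def two_w(self) -> float:
        return 2.0 * self.total_weight


def visit_rates(net: nx.Graph) -> FlowNetwork:
    """Strength-proportional stationary visit rates, p = strength / 2W."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = sorted(net.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    neighbors: list[dict[int, float]] = [dict() for _ in nodes]
    w_total = 0.0
    for u, v, data in net.edges(data=True):
        if u == v:
            continue
        w = float(data.get("weight", 1.0))
        if w < 0:
            raise ValueError(f"negative edge weight on ({u}, {v})")
        neighbors[index[u]][index[v]] = neighbors[index[u]].get(index[v], 0.0) + w
        neighbors[index[v]][index[u]] = neighbors[index[v]].get(index[u], 0.0) + w
        w_total += w
    if w_total <= 0:
        raise ValueError("network has zero total edge weight")
    strength = np.array([sum(nb.values()) for nb in neighbors])
    p = strength / (2.0 * w_total)
    # isolated declared nodes carry zero flow; they stay representable
    return FlowNetwork(nodes, p, neighbors, w_total)


def codelength(flow: FlowNetwork, partition: dict[str, object]) -> float:
    """Two-level map-equation codelength of a partition, in bits per step."""
    missing = [v for v in flow.nodes if v not in partition]
    if missing:
        raise KeyError(f"nodes missing from partition: {missing[:5]}")
    modules: dict[object, list[int]] = {}
    for v, m in partition.items():
        if v not in flow.index:
            raise KeyError(f"unknown node in partition: {v!r}")
        modules.setdefault(m, []).append(flow.index[v])
    two_w = flow.two_w
    q_total = 0.0
    L = 0.0
    q_terms = 0.0
    for members in modules.values():
        inside = set(members)
        cut = 0.0
        s_p = 0.0
        for i in members:
            s_p += flow.p[i]
            for j, w in flow.neighbors[i].items():
                if j not in inside:
                    cut += w
        q_i = cut / two_w
        q_total += q_i
        q_terms += _plogp(q_i)
        L += _plogp(q_i + s_p)
    L += _plogp(q_total) - 2.0 * q_terms
    L -= sum(_plogp(p) for p in flow.p)
    return L


# ---------------------------------------------------------------------------
# module trees


@dataclass
class ModuleNode:
    """Internal node of a module tree: either submodules or member genes."""

    children: list["ModuleNode"] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    label: str | None = None

    @property
    def is_leaf_module(self) -> bool:
        return not self.children

    def member_genes(self) -> list[str]:
        if self.is_leaf_module:
            return list(self.genes)
        out: list[str] = []
        for c in self.children:
            out.extend(c.member_genes())
        return out

    @property
    def size(self) -> int:
        return len(self.genes) if self.is_leaf_module else sum(c.size for c in self.children)


@dataclass
class ModuleTree:
    """Rooted hierarchy of modules whose leaves are genes."""

    root: ModuleNode
    codelength_bits: float | None = None

    def leaf_paths(self) -> dict[str, tuple[int, ...]]:
        """Module path (1-based indices) of each gene, excluding leaf position."""
        paths: dict[str, tuple[int, ...]] = {}

        def walk(node: ModuleNode, prefix: tuple[int, ...]) -> None:
            if node.is_leaf_module:
                for g in node.genes:
                    paths[g] = prefix
            else:
                for i, c in enumerate(node.children, 1):
                    walk(c, prefix + (i,))

        walk(self.root, ())
        return paths

    def genes(self) -> list[str]:
        return self.root.member_genes()

    def modules_at_level(self, level: int) -> list[tuple[tuple[int, ...], ModuleNode]]:
        """Internal module nodes whose path length equals ``level``."""
        out: list[tuple[tuple[int, ...], ModuleNode]] = []

        def walk(node: ModuleNode, prefix: tuple[int, ...]) -> None:
            for i, c in enumerate(node.children, 1):
                path = prefix + (i,)
                if len(path) == level:
                    out.append((path, c))
                elif len(path) < level:
                    walk(c, path)

        walk(self.root, ())
        return out

    @property
    def depth(self) -> int:
        """Deepest module level (1 = flat partition)."""

        def d(node: ModuleNode) -> int:
            if node.is_leaf_module:
                return 0
            return 1 + max(d(c) for c in node.children)

        return d(self.root)

    def top_assignment(self) -> dict[str, int]:
        return {g: path[0] for g, path in self.leaf_paths().items()}

    def assignment_frame(self) -> pd.DataFrame:
        """Per-gene module membership table (gene, level1, level2, label)."""
        rows = []
        top_labels = {i: c.label for i, c in enumerate(self.root.children, 1)}
        for g, path in sorted(self.leaf_paths().items()):
            lvl1 = path[0]
            lvl2 = path[1] if len(path) > 1 else ""
            rows.append((g, lvl1, lvl2, top_labels.get(lvl1) or str(lvl1)))
        return pd.DataFrame(rows, columns=["gene", "level1", "level2", "label"])

    def to_tree_lines(self, flows: dict[str, float] | None = None) -> list[str]:
        """Infomap-style `.tree` lines: ``1:2:7 0.0034 "GENE"``."""
        lines: list[str] = []

        def walk(node: ModuleNode, prefix: tuple[int, ...]) -> None:
            if node.is_leaf_module:
                for i, g in enumerate(sorted(node.genes), 1):
                    path = ":".join(str(x) for x in prefix + (i,))
                    f = (flows or {}).get(g, 0.0)
                    lines.append(f'{path} {f:.6g} "{g}"')
            else:
                for i, c in enumerate(node.children, 1):
                    walk(c, prefix + (i,))

        walk(self.root, ())
        return lines


def hierarchical_codelength(flow: FlowNetwork, tree: ModuleTree) -> float:
    """Multilevel map-equation codelength of a module tree, in bits.

    Reduces to the two-level formula for depth-2 trees and to the node-visit
    entropy H(p) for a single all-in-one module.
    """
    tree_genes = set(tree.genes())
    if tree_genes != set(flow.nodes):
        raise ValueError("tree leaves must coincide with network nodes")
    two_w = flow.two_w

    def exit_rate(members: set[int]) -> float:
        cut = 0.0
        for i in members:
            for j, w in flow.neighbors[i].items():
                if j not in members:
                    cut += w
        return cut / two_w

    def walk(node: ModuleNode, is_root: bool) -> tuple[float, float, set[int]]:
        """Returns (codelength contribution of subtree, exit rate, members)."""
        if node.is_leaf_module:
            members = {flow.index[g] for g in node.genes}
            q = 0.0 if is_root else exit_rate(members)
            rate = q + sum(flow.p[i] for i in members)
            term = _plogp(rate) - _plogp(q) - sum(_plogp(flow.p[i]) for i in members)
            return term, q, members
        total = 0.0
        child_exits = []
        members: set[int] = set()
        for c in node.children:
            sub, _, mem = walk(c, False)
            total += sub
            members |= mem
            child_exits.append(exit_rate(mem))
        q = 0.0 if is_root else exit_rate(members)
        rate = q + sum(child_exits)
        index_term = (
            _plogp(rate) - _plogp(q) - sum(_plogp(x) for x in child_exits)
        )
        return total + index_term, q, members

    L, _, _ = walk(tree.root, True)
    return L


# ---------------------------------------------------------------------------
# search


class _SubProblem:
    """Two-level codelength minimization over a node subset.

    Minimizes  G(P) = plogp(exit_rate + sum_c q_c) - 2 sum_c plogp(q_c)
                      + sum_c plogp(q_c + S_c)
    where q_c is the exit rate of submodule c measured against the *whole*
    network (internal boundary plus the subset's external edges), and S_c
    the summed node flows.  At the top level (exit_rate = 0, no external
    edges) G differs from the two-level codelength only by the constant
    node-visit entropy term.
    """

    def __init__(
        self,
        adj: list[dict[int, float]],
        ext: np.ndarray,
        p: np.ndarray,
        exit_rate: float,
        two_w: float,
    ):
        self.adj = adj
        self.ext = ext
        self.p = p
        self.exit_rate = exit_rate
        self.two_w = two_w
        self.n = len(p)

    def objective(self, assign: np.ndarray) -> float:
        """Full recomputation of G for a given assignment (oracle path)."""
        mods = {}
        for v, m in enumerate(assign):
            mods.setdefault(int(m), []).append(v)
        g = 0.0
        q_tot = 0.0
        for members in mods.values():
            inside = set(members)
            cut = sum(self.ext[v] for v in members)
            for v in members:
                for u, w in self.adj[v].items():
                    if u not in inside:
                        cut += w
            q = cut / self.two_w
            s = float(self.p[members].sum())
            q_tot += q
            g += -2.0 * _plogp(q) + _plogp(q + s)
        return g + _plogp(self.exit_rate + q_tot)

    def optimize(self, rng: np.random.Generator) -> tuple[np.ndarray, float]:
        """One Louvain run (local moves + aggregation) from singletons."""
        # current aggregation level state
        adj = [dict(d) for d in self.adj]
        ext = self.ext.astype(float).copy()
        p = self.p.astype(float).copy()
        mapping = np.arange(self.n)  # original node -> current supernode
        g_inc = self.objective(mapping)
        while True:
            assign, improved, g_inc = self._move_phase(adj, ext, p, rng)
            mapping = assign[mapping]
            n_mod = int(assign.max()) + 1 if assign.size else 0
            if not improved or n_mod == len(adj):
                break
            adj, ext, p = self._aggregate(adj, ext, p, assign, n_mod)
        return mapping, g_inc

    def _move_phase(
        self,
        adj: list[dict[int, float]],
        ext: np.ndarray,
        p: np.ndarray,
        rng: np.random.Generator,
    ) -> tuple[np.ndarray, bool, float]:
        n = len(p)
        assign = np.arange(n)
        d_ext = np.array([sum(a.values()) for a in adj]) + ext  # non-self incident
        cut = d_ext.copy()  # singleton cut weight (raw units)
        s_p = p.copy()
        count = np.ones(n, dtype=int)
        two_w = self.two_w
        er = self.exit_rate
        t_q = float(cut.sum()) / two_w  # sum of module exit rates
        # incrementally maintained objective; must track full recomputation
        g_inc = _plogp(er + t_q) + sum(
            -2.0 * _plogp(cut[m] / two_w) + _plogp(cut[m] / two_w + s_p[m])
            for m in range(n)
        )
        improved_any = False
        for _ in range(100):
            improved = False
            order = rng.permutation(n)
            for v in order:
                a = int(assign[v])
                w_to = {}
                for u, w in adj[v].items():
                    m = int(assign[u])
                    w_to[m] = w_to.get(m, 0.0) + w
                k_a = w_to.get(a, 0.0)
                # removal update for source module
                cut_a_new = cut[a] - d_ext[v] + 2.0 * k_a
                q_a, q_a_new = cut[a] / two_w, cut_a_new / two_w
                s_a, s_a_new = s_p[a], s_p[a] - p[v]
                base_remove = (
                    -2.0 * (_plogp(q_a_new) - _plogp(q_a))
                    + _plogp(q_a_new + s_a_new)
                    - _plogp(q_a + s_a)
                )
                best_delta = 0.0
                best_target = a
                candidates = [m for m in w_to if m != a]
                if count[a] > 1:
                    candidates.append(-1)  # fresh singleton module
                for b in candidates:
                    k_b = w_to.get(b, 0.0)
                    cut_b = 0.0 if b == -1 else cut[b]
                    s_b = 0.0 if b == -1 else s_p[b]
                    cut_b_new = cut_b + d_ext[v] - 2.0 * k_b
                    q_b, q_b_new = cut_b / two_w, cut_b_new / two_w
                    t_new = t_q + (q_a_new - q_a) + (q_b_new - q_b)
                    delta = (
                        base_remove
                        + _plogp(er + t_new)
                        - _plogp(er + t_q)
                        - 2.0 * (_plogp(q_b_new) - _plogp(q_b))
                        + _plogp(q_b_new + s_b + p[v])
                        - _plogp(q_b + s_b)
                    )
                    if delta < best_delta - 1e-13:
                        best_delta = delta
                        best_target = b
                if best_target != a:
                    b = best_target
                    if b == -1:
                        b = len(cut)
                        cut = np.append(cut, 0.0)
                        s_p = np.append(s_p, 0.0)
                        count = np.append(count, 0)
                    k_b = w_to.get(b, 0.0)
                    t_q += (cut_a_new - cut[a]) / two_w
                    cut[a] = cut_a_new
                    s_p[a] -= p[v]
                    count[a] -= 1
                    cut_b_new = cut[b] + d_ext[v] - 2.0 * k_b
                    t_q += (cut_b_new - cut[b]) / two_w
                    cut[b] = cut_b_new
                    s_p[b] += p[v]
                    count[b] += 1
                    assign[v] = b
                    g_inc += best_delta
                    improved = True
                    improved_any = True
            if not improved:
                break
        # compact module ids, deterministic by smallest member node
        used = {}
        out = np.empty(len(assign), dtype=int)
        for v in range(len(assign)):
            m = int(assign[v])
            if m not in used:
                used[m] = len(used)
            out[v] = used[m]
        return out, improved_any, g_inc

    @staticmethod
    def _aggregate(
        adj: list[dict[int, float]],
        ext: np.ndarray,
        p: np.ndarray,
        assign: np.ndarray,
        n_mod: int,
    ) -> tuple[list[dict[int, float]], np.ndarray, np.ndarray]:
        new_adj: list[dict[int, float]] = [dict() for _ in range(n_mod)]
        new_ext = np.zeros(n_mod)
        new_p = np.zeros(n_mod)
        for v, m in enumerate(assign):
            m = int(m)
            new_ext[m] += ext[v]
            new_p[m] += p[v]
            for u, w in adj[v].items():
                mu = int(assign[u])
                if mu != m:
                    # each direction of the symmetric pair is visited once
                    new_adj[m][mu] = new_adj[m].get(mu, 0.0) + w
        return new_adj, new_ext, new_p


def _search_partition(
    sub: _SubProblem, n_trials: int, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    best_assign: np.ndarray | None = None
    best_g = math.inf
    for _ in range(max(1, n_trials)):
        assign, g = sub.optimize(rng)
        if g < best_g - 1e-13:
            best_g = g
            best_assign = assign
    assert best_assign is not None
    return best_assign, best_g


def _canonical_modules(nodes: list[str], assign: np.ndarray) -> list[list[str]]:
    """Modules as sorted gene lists, ordered by size desc then first member."""
    mods: dict[int, list[str]] = {}
    for v, m in zip(nodes, assign):
        mods.setdefault(int(m), []).append(v)
    out = [sorted(m) for m in mods.values()]
    out.sort(key=lambda m: (-len(m), m[0]))
    return out


def detect_modules(
    net: nx.Graph,
    n_trials: int = 20,
    rng_seed: int = 0,
    max_depth: int = 3,
) -> ModuleTree:
    """Best-of-trials hierarchical codelength minimization.

    Visit rates are computed over the whole input network; disconnected
    components are partitioned independently (Louvain moves never cross
    components).  Modules are recursively subdivided while the hierarchical
    codelength drops by more than 1e-10 bits and the tree stays within
    ``max_depth`` levels (root excluded).  Deterministic for a fixed seed.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    if net.number_of_nodes() == 1:
        only = next(iter(net.nodes))
        tree = ModuleTree(ModuleNode(children=[ModuleNode(genes=[only])]))
        tree.codelength_bits = 0.0
        return tree
    flow = visit_rates(net)
    rng = np.random.default_rng(rng_seed)
    two_w = flow.two_w
    n = len(flow.nodes)

    top = _SubProblem(flow.neighbors, np.zeros(n), flow.p, 0.0, two_w)
    assign, _ = _search_partition(top, n_trials, rng)
    modules = _canonical_modules(flow.nodes, assign)

    def external_weight(members: set[int]) -> np.ndarray:
        ext = np.zeros(len(members))
        for k, i in enumerate(sorted(members)):
            for j, w in flow.neighbors[i].items():
                if j not in members:
                    ext[k] += w
        return ext

    def subdivide(genes: list[str], depth: int) -> ModuleNode:
        # max_depth counts the root, so internal module levels stop at
        # max_depth - 1 (default: modules and submodules)
        node = ModuleNode(genes=list(genes))
        if depth >= max_depth - 1 or len(genes) < 2:
            return node
        members = {flow.index[g] for g in genes}
        order = sorted(members)
        local = {i: k for k, i in enumerate(order)}
        adj: list[dict[int, float]] = [dict() for _ in order]
        ext = external_weight(members)
        for k, i in enumerate(order):
            for j, w in flow.neighbors[i].items():
                if j in members:
                    adj[k][local[j]] = w
        p_local = flow.p[order]
        q_m = float(ext.sum()) / two_w
        sub = _SubProblem(adj, ext, p_local, q_m, two_w)
        sub_assign, g_split = _search_partition(sub, n_trials, rng)
        if int(sub_assign.max()) == 0:
            return node
        leaf_term = _plogp(q_m + float(p_local.sum()))
        if g_split >= leaf_term - _EPS:
            return node
        names = [flow.nodes[i] for i in order]
        node.genes = []
        node.children = [
            subdivide(mod, depth + 1) for mod in _canonical_modules(names, sub_assign)
        ]
        return node

    children = [subdivide(mod, 1) for mod in modules]
    tree = ModuleTree(ModuleNode(children=children))

    # never return a tree worse than the flat one-module baseline
    L = hierarchical_codelength(flow, tree)
    flat = ModuleTree(ModuleNode(children=[ModuleNode(genes=list(flow.nodes))]))
    L_flat = hierarchical_codelength(flow, flat)
    if L > L_flat + _EPS:
        flat.codelength_bits = L_flat
        return flat
    tree.codelength_bits = L
    return tree


# ---------------------------------------------------------------------------
# labeling and summaries


def pagerank(
    net: nx.Graph, d: float = 0.85, tol: float = 1e-10, max_iter: int = 100000
) -> pd.Series:
    """Weighted PageRank with uniform teleportation, by power iteration."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = sorted(net.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    src, dst, wts = [], [], []
    for u, v, data in net.edges(data=True):
        wt = float(data.get("weight", 1.0))
        src += [index[u], index[v]]
        dst += [index[v], index[u]]
        wts += [wt, wt]
    src = np.array(src, dtype=int)
    dst = np.array(dst, dtype=int)
    wts = np.array(wts, dtype=float)
    strength = np.zeros(n)
    np.add.at(strength, src, wts)
    dangling = strength == 0
    r = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        contrib = np.zeros(n)
        scale = np.where(dangling, 0.0, r / np.where(dangling, 1.0, strength))
        np.add.at(contrib, dst, wts * scale[src])
        r_new = (1.0 - d) / n + d * (contrib + r[dangling].sum() / n)
        if np.abs(r_new - r).sum() < tol:
            r = r_new
            break
        r = r_new
    else:
        raise RuntimeError(f"PageRank failed to converge in {max_iter} iterations")
    r = r / r.sum()
    return pd.Series(r, index=nodes, name="pagerank")


def label_modules(tree: ModuleTree, pr: pd.Series) -> ModuleTree:
    """Label every module by its highest-PageRank member gene (ties: lexicographic)."""
    missing = [g for g in tree.genes() if g not in pr.index]
    if missing:
        raise KeyError(f"PageRank scores missing for genes: {missing[:5]}")

    def walk(node: ModuleNode) -> None:
        genes = node.member_genes()
        best = min(genes, key=lambda g: (-pr[g], g))
        node.label = best
        for c in node.children:
            walk(c)

    for c in tree.root.children:
        walk(c)
    return tree


def hierarchy_summary(tree: ModuleTree) -> dict:
    """Counts per level, per-module gene counts, and the component gene total.

    ``module_sizes`` is keyed by level, then by module label (falling back
    to the colon-joined path when unlabeled).
    """
    summary: dict = {"modules_per_level": {}, "module_sizes": {}, "total_genes": 0}
    level = 1
    while True:
        mods = tree.modules_at_level(level)
        if not mods:
            break
        summary["modules_per_level"][level] = len(mods)
        sizes: dict[str, int] = {}
        for path, node in mods:
            key = node.label or ":".join(str(x) for x in path)
            sizes[key] = node.size
        summary["module_sizes"][level] = sizes
        level += 1
    summary["total_genes"] = sum(c.size for c in tree.root.children)
    return summary
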