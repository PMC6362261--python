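"""Hypergeometric over-representation analysis of modules against gene sets.

For a module of n genes drawn from a background universe of N genes, overlap
with a K-gene annotation set is scored by the hypergeometric upper tail

    p = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N,n)

evaluated in log space for numerical safety.  Within each module, p-values
are Benjamini-Hochberg adjusted across the tested sets, and records are
flagged at two significance regimes commonly used for module annotation:
a BH q <= 0.05 screen and a stricter raw p <= 1e-5 cut.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .community import ModuleTree
from .expression import bh_adjust

log = logging.getLogger(__name__)

__all__ = ["hypergeom_upper_tail", "bh_adjust", "ora"]


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), in log-space summation."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"impossible configuration N={N}, K={K}, n={n}")
    hi = min(n, K)
    if not 0 <= k <= hi:
        raise ValueError(f"overlap k={k} outside [0, min(n, K)={hi}]")
    if k == 0:
        return 1.0
    lo = max(k, n + K - N)
    i = np.arange(lo, hi + 1)
    log_terms = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def _module_sets(modules) -> dict[str, list[str]]:
    """Accept a ModuleTree (all levels) or a mapping of label -> genes."""
    if isinstance(modules, ModuleTree):
        out: dict[str, list[str]] = {}
        level = 1
        while True:
            mods = modules.modules_at_level(level)
            if not mods:
                break
            for path, node in mods:
                key = ":".join(str(x) for x in path)
                if node.label:
                    key = f"{node.label}[{key}]"
                out[key] = node.member_genes()
            level += 1
        return out
    return {str(k): list(v) for k, v in modules.items()}


def ora(
    modules,
    sets: Mapping[str, Iterable[str]],
    background: Iterable[str],
    alpha: float = 0.05,
    alpha_strict: float = 1e-5,
) -> pd.DataFrame:
    """Over-representation of every module against every gene set.

    ``modules`` may be a :class:`ModuleTree` (all hierarchy levels are
    tested) or a mapping of module label to gene list.  Genes outside the
    background are dropped with a logged count.  BH adjustment is applied
    within each module across the tested sets; only overlapping records
    (k >= 1) are returned.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background universe")
    N = len(bg)
    trimmed_sets = {}
    for name, members in sets.items():
        inside = sorted(set(members) & bg)
        if inside:
            trimmed_sets[name] = inside
    rows = []
    for mod_label, genes in sorted(_module_sets(modules).items()):
        mod_genes = set(genes)
        dropped = len(mod_genes - bg)
        if dropped:
            log.info("module %s: %d genes outside background dropped", mod_label, dropped)
        mod_genes &= bg
        n = len(mod_genes)
        if n == 0:
            continue
        recs = []
        for name in sorted(trimmed_sets):
            members = trimmed_sets[name]
            k = len(mod_genes.intersection(members))
            if k == 0:
                continue
            K = len(members)
            p = hypergeom_upper_tail(N, K, n, k)
            recs.append((mod_label, name, k, n, K, N, p))
        if not recs:
            continue
        q = bh_adjust([r[6] for r in recs])
        for r, qv in zip(recs, q):
            rows.append((*r, qv))
    out = pd.DataFrame(
        rows, columns=["module", "term", "k", "n", "K", "N", "p", "q"]
    )
    if not out.empty:
        out[f"significant_{alpha:g}"] = out["q"] <= alpha
        out[f"significant_{alpha_strict:g}"] = out["p"] <= alpha_strict
        out = out.sort_values(["module", "p", "term"], kind="stable").reset_index(drop=True)
    else:
        out[f"significant_{alpha:g}"] = pd.Series(dtype=bool)
        out[f"significant_{alpha_strict:g}"] = pd.Series(dtype=bool)
    return out
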