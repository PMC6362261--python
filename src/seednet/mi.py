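"""Mutual-information estimation and the globally ranked edge list.

MI is estimated on equal-frequency (rank-based) bins, which makes the
estimate invariant under strictly monotone transforms of either margin —
the reparameterization invariance that motivates MI for expression data.
The plug-in estimate H(X) + H(Y) - H(X,Y) is debiased with a Miller-Madow
term whose support sizes are estimated Chao1-style from the occupied-cell
spectrum (singletons/doubletons), which adapts between the dense
independent regime (support ~ B^2) and concentrated dependent joints.  The
result is clipped to the information inequality 0 <= MI <= min(H(X), H(Y)).

The number of bins defaults to ``round(3 * n**0.25)``: fine enough that
discretization loses little dependence signal at the sample sizes used
here, coarse enough that the joint histogram stays well populated.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = ["default_bins", "estimate_mi", "all_pairs_mi", "sort_edges"]

LN2 = np.log(2.0)


def default_bins(n_samples: int) -> int:
    return max(2, int(round(3.0 * n_samples**0.25)))


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each value to one of n_bins equal-frequency bins via ranks.

    Stable argsort makes tie handling deterministic (ties broken by input
    position), so repeated runs produce identical bin assignments.
    """
    n = x.size
    rank = np.empty(n, dtype=np.int64)
    rank[np.argsort(x, kind="stable")] = np.arange(n)
    return (rank * n_bins) // n


def _plugin_entropy_bits(counts: np.ndarray, n: int) -> float:
    # summation over sorted counts makes the estimate exactly symmetric in
    # the two arguments (the joint histogram transposes between them)
    c = np.sort(counts[counts > 0])
    p = c / n
    return float(-(p * np.log(p)).sum() / LN2)


def _support_estimate(counts: np.ndarray, cap: int) -> float:
    """Chao1 estimate of the number of cells with positive probability."""
    occ = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        est = occ + f1 * f1 / (2.0 * f2)
    else:
        est = occ + f1 * (f1 - 1) / 2.0
    return float(min(est, cap))


def estimate_mi(
    x,
    y,
    n_bins: int | None = None,
    correction: str = "chao-mm",
) -> float:
    """Mutual information between two samples, in bits.

    correction: ``"chao-mm"`` (default) applies the support-adjusted
    Miller-Madow debiasing; ``"none"`` returns the clipped plug-in estimate
    (exact for, e.g., MI(X;X) = log2(n_bins) on tie-free data).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length 1-D vectors, got {x.shape}, {y.shape}")
    n = x.size
    if n < 8:
        raise ValueError(f"need at least 8 observations, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if correction not in ("chao-mm", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input vector; MI set to 0")
        return 0.0
    b = default_bins(n) if n_bins is None else int(n_bins)
    if b < 2:
        raise ValueError("n_bins must be >= 2")

    bx = _equal_frequency_bins(x, b)
    by = _equal_frequency_bins(y, b)
    joint = np.bincount(bx * b + by, minlength=b * b).astype(float)
    cx = np.bincount(bx, minlength=b).astype(float)
    cy = np.bincount(by, minlength=b).astype(float)
    hx = _plugin_entropy_bits(cx, n)
    hy = _plugin_entropy_bits(cy, n)
    hxy = _plugin_entropy_bits(joint, n)
    mi = hx + hy - hxy
    if correction == "chao-mm":
        mx = _support_estimate(cx, b)
        my = _support_estimate(cy, b)
        mxy = _support_estimate(joint, b * b)
        mi -= (mxy - mx - my + 1.0) / (2.0 * n * LN2)
    return float(np.clip(mi, 0.0, min(hx, hy)))


def sort_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Canonical edge order: MI descending, ties by (gene_a, gene_b)."""
    out = edges.sort_values(
        ["mi", "gene_a", "gene_b"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    return out


def all_pairs_mi(
    expr: ExpressionMatrix,
    subset: list[str] | None = None,
    n_bins: int | None = None,
    correction: str = "chao-mm",
    max_genes: int = 5000,
    force: bool = False,
) -> pd.DataFrame:
    """MI for every gene pair, as a ranked edge list (no significance filter).

    Returns a DataFrame (gene_a, gene_b, mi) with gene_a < gene_b
    lexicographically within each row, sorted by MI descending with
    deterministic lexicographic tie-breaks.  Refuses more than ``max_genes``
    genes unless ``force`` is set (the edge count grows quadratically).
    """
    values = expr.values
    if subset is not None:
        missing = sorted(set(subset) - set(values.index))
        if missing:
            raise KeyError(f"subset genes absent from matrix: {missing[:5]}")
        values = values.loc[list(subset)]
    genes = np.array(sorted(values.index))
    g = genes.size
    if g < 2:
        raise ValueError("need at least 2 genes")
    if g > max_genes and not force:
        raise ValueError(
            f"{g} genes would give {g * (g - 1) // 2} pairs; pass force=True to override"
        )
    x = values.loc[genes].to_numpy()
    n = x.shape[1]
    b = default_bins(n) if n_bins is None else int(n_bins)

    bins = np.empty((g, n), dtype=np.int64)
    for i in range(g):
        bins[i] = _equal_frequency_bins(x[i], b)
    const = np.ptp(x, axis=1) == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant genes; their MI set to 0")

    # marginal entropies and support statistics per gene
    hx = np.empty(g)
    msup = np.empty(g)
    for i in range(g):
        c = np.bincount(bins[i], minlength=b).astype(float)
        hx[i] = _plugin_entropy_bits(c, n)
        msup[i] = _support_estimate(c, b)

    rows_a, rows_b, vals = [], [], []
    nn = float(n)
    for i in range(g - 1):
        rest = np.arange(i + 1, g)
        codes = bins[i] * b + bins[rest]  # (g-i-1, n)
        offset = np.arange(rest.size)[:, None] * (b * b)
        counts = np.bincount(
            (codes + offset).ravel(), minlength=rest.size * b * b
        ).astype(float).reshape(rest.size, b * b)
        p = counts / nn
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        hxy = -plogp.sum(axis=1) / LN2
        mi = hx[i] + hx[rest] - hxy
        if correction == "chao-mm":
            occ = (counts > 0).sum(axis=1)
            f1 = (counts == 1).sum(axis=1)
            f2 = (counts == 2).sum(axis=1)
            mxy = np.where(
                f2 > 0, occ + f1 * f1 / (2.0 * f2), occ + f1 * (f1 - 1) / 2.0
            )
            mxy = np.minimum(mxy, b * b)
            mi = mi - (mxy - msup[i] - msup[rest] + 1.0) / (2.0 * nn * LN2)
        mi = np.clip(mi, 0.0, np.minimum(hx[i], hx[rest]))
        if const[i]:
            mi[:] = 0.0
        mi[const[rest]] = 0.0
        rows_a.append(np.full(rest.size, genes[i]))
        rows_b.append(genes[rest])
        vals.append(mi)

    edges = pd.DataFrame(
        {
            "gene_a": np.concatenate(rows_a),
            "gene_b": np.concatenate(rows_b),
            "mi": np.concatenate(vals),
        }
    )
    return sort_edges(edges)
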