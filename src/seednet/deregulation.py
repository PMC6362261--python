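"""Principal-curve pathway deregulation scores and four-group classification.

For one pathway, samples are projected onto the leading principal
components of the pathway-gene expression submatrix and a one-dimensional
principal curve is fitted through the cloud by the classic
iterate-project-smooth scheme.  Each sample's pathway deregulation score
(PDS) is its arc-length position along the curve, with the origin anchored
at the end nearest the normal-sample centroid and the scale normalized by
the total curve length, so PDS lies in [0, 1] and normal samples score near
zero by construction.

Samples are then classified against a threshold theta (default 0.4, strict
inequality) on two pathway scores — inflammation and adaptive immunity —
into four groups: both, adaptive_only, inflammation_only, neither.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .expression import ExpressionMatrix, NORMAL

__all__ = [
    "fit_principal_curve",
    "pathway_pds",
    "classify_deregulation",
    "group_report",
    "conditional_percentage",
    "GROUPS",
]

GROUPS = ("both", "adaptive_only", "inflammation_only", "neither")


def _project_to_polyline(points: np.ndarray, curve: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project points onto a polyline; returns (arc-length positions, sq dists)."""
    seg = curve[1:] - curve[:-1]  # (m-1, d)
    seg_len = np.linalg.norm(seg, axis=1)
    keep = seg_len > 0
    starts = curve[:-1][keep]
    seg = seg[keep]
    seg_len = seg_len[keep]
    if seg.shape[0] == 0:
        lam = np.zeros(len(points))
        d2 = ((points - curve[0]) ** 2).sum(axis=1)
        return lam, d2
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])[:-1]
    diff = points[:, None, :] - starts[None, :, :]  # (n, s, d)
    t = np.clip((diff * seg[None, :, :]).sum(-1) / (seg_len**2)[None, :], 0.0, 1.0)
    proj = starts[None, :, :] + t[:, :, None] * seg[None, :, :]
    d2 = ((points[:, None, :] - proj) ** 2).sum(-1)
    best = d2.argmin(axis=1)
    n = len(points)
    lam = cum[best] + t[np.arange(n), best] * seg_len[best]
    return lam, d2[np.arange(n), best]


def _smooth_sorted(y: np.ndarray, span: float) -> np.ndarray:
    """Running-mean smoother over a window of span * n points (odd, >= 3)."""
    n = len(y)
    w = max(3, int(round(span * n)))
    if w % 2 == 0:
        w += 1
    half = w // 2
    pad = np.concatenate([np.repeat(y[:1], half, axis=0), y, np.repeat(y[-1:], half, axis=0)])
    kernel = np.ones(w) / w
    out = np.empty_like(y)
    for d in range(y.shape[1]):
        out[:, d] = np.convolve(pad[:, d], kernel, mode="valid")
    return out


def fit_principal_curve(
    points: np.ndarray,
    span: float = 0.3,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit a one-dimensional principal curve by iterate-project-smooth.

    Returns (lam, curve): per-point arc-length positions and the ordered
    polyline vertices.  Initialization is the first principal axis;
    iteration stops when the mean projection displacement falls below
    ``tol`` times the data scale.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n < 5:
        raise ValueError("need at least 5 points to fit a principal curve")
    center = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - center, full_matrices=False)
    if s[0] <= 0:
        raise ValueError("degenerate input: all points identical")
    lam = (pts - center) @ vt[0]
    scale = float(np.linalg.norm(pts - center, axis=1).mean())

    def ordering(l: np.ndarray) -> np.ndarray:
        # ties in arc-length position (points projecting onto the same
        # vertex) are broken by coordinates, so the fit is independent of
        # input row order
        return np.lexsort((*pts.T[::-1], l))

    for _ in range(max_iter):
        curve = _smooth_sorted(pts[ordering(lam)], span)
        new_lam, _ = _project_to_polyline(pts, curve)
        # arc-length origins differ between iterations; compare re-anchored
        move = float(np.mean(np.abs((new_lam - new_lam.min()) - (lam - lam.min()))))
        lam = new_lam
        if move < tol * max(scale, 1e-12):
            break
    curve = _smooth_sorted(pts[ordering(lam)], span)
    lam, _ = _project_to_polyline(pts, curve)
    return lam, curve


def pathway_pds(
    expr: ExpressionMatrix,
    pathway: Iterable[str],
    n_components: int = 3,
    span: float = 0.3,
    max_iter: int = 50,
) -> pd.Series:
    """Per-sample pathway deregulation score in [0, 1].

    Requires at least 5 pathway genes present in the matrix and at least 3
    normal samples to anchor the curve origin.
    """
    genes = [g for g in pathway if g in expr.values.index]
    if len(genes) < 5:
        raise ValueError(
            f"only {len(genes)} pathway genes present in the matrix (need >= 5)"
        )
    normals = expr.sample_ids(NORMAL)
    if len(normals) < 3:
        raise ValueError(f"need >= 3 normal samples, got {len(normals)}")
    x = expr.values.loc[genes].to_numpy().T  # samples x genes
    x = x - x.mean(axis=0)
    if not np.any(x.std(axis=0) > 0):
        raise ValueError("degenerate pathway submatrix: zero variance everywhere")
    k = min(n_components, len(genes), x.shape[0] - 1)
    scores = PCA(n_components=k, svd_solver="full").fit_transform(x)
    lam, _ = fit_principal_curve(scores, span=span, max_iter=max_iter)
    total = float(lam.max() - lam.min())
    if total <= 0:
        raise ValueError("degenerate principal curve: zero length")
    lam = lam - lam.min()
    is_normal = np.array([s in set(normals) for s in expr.samples])
    if lam[is_normal].mean() > total / 2.0:
        lam = total - lam
    pds = lam / total
    return pd.Series(pds, index=expr.samples, name="pds")


def classify_deregulation(pds_inflammation: float, pds_adaptive: float, theta: float = 0.4) -> str:
    """Four-group call from two PDS values; deregulated means PDS > theta."""
    for name, v in (("inflammation", pds_inflammation), ("adaptive", pds_adaptive)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} PDS {v} outside [0, 1]")
    infl = pds_inflammation > theta
    adap = pds_adaptive > theta
    if infl and adap:
        return "both"
    if adap:
        return "adaptive_only"
    if infl:
        return "inflammation_only"
    return "neither"


def group_report(labels: Sequence[str], decimals: int = 1) -> pd.DataFrame:
    """Counts and percentages per deregulation group.

    Returns one row per group (fixed order) with count and
    ``percentage = round(100 * count / total, decimals)``.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("empty label list")
    bad = sorted(set(labels) - set(GROUPS))
    if bad:
        raise ValueError(f"unknown group labels: {bad}")
    total = len(labels)
    rows = []
    for g in GROUPS:
        c = labels.count(g)
        rows.append((g, c, round(100.0 * c / total, decimals)))
    return pd.DataFrame(rows, columns=["group", "count", "percentage"])


def conditional_percentage(
    counts: Mapping[str, int],
    numerator: Sequence[str],
    denominator: Sequence[str],
    decimals: int = 1,
) -> float:
    """Percentage of ``numerator`` groups within ``denominator`` groups.

    E.g. the share of inflammation-deregulated tumors that are also
    adaptive-deregulated is ``conditional_percentage(counts, ["both"],
    ["both", "inflammation_only"])``.
    """
    bad = sorted((set(numerator) | set(denominator)) - set(GROUPS))
    if bad:
        raise ValueError(f"unknown group labels: {bad}")
    if not set(numerator) <= set(denominator):
        raise ValueError("numerator groups must be a subset of denominator groups")
    den = sum(int(counts.get(g, 0)) for g in denominator)
    if den == 0:
        raise ValueError("denominator count is zero")
    num = sum(int(counts.get(g, 0)) for g in numerator)
    return round(100.0 * num / den, decimals)
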