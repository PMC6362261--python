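"""Expression matrices and empirical-Bayes differential expression.

The differential-expression statistic is the moderated t: per-gene residual
variances are shrunk toward a common prior whose scale ``s0^2`` and degrees
of freedom ``d0`` are estimated from the spread of the observed
log-variances (the canonical hierarchical-variance empirical-Bayes model).
With pooled two-group variance ``s_g^2`` on ``df`` residual degrees of
freedom,

    s_post^2 = (d0*s0^2 + df*s_g^2) / (d0 + df)
    t_g      = logFC_g / (s_post * sqrt(1/n_t + 1/n_n))

and p-values come from a t distribution with ``df + d0`` degrees of freedom.
Genes are then banded by fold change alone: over (logFC > 1), under
(logFC < -1), nochange otherwise (bounds inclusive in nochange).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from . import io

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "moderated_t",
    "classify_de",
    "bh_adjust",
]

TUMOR = "tumor"
NORMAL = "normal"


@dataclass
class ExpressionMatrix:
    """Log2 expression, genes x samples, with per-sample group labels."""

    values: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        missing = [s for s in self.values.columns if s not in self.group.index]
        if missing:
            raise ValueError(f"samples missing from labels: {missing[:5]}")
        self.group = self.group.reindex(self.values.columns)
        bad = sorted(set(self.group) - {TUMOR, NORMAL})
        if bad:
            raise ValueError(f"unknown group labels {bad}; expected tumor/normal")

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def sample_ids(self, which: str) -> list[str]:
        return self.group.index[self.group == which].tolist()

    def subset_genes(self, genes) -> "ExpressionMatrix":
        keep = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[keep], self.group.copy())


def read_expression(matrix_path, labels_path) -> ExpressionMatrix:
    """Load an expression TSV plus sample-label TSV into a validated matrix.

    Duplicated gene rows are collapsed to the single row with the highest
    mean expression (the usual microarray probe-collapse rule).
    """
    values = io.read_expression_tsv(matrix_path)
    labels = io.read_labels_tsv(labels_path)
    missing = [s for s in values.columns if s not in labels.index]
    if missing:
        raise ValueError(f"label file does not cover samples: {missing[:5]}")
    if values.index.duplicated().any():
        means = values.mean(axis=1)
        order = np.argsort(-means.values, kind="stable")
        dedup = values.iloc[order]
        dedup = dedup[~dedup.index.duplicated(keep="first")]
        values = dedup.loc[sorted(dedup.index)]
    return ExpressionMatrix(values, labels)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < 1e-8:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) from pooled variances by moments of log variances.

    Returns ``d0 = inf`` when the observed spread of log-variances does not
    exceed what sampling alone explains (all genes then share one pooled
    variance).
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return math.inf, float(np.median(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    emean = float(np.mean(e))
    if evar <= 0:
        return math.inf, math.exp(emean)
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_2 = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return d0, s0_2


def moderated_t(expr: ExpressionMatrix, prior_df: float | None = None) -> pd.DataFrame:
    """Per-gene moderated t contrasting tumor against normal.

    Returns a DataFrame with columns gene, logfc, t_mod, p, q, status.
    ``prior_df`` overrides the estimated prior degrees of freedom: 0 gives
    the ordinary pooled two-sample t, ``inf`` a single common variance.
    """
    t_ids = expr.sample_ids(TUMOR)
    n_ids = expr.sample_ids(NORMAL)
    if len(t_ids) < 2 or len(n_ids) < 2:
        raise ValueError(
            f"need >=2 samples per group (tumor={len(t_ids)}, normal={len(n_ids)})"
        )
    xt = expr.values[t_ids].to_numpy()
    xn = expr.values[n_ids].to_numpy()
    nt, nn = xt.shape[1], xn.shape[1]
    df = float(nt + nn - 2)
    logfc = xt.mean(axis=1) - xn.mean(axis=1)
    ss = ((xt - xt.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (xn - xn.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df

    d0, s0_2 = _fit_variance_prior(s2, df)
    if prior_df is not None:
        # override shrinkage weight only; the prior scale stays as estimated
        d0 = float(prior_df)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = math.inf
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = df + d0
    zero = s2_post <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} genes with zero posterior variance; t set to 0")
    se = np.sqrt(np.where(zero, np.nan, s2_post) * (1.0 / nt + 1.0 / nn))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(zero, 0.0, logfc / se)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q = bh_adjust(p)
    status = [classify_de(f) for f in logfc]
    out = pd.DataFrame(
        {
            "gene": expr.genes,
            "logfc": logfc,
            "t_mod": t,
            "p": p,
            "q": q,
            "status": status,
        }
    )
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0_2
    return out


def classify_de(logfc: float, lower: float = -1.0, upper: float = 1.0) -> str:
    """Band a log2 fold change: over (> upper), under (< lower), else nochange."""
    if not np.isfinite(logfc):
        raise ValueError(f"logfc must be finite, got {logfc!r}")
    if not lower < upper:
        raise ValueError(f"require lower < upper (got {lower}, {upper})")
    if logfc > upper:
        return "over"
    if logfc < lower:
        return "under"
    return "nochange"
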