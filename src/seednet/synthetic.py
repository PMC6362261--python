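"""Synthetic two-group expression cohorts with planted co-expression hierarchy.

The generator emulates the statistical structure the downstream analysis
assumes about a tumor/normal microarray compendium: log2-scale expression,
groups of genes that are co-expressed in nested blocks (modules containing
submodules), per-block differential-expression shifts between tumor and
normal samples, and gene-set collections that align (fully or partially)
with the planted blocks.

Correlation structure is realized as nested equicorrelation through a latent
factor model: a gene in submodule *s* of module *m* is

    x = sqrt(rho_b)*Z0 + sqrt(rho_m - rho_b)*Zm + sqrt(rho_s - rho_m)*Zs
        + sqrt(1 - rho_s)*eps

so the population Pearson correlation is ``rho_within_sub`` inside a
submodule, ``rho_within_mod`` across submodules of one module and
``rho_between`` across modules.  Requiring
``rho_between <= rho_within_mod <= rho_within_sub < 1`` with non-negative
increments is exactly the positive-semi-definiteness condition for this
covariance, so validity is checkable at construction.  Background genes are
independent noise with no group shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "SyntheticDesign",
    "SyntheticTruth",
    "default_design",
    "generate_expression",
    "generate_geneset_collection",
    "generate_planted_graph",
]

BACKGROUND = "-"


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of one synthetic cohort.

    ``block_spec`` is a two-level nested list: one entry per module, each a
    list of submodule sizes.  ``de_effect`` mirrors that shape and gives the
    tumor-minus-normal mean log2 shift applied to every gene of the leaf
    block (0 = no-change block).
    """

    n_genes: int = 1000
    n_tumor: int = 64
    n_normal: int = 16
    block_spec: tuple[tuple[int, ...], ...] = ()
    de_effect: tuple[tuple[float, ...], ...] = ()
    rho_within_sub: float = 0.7
    rho_within_mod: float = 0.35
    rho_between: float = 0.0
    noise_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        spec = tuple(tuple(int(s) for s in mod) for mod in self.block_spec)
        object.__setattr__(self, "block_spec", spec)
        if not self.de_effect:
            de = tuple(tuple(0.0 for _ in mod) for mod in spec)
        else:
            de = tuple(tuple(float(e) for e in mod) for mod in self.de_effect)
        object.__setattr__(self, "de_effect", de)
        if self.n_tumor < 2 or self.n_normal < 2:
            raise ValueError("need at least 2 samples per group")
        if [len(m) for m in de] != [len(m) for m in spec]:
            raise ValueError("de_effect shape must mirror block_spec")
        if any(s < 1 for mod in spec for s in mod):
            raise ValueError("block sizes must be >= 1")
        if sum(s for mod in spec for s in mod) > self.n_genes:
            raise ValueError("sum of leaf block sizes exceeds n_genes")
        rb, rm, rs = self.rho_between, self.rho_within_mod, self.rho_within_sub
        if not (0.0 <= rb <= rm <= rs < 1.0):
            # nested equicorrelation is PSD iff the variance increments
            # rho_b, rho_m-rho_b, rho_s-rho_m, 1-rho_s are all non-negative
            for mi, mod in enumerate(spec, 1):
                raise ValueError(
                    f"block M{mi}: correlations ({rb}, {rm}, {rs}) violate "
                    "0 <= rho_between <= rho_within_mod <= rho_within_sub < 1; "
                    "implied covariance is not positive semi-definite"
                )
            raise ValueError("correlations violate PSD ordering")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def leaf_blocks(self) -> list[tuple[str, str, int, float]]:
        """(module_id, submodule_id, size, de_effect) per leaf block."""
        out = []
        for mi, mod in enumerate(self.block_spec, 1):
            for si, size in enumerate(mod, 1):
                out.append((f"M{mi}", f"M{mi}.S{si}", size, self.de_effect[mi - 1][si - 1]))
        return out


def default_design(rng_seed: int = 0) -> SyntheticDesign:
    """The reference cohort: 1,000 genes, 64 tumors, 16 normals.

    Sizes mirror the analyzed breast-cancer network shrunk roughly tenfold;
    the four modules carry over-, under- and no-change expression shifts like
    the immune, stromal and unchanged modules seen in tumor co-expression
    networks.
    """
    return SyntheticDesign(
        n_genes=1000,
        n_tumor=64,
        n_normal=16,
        block_spec=((60, 30, 15), (50, 25, 12), (40, 20), (18,)),
        de_effect=((2.0, 2.0, 2.0), (-2.0, -2.0, -2.0), (0.0, 0.0), (2.0,)),
        rho_within_sub=0.7,
        rho_within_mod=0.35,
        rho_between=0.0,
        noise_sd=1.0,
        rng_seed=rng_seed,
    )


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic cohort: one row per gene.

    Columns: gene, module_id, submodule_id, de_effect, de_status.  Background
    genes carry ``"-"`` in the module columns.
    """

    assignments: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        need = {"gene", "module_id", "submodule_id", "de_effect", "de_status"}
        if not need.issubset(self.assignments.columns):
            raise ValueError(f"truth table needs columns {sorted(need)}")
        if self.assignments["gene"].duplicated().any():
            raise ValueError("duplicate gene in truth table")

    @property
    def genes(self) -> list[str]:
        return self.assignments["gene"].tolist()

    @property
    def planted(self) -> pd.DataFrame:
        return self.assignments[self.assignments["module_id"] != BACKGROUND]

    def block_members(self, level: str = "submodule_id") -> dict[str, list[str]]:
        """Mapping of leaf (or module) id to its member genes."""
        out: dict[str, list[str]] = {}
        for bid, sub in self.planted.groupby(level, sort=True):
            out[str(bid)] = sub["gene"].tolist()
        return out

    def module_of(self) -> dict[str, str]:
        return dict(zip(self.assignments["gene"], self.assignments["module_id"]))

    def status_of(self) -> dict[str, str]:
        return dict(zip(self.assignments["gene"], self.assignments["de_status"]))

    def to_tsv(self, path) -> None:
        self.assignments.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SyntheticTruth":
        df = pd.read_csv(
            path, sep="\t", dtype={"gene": str, "module_id": str, "submodule_id": str,
                                   "de_status": str}
        )
        df["de_effect"] = df["de_effect"].astype(float)
        return cls(df)


def _status(effect: float) -> str:
    if effect > 0:
        return "over"
    if effect < 0:
        return "under"
    return "nochange"


def generate_expression(design: SyntheticDesign) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw one cohort from the design; deterministic for a fixed seed."""
    rng = np.random.default_rng(design.rng_seed)
    n_s = design.n_tumor + design.n_normal
    samples = [f"T{i:03d}" for i in range(1, design.n_tumor + 1)] + [
        f"N{i:03d}" for i in range(1, design.n_normal + 1)
    ]
    group = pd.Series(
        ["tumor"] * design.n_tumor + ["normal"] * design.n_normal,
        index=samples, name="group",
    )
    genes = [f"G{i:06d}" for i in range(1, design.n_genes + 1)]

    rb = design.rho_between
    rm = design.rho_within_mod
    rs = design.rho_within_sub
    z0 = rng.standard_normal(n_s)
    x = np.empty((design.n_genes, n_s))
    rows = []
    cursor = 0
    zm: dict[str, np.ndarray] = {}
    for module_id, sub_id, size, effect in design.leaf_blocks:
        if module_id not in zm:
            zm[module_id] = rng.standard_normal(n_s)
        zs = rng.standard_normal(n_s)
        eps = rng.standard_normal((size, n_s))
        block = (
            np.sqrt(rb) * z0
            + np.sqrt(rm - rb) * zm[module_id]
            + np.sqrt(rs - rm) * zs
            + np.sqrt(1.0 - rs) * eps
        )
        x[cursor : cursor + size] = block
        for g in genes[cursor : cursor + size]:
            rows.append((g, module_id, sub_id, effect, _status(effect)))
        cursor += size
    n_bg = design.n_genes - cursor
    if n_bg:
        x[cursor:] = rng.standard_normal((n_bg, n_s))
        for g in genes[cursor:]:
            rows.append((g, BACKGROUND, BACKGROUND, 0.0, "nochange"))

    x *= design.noise_sd
    baseline = rng.uniform(6.0, 10.0, size=design.n_genes)
    x += baseline[:, None]
    effects = np.array([r[3] for r in rows])
    x[:, : design.n_tumor] += effects[:, None]

    values = pd.DataFrame(x, index=pd.Index(genes, name="gene"), columns=samples)
    truth = SyntheticTruth(
        pd.DataFrame(rows, columns=["gene", "module_id", "submodule_id", "de_effect", "de_status"])
    )
    return ExpressionMatrix(values, group), truth


def generate_geneset_collection(
    truth: SyntheticTruth,
    overlap_fraction: float,
    n_decoy_sets: int,
    rng_seed: int = 0,
) -> dict[str, list[str]]:
    """Gene sets aligned with the planted blocks plus random decoy sets.

    Each planted leaf block yields one set of the block's size containing
    ``overlap_fraction`` of its genes, padded with random non-block genes.
    Decoy sets are drawn from the whole universe at the same sizes, cycling
    through the block sizes.
    """
    if not 0.0 < overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in (0, 1]")
    if n_decoy_sets < 0:
        raise ValueError("n_decoy_sets must be >= 0")
    rng = np.random.default_rng(rng_seed)
    universe = np.array(truth.genes)
    sets: dict[str, list[str]] = {}
    blocks = truth.block_members("submodule_id")
    for bid, members in blocks.items():
        size = len(members)
        n_in = max(1, int(round(overlap_fraction * size)))
        chosen = list(rng.choice(members, size=n_in, replace=False)) if n_in < size else list(members)
        pool = np.setdiff1d(universe, np.array(members))
        pad = list(rng.choice(pool, size=size - n_in, replace=False)) if size > n_in else []
        name = "SET_" + bid.replace(".", "_")
        sets[name] = sorted(chosen + pad)
    sizes = [len(m) for m in blocks.values()] or [20]
    for d in range(n_decoy_sets):
        size = sizes[d % len(sizes)]
        sets[f"DECOY_{d + 1:03d}"] = sorted(rng.choice(universe, size=size, replace=False))
    return sets


def generate_planted_graph(
    n_blocks: int,
    block_size: int,
    p_in: float,
    p_out: float,
    seed: int,
) -> tuple[nx.Graph, dict[str, int]]:
    """Planted-partition benchmark graph with unit edge weights.

    Returns the graph (nodes ``N0001``...) and the planted block label of
    every node.
    """
    if not (0.0 <= p_out < p_in <= 1.0):
        raise ValueError(f"require p_out < p_in (got p_in={p_in}, p_out={p_out})")
    g0 = nx.planted_partition_graph(n_blocks, block_size, p_in, p_out, seed=seed)
    mapping = {v: f"N{v + 1:04d}" for v in g0.nodes}
    g = nx.relabel_nodes(g0, mapping)
    nx.set_edge_attributes(g, 1.0, "weight")
    truth = {mapping[v]: v // block_size for v in g0.nodes}
    return g, truth
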