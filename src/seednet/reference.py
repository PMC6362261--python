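"""Published summary tables shipped as worked-example inputs.

The packaged module-size table describes the hierarchy reported for the
largest connected component of the breast-cancer inflammation co-expression
network that this pipeline reproduces in structure: 4 first-level modules
(labeled by their highest-PageRank gene) holding 28 second-level submodules
over 787 genes.  Member gene identities are not part of the table, so the
loader fills each block with placeholder leaves; the tree is meant for
summary arithmetic (module counts, sizes, totals), not for re-analysis.

The deregulation group counts reported for the same study's tumor cohorts
are shipped as plain dictionaries for the percentage-report utilities.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .community import ModuleNode, ModuleTree

__all__ = [
    "load_module_size_table",
    "reference_hierarchy",
    "DEREGULATION_COUNTS_MICROARRAY",
    "DEREGULATION_COUNTS_RNASEQ",
]

# Four-group deregulation counts of the 641-tumor microarray compendium and
# the 993-tumor RNA-seq validation cohort (printed counts used as inputs).
DEREGULATION_COUNTS_MICROARRAY = {
    "both": 395,
    "adaptive_only": 210,
    "inflammation_only": 22,
    "neither": 14,
}
DEREGULATION_COUNTS_RNASEQ = {
    "both": 973,
    "adaptive_only": 8,
    "inflammation_only": 12,
    "neither": 0,
}


def load_module_size_table() -> pd.DataFrame:
    """The packaged module/submodule gene-count table (module, submodule, n_genes)."""
    with resources.files("seednet.data").joinpath("igrn_module_sizes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def reference_hierarchy() -> ModuleTree:
    """Build a :class:`ModuleTree` with placeholder leaves from the size table.

    A ``-`` submodule entry means the module's genes sit directly under it
    (no second-level structure), so it contributes no submodule count.
    """
    table = load_module_size_table()
    children = []
    for module, sub in table.groupby("module", sort=False):
        mod_node = ModuleNode(label=str(module))
        for _, row in sub.iterrows():
            genes = [f"{module}:{row['submodule']}:{i:03d}" for i in range(1, int(row["n_genes"]) + 1)]
            if row["submodule"] == "-":
                mod_node.genes.extend(genes)
            else:
                mod_node.children.append(ModuleNode(genes=genes, label=str(row["submodule"])))
        children.append(mod_node)
    return ModuleTree(ModuleNode(children=children))
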