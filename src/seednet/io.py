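"""Readers and writers for the plain-text formats used across the pipeline.

Everything here is tab-separated text (expression matrices, sample labels,
edge lists, module assignments) or the standard GMT gene-set format, so that
every intermediate of the pipeline is greppable and diffable.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pandas as pd


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV with a header row."""
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_expression_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genes-in-rows expression TSV (first column = gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"expression file {path} has no sample columns")
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        bad = body.columns[body.isna().any()].tolist()
        raise ValueError(f"non-numeric expression values in columns {bad[:5]}")
    body.index = body.index.astype(str)
    body.index.name = "gene"
    return body


def write_expression_tsv(values: pd.DataFrame, path: str | os.PathLike) -> None:
    out = values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_labels_tsv(path: str | os.PathLike) -> pd.Series:
    """Read a two-column sample_id / group TSV into a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"}.issubset(df.columns):
        raise ValueError(f"label file {path} must have columns sample_id, group")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id in label file: {dup!r}")
    return pd.Series(df["group"].values, index=df["sample_id"].values, name="group")


def write_labels_tsv(group: pd.Series, path: str | os.PathLike) -> None:
    pd.DataFrame({"sample_id": group.index, "group": group.values}).to_csv(
        path, sep="\t", index=False
    )


def read_gene_list(path: str | os.PathLike) -> list[str]:
    """Read a one-symbol-per-line gene list; blank lines and '#' comments skipped."""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            tok = line.strip()
            if tok and not tok.startswith("#"):
                genes.append(tok)
    return genes


def write_gene_list(genes: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ...

    Returns an insertion-ordered mapping of set name to member list.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs name, description, >=1 gene")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{ln}: duplicate gene-set name {name!r}")
            members = [g for g in parts[2:] if g]
            sets[name] = members
    return sets


def write_gmt(
    sets: Mapping[str, Sequence[str]],
    path: str | os.PathLike,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_edges_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"gene_a", "gene_b", "mi"}
    if not need.issubset(df.columns):
        raise ValueError(f"edge file {path} must have columns {sorted(need)}")
    return df


def write_edges_tsv(edges: pd.DataFrame, path: str | os.PathLike) -> None:
    edges.to_csv(path, sep="\t", index=False)
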