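"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import seednet as sn


@pytest.fixture(scope="session")
def small_design() -> sn.SyntheticDesign:
    """A fast cohort with four planted submodules in two modules."""
    return sn.SyntheticDesign(
        n_genes=300,
        n_tumor=40,
        n_normal=12,
        block_spec=((30, 20), (25, 15)),
        de_effect=((2.0, 2.0), (-2.0, 0.0)),
        rho_within_sub=0.7,
        rho_within_mod=0.35,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_design):
    return sn.generate_expression(small_design)


@pytest.fixture(scope="session")
def small_ranked(small_cohort):
    expr, _ = small_cohort
    return sn.all_pairs_mi(expr)


@pytest.fixture(scope="session")
def default_cohort():
    """The reference 1,000-gene design used by the end-to-end checks."""
    design = sn.default_design(rng_seed=11)
    return sn.generate_expression(design)


@pytest.fixture()
def toy_ranked() -> pd.DataFrame:
    """The five-edge worked example for the seeded curation."""
    return pd.DataFrame(
        {
            "gene_a": ["A", "C", "A", "B", "A"],
            "gene_b": ["B", "D", "C", "D", "D"],
            "mi": [0.9, 0.8, 0.7, 0.6, 0.5],
        }
    )


@pytest.fixture()
def expression_files(tmp_path):
    """A 3-gene x 4-sample expression/label TSV pair on disk."""
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.normal(8, 1, size=(3, 4)),
        index=pd.Index(["GA", "GB", "GC"], name="gene"),
        columns=["s1", "s2", "s3", "s4"],
    )
    mpath = tmp_path / "expr.tsv"
    lpath = tmp_path / "labels.tsv"
    values.to_csv(mpath, sep="\t")
    pd.DataFrame(
        {"sample_id": ["s1", "s2", "s3", "s4"],
         "group": ["tumor", "tumor", "normal", "normal"]}
    ).to_csv(lpath, sep="\t", index=False)
    return mpath, lpath, values
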