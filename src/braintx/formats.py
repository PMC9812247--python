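"""Readers and writers for the package's tabular exchange formats.

Everything is plain text: expression matrices and spatial profiles as TSV,
gene-category annotations as GMT (one line per set: id, description, then
member genes), regulon databases as a motifs x genes rank matrix TSV with
a sidecar regulator column. These are the formats `run_pipeline` writes
and the entry points for user-supplied data: load your own tables with
these functions and feed them to `correlate_genes`, `gcea`,
`master_regulators` and friends.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .io import SpatialProfile
from .synthetic import RegulonDB

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_profile_tsv",
    "write_profile_tsv",
    "read_regulon_tsv",
    "write_regulon_tsv",
]


def _skip_comments(path) -> list[str]:
    lines = Path(path).read_text().splitlines()
    return [ln for ln in lines if ln.strip() and not ln.startswith("#")]


def read_gmt(path) -> dict[str, list[str]]:
    """GMT: category_id <tab> description <tab> gene1 <tab> gene2 ..."""
    out: dict[str, list[str]] = {}
    for ln in _skip_comments(path):
        fields = ln.split("\t")
        if len(fields) < 3:
            raise FormatError(f"GMT line with fewer than 3 fields: {ln[:60]!r}")
        out[fields[0]] = fields[2:]
    return out


def write_gmt(categories: dict[str, list[str]], path, descriptions=None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for cat in sorted(categories):
            desc = descriptions.get(cat, "na")
            members = "\t".join(categories[cat])
            fh.write(f"{cat}\t{desc}\t{members}\n")


def read_expression_tsv(path) -> pd.DataFrame:
    """Genes x units matrix; first column = gene_id, remaining = unit ids."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.empty:
        raise FormatError(f"{path}: empty expression matrix")
    # unit ids written from integer region ids round-trip as ints
    try:
        df.columns = df.columns.astype(int)
    except (TypeError, ValueError):
        pass
    return df


def write_expression_tsv(expression: pd.DataFrame, path) -> None:
    expression.to_csv(path, sep="\t", index_label="gene_id", lineterminator="\n")


def read_profile_tsv(path) -> SpatialProfile:
    """Profile TSV: unit_id, compartment, x, y, z, value."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"unit_id", "compartment", "x", "y", "z", "value"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: profile TSV needs columns {sorted(required)}")
    compartments = df["compartment"].unique()
    if len(compartments) != 1:
        raise FormatError(f"{path}: profile mixes compartments {list(compartments)}")
    return SpatialProfile(
        df["unit_id"].to_numpy(),
        df["value"].to_numpy(dtype=float),
        str(compartments[0]),
        df[["x", "y", "z"]].to_numpy(dtype=float),
    )


def write_profile_tsv(profile: SpatialProfile, path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_regulon_tsv(path) -> RegulonDB:
    """Motifs x genes rank matrix with columns motif_id, regulator, genes..."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"motif_id", "regulator"} <= set(df.columns):
        raise FormatError(f"{path}: regulon TSV needs motif_id and regulator columns")
    ranks = df.drop(columns=["regulator"]).set_index("motif_id")
    regulators = dict(zip(df["motif_id"], df["regulator"]))
    return RegulonDB(ranks.astype(int), regulators)


def write_regulon_tsv(db: RegulonDB, path) -> None:
    out = db.ranks.copy()
    out.insert(0, "regulator", [db.regulators[m] for m in out.index])
    out.to_csv(path, sep="\t", index_label="motif_id", lineterminator="\n")
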