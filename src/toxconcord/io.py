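"""Readers and writers for the pipeline's plain-text exchange formats.

Counts and metadata travel as TSV (probes as rows, samples as columns),
gene sets as GMT (``name<TAB>description<TAB>gene1<TAB>...``), probe maps,
ortholog maps, interaction catalogs and LDH tables as small TSVs.
"""

from __future__ import annotations

import os
from typing import Mapping

import pandas as pd

from .errors import InvalidInputError


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Read a probe x sample count matrix from TSV (first column = probe id)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if (counts.to_numpy() < 0).any():
        raise InvalidInputError(f"negative counts in {path}")
    return counts


def write_counts(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    counts.to_csv(path, sep="\t", index_label="probe_id")


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_metadata(metadata: pd.DataFrame, path: str | os.PathLike) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a GMT gene-set collection; tolerates empty description fields."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise InvalidInputError(f"malformed GMT line: {line[:80]!r}")
            name = fields[0]
            genes = [g for g in fields[2:] if g]
            sets[name] = genes
    return sets


def write_gmt(
    gene_sets: Mapping[str, list[str]],
    path: str | os.PathLike,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            desc = descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_probe_map(path: str | os.PathLike) -> pd.Series:
    """TSV probe_id -> gene_id, returned as a Series indexed by probe."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["gene_id"].to_numpy(), index=df["probe_id"], name="gene_id")


def write_probe_map(probe_map: pd.Series, path: str | os.PathLike) -> None:
    probe_map.rename("gene_id").rename_axis("probe_id").reset_index().to_csv(
        path, sep="\t", index=False
    )


def read_ldh_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["morphology_flag"] = df["morphology_flag"].astype(bool)
    return df


def read_interaction_catalog(path: str | os.PathLike) -> dict[str, list[str]]:
    """TSV chemical, rank, gene_id -> per-chemical ordered interacting genes."""
    df = pd.read_csv(path, sep="\t").sort_values(["chemical", "rank"])
    return {chem: grp["gene_id"].tolist() for chem, grp in df.groupby("chemical", sort=True)}
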