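"""Normalization, per-contrast differential expression, and probe collapse.

Counts are normalized by median-of-ratios size factors. Each treated group
is tested against its matched solvent control (same species/strain and
timepoint) with a Welch t-test on log2(normalized + 1); p-values are BH
adjusted within the contrast and probes with FDR < 10% are differentially
expressed (DEPs). Genes measured by several probes are collapsed to the
probe with the highest total raw count; rodent identifiers can then be
mapped onto a shared (human) namespace through a static ortholog table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientSamplesError, MissingControlError, NormalizationError

log = logging.getLogger(__name__)

DEG_FDR = 0.10


@dataclass(frozen=True)
class Contrast:
    """One treated group vs its matched solvent control."""

    species_strain: str
    chemical: str
    concentration_label: str
    timepoint_h: int

    def key(self) -> str:
        return f"{self.species_strain}|{self.chemical}|{self.concentration_label}|{self.timepoint_h}"


def median_of_ratios_normalize(
    counts: pd.DataFrame, fallback_total_count: bool = False
) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-probe geometric mean over samples, computed on
    probes with all-positive counts; each sample's factor is the median of
    its count/reference ratios over those probes. If no probe is positive in
    every sample, a :class:`NormalizationError` is raised unless
    ``fallback_total_count=True``, in which case total-count scaling is used.
    """
    mat = counts.to_numpy(dtype=float)
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        if not fallback_total_count:
            raise NormalizationError(
                "no probe has all-positive counts; rerun with fallback_total_count=True "
                "to scale by total counts"
            )
        factors = mat.sum(axis=0)
        if (factors <= 0).any():
            raise NormalizationError("sample with zero total counts")
    else:
        sub = mat[allpos]
        logref = np.log(sub).mean(axis=1)
        factors = np.exp(np.median(np.log(sub) - logref[:, None], axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))  # gmean exactly 1
    sf = pd.Series(factors, index=counts.columns, name="size_factor")
    return counts / factors, sf


def test_contrast(
    normalized: pd.DataFrame,
    metadata: pd.DataFrame,
    contrast: Contrast,
    probe_map: pd.Series,
    deg_fdr: float = DEG_FDR,
) -> pd.DataFrame:
    """Welch t-test on log2(norm+1) per probe for one treated-vs-control contrast."""
    meta = metadata[metadata["sample_id"].isin(normalized.columns)]
    stratum = meta[
        (meta["species_strain"] == contrast.species_strain)
        & (meta["timepoint_h"] == contrast.timepoint_h)
    ]
    treated = stratum[
        (stratum["chemical"] == contrast.chemical)
        & (stratum["concentration_label"] == contrast.concentration_label)
    ]
    if treated.empty:
        raise MissingControlError(f"no treated samples for {contrast.key()}")
    solvent = treated["solvent"].iloc[0]
    control = stratum[stratum["chemical"] == f"solvent_{solvent}"]
    if control.empty:
        raise MissingControlError(
            f"no matched solvent control ({solvent}) for {contrast.key()}"
        )
    if len(treated) < 2 or len(control) < 2:
        raise InsufficientSamplesError(
            f"{contrast.key()}: need >=2 replicates per arm "
            f"(treated={len(treated)}, control={len(control)})"
        )

    t_log = np.log2(normalized[treated["sample_id"]].to_numpy() + 1.0)
    c_log = np.log2(normalized[control["sample_id"]].to_numpy() + 1.0)
    log2fc = t_log.mean(axis=1) - c_log.mean(axis=1)
    tstat, pval = stats.ttest_ind(t_log, c_log, axis=1, equal_var=False)
    pval = np.where(np.isnan(pval), 1.0, pval)  # zero-variance degenerate probes
    padj = multipletests(pval, method="fdr_bh")[1]
    is_dep = padj < deg_fdr

    out = pd.DataFrame(
        {
            "probe_id": normalized.index,
            "gene_id": probe_map.reindex(normalized.index).to_numpy(),
            "contrast": contrast.key(),
            "species_strain": contrast.species_strain,
            "chemical": contrast.chemical,
            "concentration_label": contrast.concentration_label,
            "timepoint_h": contrast.timepoint_h,
            "log2fc": log2fc,
            "pvalue": pval,
            "padj": padj,
            "is_dep": is_dep,
            "direction": np.where(
                is_dep, np.where(log2fc > 0, "up", "down"), ""
            ),
        }
    )
    return out.reset_index(drop=True)


def collapse_probes_to_genes(counts: pd.DataFrame, deg: pd.DataFrame) -> pd.DataFrame:
    """Keep one probe per gene: the arg-max of total raw counts over the
    stratum's samples, ties broken by lexicographically smaller probe_id."""
    totals = counts.sum(axis=1)
    n_unmapped = int(deg["gene_id"].isna().sum())
    if n_unmapped:
        log.warning("dropping %d probe records mapped to no gene", n_unmapped)
    mapped = deg.dropna(subset=["gene_id"]).copy()
    mapped["_total"] = totals.reindex(mapped["probe_id"]).to_numpy()
    mapped = mapped.sort_values(
        ["gene_id", "_total", "probe_id"], ascending=[True, False, True]
    )
    collapsed = mapped.drop_duplicates(subset=["gene_id", "contrast"], keep="first")
    return collapsed.drop(columns="_total").reset_index(drop=True)


def map_orthologs(gene_table: pd.DataFrame, mapping: pd.DataFrame) -> pd.DataFrame:
    """Re-key a gene-level table by human identifiers via a static map.

    ``mapping`` has columns ``source_gene, human_gene`` (one-to-at-most-one).
    Unmapped genes are dropped (count in ``result.attrs['n_unmapped']``);
    collisions keep the record with the smaller p-value.
    """
    m = dict(zip(mapping["source_gene"], mapping["human_gene"]))
    out = gene_table.copy()
    out["gene_id"] = out["gene_id"].map(m)
    n_unmapped = int(out["gene_id"].isna().sum())
    out = out.dropna(subset=["gene_id"])
    before = len(out)
    out = out.sort_values(["gene_id", "pvalue"]).drop_duplicates(
        subset=["gene_id", "contrast"] if "contrast" in out.columns else ["gene_id"],
        keep="first",
    )
    n_collisions = before - len(out)
    if n_unmapped or n_collisions:
        log.info(
            "ortholog mapping: %d unmapped dropped, %d collisions resolved by smaller p",
            n_unmapped,
            n_collisions,
        )
    out = out.reset_index(drop=True)
    out.attrs["n_unmapped"] = n_unmapped
    out.attrs["n_collisions"] = n_collisions
    return out
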