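"""Interacting-gene targeted aggregation of enrichment results (ToxPi-style).

Starting from a per-chemical catalog of top interacting genes (curated
chemical-gene interactions, <=10 per chemical), gene sets containing any of
those genes are selected. Within a species/strain, adjusted p-values of
significantly enriched targeted sets are reverse log-scaled onto (0, 1]
(most significant set = 1, non-significant sets = 0), summed per interacting
gene within each treatment group, and the sums scaled to [0, 1] either
*internally* (across genes within one group/timepoint) or *externally*
(across groups/timepoints for one gene). The resulting wide table is the
per-wedge input of a radial (ToxPi) profile.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SIGNIFICANCE = 0.05
P_FLOOR = 1e-300


def select_targeted_sets(
    catalog: Mapping[str, list[str]], gene_sets: Mapping[str, Iterable[str]]
) -> dict[str, list[str]]:
    """Map each interacting gene (union over chemicals) to its containing sets."""
    genes = sorted({g for genes in catalog.values() for g in genes})
    members = {name: set(gs) for name, gs in gene_sets.items()}
    return {
        g: sorted(name for name, gs in members.items() if g in gs) for g in genes
    }


def reverse_log_scale(
    adj_p: pd.Series, alpha: float = SIGNIFICANCE
) -> pd.Series:
    """Reverse-log-scale a pool of adjusted p-values onto [0, 1].

    Significant entries (adj_p < alpha) get ``log10(p) / log10(p_min)`` with
    p_min the pool minimum, so the most significant set scores exactly 1 and
    every significant set scores in (0, 1]; non-significant entries score 0.
    p-values are floored at 1e-300 before the log. An all-non-significant
    (or empty) pool returns all zeros.
    """
    p = adj_p.astype(float).clip(lower=P_FLOOR)
    sig = p < alpha
    out = pd.Series(0.0, index=adj_p.index)
    if sig.any():
        p_min = p[sig].min()
        out[sig] = np.log10(p[sig]) / np.log10(p_min)
    return out


def aggregate_by_gene(
    scaled: pd.Series,
    gene_to_sets: Mapping[str, list[str]],
) -> pd.Series:
    """Sum one group's reverse-log-scaled values over each gene's sets.

    ``scaled`` is indexed by set name (one treatment group's enrichment
    results after scaling). A set shared by several genes contributes its
    value to each of their sums.
    """
    sums = {}
    for gene, sets in gene_to_sets.items():
        present = [s for s in sets if s in scaled.index]
        sums[gene] = float(scaled[present].sum()) if present else 0.0
    return pd.Series(sums, name="raw_sum")


def scale_internal(raw: pd.DataFrame) -> pd.DataFrame:
    """Scale each row (treatment group) by its max over genes; 0-safe."""
    mx = raw.max(axis=1)
    return raw.div(mx.where(mx > 0, 1.0), axis=0)


def scale_external(raw: pd.DataFrame) -> pd.DataFrame:
    """Scale each column (gene) by its max over groups; 0-safe."""
    mx = raw.max(axis=0)
    return raw.div(mx.where(mx > 0, 1.0), axis=1)


def export_toxpi(scores: pd.DataFrame, path: str) -> None:
    """Write the wide groups x genes table as CSV loadable by ToxPi tools."""
    if scores.empty:
        import logging

        logging.getLogger(__name__).warning("exporting empty aggregation table")
    scores.to_csv(path, index_label="treatment_group")
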