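"""Activity-concurrence matrices and Jaccard concordance between chemicals.

Per chemical, enriched gene sets are first filtered to those containing at
least one significant DEG (FDR < 10%) of matching direction, then binarized
(active = enrichment FDR < 5%). For a chemical pair, the 2x2 concurrence
matrix counts sets active for both (n_aa), active for exactly one (n_ai,
n_ia) and inactive for both (n_ii) over the union of the two filtered
lists; a set absent from one chemical's filtered list counts as inactive
for that chemical. Concordance is the Jaccard index

    J = n_aa / (n_aa + n_ai + n_ia)

which deliberately ignores n_ii: agreement on inactivity carries no
information about a shared response. J is undefined (reported missing, not
zero) when no set is active for either chemical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


@dataclass
class ConcurrenceMatrix:
    """2x2 active/inactive agreement counts plus quadrant percentages."""

    n_aa: int
    n_ai: int  # active for A, inactive for B
    n_ia: int  # inactive for A, active for B
    n_ii: int
    universe_size: int
    pair: dict = field(default_factory=dict)

    @property
    def pct(self) -> tuple[float, float, float]:
        """Percent of each active-bearing quadrant out of all active cells."""
        denom = self.n_aa + self.n_ai + self.n_ia
        if denom == 0:
            return (float("nan"),) * 3
        return tuple(100.0 * x / denom for x in (self.n_aa, self.n_ai, self.n_ia))


@dataclass
class JaccardResult:
    jaccard: float
    defined: bool
    pair: dict = field(default_factory=dict)


def filter_sets_with_deg(
    enrichment: pd.DataFrame,
    deg_table: pd.DataFrame,
    gene_sets: Mapping[str, Iterable[str]],
    direction: str,
) -> list[str]:
    """Sets containing >=1 significant DEG of the given direction.

    ``enrichment`` and ``deg_table`` are one chemical's records for a single
    contrast. Activity is not consulted here — an active set with no DEG
    overlap is excluded, an inactive one with overlap is retained.
    """
    degs = set(
        deg_table.loc[
            deg_table["is_dep"] & (deg_table["direction"] == direction), "gene_id"
        ]
    )
    names = enrichment.loc[enrichment["direction"] == direction, "set_name"]
    return [s for s in names if degs & set(gene_sets[s])]


def binarize(enrichment: pd.DataFrame, filtered_sets: Iterable[str]) -> pd.Series:
    """0/1 activity vector over the filtered sets (1 = enrichment FDR < 5%)."""
    sub = enrichment.set_index("set_name").loc[list(filtered_sets)]
    return sub["active"].astype(int)


def concurrence(vec_a: pd.Series, vec_b: pd.Series, pair: dict | None = None) -> ConcurrenceMatrix:
    """Concurrence counts over the union of the two filtered universes."""
    union = vec_a.index.union(vec_b.index)
    a = vec_a.reindex(union, fill_value=0).astype(bool)
    b = vec_b.reindex(union, fill_value=0).astype(bool)
    return ConcurrenceMatrix(
        n_aa=int((a & b).sum()),
        n_ai=int((a & ~b).sum()),
        n_ia=int((~a & b).sum()),
        n_ii=int((~a & ~b).sum()),
        universe_size=len(union),
        pair=pair or {},
    )


def jaccard(matrix: ConcurrenceMatrix) -> JaccardResult:
    """Jaccard index of the concurrence matrix; missing when no set is active."""
    denom = matrix.n_aa + matrix.n_ai + matrix.n_ia
    if denom == 0:
        return JaccardResult(jaccard=float("nan"), defined=False, pair=matrix.pair)
    return JaccardResult(jaccard=matrix.n_aa / denom, defined=True, pair=matrix.pair)


def concordance_grid(
    activity: Mapping[str, pd.Series],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All pairwise Jaccard indices over per-chemical binary activity vectors.

    Returns ``(square, long)``: a symmetric chemical x chemical matrix of J
    (NaN where undefined) and a long table with the underlying concurrence
    counts and quadrant percentages. The diagonal compares a chemical with
    itself (J = 1 whenever it has at least one active set).
    """
    chems = list(activity)
    square = pd.DataFrame(np.nan, index=chems, columns=chems)
    rows = []
    for i, a in enumerate(chems):
        for j, b in enumerate(chems):
            if j < i:
                continue
            cm = concurrence(activity[a], activity[b], pair=dict(chem_a=a, chem_b=b))
            jr = jaccard(cm)
            square.loc[a, b] = jr.jaccard
            square.loc[b, a] = jr.jaccard
            pct = cm.pct
            rows.append(
                dict(
                    chem_a=a, chem_b=b,
                    n_aa=cm.n_aa, n_ai=cm.n_ai, n_ia=cm.n_ia, n_ii=cm.n_ii,
                    universe_size=cm.universe_size,
                    pct_aa=pct[0], pct_ai=pct[1], pct_ia=pct[2],
                    jaccard=jr.jaccard, defined=jr.defined,
                )
            )
    return square, pd.DataFrame(rows)
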