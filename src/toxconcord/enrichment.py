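"""Direction-specific hypergeometric overrepresentation of DEG lists.

For each gene set, the overlap k between the DEG list (n genes) and the set
(m genes within the measured universe of N genes) is scored with the exact
one-sided (upper tail) hypergeometric probability. p-values are BH adjusted
across all sets within one (contrast, direction) and sets with FDR < 5% are
flagged *active* — the binarization that feeds the concordance analysis.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError

SET_FDR = 0.05


def hypergeometric_test(k: int, m: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric mass: P(X >= k) for X ~ Hypergeom(N, m, n).

    ``k`` = overlap (DEGs in set), ``m`` = set size within the universe,
    ``n`` = DEG-list size, ``N`` = universe size.
    """
    if not (0 <= k <= min(m, n) and 0 <= m <= N and 0 <= n <= N):
        raise InvalidInputError(f"inconsistent counts k={k}, m={m}, n={n}, N={N}")
    return float(hypergeom.sf(k - 1, N, m, n))


def enrich(
    deg_table: pd.DataFrame,
    gene_sets: Mapping[str, Iterable[str]],
    direction: str,
    universe: Iterable[str],
    set_fdr: float = SET_FDR,
) -> pd.DataFrame:
    """Overrepresentation of one contrast's DEGs (given direction) in each set.

    ``deg_table`` must be gene-level (post probe collapse) for a single
    contrast. The universe is the measured gene space after collapse; sets
    are intersected with it before sizing. With an empty DEG list all
    p-values are 1 and nothing is active.
    """
    universe = set(universe)
    if not universe:
        raise InvalidInputError("empty universe")
    N = len(universe)
    degs = set(
        deg_table.loc[
            deg_table["is_dep"] & (deg_table["direction"] == direction), "gene_id"
        ]
    ) & universe
    n = len(degs)

    contrast = deg_table["contrast"].iloc[0] if len(deg_table) else ""
    rows = []
    for name in gene_sets:
        members = set(gene_sets[name]) & universe
        m = len(members)
        k = len(members & degs)
        p = hypergeometric_test(k, m, n, N)
        rows.append(
            dict(set_name=name, direction=direction, k=k, m=m, n=n, N=N,
                 p_value=p, contrast=contrast)
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["adj_p"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
        out["active"] = out["adj_p"] < set_fdr
    else:
        out["adj_p"] = np.array([], dtype=float)
        out["active"] = np.array([], dtype=bool)
    return out
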