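"""Sample-exclusion rules and cytotoxicity calls applied before any statistics.

A sample is excluded when its total sequencing depth, or its number of
detected probes (>=1 read), falls more than *k* sample standard deviations
below the respective mean computed across all samples of the same
species/strain (pooled over chemicals and timepoints). Treatment groups left
with fewer than ``min_replicates`` usable wells are dropped entirely. A
treatment group is called cytotoxic when percent LDH release is >= 25 *and*
hepatocyte morphology changes were flagged — both conditions are required.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import InsufficientSamplesError, InvalidInputError

LDH_THRESHOLD = 25.0


@dataclass
class QcReport:
    """Per-sample exclusion flags and per-group replicate accounting."""

    samples: pd.DataFrame  # sample_id, species_strain, group_id, total_depth,
    #                        probes_detected, excluded, exclusion_reasons
    groups: pd.DataFrame  # group_id, n_total, n_excluded, n_remaining, group_dropped
    k_sd: float

    @property
    def kept_sample_ids(self) -> list[str]:
        return self.samples.loc[~self.samples["excluded"], "sample_id"].tolist()


def flag_low_quality_samples(
    counts: pd.DataFrame, metadata: pd.DataFrame, k_sd: float = 2.0
) -> QcReport:
    """Flag samples below the per-stratum depth / detected-probe thresholds.

    Thresholds are ``mean - k_sd * SD`` (sample SD, ddof=1) of each statistic
    over *all* samples of the stratum; comparison is strict ``<`` so ties at
    the threshold are retained. Each criterion is evaluated on its own
    statistic and either suffices for exclusion.
    """
    if (counts.to_numpy() < 0).any():
        raise InvalidInputError("counts must be non-negative")
    meta = metadata.set_index("sample_id")
    depth = counts.sum(axis=0)
    detected = (counts > 0).sum(axis=0)

    rows = []
    for strain, strain_meta in meta.groupby("species_strain", sort=True):
        ids = [s for s in counts.columns if s in strain_meta.index]
        if len(ids) < 3:
            raise InsufficientSamplesError(
                f"stratum {strain!r} has {len(ids)} samples; >=3 required"
            )
        d = depth[ids].to_numpy(dtype=float)
        p = detected[ids].to_numpy(dtype=float)
        thr_depth = d.mean() - k_sd * d.std(ddof=1)
        thr_probes = p.mean() - k_sd * p.std(ddof=1)
        for sid, dv, pv in zip(ids, d, p):
            reasons = []
            if dv < thr_depth:
                reasons.append("low_depth")
            if pv < thr_probes:
                reasons.append("low_probes")
            rows.append(
                dict(
                    sample_id=sid,
                    species_strain=strain,
                    group_id=meta.at[sid, "group_id"],
                    total_depth=int(dv),
                    probes_detected=int(pv),
                    excluded=bool(reasons),
                    exclusion_reasons=";".join(reasons),
                )
            )
    samples = pd.DataFrame(rows)
    return QcReport(samples=samples, groups=_group_table(samples), k_sd=k_sd)


def _group_table(samples: pd.DataFrame) -> pd.DataFrame:
    grp = samples.groupby("group_id", sort=True)
    out = grp.agg(
        n_total=("sample_id", "size"), n_excluded=("excluded", "sum")
    ).reset_index()
    out["n_excluded"] = out["n_excluded"].astype(int)
    out["n_remaining"] = out["n_total"] - out["n_excluded"]
    out["group_dropped"] = False
    return out


def drop_depleted_groups(report: QcReport, min_replicates: int = 2) -> QcReport:
    """Drop whole groups whose surviving replicate count fell below the floor."""
    groups = report.groups.copy()
    groups["group_dropped"] = groups["n_remaining"] < min_replicates
    dropped = set(groups.loc[groups["group_dropped"], "group_id"])

    samples = report.samples.copy()
    in_dropped = samples["group_id"].isin(dropped) & ~samples["excluded"]
    samples.loc[in_dropped, "excluded"] = True
    samples.loc[in_dropped, "exclusion_reasons"] = "depleted_group"
    return replace(report, samples=samples, groups=groups)


def call_cytotoxicity(ldh_table: pd.DataFrame, threshold: float = LDH_THRESHOLD) -> pd.DataFrame:
    """LDH >= threshold AND morphology change -> cytotoxic (conjunction rule)."""
    ldh = np.asarray(ldh_table["ldh_percent"], dtype=float)
    if (ldh < 0).any():
        raise InvalidInputError("negative LDH percent")
    out = ldh_table.copy()
    out["cytotoxic"] = (ldh >= threshold) & out["morphology_flag"].astype(bool)
    return out
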