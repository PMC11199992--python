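"""Seeded synthetic TempO-Seq-style study generator with known ground truth.

Emulates a multi-species primary-hepatocyte screen: several species/strains,
five chemicals (a test chemical, PPARα- and PPARγ-agonist positive controls,
and two cytotoxic positive controls) each at four concentrations plus matched
solvent controls, three treatment durations, and 3-4 replicate wells. Counts
are negative-binomial probe-level reads; a configurable fraction of genes is
measured by two probes. Pathway-level effects are planted as gene modules
whose fold change ramps monotonically with concentration rank, the test
chemical sharing its module with the PPARα agonist so that downstream
concordance analysis has a recoverable truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidConfigurationError

CONCENTRATION_LABELS = ("low", "medium", "medium_high", "high")
CONTROL_LABEL = "control"

#: log2FC multiplier applied at each concentration rank (low..high)
CONCENTRATION_RAMP = (0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class ChemicalPlan:
    """One chemical's concentration grid (4 values, ascending) and solvent."""

    name: str
    concentrations: tuple[float, ...]
    solvent: str = "DMSO"

    def label_of(self, concentration: float) -> str:
        idx = self.concentrations.index(concentration)
        return CONCENTRATION_LABELS[idx]

    @property
    def control_chemical(self) -> str:
        return f"solvent_{self.solvent}"


@dataclass(frozen=True)
class EffectSpec:
    """A planted pathway-level effect for one chemical."""

    set_name: str
    direction: str  # "up" or "down"
    max_log2fc: float


@dataclass
class StudyDesign:
    """Factorial layout: species/strains x chemicals x concentrations x timepoints."""

    species_strains: tuple[str, ...]
    chemicals: tuple[ChemicalPlan, ...]
    timepoints_h: tuple[int, ...] = (12, 24, 72)
    replicates: dict[int, int] = field(default_factory=lambda: {12: 3, 24: 4, 72: 3})

    def validate(self) -> None:
        if not self.species_strains or not self.chemicals:
            raise InvalidConfigurationError("design needs >=1 species/strain and chemical")
        for chem in self.chemicals:
            if len(chem.concentrations) != len(CONCENTRATION_LABELS):
                raise InvalidConfigurationError(
                    f"{chem.name}: exactly {len(CONCENTRATION_LABELS)} concentrations required"
                )
            if len(set(chem.concentrations)) != len(chem.concentrations):
                raise InvalidConfigurationError(f"{chem.name}: concentrations must be distinct")
            if tuple(sorted(chem.concentrations)) != tuple(chem.concentrations):
                raise InvalidConfigurationError(f"{chem.name}: concentrations must ascend")
        for tp in self.timepoints_h:
            n = self.replicates.get(tp, 0)
            if n < 1:
                raise InvalidConfigurationError(f"timepoint {tp} h: replicate count must be >=1")

    @property
    def solvents(self) -> tuple[str, ...]:
        return tuple(sorted({c.solvent for c in self.chemicals}))


def default_design() -> StudyDesign:
    """The full hepatocyte-screen layout (concentrations in µM)."""
    return StudyDesign(
        species_strains=("CD1_mouse", "B6129SF2J_mouse", "SD_rat", "human_pool"),
        chemicals=(
            ChemicalPlan("HFPO-DA", (0.1, 5.0, 50.0, 500.0), solvent="water"),
            ChemicalPlan("GW7647", (0.01, 0.1, 1.0, 10.0)),
            ChemicalPlan("rosiglitazone", (0.01, 0.1, 1.0, 10.0)),
            ChemicalPlan("acetaminophen", (300.0, 1000.0, 3000.0, 10000.0)),
            ChemicalPlan("d-galactosamine", (300.0, 1000.0, 3000.0, 10000.0)),
        ),
    )


def default_effects() -> dict[str, tuple[EffectSpec, ...]]:
    """Planted modules: test chemical shares the PPARα-like module with GW7647."""
    return {
        "HFPO-DA": (
            EffectSpec("PPARA_SIGNALING_LIKE", "up", 4.0),
            EffectSpec("FATTY_ACID_BETA_OXIDATION_LIKE", "up", 4.0),
        ),
        "GW7647": (
            EffectSpec("PPARA_SIGNALING_LIKE", "up", 4.0),
            EffectSpec("FATTY_ACID_BETA_OXIDATION_LIKE", "up", 4.0),
        ),
        "rosiglitazone": (EffectSpec("PPARG_LIPID_STORAGE_LIKE", "up", 3.0),),
        "acetaminophen": (EffectSpec("OXIDATIVE_STRESS_RESPONSE_LIKE", "up", 4.0),),
        "d-galactosamine": (EffectSpec("RRNA_PROCESSING_LIKE", "up", 4.0),),
    }


@dataclass
class GroundTruthConfig:
    """Generator knobs; defaults are the standard study conditions."""

    n_genes: int = 1000
    module_size: int = 30
    multi_probe_fraction: float = 0.2
    effects: dict[str, tuple[EffectSpec, ...]] = field(default_factory=default_effects)
    conc_ramp: tuple[float, ...] = CONCENTRATION_RAMP
    dispersion_range: tuple[float, float] = (0.05, 0.5)
    baseline_log_mean: float = math.log(100.0)
    baseline_log_sd: float = 1.0
    library_size_log_sd: float = 0.15
    #: fold-change attenuation in the human stratum (weak pathway response)
    human_attenuation: float = 0.25
    human_strata: tuple[str, ...] = ("human_pool",)
    n_bad_samples: int = 2
    bad_sample_depth_factor: float = 0.02
    #: cytotoxic groups: (chemical, concentration_label, timepoint) triples;
    #: None -> both cytotoxic-control chemicals at high concentration, 24/72 h
    cytotoxic_groups: tuple[tuple[str, str, int], ...] | None = None

    def validate(self, design: StudyDesign) -> None:
        if self.n_genes < 200:
            raise InvalidConfigurationError("n_genes must be >= 200")
        lo, hi = self.dispersion_range
        if lo <= 0 or hi < lo:
            raise InvalidConfigurationError("dispersion range must be positive")
        if self.module_size < 2:
            raise InvalidConfigurationError("module_size must be >= 2")
        chem_names = {c.name for c in design.chemicals}
        for chem in self.effects:
            if chem not in chem_names:
                raise InvalidConfigurationError(f"effect for unknown chemical {chem!r}")


@dataclass
class GroundTruth:
    """Resolved truth emitted alongside the simulated study."""

    modules: dict[str, list[str]]  # affected set name -> member genes
    effects: dict[str, tuple[EffectSpec, ...]]  # chemical -> planted effects
    gene_namespace: list[str]
    deg_genes: dict[tuple[str, str, int], dict[str, float]]  # (chem, label, tp) -> gene -> lfc
    planted_bad_samples: list[str]
    planted_cytotoxic_groups: list[str]
    group_ids: list[str]
    config: GroundTruthConfig

    def affected_sets(self, chemical: str, direction: str = "up") -> list[str]:
        return [e.set_name for e in self.effects.get(chemical, ()) if e.direction == direction]


def group_id(strain: str, chemical: str, label: str, timepoint_h: int) -> str:
    return f"{strain}|{chemical}|{label}|{timepoint_h}"


def _build_metadata(design: StudyDesign) -> pd.DataFrame:
    rows = []
    for strain in design.species_strains:
        for tp in design.timepoints_h:
            n_rep = design.replicates[tp]
            for solvent in design.solvents:
                chem_name = f"solvent_{solvent}"
                for r in range(1, n_rep + 1):
                    rows.append(
                        dict(
                            sample_id=f"{strain}.{chem_name}.{CONTROL_LABEL}.{tp}h.r{r}",
                            species_strain=strain,
                            chemical=chem_name,
                            concentration=0.0,
                            concentration_label=CONTROL_LABEL,
                            timepoint_h=tp,
                            replicate=r,
                            solvent=solvent,
                            group_id=group_id(strain, chem_name, CONTROL_LABEL, tp),
                        )
                    )
            for chem in design.chemicals:
                for conc in chem.concentrations:
                    label = chem.label_of(conc)
                    for r in range(1, n_rep + 1):
                        rows.append(
                            dict(
                                sample_id=f"{strain}.{chem.name}.{label}.{tp}h.r{r}",
                                species_strain=strain,
                                chemical=chem.name,
                                concentration=conc,
                                concentration_label=label,
                                timepoint_h=tp,
                                replicate=r,
                                solvent=chem.solvent,
                                group_id=group_id(strain, chem.name, label, tp),
                            )
                        )
    return pd.DataFrame(rows)


def _resolve_truth(
    design: StudyDesign, config: GroundTruthConfig, rng: np.random.Generator,
    metadata: pd.DataFrame,
) -> GroundTruth:
    genes = [f"GENE{i:05d}" for i in range(config.n_genes)]
    # carve disjoint modules out of the namespace, in sorted set-name order
    set_names = sorted({e.set_name for specs in config.effects.values() for e in specs})
    needed = len(set_names) * config.module_size
    if needed > config.n_genes:
        raise InvalidConfigurationError("modules do not fit into the gene namespace")
    pool = rng.permutation(config.n_genes)
    modules = {
        name: sorted(genes[g] for g in pool[i * config.module_size:(i + 1) * config.module_size])
        for i, name in enumerate(set_names)
    }

    deg_genes: dict[tuple[str, str, int], dict[str, float]] = {}
    for chem in design.chemicals:
        specs = config.effects.get(chem.name, ())
        for tp in design.timepoints_h:
            for rank, label in enumerate(CONCENTRATION_LABELS):
                planted: dict[str, float] = {}
                for spec in specs:
                    sign = 1.0 if spec.direction == "up" else -1.0
                    lfc = sign * spec.max_log2fc * config.conc_ramp[rank]
                    for g in modules[spec.set_name]:
                        planted[g] = planted.get(g, 0.0) + lfc
                if planted:
                    deg_genes[(chem.name, label, tp)] = planted

    treated_groups = sorted(
        metadata.loc[metadata["concentration_label"] != CONTROL_LABEL, "group_id"].unique()
    )
    all_groups = sorted(metadata["group_id"].unique())

    if config.cytotoxic_groups is None:
        cyto = []
        for gid in treated_groups:
            _strain, chem_name, label, tp = gid.split("|")
            if (
                chem_name in ("acetaminophen", "d-galactosamine")
                and label == "high"
                and int(tp) in (24, 72)
            ):
                cyto.append(gid)
    else:
        cyto = sorted(
            {
                group_id(strain, chem, label, tp)
                for strain in design.species_strains
                for (chem, label, tp) in config.cytotoxic_groups
            }
        )

    sample_ids = metadata["sample_id"].to_numpy()
    n_bad = min(config.n_bad_samples, len(sample_ids))
    bad = sorted(rng.choice(sample_ids, size=n_bad, replace=False).tolist()) if n_bad else []

    return GroundTruth(
        modules=modules,
        effects={k: tuple(v) for k, v in config.effects.items()},
        gene_namespace=genes,
        deg_genes=deg_genes,
        planted_bad_samples=bad,
        planted_cytotoxic_groups=cyto,
        group_ids=all_groups,
        config=config,
    )


def simulate_counts(
    design: StudyDesign,
    config: GroundTruthConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth, pd.Series]:
    """Simulate a full study.

    Returns ``(counts, metadata, truth, probe_map)`` where *counts* is a
    probe x sample integer DataFrame, *metadata* the sample table, *truth*
    the resolved ground truth and *probe_map* a probe_id -> gene_id Series.

    The count model is negative binomial: per-gene baseline mean drawn
    log-normally, per-probe efficiency, per-sample library-size factor, and
    gene-wise dispersion; planted genes have treated means multiplied by
    ``2**(log2FC * ramp[rank])``. Identical arguments give identical output.
    """
    config = config or GroundTruthConfig()
    design.validate()
    config.validate(design)
    rng = np.random.default_rng(seed)

    metadata = _build_metadata(design)
    truth = _resolve_truth(design, config, rng, metadata)
    genes = truth.gene_namespace

    n_multi = int(round(config.multi_probe_fraction * config.n_genes))
    multi = set(rng.choice(config.n_genes, size=n_multi, replace=False).tolist())
    probe_ids, probe_gene_idx = [], []
    for gi, gene in enumerate(genes):
        n_probes = 2 if gi in multi else 1
        for p in range(1, n_probes + 1):
            probe_ids.append(f"{gene}_P{p}")
            probe_gene_idx.append(gi)
    probe_gene_idx = np.asarray(probe_gene_idx)
    probe_map = pd.Series([genes[i] for i in probe_gene_idx], index=pd.Index(probe_ids, name="probe_id"), name="gene_id")

    gene_mean = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)
    probe_eff = rng.lognormal(0.0, 0.3, len(probe_ids))
    dispersion = rng.uniform(*config.dispersion_range, config.n_genes)
    lib = rng.lognormal(0.0, config.library_size_log_sd, len(metadata))

    base_mu = gene_mean[probe_gene_idx] * probe_eff  # per probe
    gene_pos = {g: i for i, g in enumerate(genes)}
    bad = set(truth.planted_bad_samples)

    mu = np.empty((len(probe_ids), len(metadata)))
    for j, row in enumerate(metadata.itertuples(index=False)):
        col = base_mu * lib[j]
        key = (row.chemical, row.concentration_label, row.timepoint_h)
        planted = truth.deg_genes.get(key)
        if planted:
            atten = (
                config.human_attenuation
                if row.species_strain in config.human_strata
                else 1.0
            )
            for g, lfc in planted.items():
                col[probe_gene_idx == gene_pos[g]] *= 2.0 ** (lfc * atten)
        if row.sample_id in bad:
            col = col * config.bad_sample_depth_factor
        mu[:, j] = col

    r = 1.0 / dispersion[probe_gene_idx]
    p = r[:, None] / (r[:, None] + mu)
    counts = rng.negative_binomial(r[:, None], p)
    counts_df = pd.DataFrame(counts, index=pd.Index(probe_ids, name="probe_id"),
                             columns=metadata["sample_id"].tolist())
    return counts_df, metadata, truth, probe_map


def emit_gene_sets(
    truth: GroundTruth, n_decoy_sets: int, seed: int = 0
) -> dict[str, list[str]]:
    """Affected modules plus size-matched decoy sets (GMT-ready dict)."""
    if n_decoy_sets < 0:
        raise InvalidConfigurationError("n_decoy_sets must be >= 0")
    for name, members in truth.modules.items():
        if len(members) < 2:
            raise InvalidConfigurationError(f"affected set {name} has <2 genes")
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {name: list(m) for name, m in sorted(truth.modules.items())}
    sizes = [len(m) for m in truth.modules.values()]
    ns = np.asarray(truth.gene_namespace)
    for d in range(1, n_decoy_sets + 1):
        size = int(rng.choice(sizes))
        members = sorted(rng.choice(ns, size=size, replace=False).tolist())
        sets[f"DECOY_SET_{d:03d}"] = members
    return sets


def emit_interaction_catalog(truth: GroundTruth, n_top: int = 10) -> dict[str, list[str]]:
    """Per-chemical top interacting genes (emulates a curated chemical-gene
    interaction list): the first ``n_top`` members of the chemical's planted
    modules, in module order."""
    catalog: dict[str, list[str]] = {}
    for chem, specs in sorted(truth.effects.items()):
        genes: list[str] = []
        for spec in specs:
            for g in truth.modules[spec.set_name]:
                if g not in genes:
                    genes.append(g)
                if len(genes) >= n_top:
                    break
            if len(genes) >= n_top:
                break
        catalog[chem] = genes
    return catalog


def emit_ldh_table(truth: GroundTruth) -> pd.DataFrame:
    """Per-group LDH release and morphology flags, cytotoxic groups planted."""
    cyto = set(truth.planted_cytotoxic_groups)
    rows = [
        dict(
            group_id=gid,
            ldh_percent=42.0 if gid in cyto else 6.0,
            morphology_flag=gid in cyto,
        )
        for gid in truth.group_ids
    ]
    return pd.DataFrame(rows)


def reduced_design(
    n_strains: int = 1,
    chemicals: tuple[str, ...] | None = None,
    timepoints_h: tuple[int, ...] = (24,),
) -> StudyDesign:
    """A cut-down layout (fewer strata/timepoints) for fast exploratory runs."""
    full = default_design()
    chems = tuple(
        c for c in full.chemicals if chemicals is None or c.name in chemicals
    )
    return replace(
        full,
        species_strains=full.species_strains[:n_strains],
        chemicals=chems,
        timepoints_h=timepoints_h,
        replicates={tp: full.replicates[tp] for tp in timepoints_h},
    )
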