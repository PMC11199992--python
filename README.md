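# toxconcord

Transcriptomic mode-of-action (MOA) concordance analysis for in vitro
toxicogenomics screens.

## The problem

A recurring question in chemical risk assessment is whether a test chemical
acts through the same mode of action as a well-characterized reference
compound. A powerful in vitro design treats primary hepatocytes from
several species/strains with the test chemical and with mechanistic
positive controls — e.g. a PPARα agonist, a PPARγ agonist, and overtly
cytotoxic agents — across a concentration grid and several exposure
durations, then asks: *whose pathway-level transcriptomic response does the
test chemical resemble?*

`toxconcord` implements that analysis as a tested, reusable pipeline over
probe-level count matrices (TempO-Seq style):

1. **Sample QC** — exclude samples whose sequencing depth or detected-probe
   count falls more than 2 SD below the stratum mean; drop groups left with
   too few replicates; call cytotoxicity (LDH release ≥ 25% **and**
   morphology change).
2. **Differential expression** — median-of-ratios normalization, Welch
   t-test on log2(norm+1) per treated-vs-solvent-control contrast,
   Benjamini–Hochberg FDR; probes with FDR < 10% are differentially
   expressed; multi-probe genes collapse to the highest-count probe.
3. **Gene-set enrichment** — exact upper-tail hypergeometric
   overrepresentation of up- and down-regulated DEG lists; sets with
   FDR < 5% are *active*.
4. **Concordance** — per chemical, keep sets containing ≥ 1 DEG, binarize
   activity, build the 2×2 concurrence matrix over the union universe, and
   score each chemical pair with the Jaccard index

   `J = n_aa / (n_aa + n_ai + n_ia)`

   where `n_aa` counts sets active for both chemicals and `n_ai`/`n_ia`
   sets active for exactly one. Sets inactive for both are deliberately
   ignored: shared silence is not shared response.
5. **Interacting-gene aggregation** — reverse-log-scale adjusted p-values
   of significant sets containing curated chemical-interacting genes
   (`s = log10 p / log10 p_min`), sum per gene, and scale to [0, 1]
   internally (within a treatment group) or externally (across groups) for
   ToxPi-style radial profiles.
6. **Benchmark concentrations (BMC)** — Williams-type monotone trend
   prefilter (permutation p < 0.05), a nine-model least-squares suite
   (linear, power, hill, poly2/3, exponential 2–5) with a benchmark
   response of 1 SD, range and confidence-interval filters, and pathway
   functional classification (two-tailed Fisher's exact < 0.1) with median
   BMCs.

A seeded synthetic-data generator emulates the full factorial study design
(species/strains × chemicals × 4 concentrations + solvent controls ×
timepoints × replicates) with negative-binomial counts and planted pathway
modules, so the entire pipeline runs — and is tested against known ground
truth — without any external download.

## Worked example

Simulate one rodent stratum at 24 h, run differential expression and
enrichment at the medium-high concentration, and compute the concordance
grid:

```python
from toxconcord import synthetic, dge, enrichment, concordance

design = synthetic.reduced_design(n_strains=1, timepoints_h=(24,))
cfg = synthetic.GroundTruthConfig(n_genes=300, module_size=25)
counts, meta, truth, pmap = synthetic.simulate_counts(design, cfg, seed=7)
gene_sets = synthetic.emit_gene_sets(truth, n_decoy_sets=25, seed=8)
norm, _ = dge.median_of_ratios_normalize(counts)

activity = {}
for chem in design.chemicals:
    c = dge.Contrast("CD1_mouse", chem.name, "medium_high", 24)
    table = dge.collapse_probes_to_genes(counts, dge.test_contrast(norm, meta, c, pmap))
    enr = enrichment.enrich(table, gene_sets, "up", table["gene_id"].unique().tolist())
    kept = concordance.filter_sets_with_deg(enr, table, gene_sets, "up")
    activity[chem.name] = concordance.binarize(enr, kept)

square, long = concordance.concordance_grid(activity)
print(square.round(2))
```

Output:

```
                 HFPO-DA  GW7647  rosiglitazone  acetaminophen  d-galactosamine
HFPO-DA              1.0     1.0            0.0            0.0              0.0
GW7647               1.0     1.0            0.0            0.0              0.0
rosiglitazone        0.0     0.0            1.0            0.0              0.0
acetaminophen        0.0     0.0            0.0            1.0              0.0
d-galactosamine      0.0     0.0            0.0            0.0              1.0
```

The test chemical (HFPO-DA) and the PPARα agonist (GW7647) share their
planted pathway modules, so their active gene sets coincide (J = 1.0) while
every other pair is disjoint (J = 0.0) — the generator's ground truth
recovered end to end. For HFPO-DA the two planted modules are the active
sets (enrichment FDR 2.0e-09 and 4.6e-07 here, 26 up-DEGs).

The same run is available from the shell:

```bash
toxconcord run-all --seed 7 --outdir run
# or stage by stage:
toxconcord simulate --seed 7 --outdir run
toxconcord qc --outdir run
toxconcord dge --outdir run
toxconcord enrich --outdir run
toxconcord concord --outdir run
toxconcord aggregate --outdir run
toxconcord bmc --outdir run
```

`run/manifest.json` records every output file, threshold, and methodological
disclosure; identical config + seed gives byte-identical outputs.

## Layout

- `src/toxconcord/synthetic.py` — study design, ground truth, NB count simulator
- `src/toxconcord/qc.py` — exclusion rules, group depletion, cytotoxicity calls
- `src/toxconcord/dge.py` — normalization, contrasts, probe collapse, orthologs
- `src/toxconcord/enrichment.py` — hypergeometric overrepresentation
- `src/toxconcord/concordance.py` — concurrence matrices, Jaccard grids
- `src/toxconcord/aggregation.py` — targeted-set ToxPi-style aggregation
- `src/toxconcord/bmc.py` — Williams prefilter, model suite, BMC filters
- `src/toxconcord/pipeline.py`, `cli.py` — orchestration and shell interface
- `docs/methods.md` — models, assumptions, numerical choices, limitations
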