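# Methods

This note documents the models, assumptions, parameter choices and known
limitations of each pipeline stage, in the order data flows through them.

## Synthetic study generator

**What it emulates.** A factorial primary-hepatocyte screen: by default 4
species/strains (two wild-type mouse strains, rat, pooled human), 5
chemicals — the test chemical (HFPO-DA, water solvent) plus PPARα-agonist
(GW7647), PPARγ-agonist (rosiglitazone) and two cytotoxic positive controls
(acetaminophen, d-galactosamine), all in DMSO — each at 4 concentrations
labeled low/medium/medium-high/high, with matched solvent controls, at
12/24/72 h with 3/4/3 replicate wells. Concentration grids: HFPO-DA
0.1/5/50/500 µM; GW7647 and rosiglitazone 0.01/0.1/1/10 µM; acetaminophen
and d-galactosamine 0.3/1/3/10 mM.

**Count model.** Probe-level reads are negative binomial. Per-gene baseline
means are log-normal (median 100 reads, log-SD 1.0 — a plausible spread for
a targeted probe-per-gene assay at a few million reads per sample, scaled
down); each probe gets a log-normal efficiency factor (log-SD 0.3); 20% of
genes carry two probes; per-sample library-size factors are log-normal
(log-SD 0.15); gene-wise dispersion is uniform on [0.05, 0.5], the range
conventionally seen in bulk count data. Real per-group biological variance
of hepatocyte cultures is not published for this design, so dispersion is
an explicit knob, not a claim of realism.

**Planted truth.** Pathway effects are disjoint gene modules (default 30
genes at the full design, 25 in the reduced test design). The test
chemical and the PPARα agonist share two modules (PPARα-signaling-like and
fatty-acid-β-oxidation-like, both max log2FC 4.0); rosiglitazone (3.0),
acetaminophen (4.0) and d-galactosamine (4.0) each get a distinct module.
These magnitudes reflect the strong induction of PPARα target pathways
reported for such screens (top pathways enriched at p ≪ 1e-10; individual
targets induced 10–100×); with 3–4 replicates and the dispersion range
above, markedly smaller effects would leave the planted pathways largely
undetectable — a different study than the one emulated. Planted log2FC
ramps with concentration rank as 0.25/0.5/0.75/1.0 of the maximum, making
|effect| non-decreasing in concentration. The human stratum's fold changes
are attenuated ×0.25, mirroring the much weaker pathway response of pooled
human hepatocytes. Two samples are planted with depth reduced ×0.02
(guaranteed QC failures), and the cytotoxic-control chemicals are flagged
cytotoxic (LDH 42%, morphology change) at high concentration, 24/72 h.

**What passing tests show.** Recovery results certify the pipeline's
statistics under NB sampling with known truth; they do not certify
performance on real data with correlated genes, batch effects, or
probe-specific biases, none of which are simulated.

**Determinism.** One `numpy.random.Generator` seeded from the single run
seed drives every draw in a fixed iteration order; identical
(design, config, seed) gives byte-identical artifacts.

## Sample QC

Per species/strain (pooled over chemicals and timepoints), a sample is
excluded if its total depth or its detected-probe count (≥ 1 read) is
below `mean − 2·SD` of that statistic across all the stratum's samples.
SD uses the sample (n−1) denominator; comparison is strict `<`, so ties at
the threshold are retained; the rule is applied once (no re-iteration on
the post-exclusion set). Groups left with fewer than 2 usable replicates
are dropped entirely (`min_replicates` configurable). Cytotoxicity is the
conjunction LDH ≥ 25% **and** a morphology flag — either alone is
insufficient. Morphology is an input flag; no image analysis is performed.

## Differential expression (documented stand-in)

The reference analysis for this kind of data is a negative-binomial GLM
(DESeq2). Reimplementing its internals (dispersion shrinkage, Cook's
filtering, independent filtering) is out of scope; the module implements a
transparent stand-in:

- **Normalization** — median-of-ratios: reference = per-probe geometric
  mean over samples (all-positive probes only); size factor = median ratio;
  factors rescaled to geometric mean exactly 1. If no probe is positive
  everywhere, an explicit error suggests `fallback_total_count=True`.
- **Testing** — Welch (unequal-variance) t-test on `log2(norm + 1)` per
  probe, treated vs matched solvent control (same stratum and timepoint).
  The pseudocount avoids −∞ at zero counts. Zero-variance-identical probes
  get p = 1.
- **Multiplicity** — BH within each contrast (one chemical × concentration
  × timepoint), matching per-comparison results behavior; DEP ⇔ adjusted
  p < 0.10 strictly.

All downstream calibration (DEG recovery, enrichment activity, concordance
patterns) is against this stand-in on synthetic data. With 4 replicates,
dispersion 0.05 and a planted log2FC of 2, the stand-in recovers the gene
as a DEP with estimated log2FC within ±0.5 in ≥ 95% of seeded runs.

Probe collapse keeps, per gene, the probe with the highest total raw count
over the stratum's samples (ties → lexicographically smaller probe id).
Ortholog mapping onto a shared namespace is a static one-to-at-most-one
table; unmapped genes are dropped and counted, collisions keep the smaller
p-value. The simulator uses a single shared gene namespace across species,
so the identity map suffices there.

## Enrichment

One-sided (upper-tail) exact hypergeometric overrepresentation:
`p = Σ_{i≥k} C(m,i)·C(N−m,n−i)/C(N,n)` with N = measured genes after
collapse (not the genome), m = set∩universe, n = DEG list, k = overlap.
Up- and down-regulated DEG lists are tested separately; BH across sets
within (contrast, direction); *active* ⇔ adjusted p < 0.05 strictly. The
test is verified exhaustively against enumeration and one-sided Fisher's
exact for all N ≤ 12.

## Concordance

Per chemical, enriched sets are first filtered to those containing ≥ 1
matching-direction DEG, then binarized on the active flag. For a pair, the
concurrence universe is the **union** of the two filtered lists (a set
missing from one list counts inactive for that chemical); the choice
affects only `n_ii`, which the Jaccard index ignores. Quadrant percentages
are taken out of the active-bearing cells (`n_aa + n_ai + n_ia`). J is
undefined — reported missing, never 0 — when that denominator is zero,
avoiding an assertion of similarity from silence. The default grid uses
upregulated sets at the medium-high concentration; a named `mixed` policy
substitutes the medium concentration for the cytotoxic controls (whose
medium-high response is confounded by cytotoxicity at later timepoints).
Direction is selectable. Alternative indices (Dice, Ochiai) are not
implemented.

## Interacting-gene aggregation

Gene sets containing any catalog gene (≤ 10 per chemical, emulating
curated chemical-gene interaction lists) are selected. Reverse-log
scaling: `s = log10(p) / log10(p_min)` over the pool of significant
(adjusted p < 0.05) targeted records across all treatment groups and
timepoints within a species/strain; non-significant records get 0;
p floored at 1e-300; ties at the minimum all map to 1. The formula is
linear in log-p and satisfies the intended constraints (s ∈ (0,1],
most-significant = 1, non-significant = 0); the pool definition (targeted
sets only, per-stratum) is a documented choice recorded in the manifest.
Internal scaling divides each group's gene sums by the group maximum;
external scaling divides each gene's sums by its maximum over groups; an
all-zero group/gene stays zero. Both scalings are invariant to positive
rescaling of the raw sums.

## Benchmark concentrations

- **Trend prefilter.** A Williams-type statistic: the isotonic
  (pool-adjacent-violators) amalgamated mean of the top dose group — which
  at the top position equals the extremal weighted suffix mean of the
  dose-group means — minus the control mean, over a pooled-variance
  standard error; both directions, take the larger. p-values come from
  seeded label permutations, `p = (1 + #{T* ≥ T}) / (1 + B)`, rather than
  tabulated critical values: reproducible at arbitrary group counts and
  verified to hold its nominal level (type-I rate within 2 SE of 0.05 over
  1000 null genes at B = 2000). All-constant genes get p = 1. The
  prefilter p is deliberately unadjusted, and no fold-change filter is
  applied.
- **Model suite.** linear, power, hill, poly2, poly3, and exponential
  models 2–5, least squares under constant variance
  (`scipy.optimize.curve_fit`, bounded shape parameters; power/exponent
  exponents in [0.1, 8], hill coefficient in [0.5, 18]). Lack-of-fit is a
  chi-square of the model RSS against the saturated group-means model.
  Winner = lowest AIC among converged fits (ties → fixed model order); the
  exact nested-ladder selection of dedicated BMC software is not
  reproduced.
- **BMC.** The smallest concentration where the fitted curve departs from
  its modeled control mean by `BMR = 1 × σ` (σ = the model's residual SD
  unless supplied), located by sign-change bracketing on a dense grid up to
  100× the top concentration and polished with Brent's method
  (tolerance 1e-14; the linear closed form σ/|b| is reproduced to 1e-6, and
  BMC is exactly scale-equivariant in concentration).
- **BMCL/BMCU.** Approximate 95% profile likelihood: candidate BMC values
  on a log grid walked outward from the estimate are accepted while
  `n·ln(RSS_b/RSS_min) ≤ χ²₁(0.95)`, with the constrained RSS obtained by a
  penalized Nelder–Mead refit. Grid resolution (8 points per side over ±2
  decades) trades sharpness of the bound for speed; bounds always bracket
  the estimate and widen with noise.
- **Filters.** Status precedence: `poor_fit` (fit p < 0.1) >
  `below_range` (BMC > 10-fold below the lowest tested concentration) >
  `above_range` (BMC above the highest, or no finite BMC — e.g. zero-slope
  genes) > `wide_ci` (BMC/BMCL > 20, BMCU/BMC > 20, or BMCU/BMCL > 40) >
  `pass`. The CI rules apply to functional classification and can be
  disabled.
- **Pathway classification.** Per set, two-tailed Fisher's exact on
  passing-vs-measured genes; sets with p < 0.1 and ≥ 1 passing gene are
  reported with the median BMC over their passing genes, plus
  accumulation-plot data (sorted medians with cumulative rank).

## Pipeline and problem sizes

`run_all` executes simulate → qc → dge → enrich → concordance → aggregate
→ bmc, writing TSV/CSV/GMT artifacts and a JSON manifest (stages, files,
thresholds, disclosures). Default thresholds: DEP FDR 0.10, set FDR 0.05,
LDH 25%, k_sd 2, min_replicates 2, trend α 0.05, Fisher two-tail 0.1,
fit p 0.1. The default run simulates one rodent stratum at 24 h with 300
genes, 30 decoy sets, 500 trend permutations and a 40-gene BMC cap per
chemical — sizes chosen so a complete run with full BMC profiling finishes
in well under a minute on a laptop core; the generator's biological
parameters are unchanged by these size knobs, and all of them are config
fields. PCA reporting uses log2(norm+1), two components, with each
component's sign fixed so its largest-|loading| feature is positive.

## Known limitations

- The DE stand-in is not a count-model GLM; its p-values on real
  low-count data will be conservative relative to DESeq2, and no claim of
  numerical agreement with DESeq2 is made.
- The generator draws genes independently: no co-expression, batch
  structure, or probe-sequence bias.
- Ortholog handling assumes a curated one-to-at-most-one table; paralog
  expansion is out of scope.
- Profile-likelihood bounds are grid-resolution-limited and can be
  slightly conservative (wide) for flat likelihoods.
- Upstream-regulator prediction and rank-based (GSEA-style) enrichment are
  out of scope.
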