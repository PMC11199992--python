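"""Normalization, contrast testing, BH, probe collapse, ortholog mapping."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from toxconcord import dge, synthetic
from toxconcord.errors import MissingControlError, NormalizationError


def _meta(samples, chemical, label, strain="m", tp=24, solvent="water"):
    rows = []
    for i, s in enumerate(samples):
        rows.append(
            dict(sample_id=s, species_strain=strain, chemical=chemical,
                 concentration=0.0 if label == "control" else 1.0,
                 concentration_label=label, timepoint_h=tp, replicate=i + 1,
                 solvent=solvent, group_id=f"{strain}|{chemical}|{label}|{tp}")
        )
    return pd.DataFrame(rows)


class TestNormalization:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]},
                              index=["P1", "P2", "P3"])
        _norm, sf = dge.median_of_ratios_normalize(counts)
        assert np.allclose(sf, 1.0)

    def test_doubled_sample_ratio_two_gmean_one(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]},
                              index=["P1", "P2", "P3"])
        norm, sf = dge.median_of_ratios_normalize(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0, abs=1e-6)
        # normalized matrices coincide
        assert np.allclose(norm["a"], norm["b"])

    def test_single_sample_factor_one(self):
        counts = pd.DataFrame({"a": [5, 7, 9]}, index=["P1", "P2", "P3"])
        _norm, sf = dge.median_of_ratios_normalize(counts)
        assert sf["a"] == pytest.approx(1.0)

    def test_no_all_positive_probe_raises_with_fallback_hint(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]}, index=["P1", "P2"])
        with pytest.raises(NormalizationError, match="fallback_total_count"):
            dge.median_of_ratios_normalize(counts)
        _norm, sf = dge.median_of_ratios_normalize(counts, fallback_total_count=True)
        assert np.allclose(sf, 1.0)  # equal totals


class TestContrast:
    def _paired_data(self, rng, n_probes=40, delta=0.0):
        treated = rng.poisson(100, size=(n_probes, 4))
        control = rng.poisson(100, size=(n_probes, 4))
        counts = pd.DataFrame(
            np.hstack([treated, control]),
            index=[f"GENE{i:03d}_P1" for i in range(n_probes)],
            columns=[f"t{i}" for i in range(4)] + [f"c{i}" for i in range(4)],
        )
        meta = pd.concat(
            [_meta([f"t{i}" for i in range(4)], "X", "high"),
             _meta([f"c{i}" for i in range(4)], "solvent_water", "control")],
            ignore_index=True,
        )
        pmap = pd.Series([p.split("_")[0] for p in counts.index],
                         index=counts.index, name="gene_id")
        return counts, meta, pmap

    def test_identical_arms_give_zero_lfc_no_deps(self):
        rng = np.random.default_rng(0)
        counts, meta, pmap = self._paired_data(rng)
        counts[[f"t{i}" for i in range(4)]] = counts[[f"c{i}" for i in range(4)]].to_numpy()
        table = dge.test_contrast(counts.astype(float), meta,
                                  dge.Contrast("m", "X", "high", 24), pmap)
        assert np.allclose(table["log2fc"], 0.0)
        assert not table["is_dep"].any()
        assert (table["pvalue"] == 1.0).all()

    def test_swapping_arms_negates_log2fc(self):
        rng = np.random.default_rng(1)
        counts, meta, pmap = self._paired_data(rng)
        fwd = dge.test_contrast(counts.astype(float), meta,
                                dge.Contrast("m", "X", "high", 24), pmap)
        swapped = meta.copy()
        swapped["chemical"] = swapped["chemical"].map(
            {"X": "solvent_water", "solvent_water": "X"})
        swapped["concentration_label"] = swapped["concentration_label"].map(
            {"high": "control", "control": "high"})
        rev = dge.test_contrast(counts.astype(float), swapped,
                                dge.Contrast("m", "X", "high", 24), pmap)
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])

    def test_missing_control_raises(self):
        rng = np.random.default_rng(2)
        counts, meta, pmap = self._paired_data(rng)
        meta = meta[meta["chemical"] == "X"]
        with pytest.raises(MissingControlError):
            dge.test_contrast(counts.astype(float), meta,
                              dge.Contrast("m", "X", "high", 24), pmap)

    def test_planted_gene_detected_across_seeds(self):
        """lfc=2 at dispersion 0.05, n=4/arm: DEP with lfc within +-0.5 in
        >=95% of 100 seeded simulations (calibration of the t-test stand-in)."""
        design = synthetic.StudyDesign(
            species_strains=("m",),
            chemicals=(synthetic.ChemicalPlan("X", (0.1, 1.0, 10.0, 100.0), "water"),),
            timepoints_h=(24,),
            replicates={24: 4},
        )
        hits = 0
        for seed in range(100):
            cfg = synthetic.GroundTruthConfig(
                n_genes=200, module_size=20,
                effects={"X": (synthetic.EffectSpec("M", "up", 2.0),)},
                dispersion_range=(0.05, 0.05), n_bad_samples=0,
            )
            counts, meta, truth, pmap = synthetic.simulate_counts(design, cfg, seed=seed)
            norm, _sf = dge.median_of_ratios_normalize(counts)
            table = dge.test_contrast(norm, meta, dge.Contrast("m", "X", "high", 24), pmap)
            table = table.set_index("probe_id")
            # best-measured probe of the module's best-measured gene
            probes = pmap.index[pmap.isin(truth.modules["M"])]
            totals = counts.loc[probes].sum(axis=1)
            probe = totals.idxmax()
            row = table.loc[probe]
            if row["is_dep"] and abs(row["log2fc"] - 2.0) <= 0.5:
                hits += 1
        assert hits >= 95

    def test_bh_adjustment_hand_values(self):
        """[0.01, 0.02, 0.03] -> step-up [0.03, 0.03, 0.03]."""
        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.03])


class TestCollapse:
    def _deg(self, probes, genes):
        return pd.DataFrame(
            dict(probe_id=probes, gene_id=genes, contrast="k",
                 log2fc=0.0, pvalue=0.5, padj=0.5, is_dep=False, direction="")
        )

    def test_argmax_probe_retained(self):
        counts = pd.DataFrame({"s1": [40, 100], "s2": [60, 150]},
                              index=["G1_P1", "G1_P2"])
        deg = self._deg(["G1_P1", "G1_P2"], ["G1", "G1"])
        out = dge.collapse_probes_to_genes(counts, deg)
        assert out["probe_id"].tolist() == ["G1_P2"]  # totals 100 vs 250

    def test_tie_broken_lexicographically(self):
        counts = pd.DataFrame({"s1": [125, 125], "s2": [125, 125]},
                              index=["G1_P2", "G1_P1"])
        deg = self._deg(["G1_P2", "G1_P1"], ["G1", "G1"])
        out = dge.collapse_probes_to_genes(counts, deg)
        assert out["probe_id"].tolist() == ["G1_P1"]

    def test_single_probe_gene_identity_and_unmapped_dropped(self):
        counts = pd.DataFrame({"s1": [10, 20]}, index=["G1_P1", "XX_P1"])
        deg = self._deg(["G1_P1", "XX_P1"], ["G1", None])
        out = dge.collapse_probes_to_genes(counts, deg)
        assert out["probe_id"].tolist() == ["G1_P1"]

    def test_one_record_per_gene_with_max_total(self, small_study):
        counts, _meta, _truth, pmap = small_study
        deg = self._deg(list(counts.index), pmap[counts.index].tolist())
        out = dge.collapse_probes_to_genes(counts, deg)
        assert out["gene_id"].is_unique
        totals = counts.sum(axis=1)
        for row in out.itertuples():
            gene_probes = pmap.index[pmap == row.gene_id]
            assert totals[row.probe_id] == totals[gene_probes].max()


class TestOrthologs:
    def _table(self, genes, pvals):
        return pd.DataFrame(
            dict(probe_id=[g + "_P1" for g in genes], gene_id=genes,
                 contrast="k", pvalue=pvals)
        )

    def test_empty_mapping_drops_everything(self):
        table = self._table(["A", "B"], [0.1, 0.2])
        out = dge.map_orthologs(table, pd.DataFrame(columns=["source_gene", "human_gene"]))
        assert len(out) == 0
        assert out.attrs["n_unmapped"] == 2

    def test_identity_mapping_is_identity(self):
        table = self._table(["A", "B"], [0.1, 0.2])
        mapping = pd.DataFrame(dict(source_gene=["A", "B"], human_gene=["A", "B"]))
        out = dge.map_orthologs(table, mapping)
        pd.testing.assert_frame_equal(
            out.sort_values("gene_id").reset_index(drop=True),
            table.sort_values("gene_id").reset_index(drop=True),
        )

    def test_collision_keeps_smaller_p(self):
        table = self._table(["A", "B"], [0.20, 0.01])
        mapping = pd.DataFrame(dict(source_gene=["A", "B"], human_gene=["H", "H"]))
        out = dge.map_orthologs(table, mapping)
        assert len(out) == 1
        assert out["pvalue"].iloc[0] == 0.01
        assert out.attrs["n_collisions"] == 1
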