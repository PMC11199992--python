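"""Shared fixtures: small synthetic studies generated at test time."""

from __future__ import annotations

import pytest

from toxconcord import dge, synthetic


@pytest.fixture(scope="session")
def small_design() -> synthetic.StudyDesign:
    """One rodent stratum, all five chemicals, 24 h only (4 replicates)."""
    return synthetic.reduced_design(n_strains=1, timepoints_h=(24,))


@pytest.fixture(scope="session")
def small_truth_config() -> synthetic.GroundTruthConfig:
    return synthetic.GroundTruthConfig(n_genes=300, module_size=25)


@pytest.fixture(scope="session")
def small_study(small_design, small_truth_config):
    """(counts, metadata, truth, probe_map) for a fixed seed."""
    return synthetic.simulate_counts(small_design, small_truth_config, seed=11)


@pytest.fixture(scope="session")
def small_gene_sets(small_study):
    _counts, _meta, truth, _pmap = small_study
    return synthetic.emit_gene_sets(truth, n_decoy_sets=25, seed=12)


@pytest.fixture(scope="session")
def small_normalized(small_study):
    counts, _meta, _truth, _pmap = small_study
    norm, sf = dge.median_of_ratios_normalize(counts)
    return norm, sf
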