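"""Shared fixtures: one small clean synthetic dataset reused across modules."""

import pytest

from gbscoal import assembly, pipeline, simulate


@pytest.fixture(scope="session")
def clean_model():
    return simulate.SpeciesTreeModel.from_newick(
        "(((A:1,B:1):1,C:2):1,D:3);", samples_per_species=2, ploidy=2)


@pytest.fixture(scope="session")
def clean_truth_reads(clean_model):
    cfg = simulate.SimulationConfig(
        n_loci=40, seq_error=0.0, mut_rate=0.004, depth_mean=20,
        depth_dispersion=100, seed=3, replicates=("A_0",))
    truth, reads = simulate.simulate_dataset(clean_model, cfg)
    return truth, reads


@pytest.fixture(scope="session")
def clean_read_sets(clean_truth_reads):
    _, reads = clean_truth_reads
    merged, unmerged, stats = pipeline.prepare_read_sets(reads)
    return merged, unmerged, stats


@pytest.fixture(scope="session")
def clean_params():
    return assembly.AssemblyParams(d=6, n=8, c=0.88, h=99, pl=2, mr=2,
                                   min_sample_coverage=0.25, error_rate=0.001)


@pytest.fixture(scope="session")
def clean_locus_sets(clean_read_sets, clean_params):
    merged, unmerged, _ = clean_read_sets
    return pipeline.assemble_read_sets(merged, unmerged, clean_params)
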