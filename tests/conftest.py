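"""Shared fixtures: hand-built gene models and simulated datasets."""

import pandas as pd
import pytest
from hypothesis import settings

import retseq as r

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def three_exon_model() -> r.GeneModel:
    """One gene with a middle (cassette) exon: exons of 100 bp each."""
    return r.GeneModel(
        gene_id="G1",
        transcript_id="T1",
        chrom="chr1",
        strand="+",
        exons=((100, 200), (300, 400), (500, 600)),
    )


@pytest.fixture(scope="session")
def small_dataset() -> r.SimulatedDataset:
    """A small synthetic dataset shared by read-only unit tests."""
    return r.simulate_dataset(r.SimConfig(n_transcripts=300, n_cassette_events=20, seed=1))


@pytest.fixture(scope="session")
def default_dataset() -> r.SimulatedDataset:
    """The default study conditions: 2000 transcripts, 4 groups x 3
    replicates, dispersion 0.05, 100 cassette events, seed 1."""
    return r.simulate_dataset(r.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_rpkm(default_dataset) -> r.ExpressionMatrix:
    lengths = r.transcript_lengths(default_dataset.models)
    return r.rpkm(default_dataset.transcript_counts, lengths)


def balanced_design(n: int = 3, groups=("D", "N")) -> r.SampleDesign:
    return r.SampleDesign.balanced(n, groups=groups)


@pytest.fixture()
def two_group_design() -> r.SampleDesign:
    return balanced_design(3, ("D", "N"))
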