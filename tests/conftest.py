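"""Shared fixtures: hand-built miniature gene models and simulated cohorts."""

import numpy as np
import pytest

from ttnpop.gene_model import BandInterval, Exon, GeneModel, Transcript
from ttnpop.synthetic_data import (
    SimConfig,
    make_table1_fixture,
    simulate_gene_model,
    simulate_variants,
)


def build_single_exon_model(strand: str = "+") -> GeneModel:
    """One-exon gene whose CDS is ATG CGA TAA read on the coding strand."""
    cds = "ATGCGATAA"
    if strand == "-":
        from Bio.Seq import Seq

        genomic = str(Seq(cds).reverse_complement())
    else:
        genomic = cds
    sequence = "ACGT" * 25 + genomic + "ACGT" * 25
    model = GeneModel(
        gene_name="MINI",
        chrom="chrT",
        strand=strand,
        locus_offset=1,
        sequence=sequence,
        exons={"E1": Exon("E1", 101, 109)},
        transcripts={"T1": Transcript("T1", "only", ("E1",), 101, 109)},
        bands=[BandInterval("A", 101, 109)],
        psi={"E1": 1.0},
    )
    model.validate()
    return model


def build_two_exon_model(strand: str = "+", seed: int = 11) -> GeneModel:
    """Two coding exons (101-199, 301-399) separated by a 101 bp intron."""
    rng = np.random.default_rng(seed)
    sequence = "".join("ACGT"[i] for i in rng.integers(0, 4, size=500))
    model = GeneModel(
        gene_name="MINI2",
        chrom="chrT",
        strand=strand,
        locus_offset=1,
        sequence=sequence,
        exons={"E1": Exon("E1", 101, 199), "E2": Exon("E2", 301, 399)},
        transcripts={
            "T1": Transcript("T1", "full", ("E1", "E2"), 101, 399),
        },
        bands=[BandInterval("I", 101, 250), BandInterval("A", 251, 399)],
        psi={"E1": 1.0, "E2": 1.0},
    )
    model.validate()
    return model


@pytest.fixture(scope="session")
def mini_model():
    return build_single_exon_model("+")


@pytest.fixture(scope="session")
def two_exon_model():
    return build_two_exon_model("+")


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def sim_model(sim_config):
    return simulate_gene_model(sim_config)


@pytest.fixture(scope="session")
def sim_cohort(sim_config, sim_model):
    return simulate_variants(sim_config, sim_model)


@pytest.fixture(scope="session")
def table1_fixture():
    return make_table1_fixture()
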