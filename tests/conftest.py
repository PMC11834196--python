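import numpy as np
import pytest

from ctrdseq import (
    EndCountProfile,
    SimulationConfig,
    TranscriptModel,
    simulate_experiment,
)


@pytest.fixture
def plus_model():
    """Single-exon + strand mRNA [100,400), CDS [130,370) incl. stop at [367,370)."""
    return TranscriptModel(
        transcript_id="TPLUS.1",
        gene_id="TPLUS",
        chrom="chr1",
        strand="+",
        exons=((100, 400),),
        cds_start_t=30,
        stop_codon_start_t=267,
    )


@pytest.fixture
def minus_model():
    """Single-exon - strand mRNA [100,400): transcript position 0 is genomic 399."""
    return TranscriptModel(
        transcript_id="TMINUS.1",
        gene_id="TMINUS",
        chrom="chr1",
        strand="-",
        exons=((100, 400),),
        cds_start_t=30,
        stop_codon_start_t=267,
    )


def make_profile(model, positions=(), counts=None, library_id="lib1"):
    """Profile with given per-position counts (impulses or a full vector)."""
    vec = np.zeros(model.length_t, dtype=np.int64)
    if counts is not None:
        vec[:] = counts
    else:
        for p in positions:
            vec[p] += 1
    return EndCountProfile(model.transcript_id, library_id, vec)


@pytest.fixture(scope="session")
def small_experiment():
    """Seeded 2-genotype x 3-replicate experiment on 60 transcripts."""
    config = SimulationConfig(n_transcripts=60, seed=11)
    tx, by_lib, sheet = simulate_experiment(config)
    return config, tx, by_lib, sheet
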