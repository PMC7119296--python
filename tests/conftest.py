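"""Shared fixtures: a small synthetic reference/cohort built once per
session, plus helpers for constructing transcripts by hand."""

from __future__ import annotations

import pytest

from synreg.model import Mutation, TranscriptModel
from synreg.simulate import SyntheticConfig, generate_cohort, generate_reference


SMALL_CFG = SyntheticConfig(
    n_genes=12,
    cds_length=(900, 1500),
    n_mutations=600,
    n_ese=60,
    n_ess=50,
    n_mirna=12,
)


@pytest.fixture(scope="session")
def small_reference():
    return generate_reference(SMALL_CFG, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_reference):
    cohort, truth = generate_cohort(SMALL_CFG, small_reference, seed=11)
    return cohort, truth


def make_transcript(
    exons,
    cds_sequence,
    strand="+",
    chrom="chr1",
    gene="GENEX",
    tid="TRX",
    cds_interval=None,
):
    exons = tuple(tuple(e) for e in exons)
    return TranscriptModel(
        gene_symbol=gene,
        transcript_id=tid,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_interval=cds_interval or (exons[0][0], exons[-1][1]),
        cds_sequence=cds_sequence,
    )


def make_mutation(
    context="AAAAATAAAAA",
    ref="T",
    alt="A",
    pos=150,
    cds_pos=6,
    score=0.8,
    sample_count=2,
    strand="+",
    gene="GENEX",
    tid="TRX",
    chrom="chr1",
):
    return Mutation(
        gene_symbol=gene,
        transcript_id=tid,
        chrom=chrom,
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        strand=strand,
        sample_count=sample_count,
        score=score,
        cds_pos=cds_pos,
        context=context,
    )
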