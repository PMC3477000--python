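"""Shared fixtures: hand-built transcripts and a light randomized-instance
generator for the indexed-vs-exhaustive mapping equivalence tests."""

from __future__ import annotations

import numpy as np
import pytest

from lncsrna.model import GenomicInterval, SmallRNACluster, TranscriptModel


def make_transcript(
    tid="t1",
    biotype="lncRNA",
    chrom="chr1",
    strand="+",
    exon_coords=((100, 200), (300, 400)),
):
    return TranscriptModel(
        transcript_id=tid,
        gene_id=f"g_{tid}",
        biotype=biotype,
        chrom=chrom,
        strand=strand,
        exons=tuple(
            GenomicInterval(chrom, s, e, strand) for s, e in exon_coords
        ),
    )


@pytest.fixture
def two_exon_plus():
    return make_transcript(strand="+")


@pytest.fixture
def two_exon_minus():
    return make_transcript(strand="-")


def random_instance(rng: np.random.Generator, n_transcripts=100, n_clusters=1000):
    """A randomized mapping instance: transcripts on a few chromosomes and
    clusters up to 7 kb long (matching the largest observed cluster scale),
    placed so that a healthy share land inside regions."""
    transcripts = []
    for k in range(n_transcripts):
        chrom = f"chr{int(rng.integers(1, 5))}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 6))
        pos = int(rng.integers(0, 200_000))
        exons = []
        for _ in range(n_exons):
            elen = int(rng.integers(50, 2_000))
            exons.append(GenomicInterval(chrom, pos, pos + elen, strand))
            pos += elen + int(rng.integers(1, 5_000))
        transcripts.append(
            TranscriptModel(
                transcript_id=f"t{k}",
                gene_id=f"g{k}",
                biotype="lncRNA" if rng.random() < 0.5 else "protein_coding",
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
            )
        )
    clusters = []
    for k in range(n_clusters):
        chrom = f"chr{int(rng.integers(1, 5))}"
        strand = ["+", "-", "."][int(rng.choice(3, p=[0.45, 0.45, 0.1]))]
        start = int(rng.integers(0, 250_000))
        length = int(rng.integers(1, 7_000))
        clusters.append(
            SmallRNACluster(
                f"c{k}", GenomicInterval(chrom, start, start + length, strand)
            )
        )
    return transcripts, clusters
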