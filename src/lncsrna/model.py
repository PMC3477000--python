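"""Gene-model primitives: genomic intervals, multi-exon transcripts, spliced coordinates.

All coordinates are 0-based half-open (BED convention). ``start`` is the first
base of a feature and ``end`` is one past the last base, on the forward genomic
axis regardless of strand. Transcript ("spliced") coordinates count exonic
bases 5'->3' on the transcript strand, so spliced position 0 is always the
transcript's 5' end: on a minus-strand transcript that is the *rightmost*
exonic base in genomic coordinates.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

STRANDS = ("+", "-", ".")
BIOTYPES = ("lncRNA", "protein_coding")
#: small RNA classes used throughout (deepBase-style labels)
CLASS_LABELS = ("miRNA", "pasRNA", "nasRNA", "repeat", "unannotated")


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0 <= int(self.start) < int(self.end)):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def contained(
    inner: GenomicInterval,
    outer: GenomicInterval,
    require_same_strand: bool = True,
) -> bool:
    """True iff ``inner`` lies entirely within ``outer``.

    With ``require_same_strand`` the strands must be equal and an unstranded
    (``"."``) inner interval never matches: a cluster counts as lncRNA-derived
    only when it maps entirely within a region in the same strand orientation.
    """
    if inner.chrom != outer.chrom:
        return False
    if require_same_strand:
        if inner.strand == "." or inner.strand != outer.strand:
            return False
    return inner.start >= outer.start and inner.end <= outer.end


@dataclass
class TranscriptModel:
    """A stranded multi-exon gene model.

    Exons must be sorted by genomic start, pairwise disjoint with strictly
    positive inter-exon gaps, and share the transcript's chromosome and strand.
    A zero-length gap between consecutive exons is rejected as a malformed
    annotation rather than silently merged.
    """

    transcript_id: str
    gene_id: str
    biotype: str
    chrom: str
    strand: str
    exons: Tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript strand must be '+'/'-', got {self.strand!r}")
        exons = tuple(self.exons)
        if not exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        for e in exons:
            if e.chrom != self.chrom:
                raise ValueError(f"{self.transcript_id}: exon on wrong chromosome")
            if e.strand not in (self.strand, "."):
                raise ValueError(f"{self.transcript_id}: exon strand mismatch")
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: exons overlap or unsorted")
            if b.start == a.end:
                raise ValueError(
                    f"{self.transcript_id}: zero-length gap between exons "
                    f"at {a.end} (malformed model)"
                )
        self.exons = exons
        # cached lookup tables for spliced-coordinate arithmetic
        self._starts = [e.start for e in exons]
        offsets = [0]
        for e in exons:
            offsets.append(offsets[-1] + e.length)
        self._offsets = offsets  # cumulative exonic bases before exon i

    @property
    def spliced_length(self) -> int:
        return self._offsets[-1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> Tuple[GenomicInterval, ...]:
        """Inter-exon gaps, 5'-agnostic genomic order; empty for single-exon models."""
        return tuple(
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        )

    def genomic_to_spliced(self, pos: int) -> int:
        """Spliced coordinate of exonic genomic base ``pos`` (0 = 5' end).

        Raises ``ValueError`` when ``pos`` falls in an intron or outside the
        transcript.
        """
        i = bisect.bisect_right(self._starts, pos) - 1
        if i < 0 or pos >= self.exons[i].end:
            raise ValueError(
                f"{self.transcript_id}: position {pos} is not exonic"
            )
        plus = self._offsets[i] + (pos - self.exons[i].start)
        if self.strand == "+":
            return plus
        return self.spliced_length - 1 - plus

    def spliced_to_genomic(self, spliced: int) -> int:
        """Inverse of :meth:`genomic_to_spliced`."""
        if not 0 <= spliced < self.spliced_length:
            raise ValueError(
                f"{self.transcript_id}: spliced position {spliced} out of range"
            )
        plus = spliced if self.strand == "+" else self.spliced_length - 1 - spliced
        i = bisect.bisect_right(self._offsets, plus) - 1
        return self.exons[i].start + (plus - self._offsets[i])

    def exon_index_at(self, pos: int) -> int:
        """Index of the exon containing genomic base ``pos``."""
        i = bisect.bisect_right(self._starts, pos) - 1
        if i < 0 or pos >= self.exons[i].end:
            raise ValueError(f"{self.transcript_id}: position {pos} is not exonic")
        return i


def derive_introns(t: TranscriptModel) -> Tuple[GenomicInterval, ...]:
    """Introns of ``t`` (exon_count - 1 intervals spanning the inter-exon gaps)."""
    return t.introns()


def genomic_to_spliced(t: TranscriptModel, pos: int) -> int:
    return t.genomic_to_spliced(pos)


def spliced_to_genomic(t: TranscriptModel, spliced: int) -> int:
    return t.spliced_to_genomic(spliced)


@dataclass
class SmallRNACluster:
    """A deepBase-style small RNA cluster: one stranded locus with optional
    class label and per-library tag counts."""

    cluster_id: str
    interval: GenomicInterval
    class_label: Optional[str] = None
    tag_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lib, n in self.tag_counts.items():
            if n < 0:
                raise ValueError(
                    f"{self.cluster_id}: negative tag count for library {lib!r}"
                )


@dataclass(frozen=True)
class MappingRecord:
    """One (cluster, transcript, region) containment event.

    ``spliced_start``/``spliced_end`` and ``midpoint_fraction`` are populated
    for exon mappings only; the fraction is 0 at the transcript's 5' end and 1
    at its 3' end.
    """

    cluster_id: str
    transcript_id: str
    region: str  # "exon" | "intron"
    region_index: int
    spliced_start: Optional[int] = None
    spliced_end: Optional[int] = None
    midpoint_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.region not in ("exon", "intron"):
            raise ValueError(f"invalid region kind {self.region!r}")
        if self.region_index < 0:
            raise ValueError("region_index must be >= 0")
        if self.midpoint_fraction is not None and not (
            0.0 <= self.midpoint_fraction <= 1.0
        ):
            raise ValueError("midpoint_fraction must lie in [0, 1]")
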