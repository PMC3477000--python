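"""BLAT PSL alignments: parsing, span-coverage filtering, best-hit selection,
and conversion of alignment blocks into transcript models.

This implements the sequence-only arm of the analysis: lncRNA sequences whose
genomic positions are unknown are aligned with BLAT, alignments covering more
than 90% of the input-sequence span are kept, a single best hit per query is
selected, and the alignment blocks become the transcript's exons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .model import GenomicInterval, TranscriptModel

logger = logging.getLogger(__name__)

PSL_N_COLUMNS = 21


@dataclass(frozen=True)
class PslAlignment:
    """One PSL row (the fields this pipeline uses).

    ``target_block_starts`` are forward-strand target coordinates regardless
    of query strand, as in the PSL format itself.
    """

    query_name: str
    query_size: int
    strand: str
    target_name: str
    target_start: int
    target_end: int
    matches: int
    block_sizes: Tuple[int, ...]
    target_block_starts: Tuple[int, ...]

    def __post_init__(self) -> None:
        if self.query_size <= 0:
            raise ValueError(f"{self.query_name}: query_size must be > 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.query_name}: strand must be '+'/'-'")
        if len(self.block_sizes) != len(self.target_block_starts) or not self.block_sizes:
            raise ValueError(f"{self.query_name}: inconsistent block lists")
        if sum(self.block_sizes) > self.query_size:
            raise ValueError(f"{self.query_name}: blocks exceed query size")
        for (s0, l0), s1 in zip(
            zip(self.target_block_starts, self.block_sizes),
            self.target_block_starts[1:],
        ):
            if s0 + l0 > s1:
                raise ValueError(f"{self.query_name}: target blocks overlap/unsorted")

    @property
    def block_count(self) -> int:
        return len(self.block_sizes)


def _parse_int_list(text: str) -> Tuple[int, ...]:
    return tuple(int(x) for x in text.rstrip(",").split(",") if x)


def read_psl(path) -> List[PslAlignment]:
    """Parse a BLAT PSL file (with or without the 5-line ``psLayout`` header)."""
    alignments: List[PslAlignment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            # header lines ("psLayout version 3", column names, dashes) lack a
            # leading integer match count
            if not fields[0].strip().isdigit():
                continue
            if len(fields) < PSL_N_COLUMNS:
                logger.warning("%s:%d: short PSL row skipped", path, lineno)
                continue
            strand = fields[8]
            alignments.append(
                PslAlignment(
                    query_name=fields[9],
                    query_size=int(fields[10]),
                    # translated BLAT writes two-character strands; the target
                    # strand (last character) is the genomic one
                    strand=strand[-1],
                    target_name=fields[13],
                    target_start=int(fields[15]),
                    target_end=int(fields[16]),
                    matches=int(fields[0]),
                    block_sizes=_parse_int_list(fields[18]),
                    target_block_starts=_parse_int_list(fields[20]),
                )
            )
    return alignments


def write_psl(alignments: Iterable[PslAlignment], path) -> None:
    """Write alignments as headerless PSL rows (fields this model does not
    track are written as zeros / derived values)."""
    with open(path, "w") as fh:
        for a in alignments:
            q_starts = []
            cursor = 0
            for size in a.block_sizes:
                q_starts.append(cursor)
                cursor += size
            row = [
                str(a.matches), "0", "0", "0", "0", "0", "0", "0",
                a.strand, a.query_name, str(a.query_size), "0",
                str(sum(a.block_sizes)), a.target_name, "0",
                str(a.target_start), str(a.target_end), str(a.block_count),
                ",".join(map(str, a.block_sizes)) + ",",
                ",".join(map(str, q_starts)) + ",",
                ",".join(map(str, a.target_block_starts)) + ",",
            ]
            fh.write("\t".join(row) + "\n")


def span_coverage(a: PslAlignment) -> float:
    """Fraction of the query sequence covered by alignment blocks.

    Aligned bases (sum of block sizes) over query length — genomic insertions
    between blocks do not inflate coverage.
    """
    return sum(a.block_sizes) / a.query_size


def select_hits(
    alignments: Sequence[PslAlignment], min_coverage: float = 0.90
) -> List[PslAlignment]:
    """Filter by span coverage and keep the single best hit per query.

    Coverage must be strictly greater than ``min_coverage`` ("more than 90
    percent span"). Among survivors of one query the alignment with the most
    matching bases wins; ties break by greater span coverage, then
    lexicographically smallest target name, then smallest target start (then
    target end and strand) — fully deterministic and invariant to input order.
    Queries with no surviving hit are logged and yield nothing.
    """
    survivors = [a for a in alignments if span_coverage(a) > min_coverage]
    dropped_queries = {a.query_name for a in alignments} - {
        a.query_name for a in survivors
    }
    for q in sorted(dropped_queries):
        logger.info("select_hits: query %s has no hit above coverage %.4f", q, min_coverage)

    def sort_key(a: PslAlignment):
        return (
            -a.matches,
            -span_coverage(a),
            a.target_name,
            a.target_start,
            a.target_end,
            a.strand,
        )

    best: Dict[str, PslAlignment] = {}
    for a in survivors:
        incumbent = best.get(a.query_name)
        if incumbent is None or sort_key(a) < sort_key(incumbent):
            best[a.query_name] = a
    return [best[q] for q in sorted(best)]


def psl_to_transcript(
    a: PslAlignment,
    biotype: str,
    transcript_id: Optional[str] = None,
    gene_id: Optional[str] = None,
) -> TranscriptModel:
    """Turn a selected alignment into a transcript model, block = exon.

    Adjacent blocks with a zero-length target gap (a BLAT artifact around
    query-only gaps) are coalesced into a single exon; overlapping blocks are
    an error.
    """
    blocks: List[List[int]] = []
    for start, size in zip(a.target_block_starts, a.block_sizes):
        end = start + size
        if blocks and start < blocks[-1][1]:
            raise ValueError(f"{a.query_name}: overlapping alignment blocks")
        if blocks and start == blocks[-1][1]:
            blocks[-1][1] = end
        else:
            blocks.append([start, end])
    exons = tuple(
        GenomicInterval(a.target_name, s, e, a.strand) for s, e in blocks
    )
    return TranscriptModel(
        transcript_id=transcript_id or a.query_name,
        gene_id=gene_id or transcript_id or a.query_name,
        biotype=biotype,
        chrom=a.target_name,
        strand=a.strand,
        exons=exons,
    )
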