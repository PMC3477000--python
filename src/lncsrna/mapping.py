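"""Strand-aware full-containment mapping of small RNA clusters onto exons and
introns — the pipeline's central computation.

A cluster maps to a region only when it lies entirely inside that single exon
or intron on the same strand; a cluster spanning an exon-intron junction maps
nowhere. A cluster contained in regions of k transcripts yields k mapping
events (distinct-cluster counts are reported alongside downstream).

Two implementations are provided: an intervaltree-indexed path
(:func:`map_clusters`) and an exhaustive all-pairs oracle
(:func:`brute_force_map`) whose results must be identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .model import GenomicInterval, MappingRecord, SmallRNACluster, TranscriptModel

logger = logging.getLogger(__name__)

REGION_KINDS = ("exon", "intron")


@dataclass(frozen=True)
class RegionRef:
    """A tagged region in the index: which transcript, which kind, which slot."""

    transcript: TranscriptModel
    kind: str
    index: int
    interval: GenomicInterval


class RegionIndex:
    """Per-chromosome interval trees over all exons (or introns) of a
    transcript set. Query results are identical to a linear scan."""

    def __init__(self, region_kind: str):
        if region_kind not in REGION_KINDS:
            raise ValueError(f"invalid region kind {region_kind!r}")
        self.region_kind = region_kind
        self._trees: Dict[str, IntervalTree] = {}
        self.n_regions = 0

    def add(self, ref: RegionRef) -> None:
        tree = self._trees.setdefault(ref.interval.chrom, IntervalTree())
        tree.addi(ref.interval.start, ref.interval.end, ref)
        self.n_regions += 1

    def enclosing(self, interval: GenomicInterval) -> List[RegionRef]:
        """All indexed regions that fully contain ``interval`` (strand ignored)."""
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        return [
            hit.data
            for hit in tree.overlap(interval.start, interval.end)
            if hit.begin <= interval.start and interval.end <= hit.end
        ]


def regions_of(t: TranscriptModel, region_kind: str) -> Sequence[GenomicInterval]:
    if region_kind == "exon":
        return t.exons
    if region_kind == "intron":
        return t.introns()
    raise ValueError(f"invalid region kind {region_kind!r}")


def build_index(
    transcripts: Iterable[TranscriptModel], region_kind: str
) -> RegionIndex:
    """Index every exon (or intron) of every transcript."""
    index = RegionIndex(region_kind)
    for t in transcripts:
        for i, region in enumerate(regions_of(t, region_kind)):
            index.add(RegionRef(t, region_kind, i, region))
    return index


def _make_record(cluster: SmallRNACluster, ref: RegionRef) -> MappingRecord:
    """Build the mapping record; exon records carry spliced coordinates and
    the midpoint fraction (midpoint base = (start + end) // 2)."""
    if ref.kind == "intron":
        return MappingRecord(
            cluster_id=cluster.cluster_id,
            transcript_id=ref.transcript.transcript_id,
            region="intron",
            region_index=ref.index,
        )
    t = ref.transcript
    iv = cluster.interval
    if t.strand == "+":
        spliced_start = t.genomic_to_spliced(iv.start)
    else:
        spliced_start = t.genomic_to_spliced(iv.end - 1)
    spliced_end = spliced_start + iv.length
    mid_genomic = (iv.start + iv.end) // 2
    L = t.spliced_length
    fraction = t.genomic_to_spliced(mid_genomic) / (L - 1) if L > 1 else 0.0
    return MappingRecord(
        cluster_id=cluster.cluster_id,
        transcript_id=t.transcript_id,
        region="exon",
        region_index=ref.index,
        spliced_start=spliced_start,
        spliced_end=spliced_end,
        midpoint_fraction=fraction,
    )


def _record_sort_key(r: MappingRecord):
    return (r.cluster_id, r.transcript_id, r.region, r.region_index)


def map_clusters(
    clusters: Iterable[SmallRNACluster],
    index: RegionIndex,
    require_same_strand: bool = True,
    max_cluster_length: Optional[int] = None,
) -> List[MappingRecord]:
    """One :class:`MappingRecord` per (cluster, region) full-containment pair.

    Unstranded clusters are excluded (and counted in the log) when strand
    matching is required. ``max_cluster_length`` optionally drops long
    clusters before mapping.
    """
    records: List[MappingRecord] = []
    n_unstranded = 0
    n_too_long = 0
    for c in clusters:
        iv = c.interval
        if max_cluster_length is not None and iv.length > max_cluster_length:
            n_too_long += 1
            continue
        if require_same_strand and iv.strand == ".":
            n_unstranded += 1
            continue
        for ref in index.enclosing(iv):
            if require_same_strand and ref.interval.strand != iv.strand:
                continue
            records.append(_make_record(c, ref))
    if n_unstranded:
        logger.info("map_clusters: %d unstranded clusters excluded", n_unstranded)
    if n_too_long:
        logger.info(
            "map_clusters: %d clusters longer than %d excluded",
            n_too_long,
            max_cluster_length,
        )
    records.sort(key=_record_sort_key)
    return records


def brute_force_map(
    clusters: Sequence[SmallRNACluster],
    transcripts: Sequence[TranscriptModel],
    region_kind: str,
    require_same_strand: bool = True,
    max_cluster_length: Optional[int] = None,
) -> List[MappingRecord]:
    """Exhaustive all-pairs containment oracle.

    Semantics identical to :func:`map_clusters` over :func:`build_index`, by
    checking every (cluster, region) pair; the containment predicate is
    evaluated for the full cross product (vectorised over the flattened region
    arrays, with no indexing or pruning).
    """
    refs: List[RegionRef] = []
    for t in transcripts:
        for i, region in enumerate(regions_of(t, region_kind)):
            refs.append(RegionRef(t, region_kind, i, region))
    if not refs:
        return []
    chrom_codes: Dict[str, int] = {}
    strand_codes = {"+": 0, "-": 1, ".": 2}

    def chrom_code(name: str) -> int:
        return chrom_codes.setdefault(name, len(chrom_codes))

    r_chrom = np.array([chrom_code(r.interval.chrom) for r in refs])
    r_start = np.array([r.interval.start for r in refs])
    r_end = np.array([r.interval.end for r in refs])
    r_strand = np.array([strand_codes[r.interval.strand] for r in refs])

    records: List[MappingRecord] = []
    for c in clusters:
        iv = c.interval
        if max_cluster_length is not None and iv.length > max_cluster_length:
            continue
        if require_same_strand and iv.strand == ".":
            continue
        if iv.chrom not in chrom_codes:
            continue
        mask = (
            (r_chrom == chrom_codes[iv.chrom])
            & (r_start <= iv.start)
            & (r_end >= iv.end)
        )
        if require_same_strand:
            mask &= r_strand == strand_codes[iv.strand]
        for j in np.nonzero(mask)[0]:
            records.append(_make_record(c, refs[j]))
    records.sort(key=_record_sort_key)
    return records


def check_records(
    records: Sequence[MappingRecord],
    clusters_by_id: Dict[str, SmallRNACluster],
    transcripts_by_id: Dict[str, TranscriptModel],
    require_same_strand: bool = True,
) -> None:
    """Post-hoc re-check that every record's cluster satisfies containment.

    Raises ``AssertionError`` on any violation; used in tests and in the
    pipeline's paranoid mode.
    """
    from .model import contained

    for r in records:
        c = clusters_by_id[r.cluster_id]
        t = transcripts_by_id[r.transcript_id]
        region = regions_of(t, r.region)[r.region_index]
        assert contained(c.interval, region, require_same_strand), (
            f"record {r} violates containment"
        )


def write_mappings_tsv(records: Sequence[MappingRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "cluster_id\ttranscript_id\tregion\tregion_index\t"
            "spliced_start\tspliced_end\tmidpoint_fraction\n"
        )
        for r in records:
            frac = "" if r.midpoint_fraction is None else repr(r.midpoint_fraction)
            ss = "" if r.spliced_start is None else str(r.spliced_start)
            se = "" if r.spliced_end is None else str(r.spliced_end)
            fh.write(
                f"{r.cluster_id}\t{r.transcript_id}\t{r.region}\t"
                f"{r.region_index}\t{ss}\t{se}\t{frac}\n"
            )


def read_mappings_tsv(path) -> List[MappingRecord]:
    records: List[MappingRecord] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("cluster_id\t"):
            raise ValueError(f"{path}: not a mappings TSV")
        for line in fh:
            cid, tid, region, ridx, ss, se, frac = line.rstrip("\n").split("\t")
            records.append(
                MappingRecord(
                    cluster_id=cid,
                    transcript_id=tid,
                    region=region,
                    region_index=int(ridx),
                    spliced_start=int(ss) if ss else None,
                    spliced_end=int(se) if se else None,
                    midpoint_fraction=float(frac) if frac else None,
                )
            )
    return records
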