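"""Length-adjusted per-kilobase mapping densities by biotype and region kind.

The headline comparison of the analysis: mapping events per kilobase of exon
vs intron sequence, separately for lncRNA and protein-coding gene models,
plus the exon:intron density ratio per biotype. The numerator is mapping
*events*; distinct-cluster counts are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .mapping import MappingRecord, build_index, map_clusters, regions_of
from .model import SmallRNACluster, TranscriptModel

GroupKey = Tuple[str, str]  # (biotype, region_kind)


def _merge_intervals(intervals: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    merged: List[Tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def total_region_kb(
    transcripts: Sequence[TranscriptModel],
    region_kind: str,
    dedup: str = "none",
) -> float:
    """Total exon (or intron) kilobases of a transcript set.

    ``dedup="none"`` sums every region of every transcript — straight per-exon
    accounting over the redundant isoform exon list, where isoform-shared exons
    count repeatedly. ``dedup="union"`` merges overlapping same-chromosome,
    same-strand regions first.
    """
    if dedup not in ("none", "union"):
        raise ValueError(f"invalid dedup mode {dedup!r}")
    if not transcripts:
        raise ValueError("empty transcript set")
    if dedup == "none":
        total = sum(
            r.length for t in transcripts for r in regions_of(t, region_kind)
        )
    else:
        by_key: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
        for t in transcripts:
            for r in regions_of(t, region_kind):
                by_key.setdefault((r.chrom, r.strand), []).append((r.start, r.end))
        total = sum(
            end - start
            for intervals in by_key.values()
            for start, end in _merge_intervals(intervals)
        )
    return total / 1000.0


@dataclass(frozen=True)
class DensityCell:
    mapping_events: int
    distinct_clusters: int
    total_kb: float
    density_per_kb: Optional[float]  # None when total_kb == 0


@dataclass
class DensityReport:
    """Per (biotype, region) densities plus exon:intron ratios per biotype."""

    cells: Dict[GroupKey, DensityCell]
    ratios: Dict[str, Optional[float]]

    def to_dict(self) -> dict:
        return {
            "cells": {
                f"{biotype}:{kind}": {
                    "mapping_events": c.mapping_events,
                    "distinct_clusters": c.distinct_clusters,
                    "total_kb": c.total_kb,
                    "density_per_kb": c.density_per_kb,
                }
                for (biotype, kind), c in self.cells.items()
            },
            "exon_intron_ratio": dict(self.ratios),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "DensityReport":
        cells = {}
        for key, c in data["cells"].items():
            biotype, kind = key.split(":")
            cells[(biotype, kind)] = DensityCell(
                mapping_events=c["mapping_events"],
                distinct_clusters=c["distinct_clusters"],
                total_kb=c["total_kb"],
                density_per_kb=c["density_per_kb"],
            )
        return cls(cells=cells, ratios=dict(data["exon_intron_ratio"]))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "biotype": biotype,
                "region": kind,
                "mapping_events": c.mapping_events,
                "distinct_clusters": c.distinct_clusters,
                "total_kb": c.total_kb,
                "density_per_kb": c.density_per_kb,
            }
            for (biotype, kind), c in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows)


def density_report(
    mappings_by_group: Mapping[GroupKey, Sequence[MappingRecord]],
    lengths_by_group: Mapping[GroupKey, float],
) -> DensityReport:
    """Assemble the density report from per-group mapping records and region
    kilobases. A zero-length group's density is undefined and reported as
    missing (``None``)."""
    cells: Dict[GroupKey, DensityCell] = {}
    for key, kb in lengths_by_group.items():
        records = list(mappings_by_group.get(key, ()))
        events = len(records)
        distinct = len({r.cluster_id for r in records})
        density = events / kb if kb > 0 else None
        cells[key] = DensityCell(events, distinct, kb, density)
    ratios: Dict[str, Optional[float]] = {}
    for biotype in sorted({b for b, _ in cells}):
        ex = cells.get((biotype, "exon"))
        intron = cells.get((biotype, "intron"))
        if (
            ex is not None
            and intron is not None
            and ex.density_per_kb is not None
            and intron.density_per_kb
        ):
            ratios[biotype] = ex.density_per_kb / intron.density_per_kb
        else:
            ratios[biotype] = None
    return DensityReport(cells=cells, ratios=ratios)


def compute_density(
    transcripts: Sequence[TranscriptModel],
    clusters: Iterable[SmallRNACluster],
    require_same_strand: bool = True,
    dedup: str = "none",
    max_cluster_length: Optional[int] = None,
) -> Tuple[DensityReport, Dict[GroupKey, List[MappingRecord]]]:
    """Map clusters to every (biotype, region kind) group and report densities.

    Returns the report and the grouped mapping records (the exon records feed
    the positional analysis).
    """
    clusters = list(clusters)
    by_biotype: Dict[str, List[TranscriptModel]] = {}
    for t in transcripts:
        by_biotype.setdefault(t.biotype, []).append(t)
    mappings: Dict[GroupKey, List[MappingRecord]] = {}
    lengths: Dict[GroupKey, float] = {}
    for biotype, ts in sorted(by_biotype.items()):
        for kind in ("exon", "intron"):
            key = (biotype, kind)
            n_regions = sum(len(regions_of(t, kind)) for t in ts)
            lengths[key] = (
                total_region_kb(ts, kind, dedup=dedup) if n_regions else 0.0
            )
            index = build_index(ts, kind)
            mappings[key] = map_clusters(
                clusters,
                index,
                require_same_strand=require_same_strand,
                max_cluster_length=max_cluster_length,
            )
    return density_report(mappings, lengths), mappings
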