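"""Cross-classification of mapped clusters against reference small RNA
annotation sets (miRNA, pasRNA, nasRNA, repeats, ...).

A cluster receives every class whose reference features it overlaps on the
same strand (multi-label by default; a priority collapse is available for
single-label summaries). The report counts both directions — clusters per
class and distinct reference features hit per class — mirroring dual
cluster/feature tallies such as "9 clusters catalogued as 41 pasRNAs".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .model import GenomicInterval, SmallRNACluster, contained

DEFAULT_PRIORITY = ("miRNA", "nasRNA", "pasRNA", "repeat")


@dataclass
class ReferenceSet:
    """A named reference annotation set of stranded features."""

    name: str
    features: List[Tuple[str, GenomicInterval]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class ClassCount:
    n_clusters: int
    n_features: int


@dataclass
class ClassificationReport:
    classes: Dict[str, ClassCount]
    unannotated: int
    total_clusters: int

    def to_dict(self) -> dict:
        return {
            "classes": {
                name: {"n_clusters": c.n_clusters, "n_features": c.n_features}
                for name, c in self.classes.items()
            },
            "unannotated": self.unannotated,
            "total_clusters": self.total_clusters,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ClassificationReport":
        return cls(
            classes={
                name: ClassCount(c["n_clusters"], c["n_features"])
                for name, c in data["classes"].items()
            },
            unannotated=data["unannotated"],
            total_clusters=data["total_clusters"],
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"class": name, "n_clusters": c.n_clusters, "n_features": c.n_features}
            for name, c in sorted(self.classes.items())
        ]
        rows.append(
            {
                "class": "unannotated",
                "n_clusters": self.unannotated,
                "n_features": 0,
            }
        )
        return pd.DataFrame(rows)


def classify_clusters(
    clusters: Sequence[SmallRNACluster],
    reference_sets: Sequence[ReferenceSet],
    min_overlap_fraction: float = 1e-9,
    require_same_strand: bool = True,
    containment: bool = False,
    priority: Optional[Sequence[str]] = None,
) -> Tuple[ClassificationReport, Dict[str, List[str]]]:
    """Label clusters by overlap with reference sets and tally both directions.

    A feature qualifies when the overlap covers at least
    ``min_overlap_fraction`` of the cluster length (any >= 1 base overlap with
    the default) on the same strand; with ``containment`` the cluster must lie
    entirely within the feature. With a ``priority`` order each cluster keeps
    only its highest-priority class. Returns the report and the per-cluster
    label lists (classified + unannotated = total clusters).
    """
    trees: Dict[str, Dict[str, IntervalTree]] = {}
    for ref in reference_sets:
        per_chrom = trees.setdefault(ref.name, {})
        for fid, iv in ref.features:
            per_chrom.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, (fid, iv)
            )

    labels: Dict[str, List[str]] = {}
    features_hit: Dict[str, set] = {ref.name: set() for ref in reference_sets}
    clusters_per_class: Dict[str, int] = {ref.name: 0 for ref in reference_sets}
    n_unannotated = 0

    for c in clusters:
        civ = c.interval
        hit_classes: List[str] = []
        hits_by_class: Dict[str, List[str]] = {}
        for ref in reference_sets:
            tree = trees[ref.name].get(civ.chrom)
            if tree is None:
                continue
            qualifying: List[str] = []
            for hit in tree.overlap(civ.start, civ.end):
                fid, fiv = hit.data
                if require_same_strand and (
                    civ.strand == "." or civ.strand != fiv.strand
                ):
                    continue
                if containment:
                    if not contained(civ, fiv, require_same_strand):
                        continue
                else:
                    overlap = min(civ.end, fiv.end) - max(civ.start, fiv.start)
                    if overlap / civ.length < min_overlap_fraction:
                        continue
                qualifying.append(fid)
            if qualifying:
                hit_classes.append(ref.name)
                hits_by_class[ref.name] = qualifying
        if priority is not None and hit_classes:
            for name in priority:
                if name in hit_classes:
                    hit_classes = [name]
                    hits_by_class = {name: hits_by_class[name]}
                    break
        if hit_classes:
            for name in hit_classes:
                clusters_per_class[name] += 1
                features_hit[name].update(hits_by_class[name])
        else:
            n_unannotated += 1
        labels[c.cluster_id] = hit_classes

    report = ClassificationReport(
        classes={
            ref.name: ClassCount(
                n_clusters=clusters_per_class[ref.name],
                n_features=len(features_hit[ref.name]),
            )
            for ref in reference_sets
        },
        unannotated=n_unannotated,
        total_clusters=len(clusters),
    )
    return report, labels
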