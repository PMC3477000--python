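"""Tissue/cell-type expression summaries of small RNA clusters.

Raw tag counts are the primary observable (cloning and sequencing biases
preclude comparing absolute levels between different small RNAs); tags-per-
million normalization and an entropy-based tissue-specificity score are
provided on top so profiles are comparable across libraries of different
depth. Subcluster decomposition splits a parent cluster into maximal runs of
independently cloned loci separated by a gap threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .model import GenomicInterval, SmallRNACluster, contained


def normalize_tpm(matrix: pd.DataFrame) -> pd.DataFrame:
    """Tags-per-million per library: count / library_total * 1e6.

    Columns are libraries; every column of the result sums to 1e6 over the
    clusters in the matrix. A zero-total library is an error (named in the
    message) since its normalization is undefined.
    """
    totals = matrix.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(
            f"library with zero total tags: {', '.join(map(str, zero.index))}"
        )
    return matrix / totals * 1e6


def specificity_score(profile: Sequence[float]) -> float:
    """Entropy-based tissue specificity in [0, 1].

    1 - H/Hmax, where H is the Shannon entropy of the profile renormalized to
    sum 1 and Hmax = ln(n_libraries): 0 for a uniform profile, 1 when all
    mass sits in a single library. An all-zero profile is undefined and
    returns NaN. Requires at least two libraries.
    """
    p = np.asarray(list(profile), dtype=float)
    if p.size < 2:
        raise ValueError("specificity_score needs >= 2 libraries")
    if (p < 0).any():
        raise ValueError("negative abundances")
    total = p.sum()
    if total == 0:
        return float("nan")
    q = p / total
    q = q[q > 0]
    entropy = float(-(q * np.log(q)).sum())
    return min(1.0, max(0.0, 1.0 - entropy / math.log(p.size)))


@dataclass
class ClusterExpressionProfile:
    """Per-cluster expression profile: raw tags, tags-per-million, specificity."""

    cluster_id: str
    raw_counts: Dict[str, int]
    tpm: Dict[str, float]
    specificity: float
    interval: Optional[GenomicInterval] = None

    def to_dict(self) -> dict:
        return {
            "cluster_id": self.cluster_id,
            "raw_counts": dict(self.raw_counts),
            "tpm": dict(self.tpm),
            "specificity": None if math.isnan(self.specificity) else self.specificity,
        }


def profile_clusters(
    matrix: pd.DataFrame, cluster_ids: Optional[Sequence[str]] = None
) -> List[ClusterExpressionProfile]:
    """Expression profiles for ``cluster_ids`` (default: every matrix row),
    normalized against the full matrix's library totals."""
    tpm = normalize_tpm(matrix)
    ids = list(cluster_ids) if cluster_ids is not None else list(matrix.index)
    profiles = []
    for cid in ids:
        raw = matrix.loc[cid]
        profiles.append(
            ClusterExpressionProfile(
                cluster_id=str(cid),
                raw_counts={str(k): int(v) for k, v in raw.items()},
                tpm={str(k): float(v) for k, v in tpm.loc[cid].items()},
                specificity=specificity_score(raw.values),
            )
        )
    return profiles


def subcluster_profiles(
    parent: SmallRNACluster,
    loci: Sequence[SmallRNACluster],
    matrix: pd.DataFrame,
    gap_threshold: int = 10,
) -> List[ClusterExpressionProfile]:
    """Decompose a parent cluster into subclusters using independently cloned
    loci (smiRNAdb-style) and profile each.

    Loci fully contained in the parent on the same strand are sorted and
    grouped into maximal runs: a new run starts when a locus lies
    ``gap_threshold`` or more bases beyond the previous run's end. Each run is
    one subcluster whose counts are the member loci's counts summed per
    library; tags-per-million uses the full matrix's library totals. Returns
    an empty list when no locus is contained.
    """
    inside = sorted(
        (l for l in loci if contained(l.interval, parent.interval, True)),
        key=lambda l: (l.interval.start, l.interval.end, l.cluster_id),
    )
    if not inside:
        return []
    runs: List[List[SmallRNACluster]] = [[inside[0]]]
    run_end = inside[0].interval.end
    for locus in inside[1:]:
        if locus.interval.start - run_end >= gap_threshold:
            runs.append([locus])
            run_end = locus.interval.end
        else:
            runs[-1].append(locus)
            run_end = max(run_end, locus.interval.end)

    totals = matrix.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(
            f"library with zero total tags: {', '.join(map(str, zero.index))}"
        )
    libraries = list(matrix.columns)
    profiles: List[ClusterExpressionProfile] = []
    for i, run in enumerate(runs, start=1):
        counts = {lib: 0 for lib in libraries}
        for locus in run:
            if locus.cluster_id in matrix.index:
                row = matrix.loc[locus.cluster_id]
            else:
                row = locus.tag_counts
            for lib in libraries:
                counts[lib] += int(row.get(lib, 0) if hasattr(row, "get") else row[lib])
        start = min(l.interval.start for l in run)
        end = max(l.interval.end for l in run)
        values = [counts[lib] for lib in libraries]
        profiles.append(
            ClusterExpressionProfile(
                cluster_id=f"{parent.cluster_id}.sub{i}",
                raw_counts=counts,
                tpm={
                    lib: counts[lib] / float(totals[lib]) * 1e6 for lib in libraries
                },
                specificity=specificity_score(values),
                interval=GenomicInterval(
                    parent.interval.chrom, start, end, parent.interval.strand
                ),
            )
        )
    return profiles


def plot_heatmap(matrix: pd.DataFrame, path) -> None:
    """Simple library x cluster heatmap of tags-per-million."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tpm = normalize_tpm(matrix)
    fig, ax = plt.subplots(figsize=(8, max(2, 0.3 * len(tpm))))
    im = ax.imshow(np.log1p(tpm.values), aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(tpm.index)), labels=tpm.index, fontsize=6)
    ax.set_xticks(range(len(tpm.columns)), labels=tpm.columns, rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax, label="log1p(tags per million)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
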