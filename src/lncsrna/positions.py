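"""Positional preference of exon-mapped clusters along spliced transcripts.

Each exon mapping event is reduced to the transcript-relative fraction of its
midpoint (0 = 5' end, 1 = 3' end, strand-aware), the fractions are binned into
5% frames (20 bins) or thirds (3 bins), and a chi-square goodness-of-fit test
quantifies departure from uniform placement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .model import MappingRecord, TranscriptModel


def midpoint_fraction(record: MappingRecord, t: TranscriptModel) -> float:
    """Transcript-relative position of an exon mapping's midpoint base.

    The midpoint base is the spliced image of genomic base
    ``(start + end) // 2``; the fraction divides its spliced coordinate by
    ``spliced_length - 1`` so a cluster centred on the first transcript base
    scores 0.0 and one centred on the last scores 1.0. Intron records have no
    spliced position and raise ``ValueError``.
    """
    if record.region != "exon":
        raise ValueError("midpoint_fraction is defined for exon mappings only")
    L = t.spliced_length
    if L <= 1:
        return 0.0
    length = record.spliced_end - record.spliced_start
    # spliced offset of the genomic midpoint base within the cluster's
    # contiguous spliced span; the genomic floor-midpoint lands on different
    # relative offsets for the two strands
    offset = length // 2 if t.strand == "+" else (length - 1) // 2
    return (record.spliced_start + offset) / (L - 1)


def fractions_from_records(
    records: Iterable[MappingRecord],
    transcripts_by_id: Optional[Mapping[str, TranscriptModel]] = None,
) -> List[float]:
    """Midpoint fractions of the exon records (intron records are skipped).

    Uses each record's stored fraction; when a transcript lookup is supplied,
    the fraction is recomputed from spliced coordinates instead.
    """
    fractions: List[float] = []
    for r in records:
        if r.region != "exon":
            continue
        if transcripts_by_id is not None:
            fractions.append(midpoint_fraction(r, transcripts_by_id[r.transcript_id]))
        elif r.midpoint_fraction is not None:
            fractions.append(r.midpoint_fraction)
    return fractions


@dataclass
class PositionalProfile:
    """Counts of mapping events per positional bin over [0, 1]."""

    n_bins: int
    bin_edges: Tuple[float, ...]
    counts: Tuple[int, ...]
    total: int

    def __post_init__(self) -> None:
        if sum(self.counts) != self.total:
            raise ValueError("profile counts do not sum to total")

    @property
    def fractions(self) -> Tuple[float, ...]:
        """Per-bin share of events (all zeros for an empty profile)."""
        if self.total == 0:
            return tuple(0.0 for _ in self.counts)
        return tuple(c / self.total for c in self.counts)

    def to_dict(self) -> dict:
        return {
            "n_bins": self.n_bins,
            "bin_edges": list(self.bin_edges),
            "counts": list(self.counts),
            "total": self.total,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PositionalProfile":
        return cls(
            n_bins=data["n_bins"],
            bin_edges=tuple(data["bin_edges"]),
            counts=tuple(data["counts"]),
            total=data["total"],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "count": self.counts,
                "fraction": self.fractions,
            }
        )


def bin_profile(fractions: Sequence[float], n_bins: int = 20) -> PositionalProfile:
    """Tally fractions into ``n_bins`` equal bins over [0, 1].

    Bin i covers [i/n, (i+1)/n); the last bin is closed at 1.0 so
    3'-terminal events are counted.
    """
    arr = np.asarray(list(fractions), dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValueError("fractions must lie in [0, 1]")
    counts, edges = np.histogram(arr, bins=n_bins, range=(0.0, 1.0))
    return PositionalProfile(
        n_bins=n_bins,
        bin_edges=tuple(float(e) for e in edges),
        counts=tuple(int(c) for c in counts),
        total=int(arr.size),
    )


@dataclass(frozen=True)
class ThirdsSummary:
    """Event counts in the 5' third, middle third and 3' third of transcripts."""

    five_prime: int
    middle: int
    three_prime: int

    @property
    def total(self) -> int:
        return self.five_prime + self.middle + self.three_prime

    def to_dict(self) -> dict:
        return {
            "five_prime": self.five_prime,
            "middle": self.middle,
            "three_prime": self.three_prime,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ThirdsSummary":
        return cls(data["five_prime"], data["middle"], data["three_prime"])


def thirds_summary(fractions: Sequence[float]) -> ThirdsSummary:
    """Three-bin positional summary (the 5'/middle/3' partition)."""
    profile = bin_profile(fractions, n_bins=3)
    return ThirdsSummary(*profile.counts)


@dataclass(frozen=True)
class UniformityTest:
    statistic: float
    pvalue: float


def uniformity_test(profile: PositionalProfile) -> UniformityTest:
    """Chi-square goodness-of-fit of the binned profile against uniform
    placement (equal expected counts per bin). Requires at least five
    expected events per bin."""
    if profile.total < 5 * profile.n_bins:
        raise ValueError(
            f"need >= {5 * profile.n_bins} events for {profile.n_bins} bins, "
            f"got {profile.total}"
        )
    stat, p = stats.chisquare(profile.counts)
    return UniformityTest(statistic=float(stat), pvalue=float(p))


def plot_profile(profile: PositionalProfile, path) -> None:
    """Bar plot of the positional profile (mapping frequency per frame)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = [
        (a + b) / 2 for a, b in zip(profile.bin_edges, profile.bin_edges[1:])
    ]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(centers, profile.counts, width=1.0 / profile.n_bins * 0.9)
    ax.set_xlabel("transcript-relative position (0 = 5' end, 1 = 3' end)")
    ax.set_ylabel("mapping events")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
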