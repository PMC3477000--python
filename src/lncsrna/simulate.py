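"""Seeded synthetic-data generator with planted truth.

Emulates the external resources the analysis consumes — a Gencode-like
annotation of lncRNA and protein-coding gene models, a deepBase-like small
RNA cluster table with class labels and matching reference annotation sets,
and a tissue tag-count matrix — with every generative parameter planted and
recorded, so the full pipeline can be validated by recovery tests without any
download.

Clusters are planted relative to transcripts: exon events arrive as a Poisson
process at the configured per-kilobase rate over each transcript's spliced
length, are positioned by the configured positional law in spliced
coordinates, then projected to genomic coordinates on the transcript strand.
Cluster lengths follow a log-normal law fitted to the observed cluster
footprint (mean 105.25 bases, median 86: sigma^2 = 2 ln(mean/median),
mu = ln(median)), truncated to fit the harboring region while preserving the
planted midpoint. A genome-wide uniform placement mode exists as a null
scenario.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import ClusterTable
from .model import GenomicInterval, SmallRNACluster, TranscriptModel

GroupKey = Tuple[str, str]


def _default_class_proportions() -> Dict[str, float]:
    # cluster-level label proportions among mapped clusters (12 miRNA, 9
    # nasRNA, 150 pasRNA, 113 repeat clusters of 1084)
    return {
        "miRNA": 0.011,
        "nasRNA": 0.008,
        "pasRNA": 0.138,
        "repeat": 0.104,
        "unannotated": 0.739,
    }


def _default_features_per_class() -> Dict[str, int]:
    # labeled clusters can be catalogued as several reference features
    # (e.g. 9 clusters <-> 41 pasRNAs); mean features emitted per labeled cluster
    return {"miRNA": 1, "nasRNA": 3, "pasRNA": 5, "repeat": 1}


@dataclass
class SimulationConfig:
    """All planted generative parameters. Defaults give a small, quick study;
    recovery tests scale the transcript counts up."""

    seed: int = 0
    n_lnc_transcripts: int = 200
    n_pc_transcripts: int = 100
    #: geometric mean exon counts (Gencode-like: ~2 for lncRNA, more for coding)
    lnc_exon_count_mean: float = 2.1
    pc_exon_count_mean: float = 5.0
    exon_length_median: float = 300.0
    exon_length_sigma: float = 0.5
    intron_length_median: float = 2000.0
    intron_length_sigma: float = 0.7
    #: planted mapping-event rates per kilobase, by biotype
    exon_density: Dict[str, float] = field(
        default_factory=lambda: {"lncRNA": 0.093, "protein_coding": 0.29}
    )
    intron_density: Dict[str, float] = field(
        default_factory=lambda: {"lncRNA": 0.042, "protein_coding": 0.059}
    )
    cluster_length_mean: float = 105.25
    cluster_length_median: float = 86.0
    #: "uniform" or "beta" (Beta(a, b) over transcript-relative position)
    positional_law: str = "uniform"
    beta_a: float = 0.5
    beta_b: float = 0.5
    class_proportions: Dict[str, float] = field(
        default_factory=_default_class_proportions
    )
    features_per_class: Dict[str, int] = field(
        default_factory=_default_features_per_class
    )
    n_libraries: int = 8
    dirichlet_alpha: float = 0.5
    library_depth: int = 2000
    intergenic_gap: Tuple[int, int] = (1000, 10000)
    transcripts_per_chromosome: int = 500
    chromosome_length: Optional[int] = None
    #: "transcript" plants events per region; "genome" is the uniform null
    placement: str = "transcript"
    genome_density_per_kb: float = 0.05

    def __post_init__(self) -> None:
        for rates in (self.exon_density, self.intron_density):
            if any(v < 0 for v in rates.values()):
                raise ValueError("densities must be >= 0")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("class proportions must sum to 1")
        if self.positional_law not in ("uniform", "beta"):
            raise ValueError(f"unknown positional law {self.positional_law!r}")
        if self.placement not in ("transcript", "genome"):
            raise ValueError(f"unknown placement mode {self.placement!r}")
        if not (1 < self.cluster_length_mean / self.cluster_length_median):
            raise ValueError("cluster length mean must exceed median")

    @property
    def cluster_length_mu(self) -> float:
        return math.log(self.cluster_length_median)

    @property
    def cluster_length_sigma(self) -> float:
        return math.sqrt(
            2.0 * math.log(self.cluster_length_mean / self.cluster_length_median)
        )

    def to_dict(self) -> dict:
        data = asdict(self)
        data["intergenic_gap"] = list(self.intergenic_gap)  # JSON-stable
        return data

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        if "intergenic_gap" in data:
            data["intergenic_gap"] = tuple(data["intergenic_gap"])
        return cls(**data)


@dataclass
class AnnotationLedger:
    """Generator bookkeeping for the annotation: realized per-group region
    counts and kilobases (the denominators of planted densities)."""

    region_counts: Dict[GroupKey, int]
    region_kb: Dict[GroupKey, float]


@dataclass
class ClusterTruth:
    """Planted truth for the cluster table."""

    exon_density: Dict[str, float]
    intron_density: Dict[str, float]
    region_kb: Dict[GroupKey, float]
    event_counts: Dict[GroupKey, int]
    positional_law: Tuple
    #: planted midpoint fractions of exon events, in emission order
    planted_fractions: List[float]
    class_labels: Dict[str, str]
    feature_counts: Dict[str, int]

    def to_dict(self) -> dict:
        return {
            "exon_density": self.exon_density,
            "intron_density": self.intron_density,
            "region_kb": {f"{b}:{k}": v for (b, k), v in self.region_kb.items()},
            "event_counts": {f"{b}:{k}": v for (b, k), v in self.event_counts.items()},
            "positional_law": list(self.positional_law),
            "n_planted_fractions": len(self.planted_fractions),
            "class_labels": self.class_labels,
            "feature_counts": self.feature_counts,
        }


@dataclass
class ExpressionTruth:
    """Planted per-cluster tissue weight vectors."""

    libraries: List[str]
    weights: Dict[str, List[float]]
    dirichlet_alpha: float
    library_depth: int


def _rng_for(config: SimulationConfig, stage: int) -> np.random.Generator:
    # independent integer-seeded streams per stage so each op is
    # deterministic on its own and across platforms
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


def _geometric_count(rng: np.random.Generator, mean: float, cap: int = 25) -> int:
    mean = max(1.0, mean)
    return int(min(cap, rng.geometric(1.0 / mean)))


def _lognormal_len(
    rng: np.random.Generator, median: float, sigma: float, minimum: int
) -> int:
    return max(minimum, int(round(rng.lognormal(math.log(median), sigma))))


def simulate_annotation(
    config: SimulationConfig,
) -> Tuple[List[TranscriptModel], AnnotationLedger]:
    """Place non-overlapping multi-exon gene models of both biotypes on
    synthetic chromosomes. Deterministic under a fixed seed."""
    rng = _rng_for(config, 0)
    biotypes = ["lncRNA"] * config.n_lnc_transcripts + [
        "protein_coding"
    ] * config.n_pc_transcripts
    counts: Dict[GroupKey, int] = {}
    kb: Dict[GroupKey, float] = {}
    transcripts: List[TranscriptModel] = []
    cursor = 0
    chrom_no = 1
    placed_on_chrom = 0
    for k, biotype in enumerate(biotypes):
        exon_mean = (
            config.lnc_exon_count_mean
            if biotype == "lncRNA"
            else config.pc_exon_count_mean
        )
        n_exons = _geometric_count(rng, exon_mean)
        exon_lens = [
            _lognormal_len(rng, config.exon_length_median, config.exon_length_sigma, 30)
            for _ in range(n_exons)
        ]
        intron_lens = [
            _lognormal_len(
                rng, config.intron_length_median, config.intron_length_sigma, 60
            )
            for _ in range(n_exons - 1)
        ]
        span = sum(exon_lens) + sum(intron_lens)
        if config.chromosome_length is not None:
            if span > config.chromosome_length:
                raise ValueError(
                    f"transcript span {span} exceeds chromosome length "
                    f"{config.chromosome_length}; increase chromosome_length"
                )
            if cursor + span + config.intergenic_gap[1] > config.chromosome_length:
                chrom_no += 1
                cursor = 0
                placed_on_chrom = 0
        elif placed_on_chrom >= config.transcripts_per_chromosome:
            chrom_no += 1
            cursor = 0
            placed_on_chrom = 0
        gap = int(rng.integers(config.intergenic_gap[0], config.intergenic_gap[1]))
        start = cursor + gap
        strand = "+" if rng.random() < 0.5 else "-"
        chrom = f"chr{chrom_no}"
        exons = []
        pos = start
        for i, elen in enumerate(exon_lens):
            exons.append(GenomicInterval(chrom, pos, pos + elen, strand))
            pos += elen
            if i < len(intron_lens):
                pos += intron_lens[i]
        t = TranscriptModel(
            transcript_id=f"T{k:06d}",
            gene_id=f"G{k:06d}",
            biotype=biotype,
            chrom=chrom,
            strand=strand,
            exons=tuple(exons),
        )
        transcripts.append(t)
        cursor = pos
        placed_on_chrom += 1
        counts[(biotype, "exon")] = counts.get((biotype, "exon"), 0) + n_exons
        counts[(biotype, "intron")] = counts.get((biotype, "intron"), 0) + n_exons - 1
        kb[(biotype, "exon")] = kb.get((biotype, "exon"), 0.0) + sum(exon_lens) / 1000.0
        kb[(biotype, "intron")] = (
            kb.get((biotype, "intron"), 0.0) + sum(intron_lens) / 1000.0
        )
    return transcripts, AnnotationLedger(region_counts=counts, region_kb=kb)


def _draw_fraction(rng: np.random.Generator, config: SimulationConfig) -> float:
    if config.positional_law == "uniform":
        return float(rng.random())
    return float(rng.beta(config.beta_a, config.beta_b))


def _place_cluster(
    rng: np.random.Generator,
    config: SimulationConfig,
    chrom: str,
    strand: str,
    mid: int,
    lo: int,
    hi: int,
) -> GenomicInterval:
    """A cluster whose genomic midpoint base (start+end)//2 is exactly ``mid``,
    shrunk if needed to stay within [lo, hi)."""
    length = max(
        1, int(round(rng.lognormal(config.cluster_length_mu, config.cluster_length_sigma)))
    )
    left = mid - lo
    right = hi - 1 - mid
    length = min(length, 2 * min(left, right) + 1)
    start = mid - length // 2
    return GenomicInterval(chrom, start, start + length, strand)


def simulate_clusters(
    config: SimulationConfig, transcripts: Sequence[TranscriptModel]
) -> Tuple[ClusterTable, Dict[str, List[Tuple[str, GenomicInterval]]], ClusterTruth]:
    """Plant small RNA clusters at the configured densities and positional law.

    Returns the cluster table, the matching reference annotation sets
    (class name -> features) and the planted truth.
    """
    rng = _rng_for(config, 1)
    clusters: List[SmallRNACluster] = []
    references: Dict[str, List[Tuple[str, GenomicInterval]]] = {}
    event_counts: Dict[GroupKey, int] = {}
    planted_fractions: List[float] = []
    n_skipped_regions = 0

    if config.placement == "genome":
        # null scenario: clusters uniform over the spanned genome, both strands
        span_by_chrom: Dict[str, int] = {}
        for t in transcripts:
            span_by_chrom[t.chrom] = max(
                span_by_chrom.get(t.chrom, 0), t.exons[-1].end + 10000
            )
        idx = 0
        for chrom in sorted(span_by_chrom):
            span = span_by_chrom[chrom]
            n = int(rng.poisson(config.genome_density_per_kb * span / 1000.0))
            for _ in range(n):
                mid = int(rng.integers(0, span))
                strand = "+" if rng.random() < 0.5 else "-"
                iv = _place_cluster(rng, config, chrom, strand, mid, 0, span)
                clusters.append(SmallRNACluster(f"scl{idx:06d}", iv))
                idx += 1
    else:
        idx = 0
        for t in transcripts:
            L = t.spliced_length
            rate = config.exon_density.get(t.biotype, 0.0)
            n_exon_events = int(rng.poisson(rate * L / 1000.0)) if rate > 0 else 0
            for _ in range(n_exon_events):
                frac = _draw_fraction(rng, config)
                mid_spliced = int(round(frac * (L - 1))) if L > 1 else 0
                mid = t.spliced_to_genomic(mid_spliced)
                exon = t.exons[t.exon_index_at(mid)]
                iv = _place_cluster(
                    rng, config, t.chrom, t.strand, mid, exon.start, exon.end
                )
                clusters.append(SmallRNACluster(f"scl{idx:06d}", iv))
                idx += 1
                planted_fractions.append(frac)
                key = (t.biotype, "exon")
                event_counts[key] = event_counts.get(key, 0) + 1
            irate = config.intron_density.get(t.biotype, 0.0)
            for intron in t.introns():
                if intron.length < 1:
                    n_skipped_regions += 1
                    continue
                n = (
                    int(rng.poisson(irate * intron.length / 1000.0))
                    if irate > 0
                    else 0
                )
                for _ in range(n):
                    mid = int(rng.integers(intron.start, intron.end))
                    iv = _place_cluster(
                        rng, config, t.chrom, t.strand, mid, intron.start, intron.end
                    )
                    clusters.append(SmallRNACluster(f"scl{idx:06d}", iv))
                    idx += 1
                    key = (t.biotype, "intron")
                    event_counts[key] = event_counts.get(key, 0) + 1

    # class labels and matching reference features
    label_names = sorted(config.class_proportions)
    probs = np.array([config.class_proportions[n] for n in label_names])
    class_labels: Dict[str, str] = {}
    feature_counts: Dict[str, int] = {}
    for c in clusters:
        label = label_names[int(rng.choice(len(label_names), p=probs))]
        class_labels[c.cluster_id] = label
        c.class_label = label
        if label == "unannotated":
            continue
        k = max(1, int(config.features_per_class.get(label, 1)))
        iv = c.interval
        k = min(k, iv.length)
        # tile k features across the cluster so each overlaps it on-strand
        edges = np.linspace(iv.start, iv.end, k + 1).astype(int)
        for j in range(k):
            fstart, fend = int(edges[j]), int(max(edges[j] + 1, edges[j + 1]))
            n_prev = feature_counts.get(label, 0)
            fid = f"{label}_{n_prev:05d}"
            references.setdefault(label, []).append(
                (fid, GenomicInterval(iv.chrom, fstart, fend, iv.strand))
            )
            feature_counts[label] = n_prev + 1

    region_kb: Dict[GroupKey, float] = {}
    for t in transcripts:
        region_kb[(t.biotype, "exon")] = (
            region_kb.get((t.biotype, "exon"), 0.0) + t.spliced_length / 1000.0
        )
        region_kb[(t.biotype, "intron")] = (
            region_kb.get((t.biotype, "intron"), 0.0)
            + sum(i.length for i in t.introns()) / 1000.0
        )

    law: Tuple = (
        ("beta", config.beta_a, config.beta_b)
        if config.positional_law == "beta"
        else ("uniform",)
    )
    truth = ClusterTruth(
        exon_density=dict(config.exon_density),
        intron_density=dict(config.intron_density),
        region_kb=region_kb,
        event_counts=event_counts,
        positional_law=law,
        planted_fractions=planted_fractions,
        class_labels=class_labels,
        feature_counts=feature_counts,
    )
    return ClusterTable(clusters=clusters), references, truth


def simulate_expression(
    config: SimulationConfig, clusters: Sequence[SmallRNACluster]
) -> Tuple[pd.DataFrame, ExpressionTruth]:
    """Per-cluster tissue weights ~ Dirichlet(alpha), tag counts multinomial
    at the configured depth. Low alpha concentrates mass in few libraries
    (high specificity)."""
    rng = _rng_for(config, 2)
    libraries = [f"tissue{i + 1:02d}" for i in range(config.n_libraries)]
    weights: Dict[str, List[float]] = {}
    rows = []
    ids = []
    alpha = np.full(config.n_libraries, config.dirichlet_alpha)
    for c in clusters:
        w = rng.dirichlet(alpha)
        counts = rng.multinomial(config.library_depth, w)
        weights[c.cluster_id] = [float(x) for x in w]
        rows.append(counts)
        ids.append(c.cluster_id)
        c.tag_counts = {lib: int(n) for lib, n in zip(libraries, counts)}
    matrix = pd.DataFrame(
        np.array(rows, dtype=int) if rows else np.zeros((0, config.n_libraries), int),
        index=pd.Index(ids, name="cluster_id"),
        columns=libraries,
    )
    truth = ExpressionTruth(
        libraries=libraries,
        weights=weights,
        dirichlet_alpha=config.dirichlet_alpha,
        library_depth=config.library_depth,
    )
    return matrix, truth


@dataclass
class SimulatedDataset:
    """Everything one simulation run produces, plus its planted truth."""

    config: SimulationConfig
    transcripts: List[TranscriptModel]
    ledger: AnnotationLedger
    clusters: ClusterTable
    references: Dict[str, List[Tuple[str, GenomicInterval]]]
    expression: pd.DataFrame
    cluster_truth: ClusterTruth
    expression_truth: ExpressionTruth

    def truth_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "clusters": self.cluster_truth.to_dict(),
            "expression": {
                "libraries": self.expression_truth.libraries,
                "dirichlet_alpha": self.expression_truth.dirichlet_alpha,
                "library_depth": self.expression_truth.library_depth,
            },
        }

    def write_truth_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run all three generator stages under one seed."""
    transcripts, ledger = simulate_annotation(config)
    clusters, references, cluster_truth = simulate_clusters(config, transcripts)
    expression, expression_truth = simulate_expression(config, clusters.clusters)
    return SimulatedDataset(
        config=config,
        transcripts=transcripts,
        ledger=ledger,
        clusters=clusters,
        references=references,
        expression=expression,
        cluster_truth=cluster_truth,
        expression_truth=expression_truth,
    )
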