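"""Readers and writers for the external formats the pipeline touches.

* Gencode-dialect GTF for transcript models (via :mod:`gffutils`); the
  1-based inclusive GTF convention is converted to 0-based half-open at parse
  time.
* BED6+N for small RNA cluster tables. Columns beyond the six BED fields are
  named by a ``#``-prefixed header line: a column named ``class`` carries the
  small RNA class label, columns named ``lib:<library>`` carry per-library tag
  counts. This explicit header is the dialect contract for deepBase-like
  dumps, whose column schemas vary.
* BED6 for reference small RNA annotation sets.
* TSV for expression matrices (clusters x libraries), JSON/TSV for reports.

Malformed rows in public annotation dumps are skipped and logged, not fatal.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
import pandas as pd

from .model import GenomicInterval, SmallRNACluster, TranscriptModel

logger = logging.getLogger(__name__)

_BIOTYPE_KEYS = ("transcript_type", "transcript_biotype", "gene_type", "gene_biotype")


@dataclass
class ClusterTable:
    """Rows of :class:`SmallRNACluster` plus bookkeeping about rejected rows."""

    clusters: List[SmallRNACluster] = field(default_factory=list)
    n_rejected: int = 0

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def library_ids(self) -> List[str]:
        libs: List[str] = []
        for c in self.clusters:
            for lib in c.tag_counts:
                if lib not in libs:
                    libs.append(lib)
        return libs


# ---------------------------------------------------------------------------
# GTF


def read_transcripts_gtf(
    path, biotype_filter: Optional[str] = None
) -> List[TranscriptModel]:
    """Read transcript models from a Gencode-dialect GTF.

    Exon features are grouped by ``transcript_id``; transcripts failing model
    validation (overlapping exons, zero-length gaps, ...) are skipped with a
    logged reason. Raises if the file is unreadable or no transcript survives
    the biotype filter.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: Dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        tid = feat.attributes.get("transcript_id", [None])[0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        if tid is None:
            logger.warning("GTF exon without transcript_id skipped (%s)", feat)
            continue
        biotype = None
        for key in _BIOTYPE_KEYS:
            if key in feat.attributes:
                biotype = feat.attributes[key][0]
                break
        entry = grouped.setdefault(
            tid,
            {
                "gene_id": gid,
                "biotype": biotype or "unknown",
                "chrom": feat.seqid,
                "strand": feat.strand,
                "exons": [],
            },
        )
        # GTF is 1-based inclusive; convert to 0-based half-open
        entry["exons"].append((feat.start - 1, feat.end))

    transcripts: List[TranscriptModel] = []
    n_skipped = 0
    for tid, entry in grouped.items():
        if biotype_filter is not None and entry["biotype"] != biotype_filter:
            continue
        exon_coords = sorted(entry["exons"])
        try:
            exons = tuple(
                GenomicInterval(entry["chrom"], s, e, entry["strand"])
                for s, e in exon_coords
            )
            transcripts.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=entry["gene_id"],
                    biotype=entry["biotype"],
                    chrom=entry["chrom"],
                    strand=entry["strand"],
                    exons=exons,
                )
            )
        except ValueError as exc:
            n_skipped += 1
            logger.warning("skipping transcript %s: %s", tid, exc)
    if n_skipped:
        logger.info("read_transcripts_gtf: skipped %d invalid transcripts", n_skipped)
    if not transcripts:
        raise ValueError(
            f"{path}: no transcripts left after biotype filter {biotype_filter!r}"
        )
    return transcripts


def write_transcripts_gtf(transcripts: Sequence[TranscriptModel], path) -> None:
    """Write transcript models as GTF (transcript + exon features)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'transcript_type "{t.biotype}";'
            )
            tx_start = t.exons[0].start + 1
            tx_end = t.exons[-1].end
            fh.write(
                f"{t.chrom}\tlncsrna\ttranscript\t{tx_start}\t{tx_end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for e in t.exons:
                fh.write(
                    f"{t.chrom}\tlncsrna\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Cluster tables (BED6+N)


def read_clusters_bed(path) -> ClusterTable:
    """Read a BED6+N small RNA cluster table.

    Without a header only the six BED columns are interpreted. With a header
    line ``#chrom start end name score strand [class] [lib:<id> ...]`` the
    ``class`` column supplies the class label ('.' = none) and ``lib:`` columns
    supply tag counts. Rows violating the interval invariants are rejected and
    logged.
    """
    path = Path(path)
    names: Optional[List[str]] = None
    clusters: List[SmallRNACluster] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                names = line.lstrip("#").split("\t")
                if len(names) == 1:  # tolerate space-separated headers
                    names = line.lstrip("#").split()
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 6:
                    raise ValueError("fewer than 6 columns")
                chrom, start, end, name, _score, strand = fields[:6]
                interval = GenomicInterval(chrom, int(start), int(end), strand)
                class_label = None
                tag_counts: Dict[str, int] = {}
                if names is not None:
                    for col, value in zip(names[6:], fields[6:]):
                        if col == "class":
                            class_label = None if value in (".", "") else value
                        elif col.startswith("lib:"):
                            tag_counts[col[4:]] = int(value)
                clusters.append(
                    SmallRNACluster(name, interval, class_label, tag_counts)
                )
            except ValueError as exc:
                n_rejected += 1
                logger.warning("%s:%d rejected row: %s", path, lineno, exc)
    seen = set()
    for c in clusters:
        if c.cluster_id in seen:
            raise ValueError(f"{path}: duplicate cluster id {c.cluster_id!r}")
        seen.add(c.cluster_id)
    return ClusterTable(clusters=clusters, n_rejected=n_rejected)


def write_clusters_bed(table, path) -> None:
    """Write clusters as BED6+N with an explicit ``#`` header line."""
    clusters = list(table)
    libs: List[str] = []
    has_class = any(c.class_label is not None for c in clusters)
    for c in clusters:
        for lib in c.tag_counts:
            if lib not in libs:
                libs.append(lib)
    header = ["chrom", "start", "end", "name", "score", "strand"]
    if has_class or libs:
        header.append("class")
    header += [f"lib:{lib}" for lib in libs]
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(header) + "\n")
        for c in clusters:
            iv = c.interval
            row = [iv.chrom, str(iv.start), str(iv.end), c.cluster_id, "0", iv.strand]
            if has_class or libs:
                row.append(c.class_label or ".")
            row += [str(c.tag_counts.get(lib, 0)) for lib in libs]
            fh.write("\t".join(row) + "\n")


def read_reference_bed(path) -> List[Tuple[str, GenomicInterval]]:
    """Read a BED6 reference annotation set as ``(feature_id, interval)`` pairs."""
    features: List[Tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 6:
                    raise ValueError("fewer than 6 columns")
                chrom, start, end, name, _score, strand = fields[:6]
                features.append((name, GenomicInterval(chrom, int(start), int(end), strand)))
            except ValueError as exc:
                logger.warning("%s:%d rejected feature: %s", path, lineno, exc)
    return features


def write_reference_bed(features: Iterable[Tuple[str, GenomicInterval]], path) -> None:
    with open(path, "w") as fh:
        for name, iv in features:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Expression matrices


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a cluster x library tag-count matrix.

    Missing cells are read as 0 with a warning; negative counts are an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        warnings.warn(f"{path}: missing cells read as 0", stacklevel=2)
        df = df.fillna(0)
    df = df.astype(int)
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative tag counts")
    return df


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="cluster_id")


# ---------------------------------------------------------------------------
# Reports


def write_report(obj, path, format: str = "json") -> None:
    """Write any report object exposing ``to_dict()`` (and optionally
    ``to_frame()`` for TSV output)."""
    if format == "json":
        with open(path, "w") as fh:
            json.dump(obj.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif format == "tsv":
        obj.to_frame().to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path, cls):
    """Read a JSON report written by :func:`write_report` back into ``cls``."""
    with open(path) as fh:
        return cls.from_dict(json.load(fh))
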