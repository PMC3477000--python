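# lncsrna

Strand-aware mapping of small RNA sequencing clusters onto long non-coding
RNA (lncRNA) and protein-coding gene models.

A subset of lncRNAs appears to be processed into small RNAs: when deepBase-
style small RNA clusters are intersected with lncRNA annotations, a
disproportionate number of clusters sit entirely inside lncRNA exons, with a
positional preference for the transcript ends. `lncsrna` implements this
integrative analysis as a tested pipeline for computational biologists who
want to run it on their own annotation/cluster tables — or validate it end to
end on synthetic data with planted truth.

## What it computes

Given transcript models *T* (multi-exon, stranded, biotype lncRNA or
protein-coding) and small RNA clusters *C* (stranded genomic intervals with
optional class labels and per-library tag counts):

* **Containment mapping** — a mapping event is a pair (*c*, *r*) where
  cluster *c* lies entirely within a single exon or intron *r* of some
  transcript, on the same strand. A cluster spanning an exon–intron junction
  maps nowhere; a cluster inside exons of *k* transcripts yields *k* events.
  An intervaltree-indexed implementation is verified against an exhaustive
  all-pairs oracle.
* **Length-adjusted density** — for each biotype × region-kind cell,
  events / total region length in kb, plus the exon:intron density ratio per
  biotype and distinct-cluster counts.
* **Positional preference** — each exon event's midpoint is mapped to
  spliced transcript coordinates (0 = 5' end, 1 = 3' end, strand-aware),
  binned into 5% frames (20 bins) or thirds, with a chi-square test against
  uniform placement.
* **Class annotation** — clusters are cross-referenced against reference
  small RNA sets (miRNA, pasRNA, nasRNA, repeats) with dual bookkeeping:
  clusters per class and distinct features per class.
* **Expression profiles** — tags-per-million normalization per library,
  an entropy-based tissue-specificity score (1 − H/ln n), and decomposition
  of a parent cluster into subclusters from independently cloned loci.
* **BLAT PSL arm** — for sequence-only lncRNA inputs: parse PSL, keep
  alignments covering > 90% of the query span, select one best hit per query
  deterministically, and turn alignment blocks into exons.

The synthetic-data generator plants all of these quantities (Poisson event
rates per kb, a Beta or uniform positional law, class proportions, Dirichlet
tissue weights) so every stage is testable by recovery.

## Worked example

```sh
lncsrna run-all --seed 7 --out-dir demo
```

simulates 200 lncRNA + 100 protein-coding gene models with clusters planted
at the default per-kb rates (lncRNA 0.093 exon / 0.042 intron;
protein-coding 0.29 / 0.059), runs every stage, and writes `demo/summary.json`:

```
run-all complete: 168 mapping events -> demo/summary.json
```

with densities recovered from the 168 mapped clusters (small-sample noise at
this size is expected; the recovery tests use larger simulations):

| biotype × region | events | total kb | density /kb |
|---|---|---|---|
| lncRNA exon | 8 | 142.1 | 0.056 |
| lncRNA intron | 29 | 600.9 | 0.048 |
| protein-coding exon | 55 | 193.5 | 0.284 |
| protein-coding intron | 76 | 1169.5 | 0.065 |

The summary also contains the 20-bin positional profile and thirds counts of
the lncRNA exon events, the class-annotation table (here 14 clusters hit 66
pasRNA features, 7 hit repeats, 42 unannotated of 63 mapped), and expression
summaries (median tissue specificity 0.298 across 63 profiled clusters).
Individual stages are available as `lncsrna simulate | map | density |
positions | classify | expression` on GTF/BED/TSV inputs.

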