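# Methods

## Coordinate model

All genomic intervals are 0-based half-open (BED convention); GTF input
(1-based inclusive) is converted at parse time, so interval arithmetic never
needs ±1 corrections. Spliced (transcript) coordinates number exonic bases
5'→3' on the transcript strand: position 0 is always the biological 5' end,
which for a minus-strand gene is the genomically rightmost exonic base. This
makes "3'-end preference" a strand-aware, transcript-relative statement.
Transcript models require sorted, disjoint exons with strictly positive
inter-exon gaps; a zero-length gap is rejected as a malformed annotation
rather than silently merged, so dirty inputs surface instead of shifting
intron counts. (The one exception is PSL block coalescing, below.)

## Containment mapping

A mapping event is full containment of a cluster in a *single* exon or
intron on the same strand. Spliced containment across a junction is
deliberately not a match: junction-spanning clusters are evidence against
simple processing of the mature transcript region and are excluded.
Unstranded clusters (BED strand ".") are excluded whenever strand agreement
is required — the conservative reading of same-orientation mapping — and are
counted in the log. Both mapping events and distinct mapped clusters are
reported; densities use events, since a cluster shared by the exons of k
isoforms occupies k denominators.

The indexed implementation uses one intervaltree per chromosome with a
containment post-filter. Its oracle, `brute_force_map`, evaluates the
containment predicate for the complete (cluster × region) cross product —
vectorised with numpy over flattened region arrays but with no indexing or
pruning — and the two paths must produce identical record sets; this
equivalence is exercised on randomized instances with clusters up to 7 kb
(the largest observed cluster scale) in the test suite.

## Densities

`total_region_kb` defaults to `dedup="none"`: region lengths are summed over
the redundant per-transcript exon/intron lists, i.e. straight per-exon
accounting in which isoform-shared exons count repeatedly. A `union` mode
merges overlapping same-strand regions first for a non-redundant
denominator; both are exposed because annotation-derived denominators are
ambiguous on this point. A zero-length group has undefined density and is
reported as missing rather than zero. No significance test is attached to
density differences; a chi-square uniformity test is provided for the
positional profile, where a quantitative check of the end-preference claim
is most needed.

## Positional metric

The position of an exon mapping is the spliced coordinate of its genomic
midpoint base `(start + end) // 2`, divided by `spliced_length − 1`, giving
0 for a cluster centred on the first transcript base and 1 for the last. The
midpoint was chosen because it is symmetric under strand reversal and robust
to cluster length; a start-based metric is a one-line variant for
sensitivity analysis. Binning uses `numpy.histogram` over [0, 1]: bin i is
[i/n, (i+1)/n) with the last bin closed at 1.0 so 3'-terminal events — the
region of interest — are never dropped. The thirds summary is the same
binning with n = 3. The uniformity test is a standard chi-square
goodness-of-fit against equal expected counts and requires ≥ 5 expected
events per bin.

## Class annotation

Multi-label by default: a cluster is tagged with every reference class it
overlaps by ≥ 1 base on the same strand (threshold `min_overlap_fraction`
of the cluster length, default effectively any overlap; a containment mode
and a miRNA > nasRNA > pasRNA > repeat priority collapse are switchable).
The report counts clusters per class and distinct features per class,
because one cluster can be catalogued as many features (9 clusters ↔ 41
pasRNAs in the curated arm).

## PSL filtering

Span coverage is aligned bases (Σ block sizes) over query length — not
target span over query length — so genomic insertions between blocks do not
inflate coverage. The filter keeps alignments with coverage strictly greater
than 0.90 ("more than 90 percent"), so exactly 0.90 fails. Best-hit
selection among survivors of one query maximizes matching bases with a fully
specified tie-break chain (greater coverage, then smallest target name,
start, end, strand), making the output invariant to input order. Adjacent
blocks with a zero-length target gap are coalesced into one exon before
model construction, since they are an alignment artifact (query-only gaps),
not an annotation error; overlapping blocks are rejected.

## Expression

Tags-per-million normalizes each library by its own total over the matrix at
hand. Specificity is 1 − H/ln(n) with H the Shannon entropy of the
renormalized profile: 0 = uniform, 1 = single-library. Both constructs are
this package's additions on top of the raw tag counts, which remain the
primary emitted values — cloning biases in small RNA libraries make
cross-small-RNA comparisons of absolute levels unreliable, so normalization
helps only across libraries, not across clusters. Subcluster decomposition
groups loci contained in a parent cluster into maximal runs split where
consecutive loci are ≥ `gap_threshold` bases apart (default 10 bases; there
is no standard delimitation rule, so the threshold is exposed as a flag).

## Synthetic data and what recovery shows

The generator emulates a Gencode-like annotation (two biotypes, geometric
exon counts, log-normal exon/intron lengths, non-overlapping placement on
synthetic chromosomes) and a deepBase-like cluster table. Exon events arrive
per transcript as Poisson with rate density × spliced kb, positioned by the
configured law (uniform or Beta(a, b)) in spliced coordinates and projected
to the genome on the transcript strand; intron events are uniform within
introns. Cluster lengths are log-normal fitted to the observed footprint
(mean 105.25 b, median 86 b: μ = ln 86, σ² = 2 ln(105.25/86)), truncated to
fit the harboring region *while preserving the planted midpoint*, so planted
positional fractions are recovered exactly up to base-grid rounding.
Default class proportions follow the observed cluster-level label shares
(≈1.1% miRNA, 0.8% nasRNA, 13.8% pasRNA, 10.4% repeat), with matching
reference features tiled over each labeled cluster. Expression counts are
multinomial at a configured depth with Dirichlet(α) tissue weights; small α
concentrates mass and raises specificity.

Because clusters are planted relative to transcripts, recovery of the
planted densities tests the mapping and accounting machinery, not genomic
realism: simulated transcripts never overlap, chromosomes are ideal, and
cluster positions are conditionally independent given the annotation. A
genome-wide uniform placement mode exists as a null scenario. Passing
recovery tests therefore demonstrates correctness of the computation on
data whose generative structure matches the model's assumptions — they say
nothing about biological enrichment in real annotations.

Recovery scales were chosen so every Poisson cell holds on the order of
1,000+ events (≈ 74,000 kb of simulated regions for the density check;
≈ 13,000 exon events for the positional check): enough for 3-standard-error
bands to be meaningfully narrow. Exon/intron length medians in those runs
(1 kb / 3 kb) are scaled rather than Gencode-realistic so the region totals
are reached with a tractable number of transcript objects; estimates are
compared against realized region lengths from the generator's ledger, so
the scaling does not bias recovery.

## Determinism

All randomness flows through `numpy.random.default_rng` seeded from integer
`SeedSequence` streams, one per generator stage. Reports are JSON with
sorted keys and no timestamps; `run-all` with a fixed seed is byte-identical
across runs, and the configuration (minus run-local paths) plus package
version is stamped into every summary.

## Known limitations

* Manual curation of exon annotations after BLAT filtering is inherently
  irreproducible; the filtered best-hit output is exposed for optional
  manual review instead.
* Cluster tables use an explicit `#`-header BED6+N dialect; headerless
  tables lose class labels and tag counts.
* The maximum-cluster-length filter defaults to off: reported cluster size
  ranges differ between resources (clusters up to ~7 kb, but some analyses
  restrict to ≤ 100 bp); `--max-cluster-length` reproduces either choice.
* Antisense (opposite-strand) mapping is available as a switch but no
  antisense-specific analysis is built on it.
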