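"""Synthetic-data generator: determinism, ledger consistency with emitted
files, planted positional/expression structure."""

import numpy as np
import pytest
from scipy import stats

from lncsrna import io as lio
from lncsrna.density import compute_density
from lncsrna.expression import specificity_score
from lncsrna.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_clusters,
    simulate_dataset,
    simulate_expression,
)


SMALL = dict(n_lnc_transcripts=60, n_pc_transcripts=30)


class TestDeterminism:
    def test_same_seed_byte_identical_gtf(self, tmp_path):
        for run in ("a", "b"):
            transcripts, _ = simulate_annotation(SimulationConfig(seed=9, **SMALL))
            lio.write_transcripts_gtf(transcripts, tmp_path / f"{run}.gtf")
        assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()

    def test_same_seed_identical_matrix(self):
        config = SimulationConfig(seed=3, **SMALL)
        ds1 = simulate_dataset(config)
        ds2 = simulate_dataset(config)
        assert ds1.expression.equals(ds2.expression)
        assert [c.interval for c in ds1.clusters] == [c.interval for c in ds2.clusters]

    def test_different_seeds_differ(self):
        a = simulate_dataset(SimulationConfig(seed=1, **SMALL))
        b = simulate_dataset(SimulationConfig(seed=2, **SMALL))
        assert [c.interval for c in a.clusters] != [c.interval for c in b.clusters]


class TestAnnotation:
    def test_single_exon_single_transcript(self):
        config = SimulationConfig(
            seed=0, n_lnc_transcripts=1, n_pc_transcripts=0, lnc_exon_count_mean=1.0
        )
        transcripts, ledger = simulate_annotation(config)
        assert len(transcripts) == 1
        assert transcripts[0].n_exons >= 1
        assert transcripts[0].biotype == "lncRNA"

    def test_ledger_matches_models(self):
        transcripts, ledger = simulate_annotation(SimulationConfig(seed=5, **SMALL))
        for biotype in ("lncRNA", "protein_coding"):
            ts = [t for t in transcripts if t.biotype == biotype]
            assert ledger.region_counts[(biotype, "exon")] == sum(t.n_exons for t in ts)
            assert ledger.region_kb[(biotype, "exon")] == pytest.approx(
                sum(t.spliced_length for t in ts) / 1000
            )
            assert ledger.region_kb[(biotype, "intron")] == pytest.approx(
                sum(i.length for t in ts for i in t.introns()) / 1000
            )

    def test_transcripts_do_not_overlap(self):
        transcripts, _ = simulate_annotation(SimulationConfig(seed=8, **SMALL))
        by_chrom = {}
        for t in transcripts:
            by_chrom.setdefault(t.chrom, []).append((t.exons[0].start, t.exons[-1].end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_infeasible_packing_errors(self):
        config = SimulationConfig(
            seed=0,
            n_lnc_transcripts=1,
            n_pc_transcripts=0,
            chromosome_length=100,
            exon_length_median=5000.0,
        )
        with pytest.raises(ValueError, match="chromosome_length"):
            simulate_annotation(config)

    def test_ledger_round_trips_through_gtf(self, tmp_path):
        """Generator bookkeeping equals what a fresh parse of the emitted
        file reports."""
        transcripts, ledger = simulate_annotation(SimulationConfig(seed=4, **SMALL))
        path = tmp_path / "sim.gtf"
        lio.write_transcripts_gtf(transcripts, path)
        parsed = lio.read_transcripts_gtf(path)
        assert len(parsed) == len(transcripts)
        assert sum(t.n_exons for t in parsed) == sum(
            ledger.region_counts[(b, "exon")] for b in ("lncRNA", "protein_coding")
        )


class TestClusters:
    def test_zero_densities_zero_clusters(self):
        config = SimulationConfig(
            seed=0,
            **SMALL,
            exon_density={"lncRNA": 0.0, "protein_coding": 0.0},
            intron_density={"lncRNA": 0.0, "protein_coding": 0.0},
        )
        transcripts, _ = simulate_annotation(config)
        table, refs, truth = simulate_clusters(config, transcripts)
        assert len(table) == 0 and truth.event_counts == {}

    def test_planted_clusters_all_recoverable(self):
        """Every planted event is recovered by the mapping pipeline: counts
        per cell equal the generator's bookkeeping exactly."""
        config = SimulationConfig(seed=6, n_lnc_transcripts=300, n_pc_transcripts=150)
        transcripts, _ = simulate_annotation(config)
        table, _, truth = simulate_clusters(config, transcripts)
        report, _ = compute_density(transcripts, table.clusters)
        for key, planted in truth.event_counts.items():
            assert report.cells[key].mapping_events == planted

    def test_cluster_table_round_trips(self, tmp_path):
        config = SimulationConfig(seed=6, **SMALL)
        ds = simulate_dataset(config)
        path = tmp_path / "clusters.bed"
        lio.write_clusters_bed(ds.clusters, path)
        back = lio.read_clusters_bed(path)
        assert len(back) == len(ds.clusters) and back.n_rejected == 0
        for orig, new in zip(ds.clusters, back):
            assert orig.interval == new.interval
            assert orig.class_label == new.class_label
            assert orig.tag_counts == new.tag_counts

    def test_beta_bias_recovered_in_fractions(self):
        """Planted Beta(0.5, 0.5) law shows up in the recovered midpoint
        fractions: terminal thirds exceed the middle third per the Beta CDF."""
        config = SimulationConfig(
            seed=7,
            n_lnc_transcripts=400,
            n_pc_transcripts=0,
            exon_density={"lncRNA": 2.0, "protein_coding": 0.0},
            intron_density={"lncRNA": 0.0, "protein_coding": 0.0},
            positional_law="beta",
        )
        transcripts, _ = simulate_annotation(config)
        table, _, truth = simulate_clusters(config, transcripts)
        _, mappings = compute_density(transcripts, table.clusters)
        fracs = [
            r.midpoint_fraction for r in mappings[("lncRNA", "exon")]
        ]
        n = len(fracs)
        assert n > 500
        p_mid = stats.beta.cdf(2 / 3, 0.5, 0.5) - stats.beta.cdf(1 / 3, 0.5, 0.5)
        n_mid = sum(1 / 3 <= f < 2 / 3 for f in fracs)
        assert abs(n_mid - n * p_mid) < 3 * np.sqrt(n * p_mid * (1 - p_mid))

    def test_reference_features_overlap_their_clusters(self):
        config = SimulationConfig(seed=10, **SMALL)
        ds = simulate_dataset(config)
        by_id = {c.cluster_id: c for c in ds.clusters}
        labeled = {
            cid: label
            for cid, label in ds.cluster_truth.class_labels.items()
            if label != "unannotated"
        }
        feature_intervals = {
            name: feats for name, feats in ds.references.items()
        }
        for cid, label in labeled.items():
            c = by_id[cid]
            hits = [
                iv
                for _, iv in feature_intervals[label]
                if iv.chrom == c.interval.chrom
                and iv.start < c.interval.end
                and c.interval.start < iv.end
                and iv.strand == c.interval.strand
            ]
            assert hits, f"labeled cluster {cid} has no overlapping {label} feature"


class TestExpression:
    def test_fixed_seed_identical(self):
        config = SimulationConfig(seed=12, **SMALL)
        transcripts, _ = simulate_annotation(config)
        table, _, _ = simulate_clusters(config, transcripts)
        m1, _ = simulate_expression(config, table.clusters)
        m2, _ = simulate_expression(config, table.clusters)
        assert m1.equals(m2)

    def test_near_uniform_alpha_low_specificity(self):
        """Large Dirichlet alpha -> near-uniform weights -> specificity ~0."""
        config = SimulationConfig(
            seed=13, **SMALL, dirichlet_alpha=1000.0, library_depth=100_000
        )
        transcripts, _ = simulate_annotation(config)
        table, _, _ = simulate_clusters(config, transcripts)
        matrix, _ = simulate_expression(config, table.clusters)
        scores = [specificity_score(row) for row in matrix.values if row.sum() > 0]
        assert np.median(scores) < 0.01

    def test_concentrated_alpha_higher_specificity(self):
        def median_specificity(alpha):
            config = SimulationConfig(seed=14, **SMALL, dirichlet_alpha=alpha)
            transcripts, _ = simulate_annotation(config)
            table, _, _ = simulate_clusters(config, transcripts)
            matrix, _ = simulate_expression(config, table.clusters)
            return np.median(
                [specificity_score(row) for row in matrix.values if row.sum() > 0]
            )

        assert median_specificity(0.1) > median_specificity(1000.0)
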