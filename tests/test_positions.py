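"""Positional analysis: midpoint fractions, binning conventions, thirds,
chi-square uniformity, strand-mirror symmetry."""

import numpy as np
import pytest
from scipy import stats

from lncsrna.mapping import build_index, map_clusters
from lncsrna.model import GenomicInterval, SmallRNACluster
from lncsrna.positions import (
    bin_profile,
    fractions_from_records,
    midpoint_fraction,
    thirds_summary,
    uniformity_test,
)
from .conftest import make_transcript


def map_one(t, start, end):
    index = build_index([t], "exon")
    c = SmallRNACluster("c", GenomicInterval(t.chrom, start, end, t.strand))
    (record,) = map_clusters([c], index)
    return record


class TestMidpointFraction:
    def test_first_base_is_zero(self):
        t = make_transcript(exon_coords=((100, 200),))
        assert midpoint_fraction(map_one(t, 100, 101), t) == 0.0

    def test_last_base_is_one(self):
        t = make_transcript(exon_coords=((100, 200),))
        assert midpoint_fraction(map_one(t, 199, 200), t) == 1.0

    def test_minus_strand_derived_value(self, two_exon_minus):
        """Exhaustively derived: on the minus-strand model the genomic
        midpoint base 150 of cluster [140,160) is spliced position 149 of
        200, fraction 149/199 ~= 0.7487."""
        record = map_one(two_exon_minus, 140, 160)
        frac = midpoint_fraction(record, two_exon_minus)
        assert frac == pytest.approx(149 / 199, abs=1e-12)
        assert frac == pytest.approx(0.7487, abs=1e-4)
        # stored fraction agrees with the recomputation
        assert record.midpoint_fraction == pytest.approx(frac)

    def test_plus_strand_agrees_with_genomic_midpoint(self, two_exon_plus):
        record = map_one(two_exon_plus, 140, 160)
        expected = two_exon_plus.genomic_to_spliced((140 + 160) // 2) / 199
        assert midpoint_fraction(record, two_exon_plus) == pytest.approx(expected)

    def test_intron_record_errors(self, two_exon_plus):
        index = build_index([two_exon_plus], "intron")
        c = SmallRNACluster("c", GenomicInterval("chr1", 220, 240, "+"))
        (record,) = map_clusters([c], index)
        with pytest.raises(ValueError):
            midpoint_fraction(record, two_exon_plus)

    def test_strand_reversal_mirrors_fractions(self):
        """Reversing the transcript strand maps fraction f to 1 - f (up to the
        one-base discreteness of the midpoint)."""
        plus = make_transcript(strand="+", exon_coords=((0, 101),))
        minus = make_transcript(strand="-", exon_coords=((0, 101),))
        for start, end in [(0, 1), (10, 31), (40, 61), (100, 101)]:
            f_plus = midpoint_fraction(map_one(plus, start, end), plus)
            # mirror the cluster position around the transcript middle
            m_start, m_end = 101 - end, 101 - start
            f_minus = midpoint_fraction(map_one(minus, m_start, m_end), minus)
            assert f_minus == pytest.approx(f_plus, abs=0.02)


class TestBinProfile:
    def test_edge_conventions(self):
        profile = bin_profile([0.0, 0.99, 1.0], n_bins=20)
        assert profile.counts[0] == 1
        assert profile.counts[19] == 2  # last bin closed at 1.0
        assert profile.total == 3

    def test_empty_input_all_zero(self):
        profile = bin_profile([], n_bins=20)
        assert profile.total == 0 and set(profile.counts) == {0}
        assert profile.fractions == tuple([0.0] * 20)

    def test_uniform_draws_within_binomial_bound(self):
        rng = np.random.default_rng(2)
        n = 10_000
        profile = bin_profile(rng.random(n), n_bins=20)
        sigma = np.sqrt(n * 0.05 * 0.95)
        for count in profile.counts:
            assert abs(count - 500) < 4 * sigma

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        profile = bin_profile(rng.random(777), n_bins=20)
        assert sum(profile.fractions) == pytest.approx(1.0, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bin_profile([-0.1, 0.5], n_bins=3)


class TestThirds:
    def test_one_per_third(self):
        t = thirds_summary([0.1, 0.5, 0.9])
        assert (t.five_prime, t.middle, t.three_prime) == (1, 1, 1)

    def test_all_five_prime(self):
        t = thirds_summary([0.0, 0.1, 0.32])
        assert (t.five_prime, t.middle, t.three_prime) == (3, 0, 0)

    def test_totals_match_20bin_profile(self):
        rng = np.random.default_rng(4)
        fracs = rng.random(500)
        assert thirds_summary(fracs).total == bin_profile(fracs, 20).total

    def test_end_biased_beta_terminal_excess(self):
        """Beta(0.5,0.5) plants end bias; terminal thirds jointly exceed the
        middle third, matching the closed-form Beta CDF within 3 sigma."""
        rng = np.random.default_rng(5)
        n = 20_000
        t = thirds_summary(rng.beta(0.5, 0.5, size=n))
        p_terminal = stats.beta.cdf(1 / 3, 0.5, 0.5) + (
            1 - stats.beta.cdf(2 / 3, 0.5, 0.5)
        )
        expected = n * p_terminal
        sigma = np.sqrt(n * p_terminal * (1 - p_terminal))
        assert t.five_prime + t.three_prime > t.middle
        assert abs((t.five_prime + t.three_prime) - expected) < 3 * sigma


class TestUniformityTest:
    def test_perfectly_uniform_counts(self):
        profile = bin_profile(np.repeat(np.arange(20) / 20 + 0.01, 10), 20)
        result = uniformity_test(profile)
        assert result.statistic == pytest.approx(0.0)
        assert result.pvalue == pytest.approx(1.0)

    def test_all_mass_one_bin_closed_form(self):
        """100 events in one of 20 bins: chi2 = sum (O-E)^2/E = 1900."""
        profile = bin_profile([0.5] * 100, n_bins=20)
        assert uniformity_test(profile).statistic == pytest.approx(1900.0)

    def test_insufficient_total_errors(self):
        with pytest.raises(ValueError):
            uniformity_test(bin_profile([0.5] * 99, n_bins=20))

    def test_type_one_error_rate(self):
        """Under uniform placement the 5%-level rejection rate is ~5%."""
        rng = np.random.default_rng(6)
        n_reject = 0
        reps = 1000
        for _ in range(reps):
            profile = bin_profile(rng.random(400), n_bins=20)
            if uniformity_test(profile).pvalue < 0.05:
                n_reject += 1
        assert abs(n_reject / reps - 0.05) < 0.02


class TestFractionsFromRecords:
    def test_stored_and_recomputed_agree(self, two_exon_minus):
        record = map_one(two_exon_minus, 140, 160)
        stored = fractions_from_records([record])
        recomputed = fractions_from_records(
            [record], {"t1": two_exon_minus}
        )
        assert stored == pytest.approx(recomputed)
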