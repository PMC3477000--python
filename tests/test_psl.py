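"""PSL parsing, span-coverage filtering, deterministic best-hit selection,
block-to-exon conversion."""

import random

import pytest

from lncsrna.psl import (
    PslAlignment,
    psl_to_transcript,
    read_psl,
    select_hits,
    span_coverage,
    write_psl,
)


def make_hit(
    query="q1",
    qsize=100,
    strand="+",
    target="chr1",
    tstart=1000,
    matches=95,
    blocks=((1000, 95),),
):
    sizes = tuple(size for _, size in blocks)
    starts = tuple(start for start, _ in blocks)
    return PslAlignment(
        query_name=query,
        query_size=qsize,
        strand=strand,
        target_name=target,
        target_start=starts[0],
        target_end=starts[-1] + sizes[-1],
        matches=matches,
        block_sizes=sizes,
        target_block_starts=starts,
    )


class TestSpanCoverage:
    @pytest.mark.parametrize(
        "blocks,qsize,expected",
        [
            (((0, 95),), 100, 0.95),
            (((0, 50), (200, 45)), 100, 0.95),
            (((0, 30), (100, 30)), 100, 0.60),
        ],
    )
    def test_aligned_bases_over_query_size(self, blocks, qsize, expected):
        a = make_hit(qsize=qsize, blocks=blocks, matches=min(qsize, 90))
        assert span_coverage(a) == pytest.approx(expected)

    def test_zero_query_size_rejected_at_construction(self):
        with pytest.raises(ValueError):
            make_hit(qsize=0, blocks=((0, 0),))


class TestSelectHits:
    def test_strictly_more_than_threshold(self):
        kept = select_hits([make_hit(blocks=((0, 95),))])
        assert len(kept) == 1
        # exactly 90% span is NOT "more than 90 percent"
        assert select_hits([make_hit(blocks=((0, 90),), matches=90)]) == []
        assert len(select_hits([make_hit(qsize=10000, blocks=((0, 9001),), matches=9001)])) == 1

    def test_best_match_kept_among_many(self):
        # a repeat-like query with 204 hits, exactly one full-length exact match
        rng = random.Random(0)
        hits = [
            make_hit(
                query="BC200",
                qsize=200,
                target=f"chr{rng.randint(1, 22)}",
                tstart=rng.randrange(1_000_000),
                matches=rng.randint(182, 199),
                blocks=((s := rng.randrange(1_000_000), rng.randint(182, 199)),),
            )
            for _ in range(203)
        ]
        best = make_hit(
            query="BC200", qsize=200, target="chr2", tstart=500, matches=200,
            blocks=((500, 200),),
        )
        hits.append(best)
        kept = select_hits(hits)
        assert kept == [best]

    def test_single_hit_per_query_and_order_invariance(self):
        rng = random.Random(1)
        hits = []
        for q in range(10):
            for _ in range(rng.randint(1, 6)):
                hits.append(
                    make_hit(
                        query=f"q{q}",
                        qsize=100,
                        target=f"chr{rng.randint(1, 3)}",
                        matches=rng.randint(91, 100),
                        blocks=((rng.randrange(10_000), rng.randint(91, 100)),),
                    )
                )
        kept = select_hits(hits)
        assert len({a.query_name for a in kept}) == len(kept)
        for _ in range(5):
            rng.shuffle(hits)
            assert select_hits(hits) == kept

    def test_tie_breaks_deterministic(self):
        a = make_hit(target="chr2", tstart=100, matches=95, blocks=((100, 95),))
        b = make_hit(target="chr1", tstart=900, matches=95, blocks=((900, 95),))
        c = make_hit(target="chr1", tstart=200, matches=95, blocks=((200, 95),))
        assert select_hits([a, b, c]) == [c]  # smallest target_name, then start


class TestPslToTranscript:
    def test_single_block(self):
        t = psl_to_transcript(make_hit(), "lncRNA")
        assert t.n_exons == 1 and t.spliced_length == 95

    def test_three_blocks_two_introns(self):
        a = make_hit(blocks=((0, 40), (100, 30), (200, 25)), matches=95)
        t = psl_to_transcript(a, "lncRNA")
        assert t.n_exons == 3 and len(t.introns()) == 2
        assert t.spliced_length == sum(a.block_sizes)

    def test_zero_gap_blocks_coalesce(self):
        a = make_hit(blocks=((0, 40), (40, 55)), matches=95)
        t = psl_to_transcript(a, "lncRNA")
        assert t.n_exons == 1 and t.spliced_length == 95

    def test_overlapping_blocks_error(self):
        with pytest.raises(ValueError):
            make_hit(blocks=((0, 50), (30, 45)), matches=95)

    def test_strand_taken_from_psl(self):
        t = psl_to_transcript(make_hit(strand="-"), "lncRNA")
        assert t.strand == "-"


class TestReadWritePsl:
    def test_round_trip(self, tmp_path):
        hits = [
            make_hit(query="qa", blocks=((0, 40), (100, 55)), matches=95),
            make_hit(query="qb", strand="-", blocks=((5, 95),)),
        ]
        path = tmp_path / "x.psl"
        write_psl(hits, path)
        assert read_psl(path) == hits

    def test_header_skipped(self, tmp_path):
        path = tmp_path / "h.psl"
        write_psl([make_hit()], tmp_path / "body.psl")
        body = (tmp_path / "body.psl").read_text()
        path.write_text(
            "psLayout version 3\n\nmatch\tmis- \trep. \n     \tmatch\tmatch\n"
            "---------------------------------\n" + body
        )
        assert len(read_psl(path)) == 1

    def test_fixture_with_72_queries_341_blocks(self, tmp_path):
        """A synthetic PSL shaped like the curated-database arm: 72 queries,
        one surviving best hit each, 341 alignment blocks in total."""
        rng = random.Random(3)
        # distribute 341 blocks over 72 queries (each >= 1)
        block_counts = [1] * 72
        for _ in range(341 - 72):
            block_counts[rng.randrange(72)] += 1
        hits = []
        for q, nb in enumerate(block_counts):
            pos, blocks = 1000 * q, []
            for _ in range(nb):
                size = rng.randint(30, 80)
                blocks.append((pos, size))
                pos += size + rng.randint(1, 500)
            total = sum(size for _, size in blocks)
            hits.append(
                make_hit(
                    query=f"lnc{q}",
                    qsize=total,  # full coverage
                    matches=total,
                    blocks=tuple(blocks),
                )
            )
        path = tmp_path / "db.psl"
        write_psl(hits, path)
        kept = select_hits(read_psl(path))
        models = [psl_to_transcript(a, "lncRNA") for a in kept]
        assert len(models) == 72
        assert sum(t.n_exons for t in models) == 341
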