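import numpy as np
import pytest

from peakscape import genome_io as gio
from peakscape import interval_engine as ie
from peakscape import synthetic_data as sd

from conftest import coverage_oracle


def iv(chrom, start, end):
    return gio.GenomicInterval(chrom, start, end)


def mk_tx(tid, tss, aug, tes, strand="+", chrom="chr1"):
    return gio.TranscriptModel(
        tid, tid.split(".")[0], chrom, strand, tss, aug, tes,
        has_5utr=tss != aug,
    )


class TestClassifyLocations:
    @pytest.fixture
    def annotation(self):
        # gene [100, 1001) with tss at 100; gene [5000, 7001) tss at 7000 (-)
        return [
            mk_tx("A.1", 100, 200, 1000),
            mk_tx("B.1", 7000, 6800, 5000, strand="-"),
        ]

    def test_interval_on_tss(self, annotation):
        res = ie.classify_locations(gio.Track([iv("chr1", 95, 105)]), annotation)
        assert res.counts == {"TSS": 1, "GENE": 0, "INTERGENIC": 0}

    def test_interval_inside_gene(self, annotation):
        res = ie.classify_locations(gio.Track([iv("chr1", 400, 450)]), annotation)
        assert res.counts["GENE"] == 1

    def test_interval_intergenic(self, annotation):
        res = ie.classify_locations(gio.Track([iv("chr1", 2000, 2100)]), annotation)
        assert res.counts["INTERGENIC"] == 1

    def test_minus_strand_tss(self, annotation):
        res = ie.classify_locations(gio.Track([iv("chr1", 6995, 7005)]), annotation)
        assert res.counts["TSS"] == 1

    def test_unknown_chromosome_warns_intergenic(self, annotation):
        with pytest.warns(UserWarning, match="absent"):
            res = ie.classify_locations(
                gio.Track([iv("chrX", 0, 100)]), annotation
            )
        assert res.counts["INTERGENIC"] == 1

    def test_counts_sum_and_fractions(self, small_track, small_genome):
        res = ie.classify_locations(small_track, small_genome.transcripts)
        assert res.n == len(small_track)
        assert abs(sum(res.fractions.values()) - 1) < 1e-12

    def test_empty_annotation_raises(self, small_track):
        with pytest.raises(ValueError):
            ie.classify_locations(small_track, [])


class TestIntersect:
    def test_simple_overlap(self):
        out = ie.intersect(
            gio.Track([iv("chr1", 0, 100)]), gio.Track([iv("chr1", 50, 150)])
        )
        assert [(i.start, i.end) for i in out.intervals()] == [(50, 100)]

    def test_disjoint(self):
        out = ie.intersect(
            gio.Track([iv("chr1", 0, 10)]), gio.Track([iv("chr1", 20, 30)])
        )
        assert len(out) == 0

    def test_self_intersection_identity(self, small_track):
        m = small_track.merged()
        assert ie.intersect(m, m) == m

    def test_commutative_total_length(self, small_track, small_state_map):
        a, b = small_track, small_state_map.track(2, 4)
        assert (
            ie.intersect(a, b).total_length == ie.intersect(b, a).total_length
        )

    def test_against_per_base_oracle(self, small_state_map):
        rng = np.random.default_rng(5)
        starts = rng.integers(0, 990_000, size=200)
        track = gio.Track(
            [iv("chr1", int(s), int(s + rng.integers(20, 900))) for s in starts]
        ).merged()
        state_track = small_state_map.track(*small_state_map.labels[:4])
        out = ie.intersect(track, state_track)
        cov_a = coverage_oracle(track, 1_000_000)
        cov_b = coverage_oracle(state_track, 1_000_000)
        # oracle: per-base boolean AND
        assert out.total_length == int((cov_a & cov_b).sum())


class TestSubtract:
    def test_middle_hole(self):
        out = ie.subtract(
            gio.Track([iv("chr1", 0, 100)]), gio.Track([iv("chr1", 40, 60)])
        )
        assert [(i.start, i.end) for i in out.intervals()] == [(0, 40), (60, 100)]

    def test_partition(self, small_track, small_state_map):
        s = small_state_map.track(2)
        inside = ie.intersect(small_track, s)
        outside = ie.subtract(small_track, s)
        assert (
            inside.total_length + outside.total_length
            == small_track.merged().total_length
        )


class TestOverlapFraction:
    def test_half(self):
        assert ie.overlap_fraction(
            gio.Track([iv("chr1", 0, 100)]), gio.Track([iv("chr1", 50, 150)])
        ) == 0.5

    def test_subset_is_one(self):
        assert ie.overlap_fraction(
            gio.Track([iv("chr1", 10, 20)]), gio.Track([iv("chr1", 0, 100)])
        ) == 1.0

    def test_disjoint_zero(self):
        assert ie.overlap_fraction(
            gio.Track([iv("chr1", 0, 10)]), gio.Track([iv("chr1", 50, 60)])
        ) == 0.0

    def test_empty_query_raises(self):
        with pytest.raises(ValueError):
            ie.overlap_fraction(gio.Track(), gio.Track([iv("chr1", 0, 10)]))

    def test_genome_covering_reference(self, small_track):
        genome = gio.Track([iv(c, 0, 1_000_000) for c in ("chr1", "chr2")])
        assert ie.overlap_fraction(small_track, genome) == 1.0


class TestUpstreamWindow:
    def test_plus_strand(self):
        tx = mk_tx("A.1", 10_000, 10_200, 11_999)
        w = ie.upstream_window(tx, -500, 0)
        assert (w.start, w.end) == (9_500, 10_000)

    def test_minus_strand_mirrored(self):
        tx = mk_tx("B.1", 11_999, 11_800, 10_000, strand="-")
        w = ie.upstream_window(tx, -500, 0)
        assert (w.start, w.end) == (12_000, 12_500)

    def test_truncated_at_chromosome_start(self):
        tx = mk_tx("A.1", 300, 400, 1_200)
        w = ie.upstream_window(tx, -500, 0)
        assert (w.start, w.end) == (0, 300)

    def test_fully_off_chromosome_is_none(self):
        tx = mk_tx("A.1", 100, 200, 1_000)
        assert ie.upstream_window(tx, -3500, -3000) is None


class TestBuildUpstreamDatasets:
    def test_isolated_gene_all_eight(self):
        tx = mk_tx("A.1", 10_000, 10_200, 11_999)
        ds = ie.build_upstream_datasets([tx])
        assert ds.counts == [1] * 8

    def test_two_gene_hand_enumeration(self, two_gene_fixture):
        # hand-worked: all 7 bins + UTR survive for the upstream gene A;
        # for B only the [-500,0) bin and the UTR survive (bins 2-6 hit
        # gene A's body, bin 1 hits the depth-3000 upstream windows)
        ds = ie.build_upstream_datasets(two_gene_fixture)
        assert ds.counts == [1, 1, 1, 1, 1, 1, 2, 2]

    def test_no_overlap_with_transcripts(self, small_genome):
        txs = gio.dedupe_by_tss(small_genome.transcripts)
        ds = ie.build_upstream_datasets(txs)
        spans = ie.transcript_span_track(txs)
        for t in ds.tracks[:7]:
            assert ie.overlap_length(t, spans) == 0

    def test_bin7_never_overlaps_depth500_windows_of_others(self, small_genome):
        # invariant: dataset k<=6 regions avoid the nested upstream range
        txs = gio.dedupe_by_tss(small_genome.transcripts)
        ds = ie.build_upstream_datasets(txs)
        for k in range(1, 7):
            depth = 3500 - k * 500
            nested = gio.Track(
                [
                    w
                    for tx in txs
                    if (w := ie.upstream_window(tx, -depth, 0)) is not None
                ]
            ).merged()
            assert ie.overlap_length(ds.tracks[k - 1], nested) == 0

    def test_utr_dataset_requires_5utr(self):
        tx = mk_tx("A.1", 10_000, 10_000, 11_999)  # tss == aug
        ds = ie.build_upstream_datasets([tx])
        assert ds.counts[7] == 0

    def test_candidate_bins_march_toward_tss(self, two_gene_fixture):
        tx = two_gene_fixture[0]
        uppers = []
        for k in range(1, 8):
            lo = -3500 + (k - 1) * 500
            w = ie.upstream_window(tx, lo, lo + 500)
            uppers.append(w.start)
        assert uppers == sorted(uppers)


class TestLinkGenes:
    def test_edge_inside_window(self):
        tx = mk_tx("A.1", 10_000, 10_200, 11_999)
        track = gio.Track([iv("chr1", 6_500, 6_501)])  # offset -3500, 1 bp
        assert "A" in ie.link_genes(track, [tx])

    def test_just_outside_window(self):
        tx = mk_tx("A.1", 10_000, 10_200, 11_999)
        track = gio.Track([iv("chr1", 6_499, 6_500)])  # offset -3501
        assert ie.link_genes(track, [tx]) == {}

    def test_matches_boolean_oracle(self, small_genome, small_track):
        txs = small_genome.transcripts
        linked = set(ie.link_genes(small_track, txs))
        # oracle: per-base AND of window coverage and track coverage
        expected = set()
        for chrom in ("chr1", "chr2"):
            cov = coverage_oracle(small_track, 1_000_000, chrom=chrom)
            for tx in txs:
                if tx.chrom != chrom:
                    continue
                if tx.strand == "+":
                    lo, hi = tx.tss - 3500, tx.tss + 1
                else:
                    lo, hi = tx.tss, tx.tss + 3501
                if cov[max(lo, 0) : hi].any():
                    expected.add(tx.gene_id)
        assert linked == expected
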