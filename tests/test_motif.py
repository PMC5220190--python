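import itertools

import numpy as np
import pytest

from peakscape import genome_io as gio
from peakscape import motif as mo
from peakscape import synthetic_data as sd


@pytest.fixture(scope="module")
def pwm():
    return mo.pwm_from_pfm(mo.teil_pfm())


def naive_score(pwm, seq):
    """Independent per-window scoring oracle (pure python)."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    raw = 0.0
    for j, base in enumerate(seq):
        if base not in idx:
            return None
        raw += pwm.weights[idx[base], j]
    return (raw - pwm.s_min) / (pwm.s_max - pwm.s_min)


def naive_scan(pwm, seq, threshold, both_strands):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    L = pwm.length
    positions = hits = 0
    for i in range(len(seq) - L + 1):
        win = seq[i : i + L]
        s_f = naive_score(pwm, win)
        s_r = None
        if both_strands:
            rc = "".join(comp.get(b, "N") for b in reversed(win))
            s_r = naive_score(pwm, rc)
        scores = [s for s in (s_f, s_r) if s is not None]
        if not scores:
            continue
        positions += 1
        if max(scores) >= threshold - 1e-12:
            hits += 1
    return positions, hits


class TestPfm:
    def test_from_consensus_shape_and_sums(self):
        pfm = mo.teil_pfm()
        assert pfm.counts.shape == (4, 8)
        assert (pfm.counts.sum(axis=0) == 12).all()

    def test_consensus_roundtrip(self):
        assert mo.teil_pfm().consensus == mo.CONSENSUS

    def test_unequal_column_sums_rejected(self):
        counts = np.ones((4, 3))
        counts[0, 0] = 5
        with pytest.raises(ValueError, match="column sums"):
            mo.Pfm(counts)

    def test_file_roundtrip(self, tmp_path):
        pfm = mo.teil_pfm()
        p = tmp_path / "m.pfm"
        mo.write_pfm(pfm, p)
        back = mo.read_pfm(p)
        np.testing.assert_array_equal(back.counts, pfm.counts)


class TestPwmFromPfm:
    def test_uniform_pfm_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            mo.pwm_from_pfm(mo.Pfm(np.full((4, 4), 3.0)))

    def test_single_sequence_consensus_is_max(self):
        pfm = mo.Pfm.from_consensus("ACGTACGT", sites=12)
        pwm = mo.pwm_from_pfm(pfm)
        assert mo.score_normalized(pwm, "ACGTACGT") == pytest.approx(1.0)
        for j, alt in enumerate("GCGTACGT ATGTACGT".split()):
            assert mo.score_normalized(pwm, alt) < 1.0

    def test_mismatch_strictly_lowers(self):
        pfm = mo.Pfm.from_consensus("ACGTACGT", sites=12)
        pwm = mo.pwm_from_pfm(pfm)
        best = mo.score_normalized(pwm, "ACGTACGT")
        seq = list("ACGTACGT")
        for j in range(8):
            for b in "ACGT":
                if b == seq[j]:
                    continue
                mut = seq.copy()
                mut[j] = b
                assert mo.score_normalized(pwm, "".join(mut)) < best

    def test_pseudocount_positive_required(self):
        with pytest.raises(ValueError):
            mo.pwm_from_pfm(mo.teil_pfm(), pseudocount=0)


class TestScoreNormalized:
    def test_consensus_one_anticonsensus_zero(self, pwm):
        scores = {
            oct_: mo.score_normalized(pwm, "".join(oct_))
            for oct_ in itertools.product("ACGT", repeat=8)
        }
        vals = np.array(list(scores.values()))
        assert vals.min() >= 0 and vals.max() <= 1
        assert scores[tuple("ACGAACCT")] == pytest.approx(1.0)
        # every fully degenerate-consensus octamer scores 1.0
        for y1 in "CT":
            for w in "AT":
                for y2 in "CT":
                    assert scores[tuple(f"A{y1}G{w}A{y2}CT")] == pytest.approx(1.0)

    def test_threshold_counts_match_exhaustive_oracle(self, pwm):
        all_scores = np.array(
            [
                naive_score(pwm, "".join(oct_))
                for oct_ in itertools.product("ACGT", repeat=8)
            ]
        )
        for thr in (0.5, 0.8, 0.91, 1.0):
            fast = sum(
                mo.score_normalized(pwm, "".join(o)) >= thr
                for o in itertools.islice(
                    itertools.product("ACGT", repeat=8), 0, None, 97
                )
            )
            oracle = sum(
                s >= thr for s in all_scores[::97]
            )
            assert fast == oracle

    def test_wrong_length_raises(self, pwm):
        with pytest.raises(ValueError):
            mo.score_normalized(pwm, "ACGT")

    def test_ambiguous_base_raises(self, pwm):
        with pytest.raises(ValueError, match="ambiguous"):
            mo.score_normalized(pwm, "ACGNACGT")


class TestScan:
    def test_single_planted_consensus(self, pwm):
        rng = np.random.default_rng(1)
        # background guaranteed free of any hit at threshold 1.0: use a
        # repeat that cannot reach the maximal score on either strand
        seq = "ACCA" * 100 + "ACGAACCT" + "ACCA" * 100
        res = mo.scan(pwm, {"s": seq}, threshold=1.0)
        assert res.hits == 1

    def test_short_sequence_contributes_nothing(self, pwm):
        res = mo.scan(pwm, {"s": "ACGT"})
        assert res.positions == 0
        with pytest.raises(ZeroDivisionError):
            res.density

    def test_empty_sequence_set_raises(self, pwm):
        with pytest.raises(ValueError):
            mo.scan(pwm, {})

    def test_matches_naive_oracle_exactly(self, pwm):
        rng = np.random.default_rng(3)
        for trial in range(5):
            seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04], size=400))
            for thr in (0.6, 0.91):
                for both in (True, False):
                    res = mo.scan(pwm, {"s": seq}, threshold=thr, both_strands=both)
                    positions, hits = naive_scan(pwm, seq, thr, both)
                    assert (res.positions, res.hits) == (positions, hits)

    def test_random_pwm_random_sequences_oracle(self):
        rng = np.random.default_rng(11)
        for trial in range(3):
            counts = rng.integers(0, 9, size=(4, 6)).astype(float)
            counts += (counts.sum(axis=0).max() - counts.sum(axis=0)) / 4
            # make column sums equal by padding evenly
            pfm = mo.Pfm(counts)
            try:
                pwm_r = mo.pwm_from_pfm(pfm)
            except ValueError:
                continue
            seq = "".join(rng.choice(list("ACGT"), size=300))
            res = mo.scan(pwm_r, {"s": seq}, threshold=0.8)
            positions, hits = naive_scan(pwm_r, seq, 0.8, True)
            assert (res.positions, res.hits) == (positions, hits)

    def test_hits_monotone_in_threshold(self, pwm):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        hits = [
            mo.scan(pwm, {"s": seq}, threshold=t).hits
            for t in np.linspace(0, 1, 11)
        ]
        assert hits == sorted(hits, reverse=True)

    def test_reverse_complement_symmetry(self, pwm):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), size=1500))
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        a = mo.scan(pwm, {"s": seq}, both_strands=True)
        b = mo.scan(pwm, {"s": rc}, both_strands=True)
        assert a.hits == b.hits and a.positions == b.positions

    def test_planted_rate_recovered(self):
        # motifs planted at a known per-kb rate: estimated density within
        # 3 binomial SE of the planted + background rate
        rng = np.random.default_rng(7)
        n_bp = 200_000
        seq = "".join(rng.choice(list("ACGT"), size=n_bp))
        domains = {1: gio.Track([gio.GenomicInterval("chr1", 0, n_bp)])}
        rate = 0.5  # per kb
        mutated, truth = sd.plant_motifs({"chr1": seq}, domains, {1: rate}, seed=8)
        pwm_t = mo.pwm_from_pfm(mo.teil_pfm())
        res = mo.scan(pwm_t, mutated, threshold=0.91)
        bg = mo.scan(pwm_t, {"chr1": seq}, threshold=0.91)
        n_planted = len(truth.params["planted"])
        expected = n_planted + bg.hits
        se = np.sqrt(expected)
        assert abs(res.hits - expected) < 3 * se + 3


class TestDensityCompare:
    def test_identical_proportions_not_significant(self):
        a = [mo.SiteScanResult(positions=1000, hits=50, label="i1")]
        b = [mo.SiteScanResult(positions=1000, hits=50, label="i1")]
        df = mo.density_compare(a, b, n_tests=8)
        assert df.loc[0, "p"] > 0.99
        assert not df.loc[0, "significant"]

    def test_extreme_table_significant(self):
        # [[10,0],[0,10]]: full hypergeometric enumeration gives
        # p = 2 / C(20,10) = 2/184756
        a = [mo.SiteScanResult(positions=10, hits=10)]
        b = [mo.SiteScanResult(positions=10, hits=0)]
        df = mo.density_compare(a, b, n_tests=8)
        assert df.loc[0, "p"] == pytest.approx(2 / 184756, rel=1e-9)
        assert df.loc[0, "significant"]

    def test_zero_positions_skipped(self):
        a = [mo.SiteScanResult(positions=0, hits=0, label="empty")]
        b = [mo.SiteScanResult(positions=100, hits=5)]
        df = mo.density_compare(a, b)
        assert "skipped" in df.loc[0, "note"]
        assert np.isnan(df.loc[0, "p"])

    def test_normalized_density(self):
        genome = mo.SiteScanResult(positions=10_000, hits=10)
        local = mo.SiteScanResult(positions=100, hits=2)
        assert local.normalized_density(genome) == pytest.approx(20.0)


class TestDensityVsThreshold:
    def test_enrichment_curve(self):
        rng = np.random.default_rng(9)
        bg = {"b": "".join(rng.choice(list("ACGT"), size=50_000))}
        domains = {1: gio.Track([gio.GenomicInterval("chr1", 0, 20_000)])}
        fg_seq = "".join(rng.choice(list("ACGT"), size=20_000))
        fg, _ = sd.plant_motifs({"chr1": fg_seq}, domains, {1: 1.0}, seed=10)
        pwm_t = mo.pwm_from_pfm(mo.teil_pfm())
        df = mo.density_vs_threshold(pwm_t, fg, bg, thresholds=[0.7, 0.91])
        # at a permissive threshold background noise swamps the signal; the
        # tight threshold separates the planted foreground cleanly
        assert df.loc[1, "enrichment"] > 2
        assert df.loc[1, "enrichment"] > df.loc[0, "enrichment"]
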