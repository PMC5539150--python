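import pytest

from luxcassette.cassette_topology import (
    DEFAULT_MAX_GAP_BP,
    TopologyError,
    TopologyPattern,
    classify_topology,
    orf_length_aa,
    pair_cassettes,
)
from luxcassette.datasets import published_cassette_features
from luxcassette.io_formats import GeneFeature


def gene(replicon, tag, start, end, strand, cls):
    return GeneFeature(replicon, tag, start, end, strand, cls)


class TestOrfLength:
    @pytest.mark.parametrize(
        "start,end,expected",
        [(38419, 38994, 191), (29123, 29698, 191), (1, 603, 200)],
    )
    def test_stop_codon_included(self, start, end, expected):
        assert orf_length_aa(gene("r", "g", start, end, "+", "luxI")) == expected

    def test_span_not_divisible_names_locus(self):
        with pytest.raises(TopologyError, match="oddspan"):
            orf_length_aa(gene("r", "oddspan", 1, 10, "+", "luxI"))

    def test_lone_stop_warns(self):
        with pytest.warns(UserWarning, match="lone stop"):
            assert orf_length_aa(gene("r", "tiny", 1, 3, "+", "luxI")) == 0


class TestPairing:
    def test_gap_is_end_to_start_arithmetic(self):
        feats = [
            gene("r", "R", 117, 689, "+", "luxR"),
            gene("r", "I", 3948, 4550, "-", "luxI"),
        ]
        result = pair_cassettes(feats, 3400)
        assert len(result.pairs) == 1
        assert result.pairs[0].gap_bp == 3948 - 689 - 1 == 3258

    def test_gap_beyond_threshold_leaves_solos(self):
        feats = [
            gene("r", "R", 100, 699, "+", "luxR"),
            gene("r", "I", 4200, 4799, "+", "luxI"),  # gap 3500
        ]
        result = pair_cassettes(feats, 3400)
        assert not result.pairs
        assert [f.locus_tag for f in result.solo_luxi] == ["I"]
        assert [f.locus_tag for f in result.solo_luxr] == ["R"]

    def test_each_luxr_used_once_and_nearest_preferred(self):
        feats = [
            gene("r", "I1", 1000, 1599, "+", "luxI"),
            gene("r", "R1", 1700, 2299, "+", "luxR"),
            gene("r", "I2", 2500, 3099, "+", "luxI"),
        ]
        result = pair_cassettes(feats, 3400)
        assert len(result.pairs) == 1
        assert result.pairs[0].luxI.locus_tag == "I1"  # gap 100 < 200
        assert [f.locus_tag for f in result.solo_luxi] == ["I2"]

    def test_overlapping_pair_flagged(self):
        feats = [
            gene("r", "R", 100, 699, "+", "luxR"),
            gene("r", "I", 650, 1249, "+", "luxI"),
        ]
        with pytest.warns(UserWarning, match="overlapping"):
            result = pair_cassettes(feats)
        assert result.pairs[0].gap_bp == 0
        assert result.pairs[0].overlapping

    def test_input_order_invariance(self, rng):
        feats = [
            gene("r1", "R1", 100, 699, "+", "luxR"),
            gene("r1", "I1", 900, 1499, "+", "luxI"),
            gene("r2", "I2", 100, 699, "-", "luxI"),
            gene("r2", "R2", 1000, 1599, "+", "luxR"),
            gene("r2", "X1", 750, 900, "+", "other"),
        ]
        baseline = pair_cassettes(feats)
        for _ in range(5):
            shuffled = list(feats)
            rng.shuffle(shuffled)
            assert pair_cassettes(shuffled) == baseline


class TestTopologyRender:
    def test_co_oriented_adjacent(self):
        feats = [
            gene("r", "R", 37479, 38207, "+", "luxR"),
            gene("r", "I", 38419, 38994, "+", "luxI"),
        ]
        (pair,), = (pair_cassettes(feats).pairs,)
        assert pair.pattern.render == "R>I>"

    def test_reversed_left_with_two_intervening(self):
        feats = [
            gene("r", "I", 94575, 95183, "-", "luxI"),
            gene("r", "x1", 95250, 95449, "+", "other"),
            gene("r", "x2", 95500, 95699, "-", "other"),
            gene("r", "R", 95914, 96633, "+", "luxR"),
        ]
        (pair,) = pair_cassettes(feats).pairs
        assert pair.n_intervening == 2
        assert pair.pattern.render == "<I X(2) R>"

    def test_more_than_seven_bucket(self):
        pattern = TopologyPattern("luxR", "+", "luxI", "-", 8)
        assert pattern.render == "R> X(>7) <I"
        assert TopologyPattern("luxR", "+", "luxI", "-", 7).render == "R> X(7) <I"

    def test_classify_recomputes_from_replicon(self):
        feats = [
            gene("r", "R", 100, 699, "+", "luxR"),
            gene("r", "x", 800, 899, "+", "other"),
            gene("r", "I", 1000, 1599, "-", "luxI"),
        ]
        (pair,) = pair_cassettes(feats).pairs
        assert classify_topology(pair, feats).render == "R> X(1) <I"

    def test_mirror_invariance(self):
        """Mirroring a replicon flips the render left-right and keeps counts."""
        feats = [
            gene("r", "R", 100, 699, "+", "luxR"),
            gene("r", "x1", 800, 899, "-", "other"),
            gene("r", "x2", 950, 1049, "+", "other"),
            gene("r", "I", 1200, 1799, "-", "luxI"),
        ]
        (fwd,) = pair_cassettes(feats).pairs
        total = 2000
        flip = {"+": "-", "-": "+"}
        mirrored = [
            gene("r", f.locus_tag, total - f.end + 1, total - f.start + 1,
                 flip[f.strand], f.gene_class)
            for f in feats
        ]
        (rev,) = pair_cassettes(mirrored).pairs
        assert rev.gap_bp == fwd.gap_bp
        assert rev.n_intervening == fwd.n_intervening
        # R> X(2) <I mirrors to I> X(2) <R
        assert fwd.pattern.render == "R> X(2) <I"
        assert rev.pattern.render == "I> X(2) <R"


class TestPublishedTable:
    def test_six_pairs_row_for_row(self):
        feats, _cmap, expected = published_cassette_features()
        result = pair_cassettes(feats, DEFAULT_MAX_GAP_BP)
        assert len(result.pairs) == 6
        assert not result.solo_luxi and not result.solo_luxr
        got = {p.luxI.locus_tag: p for p in result.pairs}
        for row in expected:
            pair = got[row["luxI_locus"]]
            assert pair.luxR.locus_tag == row["luxR_locus"]
            assert pair.gap_bp == row["gap_bp"]
            assert pair.pattern.render == row["pattern"]

    def test_tighter_threshold_drops_widest_pair(self):
        feats, _cmap, _expected = published_cassette_features()
        result = pair_cassettes(feats, 3000)
        assert len(result.pairs) == 5
        assert [f.locus_tag for f in result.solo_luxi] == ["ADL14_12710"]
        assert [f.locus_tag for f in result.solo_luxr] == ["ADL14_22475"]
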