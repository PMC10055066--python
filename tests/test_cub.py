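"""Codon usage bias scoring: geometric-mean oracle, extraction, filtering."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord
from hypothesis import given, settings, strategies as st

from gcicub.cub import (
    CODON_FAMILIES,
    SENSE_CODONS,
    CodingSequence,
    CodonWeightTable,
    CubError,
    cai,
    extract_cds,
    filter_cds,
    geometric_mean_score,
    tai,
)

from conftest import make_toy_table


def brute_force_score(seq, weights, excluded):
    """Independent oracle: product of weights, then the n-th root."""
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    scored = [weights[c] for c in codons if c not in excluded]
    prod = 1.0
    for w in scored:
        prod *= w
    return prod ** (1.0 / len(scored)), len(scored)


class TestGeometricMean:
    def test_toy_hand_value(self, toy_aaa_table):
        # (1 * 0.25 * 1)^(1/3)
        s = geometric_mean_score("AAAAAGAAA", toy_aaa_table)
        assert s.score == pytest.approx(0.25 ** (1 / 3), abs=1e-12)
        assert round(s.score, 4) == 0.6300
        assert s.n_codons_scored == 3

    def test_weight_one_codons_score_one(self, toy_aaa_table):
        assert geometric_mean_score("AAAAAAAAA", toy_aaa_table).score == pytest.approx(1.0)

    def test_all_excluded_is_error(self, toy_aaa_table):
        with pytest.raises(CubError, match="no scorable codons"):
            geometric_mean_score("TTTTTT", toy_aaa_table)

    def test_unknown_codon_named_in_error(self):
        table = make_toy_table({"AAA": 1.0, "TTT": 0.5})
        del table.weights["TTT"]  # simulate a corrupted table
        with pytest.raises(CubError, match="TTT"):
            geometric_mean_score("AAATTT", table)

    def test_ambiguous_codon_skipped(self, toy_aaa_table):
        s = geometric_mean_score("AAANNNAAG", toy_aaa_table)
        assert s.n_codons_scored == 2
        assert s.score == pytest.approx(math.sqrt(0.25))

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.sampled_from(["AAA", "AAG", "GGT", "GGC"]),
                    min_size=1, max_size=10),
           st.randoms(use_true_random=False))
    def test_brute_force_oracle_and_order_invariance(self, codons, rnd):
        """Score equals product-then-root to 1e-12 and is invariant under
        codon order permutation of the same multiset."""
        table = make_toy_table({"AAA": 1.0, "AAG": 0.25, "GGT": 0.8, "GGC": 0.3})
        seq = "".join(codons)
        expected, n = brute_force_score(seq, table.weights, table.excluded_codons)
        got = geometric_mean_score(seq, table)
        assert got.score == pytest.approx(expected, abs=1e-12)
        assert got.n_codons_scored == n
        shuffled = codons[:]
        rnd.shuffle(shuffled)
        assert geometric_mean_score("".join(shuffled), table).score == pytest.approx(
            got.score, abs=1e-12
        )

    def test_monotone_in_codon_weight(self):
        """Replacing a scored codon by a higher-weight synonym never
        decreases the score."""
        table = make_toy_table({"AAA": 1.0, "AAG": 0.25, "GGT": 0.8, "GGC": 0.3})
        low = geometric_mean_score("AAGGGCAAG", table).score
        for upgraded in ("AAAGGCAAG", "AAGGGTAAG", "AAAGGTAAA"):
            assert geometric_mean_score(upgraded, table).score >= low


class TestWrappers:
    def test_cai_equals_geometric_mean(self, toy_aaa_table):
        s1 = cai("AAAAAGAAA", toy_aaa_table)
        s2 = geometric_mean_score("AAAAAGAAA", toy_aaa_table)
        assert s1.score == pytest.approx(s2.score)
        assert s1.metric == "CAI"

    def test_stop_codon_never_scored(self, toy_aaa_table):
        s = cai("AAAAAGTAA", toy_aaa_table)
        assert s.n_codons_scored == 2

    def test_single_codon_families_excluded_by_default(self):
        table = make_toy_table({"AAA": 1.0, "ATG": 0.5, "TGG": 0.5})
        assert cai("ATGAAATGG", table).n_codons_scored == 1
        assert cai("ATGAAATGG", table,
                   exclude_single_codon_families=False).n_codons_scored == 3

    def test_tai_zero_weight_policy(self):
        """A zero-weight codon receives the geometric mean of the non-zero
        weights, so the score stays finite and matches a substituted-weight
        hand computation."""
        table = make_toy_table({"AAA": 1.0, "AAG": 0.25, "GGT": 0.0})
        gm_nonzero = math.sqrt(1.0 * 0.25)
        s = tai("AAAAAGGGT", table)
        expected = (1.0 * 0.25 * gm_nonzero) ** (1 / 3)
        assert s.score == pytest.approx(expected, abs=1e-12)
        with pytest.raises(CubError):
            tai("AAAAAGGGT", table, zero_policy=False)

    def test_normalization_to_max_one(self):
        t = make_toy_table({"AAA": 4.0, "AAG": 1.0}).normalized()
        assert max(t.weights.values()) == 1.0
        assert t.weights["AAG"] == pytest.approx(0.25)


class TestWeightTableValidation:
    def test_empty_table_rejected(self):
        with pytest.raises(CubError, match="empty"):
            CodonWeightTable(metric="x", weights={})

    def test_missing_sense_codon_rejected(self):
        with pytest.raises(CubError, match="missing"):
            CodonWeightTable(metric="x", weights={"AAA": 1.0})

    def test_tsv_round_trip(self, tmp_path, toy_aaa_table):
        path = tmp_path / "weights.tsv"
        toy_aaa_table.to_tsv(path)
        loaded = CodonWeightTable.from_tsv(
            path, excluded_codons=toy_aaa_table.excluded_codons
        )
        assert loaded.weights == pytest.approx(toy_aaa_table.weights)
        assert loaded.metric == "toy"


def _record(seq: str, features) -> SeqRecord:
    rec = SeqRecord(Seq(seq), id="toy", annotations={"molecule_type": "DNA"})
    rec.features = features
    return rec


class TestExtraction:
    def test_forward_single_interval(self):
        rec = _record(
            "GGATGAAATAGGG",
            [SeqFeature(SimpleLocation(2, 11, strand=1), type="CDS",
                        qualifiers={"locus_tag": ["b0001"], "gene": ["toyA"]})],
        )
        (c,) = extract_cds(rec)
        assert c.seq == "ATGAAATAG"
        assert c.id == "b0001" and c.gene_name == "toyA"
        assert c.intervals == ((3, 11),)

    def test_minus_strand_reverse_complement(self):
        # genomic slice CTATTTCAT reverse-complements to ATGAAATAG
        rec = _record(
            "GGCTATTTCATGG",
            [SeqFeature(SimpleLocation(2, 11, strand=-1), type="CDS")],
        )
        (c,) = extract_cds(rec)
        assert c.seq == "ATGAAATAG"
        assert c.strand == -1

    def test_two_exon_join_spliced_in_order(self):
        # exon1 = ATGAAA at [2,8), exon2 = GGGTAG at [10,16)
        genome = "GG" + "ATGAAA" + "CC" + "GGGTAG" + "AA"
        loc = CompoundLocation([SimpleLocation(2, 8, strand=1),
                                SimpleLocation(10, 16, strand=1)])
        rec = _record(genome, [SeqFeature(loc, type="CDS")])
        (c,) = extract_cds(rec)
        assert c.seq == "ATGAAAGGGTAG"
        assert c.intervals == ((3, 8), (11, 16))
        assert c.interval_length == 12

    def test_out_of_range_feature_skipped(self):
        rec = _record(
            "ATGAAATAG",
            [SeqFeature(SimpleLocation(0, 50, strand=1), type="CDS"),
             SeqFeature(SimpleLocation(0, 9, strand=1), type="CDS")],
        )
        assert len(extract_cds(rec)) == 1

    def test_genbank_text_round_trip(self, tmp_path):
        """Extraction agrees after writing/reading the record as a GenBank
        flat file (1-based inclusive coordinates preserved)."""
        from Bio import SeqIO

        rec = _record(
            "GGATGAAATAGGG",
            [SeqFeature(SimpleLocation(2, 11, strand=1), type="CDS",
                        qualifiers={"locus_tag": ["b0001"]})],
        )
        path = tmp_path / "toy.gb"
        SeqIO.write([rec], path, "genbank")
        (c,) = extract_cds(SeqIO.read(path, "genbank"))
        assert c.seq == "ATGAAATAG"
        assert c.intervals == ((3, 11),)


class TestFilterCds:
    def make(self, ident, n, intervals=None):
        seq = "A" * n
        return CodingSequence(id=ident, seq=seq,
                              intervals=intervals or ((1, n),))

    def test_not_divisible_by_three_removed(self):
        kept, removed = filter_cds([self.make("a", 100), self.make("b", 99)])
        assert [c.id for c in removed] == ["a"]
        assert [c.id for c in kept] == ["b"]

    def test_five_times_median_threshold(self):
        lengths = [30, 30, 30, 30, 201]
        cds = [self.make(f"g{i}", n) for i, n in enumerate(lengths)]
        kept, removed = filter_cds(cds)
        assert [c.id for c in removed] == ["g4"]  # 201 > 5*30
        assert len(kept) == 4

    def test_all_equal_lengths_kept(self):
        kept, removed = filter_cds([self.make(f"g{i}", 30) for i in range(5)])
        assert len(kept) == 5 and not removed

    def test_interval_length_mismatch_removed(self):
        bad = self.make("bad", 30, intervals=((1, 33),))
        kept, removed = filter_cds([bad, self.make("ok", 30)])
        assert [c.id for c in removed] == ["bad"]

    def test_empty_input_error(self):
        with pytest.raises(CubError):
            filter_cds([])
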