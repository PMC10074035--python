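"""PWM model, MEME/FASTA I/O and best-site scanning."""

import numpy as np
import pytest

from peako.intervals import GenomicInterval, ParseError, PeakSet
from peako.motifs import (
    Background,
    Pwm,
    SequenceRecord,
    best_match,
    log_odds,
    read_fasta,
    read_meme,
    read_meme_motifs,
    reverse_complement,
    scan_best_matches,
    write_meme_motifs,
)
from oracles import brute_best_match

MEME_SINGLE = """\
MEME version 4

ALPHABET= ACGT

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF AC_motif ac
letter-probability matrix: alength= 4 w= 2
 1 0 0 0
 0 1 0 0
"""


def make_pwm(consensus, strength=1.0, motif_id="m"):
    probs = np.full((len(consensus), 4), (1 - strength) / 3 if strength < 1 else 0.0)
    for j, b in enumerate(consensus):
        probs[j, "ACGT".index(b)] = strength
    return Pwm(motif_id, "", probs)


class TestMemeFormat:
    def test_single_motif(self, tmp_path):
        path = tmp_path / "m.meme"
        path.write_text(MEME_SINGLE)
        (pwm,) = read_meme_motifs(path)
        assert pwm.motif_id == "AC_motif"
        assert pwm.length == 2
        assert pwm.consensus() == "AC"

    def test_file_background_captured(self, tmp_path):
        path = tmp_path / "m.meme"
        path.write_text(MEME_SINGLE.replace("A 0.25 C 0.25 G 0.25 T 0.25",
                                            "A 0.3 C 0.2 G 0.2 T 0.3"))
        _, bg = read_meme(path)
        assert bg is not None
        np.testing.assert_allclose(bg.freqs, [0.3, 0.2, 0.2, 0.3])

    def test_no_motif_blocks(self, tmp_path):
        path = tmp_path / "m.meme"
        path.write_text("MEME version 4\n\nALPHABET= ACGT\n")
        assert read_meme_motifs(path) == []

    def test_missing_version_line_rejected(self, tmp_path):
        path = tmp_path / "m.meme"
        path.write_text("MOTIF x\nletter-probability matrix: w= 1\n1 0 0 0\n")
        with pytest.raises(ParseError, match="MEME version"):
            read_meme_motifs(path)

    def test_w_mismatch_rejected_naming_motif(self, tmp_path):
        path = tmp_path / "m.meme"
        path.write_text(MEME_SINGLE.replace("w= 2", "w= 3"))
        with pytest.raises(ParseError, match="AC_motif"):
            read_meme_motifs(path)

    def test_non_stochastic_row_rejected(self, tmp_path):
        path = tmp_path / "m.meme"
        path.write_text(MEME_SINGLE.replace(" 0 1 0 0", " 0 0.6 0.1 0"))
        with pytest.raises(ParseError, match="AC_motif"):
            read_meme_motifs(path)

    def test_multi_motif_roundtrip(self, tmp_path, rng):
        motifs = []
        for i in range(10):
            m = int(rng.integers(4, 15))
            probs = rng.dirichlet(np.ones(4), size=m)
            motifs.append(Pwm(f"M{i:03d}", f"name{i}", probs, nsites=20))
        path = tmp_path / "db.meme"
        write_meme_motifs(motifs, path)
        back = read_meme_motifs(path)
        assert [p.motif_id for p in back] == [p.motif_id for p in motifs]
        for orig, rt in zip(motifs, back):
            np.testing.assert_allclose(rt.probs, orig.probs, atol=1e-6)

    def test_written_file_parses_with_biopython(self, tmp_path):
        """Cross-check our writer/parser pair against Bio.motifs' independent
        minimal-format reader."""
        Bio_motifs = pytest.importorskip("Bio.motifs")
        target = make_pwm("ACGTAC", strength=0.85, motif_id="XC1")
        path = tmp_path / "db.meme"
        write_meme_motifs([target], path)
        with open(path) as fh:
            record = Bio_motifs.parse(fh, "minimal")
        (bio_motif,) = list(record)
        bio_probs = np.array(
            [[bio_motif.pwm[b][j] for b in "ACGT"] for j in range(target.length)]
        )
        np.testing.assert_allclose(bio_probs, target.probs, atol=1e-5)


class TestFasta:
    def test_plain_read(self, tmp_path):
        path = tmp_path / "s.fa"
        path.write_text(">s1\nACGT\n")
        (rec,) = read_fasta(path)
        assert (rec.seq_id, rec.bases) == ("s1", "ACGT")

    def test_region_extraction(self, tmp_path):
        path = tmp_path / "g.fa"
        path.write_text(">chr1\nAACGTTAA\n")
        regions = PeakSet([GenomicInterval("chr1", 2, 6)])
        (rec,) = read_fasta(path, regions=regions)
        assert rec.bases == "CGTT"
        assert rec.origin.key == ("chr1", 2, 6)

    def test_region_past_chromosome_end_rejected(self, tmp_path):
        path = tmp_path / "g.fa"
        path.write_text(">chr1\nAACGTTAA\n")
        with pytest.raises(ValueError, match="chr1:4-20"):
            read_fasta(path, regions=PeakSet([GenomicInterval("chr1", 4, 20)]))

    def test_random_regions_roundtrip_to_genome_substrings(self, tmp_path, rng):
        genome = "".join(rng.choice(list("ACGT"), size=5000))
        path = tmp_path / "g.fa"
        path.write_text(">chr1\n" + "\n".join(
            genome[i : i + 70] for i in range(0, 5000, 70)) + "\n")
        ivs = []
        for _ in range(50):
            start = int(rng.integers(0, 4900))
            ivs.append(GenomicInterval("chr1", start, start + int(rng.integers(1, 100))))
        for rec in read_fasta(path, regions=PeakSet(ivs)):
            assert rec.bases == genome[rec.origin.start : rec.origin.end]


class TestLogOdds:
    def test_uniform_pwm_uniform_bg_scores_zero(self):
        pwm = Pwm("u", "", np.full((3, 4), 0.25))
        np.testing.assert_allclose(
            log_odds(pwm, Background.uniform(), 0.0), np.zeros((3, 4))
        )

    def test_certain_base_scores_two_bits(self):
        pwm = make_pwm("A", strength=1.0)
        lo = log_odds(pwm, Background.uniform(), 0.0)
        assert lo[0, 0] == pytest.approx(2.0)

    def test_matches_direct_formula(self, rng):
        for _ in range(20):
            m = int(rng.integers(1, 10))
            pwm = Pwm("r", "", rng.dirichlet(np.ones(4), size=m))
            bg = Background(rng.dirichlet(np.ones(4)) + 0.01)
            c = float(rng.uniform(0, 0.5))
            lo = log_odds(pwm, bg, c)
            expected = np.log2(((1 - c) * pwm.probs + c * bg.freqs) / bg.freqs)
            np.testing.assert_allclose(lo, expected)
        assert np.all(np.isfinite(lo))

    def test_invalid_pseudocount_rejected(self):
        pwm = make_pwm("A")
        with pytest.raises(ValueError):
            log_odds(pwm, Background.uniform(), 1.0)


class TestBestMatch:
    BG = Background.uniform()

    def test_unique_exact_site(self):
        seq = SequenceRecord("s", "AAAAACAAAA")
        pwm = make_pwm("AC", strength=1.0)
        m = best_match(seq, pwm, self.BG, pseudocount=0.0)
        assert (m.offset, m.strand) == (4, "+")
        assert m.log_odds == pytest.approx(4.0)

    def test_all_n_sequence_has_no_match(self):
        m = best_match(SequenceRecord("s", "NNNNNNNN"), make_pwm("AC"), self.BG)
        assert m is None

    def test_sequence_shorter_than_motif_skipped(self):
        m = best_match(SequenceRecord("s", "AC"), make_pwm("ACGT"), self.BG)
        assert m is None

    def test_center_displacement_definition(self):
        seq = SequenceRecord("s", "AAAAACAAAA")  # L=10, m=2 -> P=9, center idx 4
        pwm = make_pwm("AC", strength=1.0)
        m = best_match(seq, pwm, self.BG, pseudocount=0.0)
        assert m.center_displacement == m.offset - (10 - 2) / 2

    def test_agrees_with_exhaustive_scan_oracle(self, rng):
        for _ in range(100):
            L = int(rng.integers(6, 40))
            m_len = int(rng.integers(2, 6))
            if L < m_len:
                continue
            bases = "".join(rng.choice(list("ACGTN"), size=L, p=[0.24] * 4 + [0.04]))
            pwm = Pwm("r", "", rng.dirichlet(np.ones(4) * 0.5, size=m_len))
            bg = Background(rng.dirichlet(np.ones(4)) + 0.05)
            lo = log_odds(pwm, bg, 0.01)
            got = best_match(SequenceRecord("s", bases), pwm, bg)
            want = brute_best_match(bases, lo.tolist())
            if want is None:
                assert got is None
            else:
                assert (got.offset, got.strand) == want[:2]
                assert got.log_odds == pytest.approx(want[2], abs=1e-9)

    def test_strand_symmetry(self, rng):
        """Scanning the reverse complement mirrors the offset and flips the
        strand, with identical score."""
        bg = Background.uniform()
        checked = 0
        while checked < 20:
            L, m_len = 30, 6
            bases = "".join(rng.choice(list("ACGT"), size=L))
            pwm = Pwm("r", "", rng.dirichlet(np.ones(4) * 0.4, size=m_len))
            lo = log_odds(pwm, bg, 0.01)
            # skip draws where the maximum is not unique across both strands
            scores = sorted(
                (
                    sum(lo[j, "ACGT".index(w[j])] for j in range(m_len))
                    for off in range(L - m_len + 1)
                    for w in (
                        bases[off : off + m_len],
                        reverse_complement(bases[off : off + m_len]),
                    )
                ),
                reverse=True,
            )
            if scores[0] - scores[1] < 1e-6:
                continue
            checked += 1
            fwd = best_match(SequenceRecord("f", bases), pwm, bg, min_score=-1e9)
            rev = best_match(
                SequenceRecord("r", reverse_complement(bases)), pwm, bg, min_score=-1e9
            )
            assert fwd is not None and rev is not None
            assert rev.log_odds == pytest.approx(fwd.log_odds, abs=1e-9)
            assert rev.offset == L - m_len - fwd.offset
            assert {fwd.strand, rev.strand} == {"+", "-"}

    def test_constant_score_shift_never_moves_argmax(self, rng):
        for _ in range(20):
            bases = "".join(rng.choice(list("ACGT"), size=25))
            probs = rng.dirichlet(np.ones(4) * 0.4, size=5)
            pwm = Pwm("r", "", probs)
            bg = Background.uniform()
            lo = log_odds(pwm, bg, 0.01)
            got = best_match(SequenceRecord("s", bases), pwm, bg, min_score=-1e9)
            shifted = brute_best_match((bases), (lo + 3.7).tolist(), min_score=-1e9)
            assert (got.offset, got.strand) == shifted[:2]

    def test_batch_scan_matches_single(self, rng):
        seqs = [
            SequenceRecord(f"s{i}", "".join(rng.choice(list("ACGT"), size=20)))
            for i in range(10)
        ]
        pwm = Pwm("r", "", rng.dirichlet(np.ones(4), size=4))
        bg = Background.uniform()
        batch = scan_best_matches(seqs, pwm, bg)
        singles = [best_match(s, pwm, bg) for s in seqs]
        assert batch == singles
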