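"""Hallmark recovery: TSD, EN site, poly(A), transductions, splicing."""

import re

import numpy as np
import pytest

from l1trace import sim, tprt
from l1trace._seq import hamming, revcomp
from l1trace.pwm import SPLICE_ACCEPTOR, SPLICE_DONOR


def brute_force_tsd(empty: str, filled: str) -> str:
    """Exhaustive factorization oracle: maximal s with
    filled = A·s·I·s·B and empty = A·s·B (leftmost on ties)."""
    d = len(filled) - len(empty)
    best = ""
    for b in range(len(empty) + 1):
        if empty[:b] != filled[:b] or empty[b:] != filled[b + d :]:
            continue
        for t in range(min(b, d), -1, -1):
            if filled[b + d - t : b + d] == empty[b - t : b]:
                if t > len(best):
                    best = empty[b - t : b]
                break
    return best


class TestFindTSD:
    def test_de_novo_fixture_recovers_printed_tsd(self, de_novo):
        _, truth, _ = de_novo
        res = tprt.find_tsd(truth.empty_allele, truth.filled_allele)
        assert res.tsd == "AAAGAAATGACATCTG"
        assert res.length == 16

    def test_blunt_insertion_has_empty_tsd(self, genome, mini_l1):
        spec = sim.InsertionSpec(contig="chr1", position=2000, terminal_polyA_length=8)
        truth = sim.plant_insertion(genome, mini_l1, spec, seed=2)
        assert tprt.find_tsd(truth.empty_allele, truth.filled_allele).tsd == ""

    def test_zero_length_insert_gives_empty_tsd(self):
        empty = "ACGTACGTACGTGGCCTTAA"
        assert tprt.find_tsd(empty, empty).tsd == ""

    @pytest.mark.parametrize("case", range(200))
    def test_matches_exhaustive_factorization_oracle(self, case):
        rng = np.random.default_rng(7000 + case)
        flank_a = sim.random_dna(rng, int(rng.integers(10, 30)))
        flank_b = sim.random_dna(rng, int(rng.integers(10, 30)))
        s = sim.random_dna(rng, int(rng.integers(0, 8)))
        core = sim.random_dna(rng, int(rng.integers(1, 20)))
        empty = flank_a + s + flank_b
        filled = flank_a + s + core + s + flank_b
        res = tprt.find_tsd(empty, filled)
        oracle = brute_force_tsd(empty, filled)
        assert len(res.tsd) == len(oracle)
        assert res.tsd == oracle

    def test_unrelated_alleles_raise(self):
        with pytest.raises(tprt.NoSharedFlankError):
            tprt.find_tsd("AAAACCCC", "GGGGTTTTTTGG")

    def test_mismatch_tolerance_recovers_degenerate_copy(self):
        empty = "GGCCTTAGCATCGA" + "TACGTAGC" + "CCGGAATTGGCA"
        degenerate = "TACGAAGC"  # one mismatch vs the empty-site copy
        filled = "GGCCTTAGCATCGA" + "TACGTAGC" + "GGTTCCGGTT" + degenerate + "CCGGAATTGGCA"
        assert tprt.find_tsd(empty, filled, max_mismatches=0).length < 8
        res = tprt.find_tsd(empty, filled, max_mismatches=1)
        assert res.length == 8


class TestEnMotif:
    def test_de_novo_site_is_degenerate_by_one(self, de_novo):
        _, truth, _ = de_novo
        res = tprt.find_tsd(truth.empty_allele, truth.filled_allele)
        site, mism = tprt.en_motif(truth.empty_allele, res.empty_start)
        assert site == "TT/AAAG"
        assert mism == 1

    def test_consensus_site_has_zero_mismatches(self):
        empty = "GGCCGGCCGG" + "TT" + "AAAA" + "CCGGCCGGCC"
        site, mism = tprt.en_motif(empty, 12)
        assert site == "TT/AAAA"
        assert mism == 0

    @pytest.mark.parametrize("case", range(50))
    def test_mismatch_count_equals_positional_oracle(self, case):
        rng = np.random.default_rng(300 + case)
        empty = sim.random_dna(rng, 40)
        site, mism = tprt.en_motif(empty, 20)
        hexamer = site.replace("/", "")
        assert hexamer == empty[18:20] + empty[20:24]
        assert mism == sum(a != b for a, b in zip(hexamer, "TTAAAA"))


class TestFindPolyA:
    def test_de_novo_tract_lengths(self, de_novo, full_l1):
        _, truth, donor_flank = de_novo
        s = tprt.characterize_insertion(
            truth.empty_allele, truth.filled_allele, full_l1, donor_flank=donor_flank
        )
        assert s.terminal_polyA_length == 33
        assert s.internal_polyA_length == 17

    def test_no_terminal_a_gives_zero(self):
        assert tprt.find_polyA("GGTTCCGGT", side="3prime")[2] == 0
        assert tprt.find_polyA("GGTTAAA", side="3prime")[2] == 0  # below min_run

    @pytest.mark.parametrize("case", range(50))
    def test_matches_run_length_oracle(self, case):
        rng = np.random.default_rng(900 + case)
        seq = "".join(rng.choice(list("AACGT"), size=60))
        start, end, length = tprt.find_polyA(seq, side="3prime")
        m = re.search(r"A+$", seq)
        expected = len(m.group()) if m and len(m.group()) >= 4 else 0
        assert length == expected
        start, end, length = tprt.find_polyA(seq, side="internal")
        m = re.match(r"A+", seq)
        expected = len(m.group()) if m and len(m.group()) >= 4 else 0
        assert length == expected


class TestCharacterize:
    def test_de_novo_full_report(self, de_novo, full_l1):
        _, truth, donor_flank = de_novo
        s = tprt.characterize_insertion(
            truth.empty_allele, truth.filled_allele, full_l1, donor_flank=donor_flank
        )
        assert s.tsd_length == 16
        assert s.en_site == "TT/AAAG"
        assert s.td5_length == 10
        assert s.td3_length == 44
        assert s.internal_polyA_length == 17
        assert s.terminal_polyA_length == 33
        assert s.full_length
        assert s.subfamily == "L1-Ta"
        assert s.l1_start == 0 and s.l1_end == len(full_l1)

    def test_truncated_element_not_full_length(self, genome, full_l1):
        trunc = 3500  # mid-ORF2
        spec = sim.InsertionSpec(
            contig="chr1", position=2500, tsd_length=12,
            terminal_polyA_length=20, truncation_point=trunc,
        )
        truth = sim.plant_insertion(genome, full_l1, spec, seed=13)
        s = tprt.characterize_insertion(truth.empty_allele, truth.filled_allele, full_l1)
        assert not s.full_length
        assert s.l1_start == trunc

    def test_pure_l1_insert_has_empty_transductions(self, genome, mini_l1):
        spec = sim.InsertionSpec(
            contig="chr1", position=2000, tsd_length=10, terminal_polyA_length=15
        )
        truth = sim.plant_insertion(genome, mini_l1, spec, seed=4)
        s = tprt.characterize_insertion(truth.empty_allele, truth.filled_allele, mini_l1)
        assert s.td5 == "" and s.td3 == ""
        assert s.terminal_polyA_length == 15

    @pytest.mark.parametrize("case", range(60))
    def test_round_trip_recovers_planted_structure(self, genome, mini_l1, case):
        rng = np.random.default_rng(5000 + case)
        spec = sim.random_insertion_spec(rng, "chr1", 2000, mini_l1)
        truth = sim.plant_insertion(genome, mini_l1, spec, seed=case)
        s = tprt.characterize_insertion(truth.empty_allele, truth.filled_allele, mini_l1)
        assert s.tsd == truth.tsd
        assert s.strand == spec.strand
        assert s.untemplated_5prime + s.td5 == spec.untemplated_5prime + spec.td5
        assert s.td3 == spec.td3
        assert s.internal_polyA_length == spec.internal_polyA_length
        assert s.terminal_polyA_length == spec.terminal_polyA_length
        assert s.l1_start == (spec.truncation_point or 0)
        assert s.l1_end == len(mini_l1)
        observed, reconstructed = s.length_audit(truth.empty_allele, truth.filled_allele)
        assert observed == reconstructed

    def test_strand_covariance(self, de_novo, full_l1):
        _, truth, _ = de_novo
        fwd = tprt.characterize_insertion(truth.empty_allele, truth.filled_allele, full_l1)
        rev = tprt.characterize_insertion(
            revcomp(truth.empty_allele), revcomp(truth.filled_allele), full_l1
        )
        assert rev.tsd == revcomp(fwd.tsd)
        assert rev.strand == "-"
        assert rev.en_site == fwd.en_site
        assert rev.en_mismatches == fwd.en_mismatches
        for attr in (
            "tsd_length", "td5_length", "td3_length", "internal_polyA_length",
            "terminal_polyA_length", "l1_start", "l1_end", "full_length", "subfamily",
        ):
            assert getattr(rev, attr) == getattr(fwd, attr), attr

    def test_ambiguous_orientation_raises(self, mini_l1):
        palindromic = mini_l1.sequence[:200] + revcomp(mini_l1.sequence[:200])
        with pytest.raises(tprt.AmbiguousOrientationError):
            tprt.extract_transductions(palindromic, mini_l1)


def _make_spliced_source(rng):
    # exon termini are pinned so no matching block can slip into the intron:
    # exon2 starts with A (intron starts GT) and exon1 ends with C (intron
    # ends ...AG)
    exon1 = sim.random_dna(rng, 79).replace("A", "G") + "C"
    exon2 = "A" + sim.random_dna(rng, 77).replace("A", "C") + "T"
    intron = (
        "GTAAGT" + sim.random_dna(rng, 40)
        + "TCTTTCTTTTC" + "CAG"  # pyrimidine tract + acceptor AG
    )
    source = exon1 + intron + exon2 + sim.random_dna(rng, 60)
    return source, exon1, intron, exon2


class TestSplicedTransduction:
    def test_two_exon_fixture(self, rng):
        source, exon1, intron, exon2 = _make_spliced_source(rng)
        td5 = "G" + exon1 + exon2
        report = tprt.analyze_spliced_transduction(td5, source)
        assert report.untemplated_5prime == "G"
        assert len(report.exons) == 2
        assert report.exons[0] == (0, len(exon1))
        assert report.exons[1] == (len(exon1) + len(intron), len(exon1) + len(intron) + len(exon2))
        j = report.junctions[0]
        # junction scores beat an unspliced control site inside exon 1
        control_d = SPLICE_DONOR.score_normalized(source[37:46])
        control_a = SPLICE_ACCEPTOR.score_normalized(source[30:45])
        assert j.donor_score > control_d
        assert j.acceptor_score > control_a

    def test_contiguous_transduction_single_exon(self, rng):
        source = sim.random_dna(rng, 400)
        td5 = source[50:250]
        report = tprt.analyze_spliced_transduction(td5, source)
        assert report.exons == ((50, 250),)
        assert report.junctions == ()
        assert report.untemplated_5prime == ""

    def test_below_length_threshold_raises(self):
        with pytest.raises(ValueError, match="threshold"):
            tprt.analyze_spliced_transduction("ACGT" * 10, "ACGT" * 100)

    def test_junction_scores_equal_direct_pwm_arithmetic(self, rng):
        source, exon1, intron, exon2 = _make_spliced_source(rng)
        td5 = exon1 + exon2
        report = tprt.analyze_spliced_transduction(td5, source)
        e0_end = report.exons[0][1]
        e1_start = report.exons[1][0]
        donor_win = source[e0_end - 3 : e0_end + 6]
        acceptor_win = source[e1_start - 14 : e1_start + 1]
        # independent arithmetic on the 9-mer / 15-mer windows
        lo = SPLICE_DONOR.log_odds
        idx = {b: i for i, b in enumerate("ACGT")}
        raw = sum(lo[i, idx[b]] for i, b in enumerate(donor_win))
        norm = (raw - lo.min(axis=1).sum()) / (lo.max(axis=1).sum() - lo.min(axis=1).sum())
        assert report.junctions[0].donor_score == pytest.approx(norm)
        assert report.junctions[0].acceptor_score == pytest.approx(
            SPLICE_ACCEPTOR.score_normalized(acceptor_win)
        )
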