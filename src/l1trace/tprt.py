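"""TPRT hallmark characterization of assembled insertion alleles.

Given an empty-site allele, a filled-site allele and an L1 body, this module
recovers the structural hallmarks that target-primed reverse transcription
leaves at an integration site: the target-site duplication (TSD), the
endonuclease nick hexamer and its divergence from the TT/AAAA consensus,
internal and terminal poly(A) tracts, 5' and 3' transductions, untemplated
5' nucleotides, the spanned L1-body interval (hence 5'-truncation vs
full-length status) and the subfamily diagnostic state.  A separate routine
dissects long 5' transductions into spliced exons and scores the inferred
junctions against splice-site weight matrices.

Conventions: all coordinates 0-based half-open; the endonuclease hexamer is
written in the 5'-NN/NNNN bottom-strand style with the slash at the nick,
regardless of the insertion's strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from difflib import SequenceMatcher

from Bio import Align

from ._seq import (
    common_prefix_len,
    common_suffix_len,
    hamming,
    leading_run,
    revcomp,
    shared_kmer_count,
    trailing_run,
)
from .pwm import SPLICE_ACCEPTOR, SPLICE_DONOR
from .sim import L1Body

__all__ = [
    "TSDResult",
    "TransductionReport",
    "InsertionStructure",
    "SpliceReport",
    "find_tsd",
    "en_motif",
    "find_polyA",
    "extract_transductions",
    "characterize_insertion",
    "analyze_spliced_transduction",
    "NoSharedFlankError",
    "AmbiguousOrientationError",
]

EN_CONSENSUS = "TTAAAA"


class NoSharedFlankError(ValueError):
    """The two alleles cannot be factored around a single insertion."""


class AmbiguousOrientationError(ValueError):
    """The insert aligns to the L1 body on both strands."""


# ---------------------------------------------------------------------------
# TSD detection


@dataclass(frozen=True)
class TSDResult:
    """A detected target-site duplication.

    ``empty_start``/``empty_end`` delimit the single target-site copy in the
    empty allele; ``insert_start``/``insert_end`` delimit the inserted
    material (between the two TSD copies) in the filled allele.
    """

    tsd: str
    empty_start: int
    empty_end: int
    insert_start: int
    insert_end: int

    @property
    def length(self) -> int:
        return len(self.tsd)


def find_tsd(empty: str, filled: str, max_mismatches: int = 0) -> TSDResult:
    """Find the longest duplicated target-site segment.

    Searches for the factorization ``filled = prefix·s·insert·s·suffix`` with
    ``empty = prefix·s·suffix``, maximizing ``|s|``; on ties the leftmost
    placement wins.  The flank matches are exact; up to ``max_mismatches``
    mismatches are tolerated between the two copies of ``s`` (counted within
    one copy).  Returns an empty TSD for a blunt insertion.
    """
    d = len(filled) - len(empty)
    if d < 0:
        raise NoSharedFlankError("filled allele is shorter than empty allele")
    lcp = common_prefix_len(empty, filled)
    lcs = common_suffix_len(empty, filled)
    lo = max(0, len(empty) - lcs)
    hi = min(lcp, len(empty))
    if lo > hi:
        raise NoSharedFlankError("alleles share no alignable flank around one insertion")
    if d == 0:
        return TSDResult("", lo, lo, lo, lo)

    best_t, best_b = -1, lo
    for b in range(lo, hi + 1):
        # longest suffix of empty[:b] matching filled[:b+d] with <= mm mismatches
        t, mm = 0, 0
        while t < min(b, d):
            if empty[b - 1 - t] != filled[b + d - 1 - t]:
                mm += 1
                if mm > max_mismatches:
                    break
            t += 1
        if t > best_t:
            best_t, best_b = t, b
    b, t = best_b, best_t
    return TSDResult(
        tsd=empty[b - t : b],
        empty_start=b - t,
        empty_end=b,
        insert_start=b,
        insert_end=b + d - t,
    )


def en_motif(
    empty: str, breakpoint: int, strand: str = "+", consensus: str = EN_CONSENSUS
) -> tuple[str, int]:
    """Endonuclease-site hexamer at the nick, plus its consensus divergence.

    ``breakpoint`` is the TSD start in the empty allele for a '+'-strand
    insertion, or the TSD end for a '-'-strand insertion (the hexamer is
    then read from the reverse complement so that it is always written in
    the 5'-NN/NNNN convention).  The mismatch count is the Hamming distance
    to TTAAAA.
    """
    b = breakpoint
    if strand == "+":
        if b < 2 or b + 4 > len(empty):
            raise ValueError("insufficient flank context for the EN hexamer")
        hexamer = empty[b - 2 : b] + empty[b : b + 4]
    else:
        if b - 4 < 0 or b + 2 > len(empty):
            raise ValueError("insufficient flank context for the EN hexamer")
        hexamer = revcomp(empty[b : b + 2]) + revcomp(empty[b - 4 : b])
    return hexamer[:2] + "/" + hexamer[2:], hamming(hexamer, consensus)


# ---------------------------------------------------------------------------
# poly(A) tracts


def find_polyA(seq: str, min_run: int = 4, side: str = "3prime") -> tuple[int, int, int]:
    """Locate a poly(A) tract as a pure A-run; returns (start, end, length).

    ``side='3prime'``: the maximal run ending at the 3' end of ``seq`` (the
    terminal tract of an insert after TSD removal).  ``side='internal'``: the
    maximal run starting at the 5' end of ``seq`` (the tract between the L1
    3' end and the 3' transduction, for which the caller passes the segment
    downstream of the L1 alignment).  Runs shorter than ``min_run`` report
    length 0; boundary ambiguity is resolved by assigning maximal length to
    the tract.
    """
    if min_run < 4:
        raise ValueError("min_run must be >= 4")
    if side == "3prime":
        run = trailing_run(seq)
        if run < min_run:
            return len(seq), len(seq), 0
        return len(seq) - run, len(seq), run
    if side == "internal":
        run = leading_run(seq)
        if run < min_run:
            return 0, 0, 0
        return 0, run, run
    raise ValueError("side must be '3prime' or 'internal'")


# ---------------------------------------------------------------------------
# transduction extraction


def _make_aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


@dataclass(frozen=True)
class TransductionReport:
    """Decomposition of one insert into its TPRT components."""

    strand: str
    untemplated_5prime: str
    td5: str
    td3: str
    internal_polyA_length: int
    terminal_polyA_length: int
    l1_start: int  # L1-body coordinates, 0-based half-open
    l1_end: int
    insert_l1_span: int  # length of the matched region in the insert
    alignment_score: float
    l1_offset_map: tuple[tuple[int, int, int], ...]  # (l1_start, l1_end, insert_start)

    def insert_base_at_l1(self, insert: str, l1_pos: int) -> str | None:
        """Base of the (sense-oriented) insert aligned to an L1 position."""
        seq = insert if self.strand == "+" else revcomp(insert)
        for l1s, l1e, ins_s in self.l1_offset_map:
            if l1s <= l1_pos < l1e:
                return seq[ins_s + (l1_pos - l1s)]
        return None


def _orientation(insert: str, l1_seq: str, k: int = 15) -> str:
    fwd = shared_kmer_count(insert, l1_seq, k)
    rev = shared_kmer_count(revcomp(insert), l1_seq, k)
    if fwd == 0 and rev == 0:
        raise ValueError("insert shares no k-mers with the L1 body on either strand")
    if min(fwd, rev) >= 5 and min(fwd, rev) / max(fwd, rev) > 0.2:
        raise AmbiguousOrientationError(
            f"insert aligns to the L1 body on both strands ({fwd} fwd / {rev} rev k-mers)"
        )
    return "+" if fwd >= rev else "-"


def extract_transductions(
    insert: str,
    l1: L1Body,
    donor_flank: str | None = None,
    min_polyA: int = 4,
) -> TransductionReport:
    """Decompose an insert (delimited by its TSD copies) into components.

    The insert is oriented against the L1 body by a k-mer vote (ambiguity on
    both strands raises), its terminal poly(A) tract stripped, and the L1
    span located by Smith-Waterman local alignment (match +2 / mismatch -3 /
    gap open -5 / extend -2).  The sequence 3' of the L1 span splits into a
    leading internal poly(A) tract and the 3' transduction; the sequence 5'
    of it is the 5' transduction.  Untemplated 5' bases can only be
    separated from the transduction when the donor's upstream flank is
    supplied (they are the 5'-terminal bases matching neither the L1 nor
    that flank); otherwise they are reported within ``td5``.
    """
    strand = _orientation(insert, l1.sequence)
    seq = insert if strand == "+" else revcomp(insert)

    _, _, terminal = find_polyA(seq, min_run=min_polyA, side="3prime")
    rem = seq[: len(seq) - terminal] if terminal else seq

    aligner = _make_aligner("local")
    alignment = aligner.align(rem, l1.sequence)[0]
    rem_blocks, l1_blocks = alignment.aligned
    i0, i1 = int(rem_blocks[0][0]), int(rem_blocks[-1][1])
    j0, j1 = int(l1_blocks[0][0]), int(l1_blocks[-1][1])

    head, tail = rem[:i0], rem[i1:]
    _, _, internal = find_polyA(tail, min_run=min_polyA, side="internal")
    td3 = tail[internal:]
    if not td3 and internal:
        # an A-run abutting the terminal tract is part of the terminal tract
        terminal += internal
        internal = 0

    untemplated = ""
    td5 = head
    if donor_flank is not None and head:
        k = 0
        while k < min(len(head), len(donor_flank)) and head[len(head) - 1 - k] == donor_flank[len(donor_flank) - 1 - k]:
            k += 1
        untemplated, td5 = head[: len(head) - k], head[len(head) - k :]

    offset_map = tuple(
        (int(lb[0]), int(lb[1]), int(rb[0])) for rb, lb in zip(rem_blocks, l1_blocks)
    )
    return TransductionReport(
        strand=strand,
        untemplated_5prime=untemplated,
        td5=td5,
        td3=td3,
        internal_polyA_length=internal,
        terminal_polyA_length=terminal,
        l1_start=j0,
        l1_end=j1,
        insert_l1_span=i1 - i0,
        alignment_score=float(alignment.score),
        l1_offset_map=offset_map,
    )


# ---------------------------------------------------------------------------
# full characterization


@dataclass(frozen=True)
class InsertionStructure:
    """The full TPRT hallmark report for one insertion."""

    tsd: str
    tsd_length: int
    en_site: str | None
    en_mismatches: int | None
    untemplated_5prime: str
    td5: str
    td5_length: int
    td3: str
    td3_length: int
    internal_polyA_length: int
    terminal_polyA_length: int
    l1_start: int
    l1_end: int
    strand: str
    full_length: bool
    subfamily: str
    insert_l1_span: int

    def length_audit(self, empty: str, filled: str) -> tuple[int, int]:
        """(observed, reconstructed) length difference between the alleles."""
        reconstructed = (
            self.tsd_length
            + len(self.untemplated_5prime)
            + self.td5_length
            + self.insert_l1_span
            + self.internal_polyA_length
            + self.td3_length
            + self.terminal_polyA_length
        )
        return len(filled) - len(empty), reconstructed

    def to_dict(self) -> dict:
        return {
            "tsd": self.tsd,
            "tsd_length": self.tsd_length,
            "en_site": self.en_site,
            "en_mismatches": self.en_mismatches,
            "untemplated_5prime": self.untemplated_5prime,
            "td5_length": self.td5_length,
            "td3_length": self.td3_length,
            "internal_polyA_length": self.internal_polyA_length,
            "terminal_polyA_length": self.terminal_polyA_length,
            "l1_start_1based": self.l1_start + 1,
            "l1_end_1based": self.l1_end,
            "strand": self.strand,
            "full_length": self.full_length,
            "subfamily": self.subfamily,
        }


def characterize_insertion(
    empty: str,
    filled: str,
    l1: L1Body,
    max_mismatches: int = 0,
    full_length_bound: int = 10,
    donor_flank: str | None = None,
    min_polyA: int = 4,
) -> InsertionStructure:
    """Compose the full hallmark report for an empty/filled allele pair.

    Deterministic composition of TSD detection, EN-site reading, insert
    orientation, transduction/poly(A) decomposition, full-length calling
    (L1 start at or before 1-based position ``full_length_bound``) and
    subfamily diagnosis from the body's diagnostic base states.
    """
    tsd = find_tsd(empty, filled, max_mismatches=max_mismatches)
    insert = filled[tsd.insert_start : tsd.insert_end]
    report = extract_transductions(insert, l1, donor_flank=donor_flank, min_polyA=min_polyA)

    breakpoint = tsd.empty_start if report.strand == "+" else tsd.empty_end
    try:
        site, mism = en_motif(empty, breakpoint, strand=report.strand)
    except ValueError:
        site, mism = None, None

    diag = [report.insert_base_at_l1(insert, pos) for pos, _ in l1.ta_diagnostic]
    if any(b is None for b in diag):
        subfamily = "indeterminate"
    elif all(b == want for b, (_, want) in zip(diag, l1.ta_diagnostic)):
        subfamily = "L1-Ta"
    else:
        subfamily = "pre-Ta/other"

    return InsertionStructure(
        tsd=tsd.tsd,
        tsd_length=tsd.length,
        en_site=site,
        en_mismatches=mism,
        untemplated_5prime=report.untemplated_5prime,
        td5=report.td5,
        td5_length=len(report.td5),
        td3=report.td3,
        td3_length=len(report.td3),
        internal_polyA_length=report.internal_polyA_length,
        terminal_polyA_length=report.terminal_polyA_length,
        l1_start=report.l1_start,
        l1_end=report.l1_end,
        strand=report.strand,
        full_length=report.l1_start + 1 <= full_length_bound,
        subfamily=subfamily,
        insert_l1_span=report.insert_l1_span,
    )


# ---------------------------------------------------------------------------
# spliced 5' transductions


@dataclass(frozen=True)
class SpliceJunction:
    """One inferred exon-exon junction with its splice-site scores in [0,1]."""

    donor_site: str  # 9-mer around the donor (last 3 exonic + 6 intronic)
    acceptor_site: str  # 15-mer ending at the acceptor (+1 exonic base)
    donor_score: float
    acceptor_score: float


@dataclass(frozen=True)
class SpliceReport:
    exons: tuple[tuple[int, int], ...]  # source-region coordinates, ordered
    junctions: tuple[SpliceJunction, ...]
    untemplated_5prime: str


def analyze_spliced_transduction(
    td5: str,
    source: str,
    min_td5: int = 100,
    min_exon: int = 20,
) -> SpliceReport:
    """Dissect a long 5' transduction into spliced exons on its source region.

    Maximal co-linear near-exact matches of the transduction against the
    source region (difflib matching blocks of at least ``min_exon`` nt) are
    chained as exons; each inferred exon-exon junction is scored against the
    bundled splice-donor (9-nt) and splice-acceptor (15-nt) weight matrices,
    normalized to [0, 1].  Transduction bases 5' of the first exon match are
    reported as untemplated.
    """
    if len(td5) < min_td5:
        raise ValueError(
            f"5' transduction of {len(td5)} nt is below the {min_td5}-nt analysis threshold"
        )
    matcher = SequenceMatcher(None, td5, source, autojunk=False)
    blocks = [b for b in matcher.get_matching_blocks() if b.size >= min_exon]
    if not blocks:
        raise ValueError("no exon-scale match between the transduction and the source region")
    exons = tuple((b.b, b.b + b.size) for b in blocks)
    untemplated = td5[: blocks[0].a]

    junctions = []
    for (s0, e0), (s1, _) in zip(exons, exons[1:]):
        donor_win = source[e0 - 3 : e0 + 6]
        acceptor_win = source[s1 - 14 : s1 + 1]
        junctions.append(
            SpliceJunction(
                donor_site=donor_win,
                acceptor_site=acceptor_win,
                donor_score=SPLICE_DONOR.score_normalized(donor_win),
                acceptor_score=SPLICE_ACCEPTOR.score_normalized(acceptor_win),
            )
        )
    return SpliceReport(exons=exons, junctions=tuple(junctions), untemplated_5prime=untemplated)
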