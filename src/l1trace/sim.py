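"""Synthetic-data generation with full ground truth.

Everything downstream of raw sequencing in this package is exercised on
synthetic inputs built here: a random genome fixture, a surrogate L1 body
with an L1.3-style coordinate frame, insertion alleles with planted TPRT
hallmarks (target-site duplications, endonuclease site, poly(A) tracts,
5'/3' transductions, 5' truncation), transduction-family locus sets related
by shared flank transductions and inherited internal SNVs, and bisulfite
amplicon reads with per-CpG methylation probabilities.

Every generator records exactly what it planted (`TruthRecord`,
`FamilyFixture`), so recovery by the analysis modules can be checked
feature-by-feature.  All randomness flows through ``numpy``'s PCG64
``default_rng`` seeded per call: a fixed seed gives byte-identical output.

Coordinates are 0-based half-open internally; user-facing tables report
1-based positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import DNA, leading_run, random_dna, revcomp, trailing_run

__all__ = [
    "GenomeFixture",
    "L1Body",
    "InsertionSpec",
    "TruthRecord",
    "MethylationProfile",
    "FamilyMemberSpec",
    "FamilyFixture",
    "make_genome",
    "make_l1_body",
    "plant_insertion",
    "random_insertion_spec",
    "de_novo_fixture",
    "make_family_fixture",
    "family_specs_from_catalog",
    "simulate_bisulfite_reads",
]

COORDINATE_CONVENTION = "internal 0-based half-open; reported 1-based"


class FixtureError(ValueError):
    """A generator precondition was violated."""


# ---------------------------------------------------------------------------
# genome + L1 body fixtures


@dataclass(frozen=True)
class GenomeFixture:
    """Named random contigs standing in for reference flanking context."""

    contigs: dict[str, str]
    coordinate_convention: str = COORDINATE_CONVENTION

    def __post_init__(self):
        if len(self.contigs) == 0:
            raise FixtureError("genome fixture needs at least one contig")
        for name, seq in self.contigs.items():
            if not seq:
                raise FixtureError(f"contig {name!r} is empty")

    def with_contig(self, name: str, seq: str) -> "GenomeFixture":
        contigs = dict(self.contigs)
        contigs[name] = seq
        return replace(self, contigs=contigs)


def make_genome(seed: int, sizes: dict[str, int] | None = None) -> GenomeFixture:
    """Random genome fixture; default one 6-kb contig named ``chr1``."""
    rng = np.random.default_rng(seed)
    sizes = sizes or {"chr1": 6000}
    return GenomeFixture({name: random_dna(rng, n) for name, n in sizes.items()})


@dataclass(frozen=True)
class L1Body:
    """A surrogate ~6-kb L1 element annotated in an L1.3-style frame.

    Feature spans are 0-based half-open over ``sequence``; ``cpg_positions``
    index the C of literal CG dinucleotides inside the 5'UTR CpG island;
    ``ta_diagnostic`` maps body positions to the base states diagnostic of
    the L1-Ta subfamily (the ACA trinucleotide in the 3'UTR).
    """

    sequence: str
    utr5: tuple[int, int]
    orf1: tuple[int, int]
    orf2: tuple[int, int]
    en_domain: tuple[int, int]
    rt_domain: tuple[int, int]
    utr3: tuple[int, int]
    cpg_positions: tuple[int, ...]
    polya_signal: int
    ta_diagnostic: tuple[tuple[int, str], ...]

    def __post_init__(self):
        n = len(self.sequence)
        for span in (self.utr5, self.orf1, self.orf2, self.utr3):
            if not (0 <= span[0] < span[1] <= n):
                raise FixtureError(f"feature span {span} outside body of length {n}")
        for sub, outer in ((self.en_domain, self.orf2), (self.rt_domain, self.orf2)):
            if not (outer[0] <= sub[0] < sub[1] <= outer[1]):
                raise FixtureError("domain sub-span not nested in ORF2")
        for p in self.cpg_positions:
            if self.sequence[p : p + 2] != "CG":
                raise FixtureError(f"annotated CpG at {p} is not a CG dinucleotide")

    def __len__(self) -> int:
        return len(self.sequence)

    def orf_residue(self, orf: tuple[int, int], codon_1based: int) -> str:
        """Codon string for an ORF-local residue number (1-based)."""
        start = orf[0] + (codon_1based - 1) * 3
        return self.sequence[start : start + 3]


_SENSE_CODONS = [
    a + b + c
    for a in DNA
    for b in DNA
    for c in DNA
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def _random_orf(rng: np.random.Generator, n_codons: int, stop: str = "TAA") -> str:
    codons = rng.choice(_SENSE_CODONS, size=n_codons - 2)
    return "ATG" + "".join(codons) + stop


def make_l1_body(seed: int = 1988, mini: bool = False) -> L1Body:
    """Build the surrogate L1 body.

    The full-size body is 6,064 nt in an L1.3-style frame: 5'UTR 1-909 with a
    CpG island, ORF1 910-1926, ORF2 1990-5814 (endonuclease domain codons
    1-239, reverse-transcriptase domain codons 498-773), 3'UTR 5815-6064 with
    the Ta-diagnostic ACA at 5930-5932 and a polyadenylation signal near the
    3' end.  ORF2 codons 159, 400 and 523 are pinned to Q/W/D so that the
    Q159H, W400* and D523H variant fixtures are expressible.  ``mini`` gives
    a 660-nt body with the same feature layout, scaled, for fast
    property-style tests.

    The last bases of the body are forced non-A so that the internal poly(A)
    boundary is well posed, and the body starts with the canonical L1 GGGGGA.
    """
    rng = np.random.default_rng(seed)
    if mini:
        n, utr5, orf1, orf2, utr3 = 660, (0, 120), (120, 240), (300, 540), (540, 660)
        en, rt = (300, 360), (447, 510)  # ORF2 codons 1-20 and 50-70
        diag_at, pa_at, island = 600, 648, (20, 100)
        pinned = {}
    else:
        n, utr5, orf1, orf2, utr3 = 6064, (0, 909), (909, 1926), (1989, 5814), (5814, 6064)
        en = (1989, 1989 + 239 * 3)
        rt = (1989 + 497 * 3, 1989 + 773 * 3)
        diag_at, pa_at, island = 5929, 6044, (150, 550)
        pinned = {159: "CAA", 400: "TGG", 523: "GAT"}  # Q, W, D

    seq = list(random_dna(rng, n))
    seq[: orf1[0]] = list(random_dna(rng, orf1[0]))
    seq[0:6] = list("GGGGGA")
    # CpG island: plant CG dinucleotides at regular spacing inside the island
    step = max(6, (island[1] - island[0]) // 22)
    for p in range(island[0], island[1] - 1, step):
        seq[p], seq[p + 1] = "C", "G"
    if not mini:
        seq[580] = "C"  # 1-based 581, the PU.1-motif context base
        seq[707] = "T"  # 1-based 708, the RXR-motif context base
    orf1_seq = _random_orf(rng, (orf1[1] - orf1[0]) // 3)
    orf2_codons = list(_random_orf(rng, (orf2[1] - orf2[0]) // 3, stop="TAG"))
    for codon_1based, codon in pinned.items():
        off = (codon_1based - 1) * 3
        orf2_codons[off : off + 3] = list(codon)
    seq[orf1[0] : orf1[1]] = list(orf1_seq)
    seq[orf2[0] : orf2[1]] = orf2_codons
    seq[diag_at : diag_at + 3] = list("ACA")
    seq[pa_at : pa_at + 6] = list("AATAAA")
    seq[n - 6 :] = list(rng.choice(["C", "G", "T"], size=6))  # non-A 3' terminus

    body = "".join(seq)
    cpgs = tuple(
        p for p in range(island[0], island[1]) if body[p : p + 2] == "CG"
    )
    return L1Body(
        sequence=body,
        utr5=utr5,
        orf1=orf1,
        orf2=orf2,
        en_domain=en,
        rt_domain=rt,
        utr3=utr3,
        cpg_positions=cpgs,
        polya_signal=pa_at,
        ta_diagnostic=tuple((diag_at + i, b) for i, b in enumerate("ACA")),
    )


# ---------------------------------------------------------------------------
# insertion planting


@dataclass(frozen=True)
class InsertionSpec:
    """Blueprint for one planted insertion.

    ``position`` is the 0-based target-site start (where the TSD begins) on
    ``contig``.  ``tsd`` overrides the genomic sequence at the target site;
    otherwise ``tsd_length`` bases of the existing flank are duplicated.
    ``en_site`` (e.g. ``"TT/AAAG"``) rewrites the local hexamer around the
    nick.  ``truncation_point`` is the 0-based L1-body coordinate at which a
    5'-truncated element begins (``None`` = full length).
    """

    contig: str
    position: int
    strand: str = "+"
    tsd: str | None = None
    tsd_length: int = 0
    en_site: str | None = None
    td5: str = ""
    td3: str = ""
    internal_polyA_length: int = 0
    terminal_polyA_length: int = 0
    truncation_point: int | None = None
    untemplated_5prime: str = ""

    def __post_init__(self):
        if self.strand not in "+-":
            raise FixtureError("strand must be '+' or '-'")
        if self.tsd is not None and self.tsd_length not in (0, len(self.tsd)):
            raise FixtureError("tsd_length conflicts with explicit tsd string")
        if self.tsd_length < 0 or self.internal_polyA_length < 0 or self.terminal_polyA_length < 0:
            raise FixtureError("lengths must be non-negative")
        if self.en_site is not None:
            if len(self.en_site) != 7 or self.en_site[2] != "/":
                raise FixtureError("en_site must be written as NN/NNNN")
            eff = self.tsd if self.tsd is not None else None
            if eff and len(eff) >= 4 and self.en_site[3:] != eff[:4]:
                raise FixtureError("en_site disagrees with the first 4 nt of the TSD")
        if self.internal_polyA_length > 0 and not self.td3:
            raise FixtureError("an internal poly(A) tract requires a 3' transduction")

    @property
    def effective_tsd_length(self) -> int:
        return len(self.tsd) if self.tsd is not None else self.tsd_length


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted insertion."""

    spec: InsertionSpec
    tsd: str
    filled_allele: str
    empty_allele: str
    insert: str  # sense-strand insert between the TSD copies
    l1_start: int  # 0-based span of the L1 body present in the insert
    l1_end: int
    flank5: str
    flank3: str

    @property
    def l1_span(self) -> tuple[int, int]:
        return (self.l1_start, self.l1_end)


def _resample_base(rng: np.random.Generator, avoid: set[str]) -> str:
    choices = [b for b in DNA if b not in avoid]
    return str(rng.choice(choices))


def plant_insertion(
    genome: GenomeFixture,
    l1: L1Body,
    spec: InsertionSpec,
    seed: int,
    flank: int = 250,
) -> TruthRecord:
    """Plant one insertion and return its filled/empty alleles plus truth.

    The filled allele reads, 5' to 3' on the target top strand::

        5'flank . TSD . [untemplated . td5 . L1 . internal-pA . td3 .
                   terminal-pA  (reverse-complemented for strand '-')] .
        TSD . 3'flank

    and the empty allele carries a single copy of the target site.  The
    local flank is adjusted so the fixture is well posed for hallmark
    recovery: the hexamer around the nick is rewritten to ``en_site``, the
    TSD string occurs nowhere else within 100 nt of the breakpoint, and the
    flank bases abutting the insert are forced to differ from the insert's
    terminal bases (otherwise the maximal duplication would be ambiguous).
    """
    rng = np.random.default_rng(seed)
    if spec.contig not in genome.contigs:
        raise FixtureError(f"unknown contig {spec.contig!r}")
    contig = list(genome.contigs[spec.contig])
    p = spec.position
    t = spec.effective_tsd_length
    guard = max(flank, 102)
    if p - guard < 0 or p + t + guard > len(contig):
        raise FixtureError("TSD window overlaps the contig edge")
    if spec.truncation_point is not None and not (0 <= spec.truncation_point < len(l1)):
        raise FixtureError("truncation_point outside the L1 body")

    if spec.en_site is not None and spec.strand == "-":
        raise FixtureError("en_site planting is only supported for '+'-strand specs")
    if spec.tsd is not None:
        contig[p : p + t] = list(spec.tsd)
    if spec.en_site is not None:
        contig[p - 2 : p] = list(spec.en_site[:2])
        contig[p : p + 4] = list(spec.en_site[3:])
    tsd = "".join(contig[p : p + t])

    l1_start = spec.truncation_point or 0
    ins = (
        spec.untemplated_5prime
        + spec.td5
        + l1.sequence[l1_start:]
        + "A" * spec.internal_polyA_length
        + spec.td3
        + "A" * spec.terminal_polyA_length
    )
    if spec.strand == "-":
        ins = revcomp(ins)
    if not ins:
        raise FixtureError("insertion spec produces an empty insert")

    # flank bases abutting the insert must differ from the insert termini,
    # otherwise the maximal duplication is longer than the planted TSD
    protected = set(range(p, p + t))
    if spec.en_site is not None:
        protected |= set(range(p - 2, p + 4))
    if contig[p + t] == ins[0]:
        if p + t in protected:
            raise FixtureError("insert start clashes with the planted en-site hexamer")
        contig[p + t] = _resample_base(rng, {ins[0]})
    if contig[p - 1] == ins[-1]:
        if p - 1 in protected:
            raise FixtureError("insert end clashes with the planted en-site hexamer")
        contig[p - 1] = _resample_base(rng, {ins[-1]})
    # non-repetitive flank: the TSD must not recur within 100 nt of the site
    if t > 0:
        for _ in range(200):
            window = "".join(contig[p - 100 : p + t + 100])
            spurious = [
                i
                for i in range(len(window) - t + 1)
                if window[i : i + t] == tsd and i != 100
            ]
            if not spurious:
                break
            off = spurious[0] + (p - 100)
            candidates = [j for j in range(off, off + t) if j not in protected]
            if not candidates:
                raise FixtureError("could not make flank non-repetitive for this TSD")
            j = candidates[int(rng.integers(0, len(candidates)))]
            avoid = {contig[j]}
            if j == p + t:
                avoid.add(ins[0])
            if j == p - 1:
                avoid.add(ins[-1])
            contig[j] = _resample_base(rng, avoid)
        else:
            raise FixtureError("could not make flank non-repetitive for this TSD")

    contig_s = "".join(contig)
    empty = contig_s[p - flank : p + t + flank]
    filled = contig_s[p - flank : p + t] + ins + contig_s[p : p + t + flank]
    return TruthRecord(
        spec=spec,
        tsd=tsd,
        filled_allele=filled,
        empty_allele=empty,
        insert=ins,
        l1_start=l1_start,
        l1_end=len(l1),
        flank5=contig_s[p - flank : p],
        flank3=contig_s[p + t : p + t + flank],
    )


def random_insertion_spec(
    rng: np.random.Generator,
    contig: str,
    position: int,
    l1: L1Body,
    max_tsd: int = 20,
    max_td: int = 60,
    allow_truncation: bool = True,
) -> InsertionSpec:
    """Sample a well-posed random insertion spec for property tests.

    Enforces the conditions under which hallmark recovery is exact:
    transduction sequences do not start or end with A (so poly(A) boundaries
    are unambiguous), td5 does not end with the L1 body's first planted base,
    and the untemplated 5' addition differs from both td5's first base and
    the L1 start.
    """

    def non_a_dna(n: int) -> str:
        if n == 0:
            return ""
        core = "".join(rng.choice(list(DNA), size=n))
        bases = list(core)
        for i in (0, n - 1):
            if bases[i] == "A":
                bases[i] = str(rng.choice(["C", "G", "T"]))
        return "".join(bases)

    trunc = None
    if allow_truncation and rng.random() < 0.4:
        trunc = int(rng.integers(len(l1) // 4, (3 * len(l1)) // 4))

    def td5_extends_alignment(td5: str) -> bool:
        # the 5' transduction must not resemble the body just upstream of
        # the element's first base, or the local alignment would absorb its
        # suffix and shift the transduction/L1 boundary
        start = trunc or 0
        if not td5:
            return False
        if start == 0:
            return td5[-1] == l1.sequence[0]
        upstream = l1.sequence[max(0, start - 15) : start]
        # best ungapped suffix-extension score (match +2 / mismatch -3)
        score, best = 0, 0
        for i in range(1, min(len(td5), len(upstream)) + 1):
            score += 2 if td5[-i] == upstream[-i] else -3
            best = max(best, score)
        if best > 0:
            return True
        # gapped extensions need a seed match nearby: a 3-mer right at the
        # boundary (one-gap cost 5 < three matches) or a 4-mer further out
        tail = td5[-12:]
        if any(tail[-8:][i : i + 3] in upstream[-8:] for i in range(max(0, len(tail[-8:]) - 2))):
            return True
        return any(tail[i : i + 4] in upstream for i in range(max(0, len(tail) - 3)))

    td5 = non_a_dna(int(rng.integers(0, max_td)))
    for _ in range(50):
        if not td5_extends_alignment(td5):
            break
        td5 = non_a_dna(len(td5))
    else:
        td5 = ""
    td3 = non_a_dna(int(rng.integers(0, max_td)))
    internal = int(rng.integers(4, 30)) if td3 else 0
    untemplated = ""
    if rng.random() < 0.3:
        head = td5[0] if td5 else l1.sequence[trunc or 0]
        untemplated = str(rng.choice([b for b in "CGT" if b != head]))
    return InsertionSpec(
        contig=contig,
        position=position,
        strand="+" if rng.random() < 0.5 else "-",
        tsd_length=int(rng.integers(0, max_tsd + 1)),
        td5=td5,
        td3=td3,
        internal_polyA_length=internal,
        terminal_polyA_length=int(rng.integers(4, 40)),
        truncation_point=trunc,
        untemplated_5prime=untemplated,
    )


# ---------------------------------------------------------------------------
# transduction-family fixtures


@dataclass(frozen=True)
class FamilyMemberSpec:
    """One locus in a synthetic transduction family.

    ``parent`` names the donor whose immediate 3' genomic flank this member
    carries as its 3' transduction (``None`` for roots/decoys).
    ``private_snvs`` are (0-based body position, alt base) substitutions
    private to this member; ancestors' private SNVs are inherited.
    """

    locus: str
    parent: str | None = None
    full_length: bool = True
    private_snvs: tuple[tuple[int, str], ...] = ()
    td5_length: int = 0
    td3_length: int = 40
    tsd: str | None = None
    tsd_length: int = 12


@dataclass(frozen=True)
class FamilyFixture:
    """Planted family: per-locus truth records, SNV truth, and lineage edges."""

    records: dict[str, TruthRecord]
    snv_truth: dict[str, frozenset[tuple[int, str]]]
    edges: frozenset[tuple[str, str]]  # (parent, child)
    member_sequences: dict[str, str]  # each member's (mutated) L1 body
    td3_tags: dict[str, str]
    td5_tags: dict[str, str]
    flank5: dict[str, str]
    flank3: dict[str, str]

    def roots(self) -> list[str]:
        children = {c for _, c in self.edges}
        return [m for m in self.records if m not in children]


def _check_forest(members: list[FamilyMemberSpec]) -> None:
    by_name = {m.locus: m for m in members}
    if len(by_name) != len(members):
        raise FixtureError("duplicate locus ids in family spec")
    for m in members:
        seen = {m.locus}
        cur = m.parent
        while cur is not None:
            if cur not in by_name:
                raise FixtureError(f"unknown parent {cur!r} for {m.locus!r}")
            if cur in seen:
                raise FixtureError(f"cyclic parent references at {cur!r}")
            seen.add(cur)
            cur = by_name[cur].parent


def make_family_fixture(
    members: list[FamilyMemberSpec],
    genome: GenomeFixture,
    l1: L1Body,
    seed: int,
    contig: str = "fam",
    spacing: int = 2500,
    flank: int = 250,
) -> FamilyFixture:
    """Plant a transduction family on a dedicated contig.

    Loci are laid out left-to-right in input order with ``spacing`` bp
    between target sites.  Every non-root member's 3' transduction is a
    verbatim copy of its parent's immediate 3' genomic flank (and its 5'
    transduction, when requested, of the parent's immediate 5' flank).
    Member L1 bodies carry the union of their ancestors' private SNVs plus
    their own, so ancestral variants become shared along each lineage.
    """
    _check_forest(members)
    rng = np.random.default_rng(seed)
    by_name = {m.locus: m for m in members}

    n = len(members) * spacing + 2 * (flank + 200)
    contig_seq = random_dna(rng, n)
    genome = genome.with_contig(contig, contig_seq)
    positions = {
        m.locus: (flank + 200) + i * spacing for i, m in enumerate(members)
    }

    # inherited SNV sets (topological walk up the parent chain)
    snv_truth: dict[str, frozenset[tuple[int, str]]] = {}

    def snvs_of(name: str) -> frozenset[tuple[int, str]]:
        if name not in snv_truth:
            m = by_name[name]
            inherited = snvs_of(m.parent) if m.parent else frozenset()
            snv_truth[name] = inherited | frozenset(m.private_snvs)
        return snv_truth[name]

    records: dict[str, TruthRecord] = {}
    member_seqs: dict[str, str] = {}
    td3_tags: dict[str, str] = {}
    td5_tags: dict[str, str] = {}
    edges: set[tuple[str, str]] = set()

    # parents must be planted before their children (their flanks feed the
    # child's transduction); keep genomic layout in input order regardless
    ordered: list[FamilyMemberSpec] = []
    placed: set[str] = set()
    pending = list(members)
    while pending:
        progressed = False
        for m in list(pending):
            if m.parent is None or m.parent in placed:
                ordered.append(m)
                placed.add(m.locus)
                pending.remove(m)
                progressed = True
        if not progressed:  # unreachable after _check_forest
            raise FixtureError("cyclic parent references")

    for m in ordered:
        body = list(l1.sequence)
        for pos, alt in sorted(snvs_of(m.locus)):
            if body[pos] == alt:
                raise FixtureError(f"SNV alt equals reference base at {pos}")
            body[pos] = alt
        mutated = L1Body(
            sequence="".join(body),
            utr5=l1.utr5,
            orf1=l1.orf1,
            orf2=l1.orf2,
            en_domain=l1.en_domain,
            rt_domain=l1.rt_domain,
            utr3=l1.utr3,
            cpg_positions=tuple(
                p for p in l1.cpg_positions if "".join(body[p : p + 2]) == "CG"
            ),
            polya_signal=l1.polya_signal,
            ta_diagnostic=l1.ta_diagnostic,
        )
        member_seqs[m.locus] = mutated.sequence

        td3 = td5 = ""
        if m.parent is not None:
            parent_rec = records[m.parent]
            td3 = parent_rec.flank3[: m.td3_length]
            if m.td5_length > 0:
                td5 = parent_rec.flank5[-m.td5_length :]
            edges.add((m.parent, m.locus))
        trunc = None if m.full_length else int(rng.integers(len(l1) // 3, (2 * len(l1)) // 3))
        spec = InsertionSpec(
            contig=contig,
            position=positions[m.locus],
            tsd=m.tsd,
            tsd_length=0 if m.tsd else m.tsd_length,
            td5=td5,
            td3=td3,
            internal_polyA_length=int(rng.integers(8, 25)) if td3 else 0,
            terminal_polyA_length=int(rng.integers(15, 45)),
            truncation_point=trunc,
        )
        rec = plant_insertion(genome, mutated, spec, seed=int(rng.integers(2**31)), flank=flank)
        records[m.locus] = rec
        td3_tags[m.locus] = td3
        td5_tags[m.locus] = td5

    return FamilyFixture(
        records=records,
        snv_truth={k: snvs_of(k) for k in records},
        edges=frozenset(edges),
        member_sequences=member_seqs,
        td3_tags=td3_tags,
        td5_tags=td5_tags,
        flank5={k: r.flank5 for k, r in records.items()},
        flank3={k: r.flank3 for k, r in records.items()},
    )


def de_novo_fixture(
    seed: int, l1: L1Body | None = None, flank: int = 250
) -> tuple[GenomeFixture, TruthRecord, str]:
    """Reconstruct the worked-example de novo locus from its printed architecture.

    Plants the bundled de novo insertion blueprint (16-nt TSD string,
    TT/AAAG endonuclease site, 10-nt 5' transduction copied from a simulated
    donor upstream flank, 44-nt 3' transduction, 17-nt internal and 33-nt
    terminal poly(A) tracts, full-length L1) between random non-repetitive
    flanks.  Returns (genome, truth record, donor upstream flank).

    The donor flank is forced not to end with the L1 first base and the 3'
    transduction not to start or end with A: otherwise those component
    boundaries are genuinely ambiguous in the assembled allele.
    """
    from .catalog import DE_NOVO_ARCHITECTURE as arch

    l1 = l1 or make_l1_body()
    genome = make_genome(seed, {"chr1": 6000})
    rng = np.random.default_rng(seed + 1)
    donor_flank = random_dna(rng, 199) + "T"
    spec = InsertionSpec(
        contig="chr1",
        position=3000,
        tsd=arch["tsd"],
        en_site=arch["en_site"],
        td5=donor_flank[-arch["td5_nt"] :],
        td3="G" + random_dna(rng, arch["td3_nt"] - 2) + "C",
        internal_polyA_length=arch["internal_polyA_nt"],
        terminal_polyA_length=arch["terminal_polyA_nt"],
    )
    truth = plant_insertion(genome, l1, spec, seed=seed + 2, flank=flank)
    return genome, truth, donor_flank


def family_specs_from_catalog(
    seed: int,
    n_decoys: int = 0,
    snvs_per_member: int = 2,
    n_shared: int = 4,
    l1: L1Body | None = None,
) -> list[FamilyMemberSpec]:
    """Member specs mirroring the bundled 14-locus transduction family.

    Lineage relations, TSD strings, full-length flags and 5'-transduction
    lengths follow the bundled catalog; each member additionally receives
    ``snvs_per_member`` random private SNVs, and the progenitor receives
    ``n_shared`` private SNVs that all descendants inherit (the family's
    shared-SNV signature).  ``n_decoys`` unrelated rooted loci are appended.
    """
    from .catalog import TRANSDUCTION_FAMILY

    l1 = l1 or make_l1_body()
    rng = np.random.default_rng(seed)
    used: set[int] = set()

    def sample_snvs(k: int) -> tuple[tuple[int, str], ...]:
        out = []
        while len(out) < k:
            pos = int(rng.integers(l1.utr5[1], len(l1) - 200))
            if pos in used:
                continue
            used.add(pos)
            ref = l1.sequence[pos]
            out.append((pos, str(rng.choice([b for b in DNA if b != ref]))))
        return tuple(out)

    specs = []
    for row in TRANSDUCTION_FAMILY:
        k = n_shared if row.parent is None else snvs_per_member
        # spliced 5' transductions are modelled by their length only here
        td5 = min(row.td5_nt, 100)
        specs.append(
            FamilyMemberSpec(
                locus=row.element,
                parent=row.parent,
                full_length=row.full_length,
                private_snvs=sample_snvs(k),
                td5_length=td5,
                td3_length=int(rng.integers(25, 60)),
                tsd=row.tsd,
            )
        )
    for i in range(n_decoys):
        specs.append(
            FamilyMemberSpec(
                locus=f"decoy_{i:02d}",
                parent=None,
                full_length=bool(rng.random() < 0.5),
                private_snvs=sample_snvs(snvs_per_member),
                td3_length=0,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# bisulfite reads


@dataclass(frozen=True)
class MethylationProfile:
    """Per-CpG methylation probabilities for one amplicon.

    ``mutated`` maps a CpG C-position to the non-C base emitted there in
    every read (a CpG-destroying mutation, rendered '×' downstream).
    """

    amplicon_id: str
    cpg_probabilities: tuple[float, ...]
    conversion_efficiency: float = 1.0
    mutated: tuple[tuple[int, str], ...] = ()

    def __post_init__(self):
        if not all(0.0 <= p <= 1.0 for p in self.cpg_probabilities):
            raise FixtureError("methylation probabilities must lie in [0, 1]")
        if not 0.0 <= self.conversion_efficiency <= 1.0:
            raise FixtureError("conversion efficiency must lie in [0, 1]")
        for _, base in self.mutated:
            if base not in "AG":
                raise FixtureError("mutated CpG base must be a non-C, non-T base (A or G)")


def simulate_bisulfite_reads(
    amplicon: str,
    cpg_positions: tuple[int, ...],
    profile: MethylationProfile,
    n_reads: int,
    seed: int,
) -> list[str]:
    """Simulate top-strand bisulfite reads of one amplicon.

    Each CpG cytosine is retained as C with its site's methylation
    probability and read as T otherwise; every other cytosine converts to T
    with probability ``conversion_efficiency``; mutated CpG positions emit
    the specified base in all reads.  Reads span the full primer-delimited
    amplicon.  Only the sense strand is simulated.
    """
    if n_reads < 1:
        raise FixtureError("n_reads must be >= 1")
    if len(profile.cpg_probabilities) != len(cpg_positions):
        raise FixtureError("probability vector length must equal the CpG count")
    for p in cpg_positions:
        if amplicon[p : p + 2] != "CG":
            raise FixtureError(f"cpg position {p} is not a CG dinucleotide")
    rng = np.random.default_rng(seed)
    cpg_set = set(cpg_positions)
    mutated = dict(profile.mutated)
    non_cpg_c = [
        i for i, b in enumerate(amplicon) if b == "C" and i not in cpg_set
    ]
    reads = []
    for _ in range(n_reads):
        read = list(amplicon)
        for p, prob in zip(cpg_positions, profile.cpg_probabilities):
            if p in mutated:
                read[p] = mutated[p]
            elif rng.random() >= prob:
                read[p] = "T"
        for i in non_cpg_c:
            if rng.random() < profile.conversion_efficiency:
                read[i] = "T"
        reads.append("".join(read))
    return reads
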