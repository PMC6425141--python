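"""Transduction-family reconstruction and internal-variant analysis.

An L1 3' transduction is a verbatim copy of the donor element's immediate 3'
genomic flank, carried along when transcription reads through the donor's
polyadenylation signal; it identifies the donor locus uniquely whenever the
transduced sequence occurs in exactly one catalogued flank.  This module
traces donors, calls internal single-nucleotide variants of family members
against an L1.3-frame body (with ORF-local amino-acid annotations),
partitions variants by how widely they are shared, discriminates allelic
variants from redundant clone sequences, assembles the donor graph as an
acyclic lineage rooted at the family progenitor, and scans variant effects
against bundled DNA-binding motif matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
from Bio import Align
from Bio.Seq import Seq

from ._seq import hamming, trailing_run
from .pwm import PWM, TF_PWMS
from .sim import L1Body

__all__ = [
    "SNV",
    "FamilyMember",
    "LocusRecord",
    "FamilyGraph",
    "AlleleSet",
    "AmbiguousDonorError",
    "trace_donor",
    "call_variants",
    "partition_variants",
    "distinguish_alleles",
    "build_family",
    "pwm_variant_effect",
]


class AmbiguousDonorError(ValueError):
    """A transduction matches the 3' flank of more than one catalogued locus."""


@dataclass(frozen=True)
class SNV:
    """One internal variant in L1.3-frame coordinates (1-based position)."""

    position: int
    ref: str
    alt: str
    aa_change: str | None = field(default=None, compare=False)
    orf: str | None = field(default=None, compare=False)
    nonsense: bool = field(default=False, compare=False)

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref, self.alt)


@dataclass(frozen=True)
class FamilyMember:
    """One L1 locus considered for family membership."""

    locus: str
    contig: str
    position: int  # 1-based
    tsd: str = ""
    full_length: bool = True
    snvs: frozenset[SNV] = frozenset()
    td5: str | None = None
    td3: str | None = None
    source: str = ""

    def snv_keys(self) -> frozenset[tuple[int, str, str]]:
        return frozenset(s.key for s in self.snvs)


@dataclass(frozen=True)
class LocusRecord:
    """Catalog entry: a locus with its immediate genomic flanks."""

    locus: str
    contig: str
    position: int  # 1-based
    flank5: str
    flank3: str
    tsd: str = ""
    full_length: bool = True


# ---------------------------------------------------------------------------
# donor tracing


def trace_donor(
    td3: str,
    locus_catalog: list[LocusRecord] | list[tuple[str, str]],
    min_len: int = 10,
    max_mismatch_per_20nt: int = 0,
) -> str | None:
    """Identify the donor locus whose 3' flank contains the transduction.

    Terminal A's are stripped from ``td3`` first (the poly(A) tail boundary
    is not part of the transduced flank).  Matching is exact by default;
    setting ``max_mismatch_per_20nt`` allows ``len//20`` mismatches per
    window for diverged copies.  Returns ``None`` for zero matches and
    raises :class:`AmbiguousDonorError` for more than one — ambiguity is
    reported, never silently resolved.
    """
    core = td3[: len(td3) - trailing_run(td3)] if trailing_run(td3) else td3
    if len(core) < min_len:
        raise ValueError(
            f"3' transduction core of {len(core)} nt is below min_len={min_len}"
        )
    entries = [
        (rec.locus, rec.flank3) if isinstance(rec, LocusRecord) else rec
        for rec in locus_catalog
    ]
    budget = (len(core) // 20) * max_mismatch_per_20nt
    hits = []
    for locus, flank in entries:
        if budget == 0:
            found = core in flank
        else:
            found = any(
                hamming(core, flank[i : i + len(core)]) <= budget
                for i in range(len(flank) - len(core) + 1)
            )
        if found:
            hits.append(locus)
    if not hits:
        return None
    if len(hits) > 1:
        raise AmbiguousDonorError(f"transduction matches multiple loci: {sorted(hits)}")
    return hits[0]


# ---------------------------------------------------------------------------
# variant calling and partitioning


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -1
    # free end gaps: 5'-truncated members align to a suffix of the body
    aligner.open_end_insertion_score = 0
    aligner.extend_end_insertion_score = 0
    aligner.open_end_deletion_score = 0
    aligner.extend_end_deletion_score = 0
    return aligner


def _annotate(pos0: int, alt: str, body: L1Body) -> tuple[str | None, str | None, bool]:
    for name, span in (("ORF1", body.orf1), ("ORF2", body.orf2)):
        if span[0] <= pos0 < span[1]:
            codon_idx = (pos0 - span[0]) // 3
            off = (pos0 - span[0]) % 3
            ref_codon = body.sequence[span[0] + codon_idx * 3 : span[0] + codon_idx * 3 + 3]
            alt_codon = ref_codon[:off] + alt + ref_codon[off + 1 :]
            aa_ref = str(Seq(ref_codon).translate())
            aa_alt = str(Seq(alt_codon).translate())
            if aa_ref == aa_alt:
                return None, name, False
            return f"{aa_ref}{codon_idx + 1}{aa_alt}", name, aa_alt == "*"
    return None, None, False


def call_variants(member_seq: str, body: L1Body) -> frozenset[SNV]:
    """Call substitutions of a member sequence against the L1.3-frame body.

    The member must align end-to-end (global alignment with free end gaps,
    so 5'-truncated members align to a body suffix).  Variants are reported
    in 1-based body coordinates; non-synonymous changes within ORF spans are
    annotated with ORF-local residue numbering (e.g. ``D523H`` in ORF2) and
    nonsense codons flagged.
    """
    aligner = _global_aligner()
    alignment = aligner.align(body.sequence, member_seq)[0]
    body_blocks, member_blocks = alignment.aligned
    snvs = []
    for (bs, be), (ms, _) in zip(
        (tuple(map(int, b)) for b in body_blocks),
        (tuple(map(int, b)) for b in member_blocks),
    ):
        for k in range(be - bs):
            ref, alt = body.sequence[bs + k], member_seq[ms + k]
            if ref != alt:
                aa, orf, stop = _annotate(bs + k, alt, body)
                snvs.append(
                    SNV(position=bs + k + 1, ref=ref, alt=alt, aa_change=aa, orf=orf, nonsense=stop)
                )
    return frozenset(snvs)


SHARED_ALL = "shared_all"
SHARED_SOME = "shared_some"
PRIVATE = "private"


def partition_variants(
    members: list[FamilyMember],
) -> dict[tuple[int, str, str], str]:
    """Classify each SNV by its carrier count across members.

    Carried by every member -> ``shared_all``; by exactly one -> ``private``;
    otherwise ``shared_some``.
    """
    if len(members) < 2:
        raise ValueError("variant partitioning requires >= 2 members")
    counts: dict[tuple[int, str, str], int] = {}
    for m in members:
        for key in m.snv_keys():
            counts[key] = counts.get(key, 0) + 1
    n = len(members)
    return {
        key: SHARED_ALL if c == n else (PRIVATE if c == 1 else SHARED_SOME)
        for key, c in counts.items()
    }


# ---------------------------------------------------------------------------
# allele discrimination from redundant clones


@dataclass(frozen=True)
class AlleleSet:
    """Alleles distilled from independent PCR clone sequences."""

    alleles: tuple[str, ...]
    discriminating_snvs: tuple[tuple[int, tuple[str, ...]], ...]  # (0-based pos, base per allele)
    assignment: tuple[int, ...]  # clone index -> allele index
    pcr_artifacts: tuple[tuple[int, int, str], ...]  # (clone, 0-based pos, base)


def distinguish_alleles(clone_seqs: list[str], min_support: int = 2) -> AlleleSet:
    """Separate real allelic variation from induced PCR mutations.

    Variants observed in at least ``min_support`` independent clones are
    retained as real; retained variants that co-segregate define alleles
    (clones sharing a genotype over the retained positions form one allele,
    whose consensus corrects any residual singleton errors).  Variants seen
    in fewer clones are labelled PCR-induced and excluded from consensi.
    """
    if len(clone_seqs) < 2:
        raise ValueError("allele discrimination requires >= 2 clones")
    n = len(clone_seqs[0])
    if any(len(s) != n for s in clone_seqs):
        raise ValueError("clone sequences must be equal length (assembled amplicons)")

    majority = []
    for i in range(n):
        column = [s[i] for s in clone_seqs]
        majority.append(max(sorted(set(column)), key=column.count))
    retained: list[int] = []
    artifacts: list[tuple[int, int, str]] = []
    for i in range(n):
        column = [s[i] for s in clone_seqs]
        for base in sorted(set(column) - {majority[i]}):
            carriers = [k for k, b in enumerate(column) if b == base]
            if len(carriers) >= min_support:
                if i not in retained:
                    retained.append(i)
            else:
                artifacts.extend((k, i, base) for k in carriers)

    artifact_at = {(k, i) for k, i, _ in artifacts}
    genotypes = []
    for k, s in enumerate(clone_seqs):
        genotypes.append(
            tuple(majority[i] if (k, i) in artifact_at else s[i] for i in retained)
        )
    unique = sorted(set(genotypes))
    assignment = tuple(unique.index(g) for g in genotypes)
    alleles = []
    for g in unique:
        seq = list(majority)
        for i, base in zip(retained, g):
            seq[i] = base
        alleles.append("".join(seq))
    discriminating = tuple(
        (i, tuple(g[j] for g in unique))
        for j, i in enumerate(retained)
        if len({g[j] for g in unique}) > 1
    )
    return AlleleSet(
        alleles=tuple(alleles),
        discriminating_snvs=discriminating,
        assignment=assignment,
        pcr_artifacts=tuple(sorted(artifacts)),
    )


# ---------------------------------------------------------------------------
# family graph


TD3_MATCH = "td3_match"
TD53_MATCH = "td5+td3_match"
SNV_SHARING = "snv_sharing"


@dataclass
class FamilyGraph:
    """Acyclic donor lineage over family members.

    Wraps a :class:`networkx.DiGraph` whose nodes are locus ids and whose
    edges run donor -> offspring with an ``evidence`` attribute.
    """

    graph: nx.DiGraph
    root: str

    @property
    def members(self) -> tuple[str, ...]:
        return tuple(sorted(self.graph.nodes))

    def edges(self) -> tuple[tuple[str, str, str], ...]:
        return tuple(
            sorted((u, v, d["evidence"]) for u, v, d in self.graph.edges(data=True))
        )

    def to_edgelist_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.edges(), columns=["donor", "offspring", "evidence"]).to_csv(
            path, sep="\t", index=False
        )

    def to_dot(self) -> str:
        lines = ["digraph transduction_family {"]
        for node in self.members:
            shape = "doubleoctagon" if node == self.root else "box"
            lines.append(f'  "{node}" [shape={shape}];')
        for u, v, ev in self.edges():
            lines.append(f'  "{u}" -> "{v}" [label="{ev}"];')
        lines.append("}")
        return "\n".join(lines)


def build_family(
    members: list[FamilyMember],
    locus_catalog: list[LocusRecord],
    seed_locus: str | None = None,
    min_td3: int = 10,
) -> FamilyGraph:
    """Assemble the transduction family graph.

    Donor edges come from :func:`trace_donor` applied to each member's 3'
    transduction against the catalogued flanks (evidence upgraded to
    ``td5+td3_match`` when the member's 5' transduction also matches the
    donor's immediate upstream flank).  The family is the component
    containing ``seed_locus`` (default: the largest component).  Members
    outside it that nevertheless carry every family-wide shared SNV attach
    to the progenitor with ``snv_sharing`` evidence.  The result is
    validated acyclic; the root is the in-degree-0 node with the most
    descendants.  Output is invariant to member input order.
    """
    members = sorted(members, key=lambda m: m.locus)
    by_locus = {m.locus: m for m in members}
    flank5 = {r.locus: r.flank5 for r in locus_catalog}
    g = nx.DiGraph()
    g.add_nodes_from(by_locus)

    for m in members:
        if not m.td3 or len(m.td3) - trailing_run(m.td3) < min_td3:
            continue
        candidates = [r for r in locus_catalog if r.locus != m.locus and r.locus in by_locus]
        donor = trace_donor(m.td3, candidates, min_len=min_td3)
        if donor is None:
            continue
        evidence = TD3_MATCH
        if m.td5 and donor in flank5 and m.td5 in flank5[donor]:
            evidence = TD53_MATCH
        g.add_edge(donor, m.locus, evidence=evidence)

    components = list(nx.weakly_connected_components(g))
    if seed_locus is not None:
        if seed_locus not in by_locus:
            raise ValueError(f"seed locus {seed_locus!r} not among members")
        family = next(c for c in components if seed_locus in c)
    else:
        family = max(components, key=lambda c: (len(c), sorted(c)[0]))

    def progenitor_of(nodes: set[str]) -> str:
        sub = g.subgraph(nodes)
        roots = [n for n in sorted(nodes) if sub.in_degree(n) == 0]
        return max(roots, key=lambda n: (len(nx.descendants(sub, n)), n))

    # attach transduction-less members carrying the full shared-SNV signature
    while True:
        with_snvs = [by_locus[n] for n in family if by_locus[n].snvs]
        if not with_snvs:
            break
        signature = frozenset.intersection(*[m.snv_keys() for m in with_snvs])
        if not signature:
            break
        root = progenitor_of(family)
        added = False
        for m in members:
            if m.locus in family or not m.snvs:
                continue
            if signature <= m.snv_keys():
                g.add_edge(root, m.locus, evidence=SNV_SHARING)
                family.add(m.locus)
                added = True
        if not added:
            break

    sub = nx.DiGraph(g.subgraph(family))
    if not nx.is_directed_acyclic_graph(sub):
        raise ValueError("donor edges form a cycle; lineage must be acyclic")
    return FamilyGraph(graph=sub, root=progenitor_of(set(sub.nodes)))


# ---------------------------------------------------------------------------
# PWM variant effects


def pwm_variant_effect(
    sequence: str,
    variant: tuple[int, str],
    pwms: dict[str, PWM] | None = None,
) -> dict[str, float]:
    """Best-window log-odds delta caused by a substitution, per matrix.

    ``variant`` is (0-based position, alt base).  For every matrix the best
    window score over both strands is computed before and after applying the
    substitution; the delta (after - before) is returned.  A variant outside
    every score-relevant window leaves all deltas at zero.
    """
    pos, alt = variant
    if not 0 <= pos < len(sequence):
        raise ValueError("variant position outside the sequence")
    pwms = pwms or TF_PWMS
    mutated = sequence[:pos] + alt + sequence[pos + 1 :]
    return {
        name: pwm.best_score(mutated) - pwm.best_score(sequence)
        for name, pwm in pwms.items()
    }
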