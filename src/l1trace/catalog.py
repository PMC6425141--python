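"""Bundled reference data for the worked example.

This module carries the published description of an experimentally
characterized 14-member human L1 transduction family (hg19 coordinates,
target-site duplications, full-length status and lineage relations), the
printed architecture of the reprogramming-associated de novo insertion that
belongs to it, and the locus-specific bisulfite methylation percentages
reported for the donor element.  These are *inputs* to the pipeline: the
synthetic-data generator uses them to rebuild each locus with known ground
truth, and the acceptance checks replay the published arithmetic on them.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FamilyCatalogRow:
    """One published transduction-family locus.

    ``parent`` names the donor element whose 3' flank this locus carries as
    a 3' transduction (``None`` for the lineage progenitor).  ``td5_nt`` is
    the length of the 5' transduction, where one was observed.
    """

    element: str
    contig: str
    position: int  # 1-based hg19-style coordinate
    tsd: str
    full_length: bool
    parent: str | None
    td5_nt: int = 0


# Lineage relations: the donor L1 sourced the de novo insertion (which also
# carries a 10-nt 5' transduction of the donor's upstream flank); the
# progenitor sourced Ref_Chr1_p31.1_a (539-nt spliced 5' transduction) and,
# via its 3' flank, every other member; Ref_Chr7_q21.3 sourced
# Non-ref_ChrX_p11.4 (18-nt 5' transduction).
TRANSDUCTION_FAMILY: tuple[FamilyCatalogRow, ...] = (
    FamilyCatalogRow("LineageProgenitor_Chr11", "chr11", 95169381, "AAAGAATTGTA", True, None),
    FamilyCatalogRow("Donor_Chr3", "chr3", 38626082, "AGAATGAGTAAATAATG", True, "LineageProgenitor_Chr11"),
    FamilyCatalogRow("DeNovo_Chr1", "chr1", 231719316, "AAAGAAATGACATCTG", True, "Donor_Chr3", td5_nt=10),
    FamilyCatalogRow("Ref_Chr7_q21.3", "chr7", 96475963, "GAAAGTTCCAGTTGC", True, "LineageProgenitor_Chr11"),
    FamilyCatalogRow("Non-ref_Chr3_p24.3", "chr3", 20748904, "TAAAGACAC", True, "LineageProgenitor_Chr11"),
    FamilyCatalogRow("Ref_Chr1_p31.1_a", "chr1", 84518060, "AGAAAAACAAATCA", True, "LineageProgenitor_Chr11", td5_nt=539),
    FamilyCatalogRow("Ref_Chr1_p31.1_b", "chr1", 83125969, "AAAAAAAATGGTTCATGC", False, "LineageProgenitor_Chr11"),
    FamilyCatalogRow("Ref_Chr9_p23", "chr9", 12556931, "GAAAAGTATTGTATTG", False, "LineageProgenitor_Chr11"),
    FamilyCatalogRow("Non-ref_Chr3_p12.2_a", "chr3", 80590176, "GAAAATGGAATGGG", True, "LineageProgenitor_Chr11"),
    FamilyCatalogRow("Non-ref_Chr3_p12.2_b", "chr3", 82144869, "AGAAATAATAATTTCC", True, "LineageProgenitor_Chr11"),
    FamilyCatalogRow("Non-ref_ChrX_p11.4", "chrX", 38097551, "AAAAGCGATATG", True, "Ref_Chr7_q21.3", td5_nt=18),
    FamilyCatalogRow("Non-ref_Chr17_q12", "chr17", 32813609, "AAGAAGGTAAGATGG", False, "LineageProgenitor_Chr11"),
    FamilyCatalogRow("Non-ref_Chr1_p22.2", "chr1", 90914512, "AAAAAGCTCTTTCAG", False, "LineageProgenitor_Chr11"),
    FamilyCatalogRow("Non-ref_Chr4_q12", "chr4", 53628490, "TAAATTACAGGTTA", False, "LineageProgenitor_Chr11"),
)

#: Printed structural architecture of the de novo insertion: a full-length
#: L1-Ta element with 16-nt TSDs, a degenerate endonuclease site, a 10-nt 5'
#: transduction, a 44-nt 3' transduction preceded by a 17-nt internal poly(A)
#: tract, and a 33-nt terminal poly(A) tract.
DE_NOVO_ARCHITECTURE = {
    "tsd": "AAAGAAATGACATCTG",
    "en_site": "TT/AAAG",
    "td5_nt": 10,
    "internal_polyA_nt": 17,
    "td3_nt": 44,
    "terminal_polyA_nt": 33,
}

#: Locus-specific bisulfite methylation percentages printed for the donor L1
#: in the CRL2429 line (mean CpG methylation of 50 sampled reads).
DONOR_METHYLATION_PCT = {"fibroblast": 66.6, "hipsc": 31.1, "neuron": 61.0}

#: Printed per-line reductions in donor-L1 promoter methylation during
#: reprogramming (fibroblast minus hiPSC), per cell line.
REPROGRAMMING_REDUCTION_PCT = {"CRL2429": 35.5, "CRL1502": 14.4}

#: Published bisulfite PCR primers (one common reverse primer combined with a
#: subfamily 5'UTR forward primer or a locus-specific flank forward primer).
#: Kept for reference/documentation; synthetic amplicons derive their own
#: primers from the surrogate sequences.
BISULFITE_PRIMERS = {
    "L1_Bis-LP": "GATTTGTTTTTGGATTGTAAAATGGTT",
    "L1_Bis-Donor": "TGGGTAGATGAACAGATAAGTAAA",
    "L1_Bis-DN": "GTTATTTGATAGTATTTTAATGAAGATT",
    "L1_Bis-F": "TAGGGAGTGTTAGATAGTGG",
    "L1_Bis-R": "ACTATAATAAACTCCACCCAAT",
}
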