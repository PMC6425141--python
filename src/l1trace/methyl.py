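"""Bisulfite amplicon CpG methylation calling and time-course statistics.

Bisulfite treatment converts unmethylated cytosine to uracil (read as T)
while 5-methylcytosine at CpG sites is protected and reads as C.  This
module assigns amplicon reads to their locus-specific or subfamily-wide
amplicon by primer matching in converted space, calls a per-CpG state vector
per read (M = methylated, U = unmethylated, X = mutated/other base),
summarizes an amplicon at one time point by sampling up to a cap of unique
QC-passing reads (mean ± sd of per-read methylation fractions, plus per-site
means), and compares time points with paired t-tests over CpG sites with a
Bonferroni correction across the batch of comparisons.

The pairing unit for the t-test is the CpG site (its mean methylation across
sampled reads), because reads are not matched across time points; see the
methods note for the rationale and caveats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import revcomp

__all__ = [
    "AmpliconDef",
    "ReadProfile",
    "MethylationSummary",
    "TimepointComparison",
    "convert_in_silico",
    "make_amplicon",
    "assign_amplicon",
    "call_cpg_states",
    "summarize_amplicon",
    "compare_timepoints",
    "render_lollipops",
    "write_summary_tsv",
]

M, U, X = "M", "U", "X"
LOLLIPOP = {M: "●", U: "○", X: "×"}


def convert_in_silico(sequence: str) -> str:
    """Fully bisulfite-converted template: non-CpG C -> T, CpG C -> Y.

    The Y wildcard (C or T) makes the template usable for primer matching
    against reads of unknown methylation state.
    """
    out = []
    n = len(sequence)
    for i, b in enumerate(sequence):
        if b == "C":
            out.append("Y" if i + 1 < n and sequence[i + 1] == "G" else "T")
        else:
            out.append(b)
    return "".join(out)


def _wildcard_mismatches(template: str, observed: str) -> int:
    """Hamming distance where template Y matches C or T."""
    if len(template) != len(observed):
        raise ValueError("length mismatch in primer comparison")
    return sum(
        not (t == o or (t == "Y" and o in "CT"))
        for t, o in zip(template, observed)
    )


def _primer_site_ok(template: str, primer_conv: str) -> bool:
    """Converted-space equality, treating Y as compatible with C/T/Y.

    A CpG cut at a primer boundary converts to Y in full-sequence context
    but to T in the isolated primer; both are accepted.
    """
    if len(template) != len(primer_conv):
        return False
    return all(
        t == p or (t == "Y" and p in "CTY") or (p == "Y" and t in "CTY")
        for t, p in zip(template, primer_conv)
    )


@dataclass(frozen=True)
class AmpliconDef:
    """One bisulfite PCR amplicon.

    ``sequence`` is the unconverted top-strand amplicon (primer to primer);
    ``cpg_positions`` index the C of each CG dinucleotide in it.
    ``locus_specific`` distinguishes flank-anchored single-locus amplicons
    from the subfamily-wide 5'UTR amplicon; on a primer-match collision the
    locus-specific assignment outranks the subfamily one.
    """

    amplicon_id: str
    forward_primer: str
    reverse_primer: str  # written 5'->3' on the bottom strand, as ordered
    sequence: str
    cpg_positions: tuple[int, ...]
    locus_specific: bool = True

    def __post_init__(self):
        for p in self.cpg_positions:
            if self.sequence[p : p + 2] != "CG":
                raise ValueError(f"cpg position {p} is not a CG dinucleotide")
        conv = convert_in_silico(self.sequence)
        fwd = convert_in_silico(self.forward_primer)
        rev = convert_in_silico(revcomp(self.reverse_primer))
        if not _primer_site_ok(conv[: len(fwd)], fwd):
            raise ValueError("forward primer does not match the converted amplicon start")
        if not _primer_site_ok(conv[len(conv) - len(rev) :], rev):
            raise ValueError("reverse primer does not match the converted amplicon end")

    @property
    def converted(self) -> str:
        return convert_in_silico(self.sequence)

    def non_cpg_c_positions(self) -> tuple[int, ...]:
        cpg = set(self.cpg_positions)
        return tuple(
            i for i, b in enumerate(self.sequence) if b == "C" and i not in cpg
        )


def make_amplicon(
    amplicon_id: str,
    sequence: str,
    locus_specific: bool = True,
    primer_len: int = 20,
) -> AmpliconDef:
    """Amplicon definition derived from a (synthetic) amplicon sequence.

    CpG positions are scanned from the unconverted sequence; primers are the
    amplicon termini (forward as-is, reverse as the bottom-strand primer).
    """
    cpgs = tuple(i for i in range(len(sequence) - 1) if sequence[i : i + 2] == "CG")
    return AmpliconDef(
        amplicon_id=amplicon_id,
        forward_primer=sequence[:primer_len],
        reverse_primer=revcomp(sequence[-primer_len:]),
        sequence=sequence,
        cpg_positions=cpgs,
        locus_specific=locus_specific,
    )


def assign_amplicon(
    read: str,
    amplicons: list[AmpliconDef],
    max_primer_mismatches: int = 1,
) -> tuple[str | None, str]:
    """Assign a read to the amplicon whose converted primers match its termini.

    Returns ``(amplicon_id, reason)``; unassigned reads return ``(None,
    reason)``.  When both a locus-specific and the subfamily amplicon match,
    the locus-specific one wins (the flanking-genome primer is the more
    specific evidence); ties within the same specificity tier are reported
    as ambiguous, not resolved.
    """
    if not amplicons:
        raise ValueError("no amplicon definitions supplied")
    hits = []
    for amp in amplicons:
        conv = amp.converted
        flen = len(amp.forward_primer)
        rlen = len(amp.reverse_primer)
        if len(read) < max(flen, rlen):
            continue
        start_ok = _wildcard_mismatches(conv[:flen], read[:flen]) <= max_primer_mismatches
        end_ok = _wildcard_mismatches(conv[-rlen:], read[-rlen:]) <= max_primer_mismatches
        if start_ok and end_ok:
            hits.append(amp)
    if not hits:
        return None, "no_primer_match"
    specific = [a for a in hits if a.locus_specific]
    tier = specific if specific else hits
    if len(tier) > 1:
        return None, "ambiguous:" + ",".join(sorted(a.amplicon_id for a in tier))
    return tier[0].amplicon_id, "ok"


@dataclass(frozen=True)
class ReadProfile:
    """Per-CpG state vector for one read, with a conversion-QC rate."""

    read_id: str
    sequence: str
    states: tuple[str, ...]
    conversion_rate: float

    def fraction_methylated(self) -> float | None:
        m = self.states.count(M)
        u = self.states.count(U)
        return m / (m + u) if (m + u) else None


def call_cpg_states(read: str, amplicon: AmpliconDef, read_id: str = "") -> ReadProfile:
    """Call M/U/X at each CpG of an assigned read.

    C -> M (protected, methylated), T -> U (converted, unmethylated), any
    other base -> X (mutated CpG).  The non-CpG conversion rate (fraction of
    non-CpG cytosine positions read as T) is computed for QC.
    """
    if len(read) != len(amplicon.sequence):
        raise ValueError("read length differs from amplicon (indels are out of scope)")
    states = []
    for p in amplicon.cpg_positions:
        b = read[p]
        states.append(M if b == "C" else U if b == "T" else X)
    non_cpg = amplicon.non_cpg_c_positions()
    if non_cpg:
        converted = sum(read[i] == "T" for i in non_cpg)
        rate = converted / len(non_cpg)
    else:
        rate = 1.0
    return ReadProfile(read_id=read_id, sequence=read, states=tuple(states), conversion_rate=rate)


@dataclass(frozen=True)
class MethylationSummary:
    """Per-amplicon, per-time-point methylation summary over sampled reads."""

    amplicon_id: str
    time_point: str
    n_sampled: int
    per_read_fractions: tuple[float, ...]
    mean_pct: float
    sd_pct: float
    site_mean_pct: tuple[float, ...]
    sampled_read_ids: tuple[str, ...]

    def __post_init__(self):
        if self.n_sampled != len(self.per_read_fractions):
            raise ValueError("n_sampled must equal the number of per-read fractions")


def summarize_amplicon(
    profiles: list[ReadProfile],
    amplicon_id: str,
    time_point: str = "",
    cap: int = 50,
    seed: int = 0,
    qc_min_conversion: float = 0.95,
    deduplicate: bool = True,
) -> MethylationSummary:
    """Summarize one amplicon at one time point.

    Reads below the conversion-QC threshold are dropped; identical read
    sequences are deduplicated (first occurrence kept) — clone-redundancy
    removal that can be disabled for reads known to be independent; up to
    ``cap`` unique reads are sampled without replacement with the given seed
    (all of them when fewer are available).  The per-read methylation
    fraction is M/(M+U), ignoring X sites, and the summary is the mean ± sd
    (ddof=1) over the sampled reads, as a percentage.  Per-site mean
    methylation across the sampled reads is retained for site-paired
    statistics.
    """
    passing = [p for p in profiles if p.conversion_rate >= qc_min_conversion]
    if deduplicate:
        seen: set[str] = set()
        unique: list[ReadProfile] = []
        for p in passing:
            if p.sequence not in seen:
                seen.add(p.sequence)
                unique.append(p)
    else:
        unique = list(passing)
    unique = [p for p in unique if p.fraction_methylated() is not None]
    if not unique:
        raise ValueError("no reads left after conversion QC and deduplication")
    # canonical order before seeded sampling: input order must not matter
    unique.sort(key=lambda p: (p.sequence, p.read_id))
    rng = np.random.default_rng(seed)
    if len(unique) > cap:
        idx = sorted(rng.choice(len(unique), size=cap, replace=False))
        sampled = [unique[i] for i in idx]
    else:
        sampled = unique

    fracs = np.array([p.fraction_methylated() for p in sampled])
    n_sites = len(sampled[0].states)
    site_means = []
    for j in range(n_sites):
        vals = [1.0 if p.states[j] == M else 0.0 for p in sampled if p.states[j] != X]
        site_means.append(100.0 * float(np.mean(vals)) if vals else float("nan"))
    sd = float(np.std(fracs, ddof=1)) if len(fracs) > 1 else 0.0
    return MethylationSummary(
        amplicon_id=amplicon_id,
        time_point=time_point,
        n_sampled=len(sampled),
        per_read_fractions=tuple(float(f) for f in fracs),
        mean_pct=100.0 * float(np.mean(fracs)),
        sd_pct=100.0 * sd,
        site_mean_pct=tuple(site_means),
        sampled_read_ids=tuple(p.read_id for p in sampled),
    )


@dataclass(frozen=True)
class TimepointComparison:
    amplicon_id: str
    time_point_a: str
    time_point_b: str
    n_sites: int
    t_statistic: float
    p_raw: float
    bonferroni_factor: int
    p_adjusted: float
    significance: str  # "", "*", "**", "***" at 0.01 / 0.001 / 0.0001


def _stars(p: float) -> str:
    if p < 0.0001:
        return "***"
    if p < 0.001:
        return "**"
    if p < 0.01:
        return "*"
    return ""


def compare_timepoints(
    summaries: list[MethylationSummary],
    pairs: list[tuple[int, int]] | None = None,
) -> list[TimepointComparison]:
    """Paired t-tests between time points of one amplicon, site-paired.

    Each comparison pairs the per-CpG-site mean methylation of two
    summaries (sites with an undefined mean in either are dropped).  The
    Bonferroni factor is the number of comparisons performed in the batch.
    Significance tiers follow the 0.01 / 0.001 / 0.0001 star convention.
    """
    if len(summaries) < 2:
        raise ValueError("need >= 2 time points to compare")
    if pairs is None:
        pairs = [(i, i + 1) for i in range(len(summaries) - 1)]
    m = len(pairs)
    out = []
    for i, j in pairs:
        a, b = summaries[i], summaries[j]
        if len(a.site_mean_pct) != len(b.site_mean_pct):
            raise ValueError("site vectors are not matched between time points")
        av = np.array(a.site_mean_pct)
        bv = np.array(b.site_mean_pct)
        keep = ~(np.isnan(av) | np.isnan(bv))
        av, bv = av[keep], bv[keep]
        if len(av) < 2:
            raise ValueError("fewer than 2 matched CpG sites")
        if np.allclose(av, bv):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(av, bv)
        p_adj = min(1.0, float(p) * m)
        out.append(
            TimepointComparison(
                amplicon_id=a.amplicon_id,
                time_point_a=a.time_point,
                time_point_b=b.time_point,
                n_sites=int(len(av)),
                t_statistic=float(t),
                p_raw=float(p),
                bonferroni_factor=m,
                p_adjusted=p_adj,
                significance=_stars(p_adj),
            )
        )
    return out


def render_lollipops(profiles: list[ReadProfile]) -> str:
    """QUMA-style text rendering: one read per line, M=●, U=○, X=×."""
    return "\n".join(
        "".join(LOLLIPOP[s] for s in p.states) + (f"  {p.read_id}" if p.read_id else "")
        for p in profiles
    )


def write_summary_tsv(summaries: list[MethylationSummary], path) -> None:
    rows = [
        {
            "amplicon": s.amplicon_id,
            "time_point": s.time_point,
            "n_reads": s.n_sampled,
            "mean_pct": round(s.mean_pct, 4),
            "sd_pct": round(s.sd_pct, 4),
        }
        for s in summaries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
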