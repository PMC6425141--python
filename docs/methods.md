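# Methods

This note documents the models, conventions and numerical choices behind
`l1trace`, and what the synthetic-data generator does and does not emulate.

## Coordinates and conventions

All internal coordinates are 0-based half-open; user-facing tables and the
structure report print 1-based positions. The endonuclease nick hexamer is
always written in the 5′-NN/NNNN convention with the slash at the nick and
compared to the TT/AAAA consensus by Hamming distance, regardless of the
insertion's strand (for a minus-strand insertion the hexamer is read from
the reverse complement at the TSD's other boundary, so that strand-flipped
alleles yield the same report).

## TSD detection

`find_tsd` searches for the factorization `filled = prefix·s·insert·s·suffix`
with `empty = prefix·s·suffix`, maximizing `|s|`. The implementation
constrains candidate breakpoints to the interval where the exact common
prefix and suffix of the two alleles overlap, then maximizes the duplicated
suffix at each breakpoint; ties resolve to the leftmost placement. Flank
matches are exact; `max_mismatches` (default 0, since experimentally
characterized TSDs in this system are exact repeats) tolerates divergence
between the two copies of `s` only. If the alleles cannot be factored
around a single insertion at all, that is an error, not an empty result. A
blunt insertion returns the empty TSD.

## Transduction/poly(A) decomposition

`extract_transductions` orients the insert against the L1 body by a shared
15-mer vote (a near-tie on both strands raises an ambiguity error rather
than guessing), strips the terminal poly(A) tract, and locates the L1 span
by Smith–Waterman local alignment (match +2, mismatch −3, gap open −5, gap
extend −2, via `Bio.Align.PairwiseAligner`). The remainder splits as:

* **terminal poly(A)** — the maximal pure A-run at the insert's 3′ end;
* **internal poly(A)** — the maximal pure A-run immediately 3′ of the L1
  span (present only when a 3′ transduction follows);
* **td3** — the sequence between the internal tract and the terminal tract;
* **td5 / untemplated** — the sequence 5′ of the L1 span. Untemplated 5′
  bases can only be separated from the transduction when the donor's
  upstream flank is supplied (they are the 5′-terminal bases matching
  neither the L1 nor that flank); otherwise they are reported inside td5.

Poly(A) tracts are pure A-runs with a minimum length of 4 nt; shorter runs
report length 0. Boundary ambiguity between an A-starting transduction and
the adjacent tract is resolved by assigning maximal length to the tract.
These choices make the decomposition exact on well-posed alleles; they are
also the limits of the method — an insert whose transduction termini mimic
the poly(A) tracts or the L1 boundary bases is genuinely ambiguous, and the
generator's random-spec sampler excludes such cases explicitly (see below).

Full-length status requires the recovered L1 start at or before 1-based
position 10 of the body (5′-transduced full-length elements begin at or
near +1). The subfamily call checks the L1-Ta diagnostic trinucleotide
state (ACA) at the annotated 3′UTR positions of the body frame, read
through the alignment.

## Spliced 5′ transductions

Long 5′ transductions (≥100 nt by default) are dissected by chaining
co-linear matching blocks (difflib matching blocks ≥20 nt) against the
source region as exons. Each inferred exon–exon junction is scored against
a 9-nt splice-donor model (MAG|GTRAGT) and a 15-nt splice-acceptor model
(pyrimidine tract + NYAG|G), both consensus-frequency PWMs normalized to
[0, 1] between the worst- and best-possible windows. Transduction bases 5′
of the first exon match are reported as untemplated. The bundled
transcription-factor matrices (FOX-, RXR- and PU.1-like) used by
`pwm_variant_effect` are consensus-derived caricatures adequate for
directional variant-effect statements only; their magnitudes are not
calibrated against any motif database.

## Call filtering

Calls within the tolerance window (default 100 nt, configurable; chosen for
breakpoint wobble between callers — no published value exists) on one
contig are grouped as a locus across cell lines by single-linkage
clustering before the three criteria are applied. A T0 detection in either
line marks the locus polymorphic for both lines (germ-line origin).
Detections in earlier hiPSC passages count toward a line's detection but
not toward T0 absence, so insertions arising during reprogramming or early
cultivation remain candidates.

## Family reconstruction

Donor tracing strips terminal A's from the 3′ transduction (the poly(A)
boundary is not flank sequence) and requires an exact substring match in
exactly one catalogued 3′ flank; matches in two or more flanks raise an
ambiguity error rather than picking one. Near-matching (one mismatch per
20 nt) sits behind a flag for diverged copies; exact matching is the
default because transduction families are young, near-identical lineages.

`build_family` adds a donor→offspring edge per traceable member, upgrades
the evidence to `td5+td3_match` when the member's 5′ transduction also
matches the donor's immediate upstream flank, takes the component
containing the seed locus as the family, and then attaches members lacking
usable transductions if they carry *every* family-wide shared SNV (the
intersection of the SNV sets of members already in the family) — these
attach to the progenitor with `snv_sharing` evidence. This
attachment-by-signature rule is this package's decision for members whose
membership rests on internal variants alone. The graph is validated
acyclic; the root is the in-degree-0 node with the most descendants.

Allele discrimination retains variants observed in ≥2 independent clones
(`min_support=2`; singleton variants are labelled PCR-induced — the
rationale for sequencing at least four independent PCR products per locus),
groups clones by their genotype over retained positions, and corrects
residual singleton errors inside each group, so the returned allele
consensi are free of polymerase noise. With `min_support=1` every clone
becomes its own allele candidate (the degenerate bound).

## Bisulfite methylation

In-silico conversion maps non-CpG C→T and CpG C→Y; primer matching runs in
this converted space with the Y wildcard, and a locus-specific (flank-
anchored) assignment outranks the subfamily-wide one on collision, because
the flanking-genome primer is the more specific evidence. State calling at
each CpG C position is C→M, T→U, anything else→×; × sites never enter the
numerator or denominator of any percentage. Reads with non-CpG conversion
below 95% are dropped (standard bisulfite QC; no published threshold
exists for this assay). Summaries deduplicate identical read sequences
(clone-redundancy removal, matching common practice of excluding identical
bisulfite clones; it can be disabled for reads known to be independent),
sort reads canonically, and sample up to 50 without replacement with the
given seed, reporting mean ± sd (ddof = 1) of per-read M/(M+U) fractions
as percentages.

**Pairing unit for the t-test.** Reads are not matched across time points,
so the paired t-test pairs *CpG sites* — each site contributes its mean
methylation across the sampled reads at each time point. This is a design
decision of this package; the source analyses do not state their pairing
unit. The Bonferroni factor is the number of comparisons in the batch, and
significance tiers are reported at 0.01/0.001/0.0001.

## Assay normalization

Each replicate's colony count is divided by (EGFP%/100) and expressed as
100 × corrected/reference-corrected-mean; the mean ± sd is then taken over
the normalized replicates, so the reference construct's normalized mean is
exactly 100 and the normalization is scale-invariant in the counts.

## The synthetic generator

The generator is first-class, tested code; every downstream module is
validated against its ground truth (`TruthRecord`, `FamilyFixture`).

* **L1 body.** A surrogate ~6,064-nt sequence is generated from a seeded
  PCG64 stream in an L1.3-style frame: 5′UTR 1–909 with a CpG island,
  ORF1 910–1926, ORF2 1990–5814 with endonuclease (codons 1–239) and
  reverse-transcriptase (codons 498–773) domain sub-spans, 3′UTR
  5815–6064 carrying the Ta-diagnostic ACA and a 3′ polyadenylation
  signal. ORF2 codons 159/400/523 are pinned to Q/W/D so the Q159H, W400*
  and D523H variant fixtures are expressible; the body's last bases are
  forced non-A so the internal poly(A) boundary is well posed. A 660-nt
  `mini` body with the same layout supports fast property-style tests.
* **Planted insertions.** The filled allele is assembled exactly as TPRT
  would leave it (flank · TSD · [untemplated · td5 · L1 · internal pA ·
  td3 · terminal pA] · TSD · flank, reverse-complemented for minus-strand
  events). The local flank is made well-posed: the nick hexamer is
  rewritten to the requested site, the TSD must not recur within 100 nt of
  the breakpoint (re-sampling flank bases otherwise), and the flank bases
  abutting the insert are forced to differ from the insert's terminal
  bases. The random-spec sampler used by property tests additionally bars
  transductions that start/end in A or whose suffixes resemble the body
  just upstream of the element's first base (which would shift the local
  alignment boundary).
* **Families.** Every non-root member's 3′ transduction is a verbatim copy
  of its parent's immediate 3′ flank; members inherit all ancestral
  private SNVs plus their own, so the progenitor's variants become the
  family-wide shared signature. The bundled 14-locus catalog (element
  names, coordinates, TSDs, full-length flags and lineage relations of an
  experimentally characterized human transduction family) parameterizes
  the default fixture; decoy loci are unrelated rooted elements. Spliced
  5′ transductions are modelled by length only in family fixtures.
* **Bisulfite reads.** Top-strand only (each amplicon's primers target one
  strand): each CpG cytosine is retained as C with its site's methylation
  probability, other cytosines convert with the profile's efficiency, and
  CpG-destroying mutations emit a fixed non-C base in all reads. The CpG
  layout of the amplicons is a parameter of the fixture, not a
  reproduction of the real amplicon (whose exact CpG positions are not
  published in machine-readable form).

**What the generator does not emulate** — sequencing error beyond bisulfite
conversion, quality scores, paired-end fragments, coverage biases,
alignment artifacts of repetitive DNA, and 5′-inversion insertion
structures. Passing tests therefore demonstrate correctness of the
analytical logic on structurally faithful inputs, not robustness to raw
sequencing noise.

## Problem sizes and determinism

All tests and the acceptance script run on fixture-scale data chosen as the
smallest sizes at which each property is informative: single ~6.5-kb allele
pairs for the worked example, 34 planted loci (14 family + 20 decoys) for
family reconstruction, a few thousand to 10,000 bisulfite reads for
parameter-recovery checks, and 660-nt mini bodies for randomized round-trip
batteries. Every stochastic step draws from `numpy.random.default_rng`
seeded per call; a fixed seed yields byte-identical generator output and
pipeline files.
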