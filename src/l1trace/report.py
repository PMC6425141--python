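"""Assay normalization arithmetic and pipeline orchestration.

The engineered retrotransposition reporter assay counts antibiotic-resistant
colonies after transfection of an L1 construct; counts are corrected for
transfection efficiency (percentage of EGFP-positive cells in a parallel
cotransfection) and expressed relative to a reference construct.  Each
replicate is normalized individually and the mean ± sd taken over the
normalized replicates, so the reference construct's normalized mean is
exactly 100 and the spread reflects replicate-level variability.

`run_pipeline` wires the synthetic generator through the analysis modules
into one reproducible demo run directory with a manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

log = logging.getLogger("l1trace")

__all__ = ["RawAssay", "AssayResult", "normalize_retro_assay", "run_pipeline", "PipelineConfigError"]


@dataclass(frozen=True)
class RawAssay:
    """Colony counts per technical replicate plus transfection efficiency."""

    construct: str
    colonies: tuple[float, ...]
    egfp_pct: float

    def __post_init__(self):
        if any(c < 0 for c in self.colonies):
            raise ValueError("colony counts must be >= 0")
        if not 0 < self.egfp_pct <= 100:
            raise ValueError("EGFP percentage must lie in (0, 100]")


@dataclass(frozen=True)
class AssayResult:
    construct: str
    colonies: tuple[float, ...]
    egfp_pct: float
    normalized_replicates: tuple[float, ...]
    normalized_mean: float
    normalized_sd: float


def normalize_retro_assay(results: list[RawAssay], reference: str) -> list[AssayResult]:
    """Normalize colony counts to a reference construct.

    Per replicate: corrected = colonies / (EGFP% / 100); normalized =
    100 x corrected / (reference's corrected mean).  The reference must be
    present with a nonzero corrected mean.  Scale-invariant in the counts.
    """
    by_name = {r.construct: r for r in results}
    if reference not in by_name:
        raise ValueError(f"reference construct {reference!r} not among results")
    ref = by_name[reference]
    ref_corrected = [c / (ref.egfp_pct / 100.0) for c in ref.colonies]
    ref_mean = float(np.mean(ref_corrected))
    if ref_mean == 0:
        raise ValueError("reference construct has zero corrected colony mean")
    out = []
    for r in results:
        corrected = [c / (r.egfp_pct / 100.0) for c in r.colonies]
        normalized = tuple(100.0 * c / ref_mean for c in corrected)
        sd = float(np.std(normalized, ddof=1)) if len(normalized) > 1 else 0.0
        out.append(
            AssayResult(
                construct=r.construct,
                colonies=r.colonies,
                egfp_pct=r.egfp_pct,
                normalized_replicates=normalized,
                normalized_mean=float(np.mean(normalized)),
                normalized_sd=sd,
            )
        )
    return out


class PipelineConfigError(ValueError):
    """A required configuration key or input path is missing."""


DEFAULT_CONFIG = {
    "seed": 7,
    "out_dir": "l1trace_run",
    "n_decoys": 20,
    "bisulfite_reads": 200,
    "methylation_by_timepoint": {
        "T0": 0.666, "T1": 0.311, "T2": 0.35, "T3": 0.45,
        "T4": 0.55, "T5": 0.40, "T6": 0.61,
    },
    "read_cap": 50,
}


def run_pipeline(config: dict | str | Path) -> dict:
    """Run the full synthetic demo pipeline and write a report bundle.

    Executes generation -> insertion characterization -> family
    reconstruction -> bisulfite methylation summarization, writing TSV/JSON
    outputs plus a manifest under ``out_dir``.  Deterministic for a fixed
    config.  Returns the manifest dictionary.
    """
    from . import family as fam
    from . import methyl, sim, tprt

    if isinstance(config, (str, Path)):
        path = Path(config)
        if not path.exists():
            raise PipelineConfigError(f"config file not found: {path}")
        config = json.loads(path.read_text())
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config)
    for key in ("seed", "out_dir"):
        if cfg.get(key) is None:
            raise PipelineConfigError(f"missing required config key: {key}")
    seed = int(cfg["seed"])
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    log.info("run_pipeline start: seed=%d out=%s", seed, out)

    manifest: dict = {"seed": seed, "outputs": {}}

    # 1. de novo locus reconstruction + characterization
    l1 = sim.make_l1_body()
    genome, truth, donor_flank = sim.de_novo_fixture(seed, l1=l1)
    structure = tprt.characterize_insertion(
        truth.empty_allele, truth.filled_allele, l1, donor_flank=donor_flank
    )
    (out / "de_novo_structure.json").write_text(
        json.dumps(structure.to_dict(), indent=2) + "\n"
    )
    manifest["outputs"]["de_novo_structure"] = "de_novo_structure.json"

    # 2. family reconstruction on the catalog-mirrored fixture
    specs = sim.family_specs_from_catalog(seed + 3, n_decoys=int(cfg["n_decoys"]), l1=l1)
    fixture = sim.make_family_fixture(specs, genome, l1, seed=seed + 4)
    members = [
        fam.FamilyMember(
            locus=name,
            contig="fam",
            position=rec.spec.position + 1,
            tsd=rec.tsd,
            snvs=frozenset(
                fam.SNV(position=p + 1, ref=l1.sequence[p], alt=alt)
                for p, alt in fixture.snv_truth[name]
            ),
            td5=fixture.td5_tags[name] or None,
            td3=fixture.td3_tags[name] or None,
        )
        for name, rec in fixture.records.items()
    ]
    catalog = [
        fam.LocusRecord(
            locus=name, contig="fam", position=fixture.records[name].spec.position + 1,
            flank5=fixture.flank5[name], flank3=fixture.flank3[name],
        )
        for name in fixture.records
    ]
    graph = fam.build_family(members, catalog, seed_locus="DeNovo_Chr1")
    graph.to_edgelist_tsv(out / "family_edges.tsv")
    (out / "family.dot").write_text(graph.to_dot() + "\n")
    manifest["outputs"]["family_edges"] = "family_edges.tsv"
    manifest["family_size"] = len(graph.members)
    manifest["family_root"] = graph.root

    # 3. bisulfite methylation time course on the donor amplicon
    amp_seq = l1.sequence[: l1.cpg_positions[-1] + 30]
    amp = methyl.make_amplicon("Donor_L1_5UTR", amp_seq, locus_specific=True)
    summaries = []
    for i, (tp, p_meth) in enumerate(sorted(cfg["methylation_by_timepoint"].items())):
        profile = sim.MethylationProfile(
            amplicon_id=amp.amplicon_id,
            cpg_probabilities=tuple([float(p_meth)] * len(amp.cpg_positions)),
        )
        reads = sim.simulate_bisulfite_reads(
            amp.sequence, amp.cpg_positions, profile,
            n_reads=int(cfg["bisulfite_reads"]), seed=seed + 10 + i,
        )
        profiles = [
            methyl.call_cpg_states(r, amp, read_id=f"{tp}_{k}")
            for k, r in enumerate(reads)
        ]
        summaries.append(
            methyl.summarize_amplicon(
                profiles, amp.amplicon_id, time_point=tp,
                cap=int(cfg["read_cap"]), seed=seed + 20 + i,
            )
        )
    methyl.write_summary_tsv(summaries, out / "methylation_summary.tsv")
    comparisons = methyl.compare_timepoints(summaries)
    with open(out / "methylation_tests.tsv", "w") as fh:
        fh.write("a\tb\tt\tp_raw\tp_adj\tstars\n")
        for c in comparisons:
            fh.write(
                f"{c.time_point_a}\t{c.time_point_b}\t{c.t_statistic:.4f}\t"
                f"{c.p_raw:.3e}\t{c.p_adjusted:.3e}\t{c.significance}\n"
            )
    manifest["outputs"]["methylation_summary"] = "methylation_summary.tsv"
    manifest["outputs"]["methylation_tests"] = "methylation_tests.tsv"
    manifest["methylation_mean_pct"] = {s.time_point: round(s.mean_pct, 2) for s in summaries}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("run_pipeline done: %s", out / "manifest.json")
    return manifest
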