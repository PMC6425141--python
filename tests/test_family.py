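"""Donor tracing, variant partitioning, allele discrimination, family graphs."""

import numpy as np
import pytest

from l1trace import family as F
from l1trace import sim
from l1trace.pwm import TF_PWMS


def _members_and_catalog(fixture, l1):
    members = [
        F.FamilyMember(
            locus=name,
            contig="fam",
            position=rec.spec.position + 1,
            tsd=rec.tsd,
            snvs=frozenset(
                F.SNV(position=p + 1, ref=l1.sequence[p], alt=alt)
                for p, alt in fixture.snv_truth[name]
            ),
            td5=fixture.td5_tags[name] or None,
            td3=fixture.td3_tags[name] or None,
        )
        for name, rec in fixture.records.items()
    ]
    catalog = [
        F.LocusRecord(
            locus=name, contig="fam", position=fixture.records[name].spec.position + 1,
            flank5=fixture.flank5[name], flank3=fixture.flank3[name],
        )
        for name in fixture.records
    ]
    return members, catalog


@pytest.fixture(scope="module")
def table_fixture(genome, full_l1):
    specs = sim.family_specs_from_catalog(77, n_decoys=20, l1=full_l1)
    return sim.make_family_fixture(specs, genome, full_l1, seed=78)


class TestTraceDonor:
    def test_fixture_transductions_trace_to_planted_parent(self, table_fixture):
        parents = {child: parent for parent, child in table_fixture.edges}
        catalog = [(k, fl) for k, fl in table_fixture.flank3.items()]
        for child, parent in parents.items():
            others = [(k, fl) for k, fl in catalog if k != child]
            assert F.trace_donor(table_fixture.td3_tags[child], others) == parent

    def test_short_transduction_fails_precondition(self):
        with pytest.raises(ValueError, match="min_len"):
            F.trace_donor("ACG", [("x", "ACGACGACG")])

    def test_polya_is_stripped_before_matching(self):
        flank = "GGTTCCAATTGGCCAATT"
        assert F.trace_donor("GGTTCCAATTGG" + "AAAAA", [("x", flank)]) == "x"

    def test_no_match_returns_none(self):
        assert F.trace_donor("GGTTCCAATTGGCC", [("x", "ACGT" * 10)]) is None

    def test_ambiguity_is_reported(self):
        td3 = "GGTTCCAATTGGCC"
        cat = [("x", "AA" + td3), ("y", td3 + "CC")]
        with pytest.raises(F.AmbiguousDonorError):
            F.trace_donor(td3, cat)

    def test_near_match_behind_flag(self):
        td3 = "GGTTCCAATTGGCCAATTGGCC"  # 22 nt -> 1 mismatch allowed
        flank = "TT" + td3[:10] + "A" + td3[11:] + "GG"
        assert F.trace_donor(td3, [("x", flank)]) is None
        assert F.trace_donor(td3, [("x", flank)], max_mismatch_per_20nt=1) == "x"


class TestCallVariants:
    def test_identical_member_has_no_variants(self, full_l1):
        assert F.call_variants(full_l1.sequence, full_l1) == frozenset()

    def test_orf2_missense_annotations(self, full_l1):
        start = full_l1.orf2[0]
        seq = list(full_l1.sequence)
        # ORF2 codon 159 CAA->CAC (Q159H) and codon 523 GAT->CAT (D523H)
        seq[start + 158 * 3 + 2] = "C"
        seq[start + 522 * 3] = "C"
        snvs = F.call_variants("".join(seq), full_l1)
        labels = {s.aa_change for s in snvs}
        assert labels == {"Q159H", "D523H"}
        assert all(s.orf == "ORF2" and not s.nonsense for s in snvs)

    def test_nonsense_in_orf2_flagged(self, full_l1):
        start = full_l1.orf2[0]
        seq = list(full_l1.sequence)
        seq[start + 399 * 3 + 2] = "A"  # codon 400 TGG -> TGA
        snvs = F.call_variants("".join(seq), full_l1)
        (snv,) = snvs
        assert snv.nonsense
        assert snv.aa_change == "W400*"
        # the stop lands before the RT domain start (codon 498)
        assert (snv.position - 1 - start) // 3 + 1 < 498

    def test_truncated_member_positions_in_body_frame(self, full_l1):
        trunc = 2000
        seq = list(full_l1.sequence[trunc:])
        seq[100] = "A" if seq[100] != "A" else "G"
        snvs = F.call_variants("".join(seq), full_l1)
        assert {s.position for s in snvs} == {trunc + 100 + 1}


class TestPartitionVariants:
    def _member(self, name, keys):
        return F.FamilyMember(
            locus=name, contig="c", position=1,
            snvs=frozenset(F.SNV(position=p, ref=r, alt=a) for p, r, a in keys),
        )

    def test_three_classes(self):
        shared = (100, "A", "G")
        some = (200, "C", "T")
        private = (300, "G", "A")
        members = [
            self._member("a", [shared, some]),
            self._member("b", [shared, some, private]),
            self._member("c", [shared]),
        ]
        part = F.partition_variants(members)
        assert part[shared] == F.SHARED_ALL
        assert part[some] == F.SHARED_SOME
        assert part[private] == F.PRIVATE

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_members, n_snvs = 6, 12
        incidence = rng.random((n_members, n_snvs)) < 0.4
        keys = [(i * 10 + 1, "A", "G") for i in range(n_snvs)]
        members = [
            self._member(f"m{i}", [k for j, k in enumerate(keys) if incidence[i, j]])
            for i in range(n_members)
        ]
        part = F.partition_variants(members)
        for j, key in enumerate(keys):
            count = int(incidence[:, j].sum())
            if count == 0:
                assert key not in part
            elif count == n_members:
                assert part[key] == F.SHARED_ALL
            elif count == 1:
                assert part[key] == F.PRIVATE
            else:
                assert part[key] == F.SHARED_SOME

    def test_requires_two_members(self):
        with pytest.raises(ValueError):
            F.partition_variants([self._member("a", [])])


class TestDistinguishAlleles:
    def test_two_alleles_four_linked_snvs(self, rng):
        base = sim.random_dna(rng, 300)
        positions = [40, 120, 200, 280]
        allele2 = list(base)
        for p in positions:
            allele2[p] = "A" if base[p] != "A" else "C"
        clones = [base, base, "".join(allele2), "".join(allele2)]
        result = F.distinguish_alleles(clones)
        assert len(result.alleles) == 2
        assert len(result.discriminating_snvs) == 4
        assert sorted(p for p, _ in result.discriminating_snvs) == positions
        assert set(result.alleles) == {base, "".join(allele2)}

    def test_identical_clones_single_allele(self):
        clones = ["ACGTACGT"] * 4
        result = F.distinguish_alleles(clones)
        assert result.alleles == ("ACGTACGT",)
        assert result.discriminating_snvs == ()

    def test_pcr_errors_filtered_and_consensus_recovered(self, rng):
        base = sim.random_dna(rng, 800)
        positions = [100, 300, 500, 700]
        allele2 = list(base)
        for p in positions:
            allele2[p] = "A" if base[p] != "A" else "C"
        allele2 = "".join(allele2)
        planted = [base, base, base, allele2, allele2, allele2]
        clones = []
        n_errors = 0
        for k, seq in enumerate(planted):
            s = list(seq)
            # Poisson(rate 1e-4/nt) PCR errors, seeded
            for pos in np.flatnonzero(rng.poisson(1e-4 * 3, size=len(s))):
                s[pos] = {"A": "G", "C": "T", "G": "A", "T": "C"}[s[pos]]
                n_errors += 1
            clones.append("".join(s))
        assert n_errors > 0  # the fixture actually plants artifacts
        result = F.distinguish_alleles(clones)
        assert set(result.alleles) == {base, allele2}
        assert len(result.discriminating_snvs) == 4
        assert len(result.pcr_artifacts) == n_errors

    def test_min_support_one_degenerate_bound(self, rng):
        base = sim.random_dna(rng, 100)
        clones = []
        for k in range(4):
            s = list(base)
            s[10 + k] = "A" if s[10 + k] != "A" else "C"
            clones.append("".join(s))
        result = F.distinguish_alleles(clones, min_support=1)
        assert len(result.alleles) == 4

    def test_requires_two_clones(self):
        with pytest.raises(ValueError):
            F.distinguish_alleles(["ACGT"])


class TestBuildFamily:
    def test_catalog_fixture_recovers_14_members(self, table_fixture, full_l1):
        members, catalog = _members_and_catalog(table_fixture, full_l1)
        graph = F.build_family(members, catalog, seed_locus="DeNovo_Chr1")
        assert len(graph.members) == 14
        assert not any(m.startswith("decoy") for m in graph.members)
        assert graph.root == "LineageProgenitor_Chr11"

    def test_td5_td3_edges_match_truth(self, table_fixture, full_l1):
        members, catalog = _members_and_catalog(table_fixture, full_l1)
        graph = F.build_family(members, catalog, seed_locus="DeNovo_Chr1")
        dual = {(u, v) for u, v, ev in graph.edges() if ev == F.TD53_MATCH}
        assert dual == {
            ("Donor_Chr3", "DeNovo_Chr1"),
            ("LineageProgenitor_Chr11", "Ref_Chr1_p31.1_a"),
            ("Ref_Chr7_q21.3", "Non-ref_ChrX_p11.4"),
        }

    def test_single_member_graph(self):
        member = F.FamilyMember(locus="solo", contig="c", position=1)
        graph = F.build_family([member], [])
        assert graph.members == ("solo",)
        assert graph.root == "solo"
        assert graph.edges() == ()

    @pytest.mark.parametrize("seed", range(5))
    def test_random_topology_edge_recovery(self, genome, mini_l1, seed):
        rng = np.random.default_rng(800 + seed)
        n = 8
        specs = [sim.FamilyMemberSpec(locus="m0")]
        for i in range(1, n):
            parent = f"m{int(rng.integers(0, i))}"
            specs.append(
                sim.FamilyMemberSpec(locus=f"m{i}", parent=parent,
                                     td3_length=int(rng.integers(25, 50)))
            )
        fixture = sim.make_family_fixture(specs, genome, mini_l1, seed=900 + seed)
        members, catalog = _members_and_catalog(fixture, mini_l1)
        graph = F.build_family(members, catalog, seed_locus="m0")
        assert {(u, v) for u, v, _ in graph.edges()} == set(fixture.edges)

    def test_order_invariance(self, table_fixture, full_l1):
        members, catalog = _members_and_catalog(table_fixture, full_l1)
        g1 = F.build_family(members, catalog, seed_locus="DeNovo_Chr1")
        g2 = F.build_family(members[::-1], catalog[::-1], seed_locus="DeNovo_Chr1")
        assert g1.members == g2.members
        assert g1.edges() == g2.edges()

    def test_snv_signature_attaches_transductionless_member(self, table_fixture, full_l1):
        members, catalog = _members_and_catalog(table_fixture, full_l1)
        # strip the transduction evidence from one non-hub member
        members = [
            m if m.locus != "Non-ref_Chr4_q12"
            else F.FamilyMember(
                locus=m.locus, contig=m.contig, position=m.position,
                tsd=m.tsd, snvs=m.snvs, td5=None, td3=None,
            )
            for m in members
        ]
        graph = F.build_family(members, catalog, seed_locus="DeNovo_Chr1")
        assert "Non-ref_Chr4_q12" in graph.members
        evidence = {
            (u, v): ev for u, v, ev in graph.edges()
        }
        assert evidence[("LineageProgenitor_Chr11", "Non-ref_Chr4_q12")] == F.SNV_SHARING

    def test_dot_export_names_root(self, table_fixture, full_l1):
        members, catalog = _members_and_catalog(table_fixture, full_l1)
        graph = F.build_family(members, catalog, seed_locus="DeNovo_Chr1")
        dot = graph.to_dot()
        assert '"LineageProgenitor_Chr11" [shape=doubleoctagon]' in dot
        assert dot.count("->") == len(graph.edges())


class TestPWMVariantEffect:
    def test_variant_far_from_scoring_windows_zero_delta(self):
        seq = "TGTTTAC" + "T" * 40  # a perfect FOX-like site plus inert tail
        deltas = F.pwm_variant_effect(seq, (30, "C"))
        assert deltas["FOX-like"] == pytest.approx(0.0)

    def test_consensus_conversion_equals_hand_arithmetic(self):
        pwm = TF_PWMS["FOX-like"]
        seq = "G" * 10 + "TGTTAAC" + "G" * 10  # one base off consensus TGTTTAC
        deltas = F.pwm_variant_effect(seq, (14, "T"), pwms={"FOX-like": pwm})
        before = pwm.best_score(seq)
        window_before = pwm.score("TGTTAAC")
        window_after = pwm.score("TGTTTAC")
        assert window_after > window_before
        assert deltas["FOX-like"] == pytest.approx(window_after - before)

    def test_t_to_c_raises_rxr_like_score(self):
        # degenerate third position: T disfavored, C tolerated
        seq = "C" * 12 + "AGTTCA" + "C" * 12
        deltas = F.pwm_variant_effect(seq, (14, "C"))
        assert deltas["RXR-like"] > 0
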