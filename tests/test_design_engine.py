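import pytest
from hypothesis import given, settings, strategies as st

from chase.design_engine import (
    DesignInfeasible,
    PamSite,
    Substitution,
    apply_substitutions,
    assemble_cassette,
    build_donor,
    candidate_pams_for_codon,
    eliminate_recutting,
    enumerate_pams,
    guide_for_pam,
    is_cleavable,
    matches_iupac,
    pam_codon_distance,
    plan_codon_edit,
)
from chase.seq_core import GeneTarget, reverse_complement, translate

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def brute_force_pams(context, pattern):
    """Independent both-strand scan oracle."""
    hits = []
    for p in range(len(context) - 2):
        trip = context[p : p + 3]
        if all(b in IUPAC_SETS[q] for b, q in zip(trip, pattern)):
            hits.append((p, "+"))
        rc = reverse_complement(trip)
        if all(b in IUPAC_SETS[q] for b, q in zip(rc, pattern)):
            hits.append((p, "-"))
    return sorted(hits)


class TestEnumeratePams:
    def test_ngg_single_site(self):
        sites = enumerate_pams("AAAAGGAAAA", "NGG")
        assert [(s.offset, s.strand, s.pam_seq) for s in sites] == [(3, "+", "AGG")]

    def test_ngn_two_sites(self):
        sites = enumerate_pams("AAAAGGAAAA", "NGN")
        assert [(s.offset, s.strand) for s in sites] == [(3, "+"), (4, "+")]

    def test_empty_window(self):
        assert enumerate_pams("AAAAGGAAAA", "NGG", (2, 2)) == []

    def test_window_out_of_bounds(self):
        with pytest.raises(ValueError):
            enumerate_pams("ACGT", "NGG", (0, 10))

    def test_overlapping_sites_found(self):
        # consecutive Gs produce overlapping NGN matches
        sites = enumerate_pams("AGGGA", "NGN")
        plus = [(s.offset) for s in sites if s.strand == "+"]
        assert plus == [0, 1, 2]

    @given(st.text(alphabet="ACGT", min_size=3, max_size=80),
           st.sampled_from(["NGG", "NGN", "NRN", "NGA"]))
    @settings(max_examples=60)
    def test_matches_brute_force(self, context, pattern):
        got = [(s.offset, s.strand) for s in enumerate_pams(context, pattern)]
        assert got == brute_force_pams(context, pattern)

    def test_minus_strand_pam_seq_is_rc(self):
        context = "CCTAAAAAAAAAAAAAAAAAAAAAAAAA"
        sites = [s for s in enumerate_pams(context, "NGG") if s.strand == "-"]
        assert sites and sites[0].pam_seq == reverse_complement(context[0:3])


class TestPamCodonDistance:
    def make(self, offset):
        return PamSite(offset=offset, strand="+", pam_seq="AGG", pattern="NGG")

    def test_overlap_is_zero(self, toy_target):
        site = toy_target.codon_site(5)
        assert pam_codon_distance(self.make(site.offset + 1), site) == 0

    def test_abutting_is_zero(self, toy_target):
        site = toy_target.codon_site(5)
        assert pam_codon_distance(self.make(site.offset + 3), site) == 0
        assert pam_codon_distance(self.make(site.offset - 3), site) == 0

    def test_gap_counts_bases_between(self, toy_target):
        site = toy_target.codon_site(5)
        assert pam_codon_distance(self.make(site.offset + 3 + 7), site) == 7

    def test_boundary_21_excluded(self, toy_target):
        site = toy_target.codon_site(8)
        pams = candidate_pams_for_codon(toy_target, site, "NGN", max_distance=20)
        for pam in pams:
            assert pam_codon_distance(pam, site) <= 20

    def test_counts_match_exhaustive_filter(self, toy_target):
        site = toy_target.codon_site(10)
        got = {(p.offset, p.strand) for p in candidate_pams_for_codon(toy_target, site, "NGN")}
        expected = set()
        for offset, strand in brute_force_pams(toy_target.context, "NGN"):
            pam = PamSite(offset, strand, "NNN", "NGN")
            if pam_codon_distance(pam, site) > 20:
                continue
            if strand == "+" and offset < 20:
                continue
            if strand == "-" and offset + 23 > len(toy_target.context):
                continue
            expected.add((offset, strand))
        assert got == expected


class TestPlanCodonEdit:
    def test_three_base_swap(self):
        from chase.seq_core import CodonSite
        s = CodonSite(codon_index=2, offset=30, wt_codon="ACT", wt_aa="T")
        subs = plan_codon_edit(s, "TTC")
        assert len(subs) == 3
        assert [x.alt for x in subs] == ["T", "T", "C"]

    def test_single_base_swap(self):
        from chase.seq_core import CodonSite
        s = CodonSite(codon_index=2, offset=30, wt_codon="ACT", wt_aa="T")
        subs = plan_codon_edit(s, "ACC")
        assert len(subs) == 1 and subs[0].offset == 32

    def test_identity_rejected(self):
        from chase.seq_core import CodonSite
        s = CodonSite(codon_index=2, offset=30, wt_codon="ACT", wt_aa="T")
        with pytest.raises(ValueError):
            plan_codon_edit(s, "ACT")


class TestSubstitution:
    def test_noop_rejected(self):
        with pytest.raises(ValueError):
            Substitution(offset=1, ref="A", alt="A")

    def test_apply_checks_ref(self):
        with pytest.raises(ValueError):
            apply_substitutions("AAAA", [Substitution(0, "C", "T")])


def _first_slot(target, codon_index, new_codon, pattern, table):
    site = target.codon_site(codon_index)
    edit = plan_codon_edit(site, new_codon)
    for pam in candidate_pams_for_codon(target, site, pattern):
        guide = guide_for_pam(target.context, pam)
        yield site, pam, guide, edit


class TestEliminateRecutting:
    def test_edit_destroying_pam_needs_nothing(self, toy_target, codon_table):
        # find a slot where the codon edit overlaps the PAM's G
        for site, pam, guide, edit in _first_slot(
            toy_target, 5, codon_table.design_codon("*", toy_target.codon_site(5).wt_codon),
            "NGN", codon_table,
        ):
            edited = apply_substitutions(toy_target.context, edit)
            if not is_cleavable(edited, pam, guide, "NGN"):
                kills = eliminate_recutting(
                    toy_target, pam, guide, edit, codon_table, "NGN",
                    forbidden_codons=frozenset({site.codon_index}),
                )
                assert kills == []
                return
        pytest.skip("no self-destroying slot in this toy gene")

    def test_kills_make_locus_uncleavable(self, toy_target, codon_table):
        checked = 0
        for idx in range(2, toy_target.n_codons - 1):
            site = toy_target.codon_site(idx)
            new_codon = codon_table.design_codon("*", site.wt_codon)
            for site, pam, guide, edit in _first_slot(toy_target, idx, new_codon, "NGN", codon_table):
                try:
                    kills = eliminate_recutting(
                        toy_target, pam, guide, edit, codon_table, "NGN",
                        forbidden_codons=frozenset({idx}),
                    )
                except DesignInfeasible:
                    continue
                edited = apply_substitutions(toy_target.context, edit + kills)
                assert not is_cleavable(edited, pam, guide, "NGN")
                checked += 1
        assert checked > 20

    def test_kills_are_synonymous(self, toy_target, codon_table):
        wt_protein = translate(toy_target.orf)
        for idx in (3, 7, 12, 20):
            site = toy_target.codon_site(idx)
            new_codon = codon_table.design_codon("A", site.wt_codon)
            if new_codon is None:
                continue
            for site, pam, guide, edit in _first_slot(toy_target, idx, new_codon, "NGN", codon_table):
                try:
                    kills = eliminate_recutting(
                        toy_target, pam, guide, edit, codon_table, "NGN",
                        forbidden_codons=frozenset({idx}),
                    )
                except DesignInfeasible:
                    continue
                edited = apply_substitutions(toy_target.context, edit + kills)
                protein = translate(edited[toy_target.orf_start : toy_target.orf_end])
                diffs = [i for i, (a, b) in enumerate(zip(wt_protein, protein)) if a != b]
                assert diffs in ([], [idx - 1])

    def test_met_trp_pam_infeasible(self, codon_table):
        # PAM inside ATG TGG with no synonymous option anywhere in reach:
        # ORF = ATG  ATG TGG ATG TGG ... Met/Trp only around the PAM.
        orf = "ATG" + "ATGTGG" * 8 + "TAA"
        context = "C" * 80 + orf + "C" * 80
        target = GeneTarget("mw", context, 80, len(orf))
        site = target.codon_site(4)  # an ATG codon
        edit = plan_codon_edit(site, "AAA")  # Met -> Lys at codon 4
        hit = False
        for pam in candidate_pams_for_codon(target, site, "NGG"):
            guide = guide_for_pam(target.context, pam)
            edited = apply_substitutions(target.context, edit)
            if not is_cleavable(edited, pam, guide, "NGG"):
                continue  # edit already kills; irrelevant here
            p0, p1 = pam.interval
            if not (target.orf_start <= p0 and p1 <= target.orf_end):
                continue
            with pytest.raises(DesignInfeasible):
                eliminate_recutting(
                    target, pam, guide, edit, codon_table, "NGG",
                    forbidden_codons=frozenset({4}),
                )
            hit = True
        assert hit


class TestBuildDonor:
    def test_single_substitution_length_101(self, toy_target):
        sub = Substitution(toy_target.orf_start + 10, toy_target.context[toy_target.orf_start + 10],
                           "G" if toy_target.context[toy_target.orf_start + 10] != "G" else "C")
        donor = build_donor(toy_target, [sub])
        assert len(donor.emitted_seq) == 101

    def test_span_arithmetic(self, toy_target):
        # 3-base codon edit plus a kill 6 bases downstream: 50 + 9 + 50
        base = toy_target.orf_start + 12
        subs = []
        for off in (base, base + 1, base + 2, base + 8):
            ref = toy_target.context[off]
            subs.append(Substitution(off, ref, "G" if ref != "G" else "C"))
        donor = build_donor(toy_target, subs)
        assert len(donor.emitted_seq) == 50 + 9 + 50 == 109

    def test_minus_strand_emitted_is_rc(self, toy_target):
        off = toy_target.orf_start + 9
        ref = toy_target.context[off]
        sub = Substitution(off, ref, "G" if ref != "G" else "C")
        plus = build_donor(toy_target, [sub], strand="+")
        minus = build_donor(toy_target, [sub], strand="-")
        assert minus.emitted_seq == reverse_complement(plus.emitted_seq)

    def test_reverting_substitutions_gives_wild_type(self, toy_target):
        off = toy_target.orf_start + 9
        ref = toy_target.context[off]
        donor = build_donor(toy_target, [Substitution(off, ref, "G" if ref != "G" else "C")], strand="-")
        assert donor.wt_emitted_seq == reverse_complement(
            toy_target.context[off - 50 : off + 51]
        )

    def test_arms_are_wild_type(self, toy_target):
        off = toy_target.orf_start + 9
        ref = toy_target.context[off]
        donor = build_donor(toy_target, [Substitution(off, ref, "G" if ref != "G" else "C")])
        assert donor.emitted_seq[:50] == donor.left_arm
        assert donor.emitted_seq[-50:] == donor.right_arm
        assert donor.left_arm == toy_target.context[off - 50 : off]

    def test_insufficient_flank(self):
        context = "ATGAAATAA" + "A" * 120
        target = GeneTarget("x", context, 0, 9)
        with pytest.raises(ValueError):
            build_donor(target, [Substitution(3, "A", "T")])

    def test_deletion_donor_length_100(self, toy_target):
        d0 = toy_target.orf_start + 12
        donor = build_donor(toy_target, [], deletion=(d0, d0 + 8))
        assert len(donor.emitted_seq) == 100


class TestAssembleCassette:
    def test_empty_adapters(self, toy_target):
        off = toy_target.orf_start + 9
        ref = toy_target.context[off]
        donor = build_donor(toy_target, [Substitution(off, ref, "G" if ref != "G" else "C")])
        pams = candidate_pams_for_codon(toy_target, toy_target.codon_site(4), "NGN")
        guide = guide_for_pam(toy_target.context, pams[0])
        oligo = assemble_cassette(donor, guide)
        assert len(oligo) == len(donor.emitted_seq) + 20
        assert oligo.endswith(guide.protospacer)

    def test_adapters_flank(self, toy_target):
        off = toy_target.orf_start + 9
        ref = toy_target.context[off]
        donor = build_donor(toy_target, [Substitution(off, ref, "G" if ref != "G" else "C")])
        pams = candidate_pams_for_codon(toy_target, toy_target.codon_site(4), "NGN")
        guide = guide_for_pam(toy_target.context, pams[0])
        oligo = assemble_cassette(donor, guide, ("AATT", "GGCC"))
        assert oligo.startswith("AATT") and oligo.endswith("GGCC")


class TestGuide:
    def test_seed_fields(self, toy_target):
        pams = candidate_pams_for_codon(toy_target, toy_target.codon_site(6), "NGN")
        for pam in pams:
            g = guide_for_pam(toy_target.context, pam)
            assert len(g.protospacer) == 20
            assert g.seed4 == g.protospacer[-4:]
            assert g.seed12 == g.protospacer[-12:]

    def test_protospacer_plus_pam_contiguous(self, toy_target):
        for pam in candidate_pams_for_codon(toy_target, toy_target.codon_site(6), "NGN"):
            g = guide_for_pam(toy_target.context, pam)
            if pam.strand == "+":
                window = toy_target.context[pam.offset - 20 : pam.offset + 3]
                assert window == g.protospacer + toy_target.context[pam.offset : pam.offset + 3]
            else:
                window = toy_target.context[pam.offset : pam.offset + 23]
                assert reverse_complement(window) == g.protospacer + pam.pam_seq


def test_matches_iupac_semantics():
    assert matches_iupac("AGG", "NGG")
    assert matches_iupac("TGA", "NGN")
    assert not matches_iupac("ATG", "NGG")
    assert matches_iupac("AAT", "NRN")  # R = purine (A or G)
    assert matches_iupac("AGT", "NRN")
    assert not matches_iupac("ACT", "NRN")
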