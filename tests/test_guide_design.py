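"""Guide enumeration, the brute-force oracle, edit simulation, motifs."""

import pytest

from besplice.annotation import Contig
from besplice.errors import ConfigError, DomainError, EmptyInputError
from besplice.fixtures import FixtureConfig, make_fixture_gene
from besplice.guide_design import (
    ABE710,
    BE4,
    EditorSpec,
    brute_force_scan,
    design_guides,
    enumerate_bystanders,
    pentanucleotide_motif,
    simulate_edit,
)


class TestEditorSpec:
    def test_invalid_edited_base_rejected(self):
        with pytest.raises(ConfigError):
            EditorSpec("bad", "G")

    def test_non_iupac_pam_rejected(self):
        with pytest.raises(ConfigError):
            EditorSpec("bad", "C", pam="NGQ")

    def test_window_outside_protospacer_rejected(self):
        with pytest.raises(ConfigError):
            EditorSpec("bad", "C", window=(0, 8))


class TestFix1WorkedExample:
    """The hand-checkable 60-nt gene: one CBE and one ABE guide, no more."""

    def test_cbe_designs_exactly_the_known_guide(self, fix1):
        (g,) = design_guides(fix1["sites"], BE4, fix1["contigs"], [fix1["transcript"]])
        assert g.protospacer == "ACTTACCTTCAGCTCCTGAA"
        assert g.pam_seq == "TGG"
        assert g.strand == "-"
        assert g.span_1based == (17, 36)
        assert g.target_position == 6
        assert g.target_coord_1based == 31
        assert g.predicted_edit == "G31>A"
        assert g.preceding_base == "A"
        assert g.in_window
        assert g.site_kind == "donor"

    def test_abe_designs_same_protospacer_position_5(self, fix1):
        (g,) = design_guides(fix1["sites"], ABE710, fix1["contigs"], [fix1["transcript"]])
        assert g.protospacer == "ACTTACCTTCAGCTCCTGAA"
        assert g.pam_seq == "TGG"
        assert g.target_position == 5
        assert g.target_coord_1based == 32
        assert g.predicted_edit == "T32>C"
        assert (g.preceding_base, g.following_base) == ("T", "C")  # TAC motif

    @pytest.mark.parametrize("editor", [BE4, ABE710], ids=["CBE", "ABE"])
    def test_acceptor_has_no_ngg_placement(self, fix1, editor):
        acceptor = [s for s in fix1["sites"] if s.kind == "acceptor"]
        assert design_guides(acceptor, editor, fix1["contigs"], [fix1["transcript"]]) == []

    def test_brute_force_agrees_on_fix1(self, fix1):
        contig = fix1["contigs"]["chrT"]
        cbe = brute_force_scan(contig, BE4, 30, "-")
        assert [g.placement_key() for g in cbe] == [
            g.placement_key()
            for g in design_guides(
                fix1["sites"][:1], BE4, fix1["contigs"], [fix1["transcript"]]
            )
        ]
        # acceptor A at genomic 49 on "+": no GG pair at any admissible offset
        assert brute_force_scan(contig, ABE710, 48, "+") == []

    def test_brute_force_rejects_wrong_target_base(self, fix1):
        with pytest.raises(DomainError):
            brute_force_scan(fix1["contigs"]["chrT"], BE4, 30, "+")

    def test_all_a_contig_yields_nothing(self):
        contig = Contig("flat", "A" * 100)
        tx_a_coord = 50
        assert brute_force_scan(contig, ABE710, tx_a_coord, "+") == []


class TestBystanders:
    def test_fix1_cbe_guide_has_one_window_bystander(self, fix1):
        (g,) = design_guides(fix1["sites"], BE4, fix1["contigs"], [fix1["transcript"]])
        assert g.bystanders == [(7, 29)]  # position 7, genomic 30 (1-based)
        assert enumerate_bystanders(g, BE4) == g.bystanders

    def test_fix1_abe_guide_has_none(self, fix1):
        (g,) = design_guides(fix1["sites"], ABE710, fix1["contigs"], [fix1["transcript"]])
        assert g.bystanders == []


class TestSimulateEdit:
    def test_cbe_target_only_destroys_donor_gt(self, fix1):
        (g,) = design_guides(fix1["sites"], BE4, fix1["contigs"], [fix1["transcript"]])
        local, destroyed = simulate_edit(g, fix1["contigs"], "target_only")
        assert destroyed
        # donor dinucleotide now reads AT on the sense strand
        seq = list(fix1["contigs"]["chrT"].sequence)
        seq[30] = "A"
        assert local == "".join(seq)[16:36]

    def test_abe_target_only_turns_donor_into_gc(self, fix1):
        (g,) = design_guides(fix1["sites"], ABE710, fix1["contigs"], [fix1["transcript"]])
        _, destroyed = simulate_edit(g, fix1["contigs"])
        assert destroyed

    def test_full_window_also_applies_bystanders(self, fix1):
        (g,) = design_guides(fix1["sites"], BE4, fix1["contigs"], [fix1["transcript"]])
        local, destroyed = simulate_edit(g, fix1["contigs"], "full_window")
        assert destroyed
        seq = list(fix1["contigs"]["chrT"].sequence)
        seq[30] = "A"  # target
        seq[29] = "A"  # bystander C on minus strand -> G30A on plus
        assert local == "".join(seq)[16:36]

    def test_every_designed_guide_kills_its_motif(self, seeded_genes):
        contigs, transcripts, truths = seeded_genes
        tx_by_id = {t.transcript_id: t for t in transcripts}
        checked = 0
        for ft in truths:
            tx = ft.transcript
            for editor in (BE4, ABE710):
                guides = design_guides(ft.sites, editor, contigs, [tx])
                for g in guides:
                    _, destroyed = simulate_edit(g, contigs)
                    assert destroyed
                    checked += 1
        assert checked > 100


class TestOracleEquivalence:
    @pytest.mark.parametrize("editor", [BE4, ABE710], ids=["CBE", "ABE"])
    def test_design_matches_oracle_on_seeded_genes(self, seeded_genes, editor):
        contigs, transcripts, truths = seeded_genes
        for ft in truths:
            designed = design_guides(ft.sites, editor, contigs, [ft.transcript])
            assert [g.placement_key() for g in designed] == [
                g.placement_key() for g in ft.truth[editor.name]
            ]

    def test_minus_strand_gene_mirrors_plus_strand(self):
        cfg_p = FixtureConfig(strand="+")
        cfg_m = FixtureConfig(strand="-")
        ft_p = make_fixture_gene(cfg_p, 99)
        ft_m = make_fixture_gene(cfg_m, 99)
        for editor in ("BE4", "ABE7.10"):
            plus = sorted(g.protospacer for g in ft_p.truth[editor])
            minus = sorted(g.protospacer for g in ft_m.truth[editor])
            assert plus == minus  # same spacers, opposite genomic strands
            strands_p = {g.strand for g in ft_p.truth[editor]}
            strands_m = {g.strand for g in ft_m.truth[editor]}
            if plus:
                assert strands_m == {{"+": "-", "-": "+"}[s] for s in strands_p}

    def test_design_is_deterministic(self, fix1):
        runs = [
            design_guides(fix1["sites"], BE4, fix1["contigs"], [fix1["transcript"]])
            for _ in range(2)
        ]
        assert [g.placement_key() for g in runs[0]] == [
            g.placement_key() for g in runs[1]
        ]


class TestForcedMotifs:
    """The GT/AG chemistry forces the context base next to every target."""

    def _guides(self, seeded_genes, editor, kind):
        contigs, transcripts, truths = seeded_genes
        out = []
        for ft in truths:
            sites = [s for s in ft.sites if s.kind == kind]
            out += design_guides(sites, editor, contigs, [ft.transcript])
        return out

    @pytest.mark.parametrize(
        "editor,kind,field,base",
        [
            (BE4, "donor", "preceding_base", "A"),
            (BE4, "acceptor", "following_base", "T"),
            (ABE710, "donor", "following_base", "C"),
            (ABE710, "acceptor", "following_base", "G"),
        ],
        ids=["CBE-donor", "CBE-acceptor", "ABE-donor", "ABE-acceptor"],
    )
    def test_forced_context_base(self, seeded_genes, editor, kind, field, base):
        guides = self._guides(seeded_genes, editor, kind)
        assert guides, "fixture produced no guides for this combination"
        assert all(getattr(g, field) == base for g in guides)

    def test_protospacer_matches_genome_slice(self, seeded_genes):
        contigs, _, truths = seeded_genes
        for ft in truths:
            for guides in ft.truth.values():
                for g in guides:
                    contig = contigs[g.contig]
                    assert g.protospacer == contig.slice(*g.span, g.strand)
                    assert g.protospacer[g.target_position - 1] == g.edited_base


class TestPentanucleotideMotif:
    def test_cbe_donor_frequency_of_a_at_minus1_is_one(self, seeded_genes):
        contigs, _, truths = seeded_genes
        guides = []
        for ft in truths:
            sites = [s for s in ft.sites if s.kind == "donor"]
            guides += design_guides(sites, BE4, contigs, [ft.transcript])
        freqs = pentanucleotide_motif(guides)
        assert freqs.loc["A", -1] == pytest.approx(1.0)
        assert freqs.loc["C", 0] == pytest.approx(1.0)

    def test_abe_acceptor_frequency_of_g_at_plus1_is_one(self, seeded_genes):
        contigs, _, truths = seeded_genes
        guides = []
        for ft in truths:
            sites = [s for s in ft.sites if s.kind == "acceptor"]
            guides += design_guides(sites, ABE710, contigs, [ft.transcript])
        freqs = pentanucleotide_motif(guides)
        assert freqs.loc["G", 1] == pytest.approx(1.0)

    def test_frequencies_match_independent_tally(self, seeded_genes):
        contigs, _, truths = seeded_genes
        guides = []
        for ft in truths:
            sites = [s for s in ft.sites if s.kind == "donor"]
            guides += design_guides(sites, BE4, contigs, [ft.transcript])
        freqs = pentanucleotide_motif(guides)
        # independent tally at offset +1
        tally = {b: 0 for b in "ACGT"}
        for g in guides:
            p = g.target_position + 1
            if 1 <= p <= len(g.protospacer):
                tally[g.protospacer[p - 1]] += 1
        total = sum(tally.values())
        for b in "ACGT":
            assert freqs.loc[b, 1] == pytest.approx(tally[b] / total)
        assert freqs.sum(axis=0).round(12).eq(1.0).all()

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            pentanucleotide_motif([])
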