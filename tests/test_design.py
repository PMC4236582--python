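"""Cassette design: geometry, variants, validation, determinism."""

import numpy as np
import pytest

from scarless import (
    DesignConfig,
    EditSpec,
    FixtureSpec,
    apply_edit,
    build_selection_cassette,
    choose_hr3,
    cleave_and_resolve,
    design,
    generate_fixture,
    integrate_in_silico,
    integration_identity_mask,
    p_desired_integration,
    rbs_score,
    scan_motif,
    translate,
    validate_design,
)
from conftest import synonymous_edit


class TestSelectionCassette:
    @pytest.mark.parametrize("n_term", [0, 1, 2])
    def test_element_order(self, library, n_term):
        core = build_selection_cassette("cat_syn", n_term, library)
        s_site, e_site = core.isceI_span
        term_spans = [(s, e) for lab, s, e in core.layout if lab.startswith("terminator")]
        assert len(term_spans) == n_term
        for s, e in term_spans:
            assert e <= s_site  # terminators strictly upstream of the cleavage site
        m_s, m_e = core.span(f"marker:cat_syn")
        assert m_s >= e_site  # marker after the site
        assert str(core.sequence) == "".join(
            str(core.sequence[s:e]) for _, s, e in core.layout
        )

    def test_no_terminator_layout_is_site_plus_marker(self, library):
        core = build_selection_cassette("cat_syn", 0, library)
        assert core.sequence.startswith(library.isceI_site.seq)
        assert core.sequence.endswith(library["cat_syn"].seq)

    def test_rbs_boost_keeps_marker_protein(self, library, table):
        plain = build_selection_cassette("cat_syn", 2, library)
        boosted = build_selection_cassette("cat_syn", 2, library, rbs_boost_tail=8)
        p0 = translate(plain.sequence[plain.marker_orf[0] : plain.marker_orf[1]], table)
        p1 = translate(boosted.sequence[boosted.marker_orf[0] : boosted.marker_orf[1]], table)
        assert p0 == p1
        from scarless import RbsModel

        tail0 = plain.sequence[plain.marker_orf[1] - 24 : plain.marker_orf[1]]
        tail1 = boosted.sequence[boosted.marker_orf[1] - 24 : boosted.marker_orf[1]]
        assert rbs_score(tail1, RbsModel())[0] >= rbs_score(tail0, RbsModel())[0]

    def test_unknown_marker_rejected(self, library):
        from scarless import LibraryError

        with pytest.raises(LibraryError):
            build_selection_cassette("nonexistent", 2, library)


class TestChooseHr3:
    def test_point_mutation_centred_tie_5prime(self, genome, config, table):
        pos = genome.features[0].region.start + 50
        base = genome.contigs["chr"][pos]
        edit = EditSpec(kind="point_mutation", start=pos + 1, end=pos + 1,
                        payload="A" if base != "A" else "G")
        choice = choose_hr3(genome, edit, config, table)
        assert choice.placement == "inside_hr3"
        assert len(choice.seq) == 40
        assert choice.mut_offsets == (19,)  # centred, tie toward the 5' side

    def test_deletion_junction_fusion(self, genome, config, table):
        d5 = genome.features[0].region.end + 30
        edit = EditSpec(kind="deletion", start=d5 + 1, end=d5 + 120)
        choice = choose_hr3(genome, edit, config, table)
        g = genome.contigs["chr"]
        assert choice.seq == g[d5 - 20 : d5] + g[d5 + 120 : d5 + 140]

    def test_essential_window_is_codon_aligned(self, genome, config, table):
        feat = next(f for f in genome.features if f.region.strand == "+")
        edit = synonymous_edit(genome, table, feat, "own_promoter")
        choice = choose_hr3(genome, edit, config, table)
        assert (choice.start - feat.region.start) % 3 == 0
        assert (choice.end - feat.region.start) % 3 == 0
        assert len(choice.seq) % 3 == 0

    def test_wide_mutation_span_rejected(self, genome, config, table):
        from scarless import DesignError

        start = genome.features[0].region.start + 30
        payload = str(genome.contigs["chr"][start - 1 : start + 79])
        edit = EditSpec(kind="point_mutation", start=start, end=start + 79, payload=payload)
        # payload identical -> no diff; force a diff at both extremes
        p = list(payload)
        p[0] = "A" if p[0] != "A" else "G"
        p[-1] = "A" if p[-1] != "A" else "G"
        edit = EditSpec(kind="point_mutation", start=start, end=start + 79, payload="".join(p))
        with pytest.raises(DesignError):
            choose_hr3(genome, edit, config, table)


class TestDesign:
    def _roundtrip(self, genome, edit, library, config):
        cassette, frags, report = design(edit, genome, library, config)
        resolved = cleave_and_resolve(integrate_in_silico(genome, cassette), library)
        intended = apply_edit(genome, edit)
        assert resolved.contigs == intended.contigs
        return cassette, frags, report

    def test_deletion_roundtrip_no_scar(self, genome, library, config):
        d5 = genome.features[1].region.end + 10
        edit = EditSpec(kind="deletion", start=d5 + 1, end=d5 + 200)
        cassette, _, report = self._roundtrip(genome, edit, library, config)
        assert report.check("scarless_round_trip").status == "pass"

    def test_flag_tag_insertion_in_frame(self, genome, library, config, table):
        feat = next(f for f in genome.features if f.region.strand == "+")
        flag = library["3xFLAG"].seq
        edit = EditSpec(kind="insertion", start=feat.region.end - 3 + 1, payload=str(flag))
        cassette, _, _ = self._roundtrip(genome, edit, library, config)
        final = cleave_and_resolve(integrate_in_silico(genome, cassette), library)
        assert len(scan_motif(final.contigs["chr"], flag, both_strands=True)) == 1
        prot = translate(final.contigs["chr"][feat.region.start : feat.region.end + len(flag)], table)
        assert prot.endswith("DYKDHDGDYKDHDIDYKDDDDK*")

    @pytest.mark.parametrize("variant", ["own_promoter", "marker_promoter", "wt_restoring"])
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_essential_variants_roundtrip(self, library, config, table, variant, strand):
        g = generate_fixture(FixtureSpec(seed=31, minus_strand_fraction=0.5))
        feat = next(f for f in g.features if f.region.strand == strand)
        edit = synonymous_edit(g, table, feat, variant)
        cassette, _, report = self._roundtrip(g, edit, library, config)
        assert report.check("intermediate_orf_reconstituted").status == "pass"
        # the intermediate genome must carry a complete ORF for the right protein
        wt_prot = translate(g.extract(feat.region), table)
        inter_prot = translate(cassette.intermediate_orf, table)
        if variant == "wt_restoring":
            assert inter_prot == wt_prot
        else:
            edited_prot = translate(apply_edit(g, edit, table).extract(feat.region), table)
            assert inter_prot == edited_prot

    def test_recoded_dominates_native_geometry(self, library, config, table):
        g = generate_fixture(FixtureSpec(seed=33))
        feat = next(f for f in g.features if f.region.strand == "+")
        edit = synonymous_edit(g, table, feat, "marker_promoter")
        cassette, _, report = design(edit, g, library, config)
        assert report.p_desired_integration > report.p_desired_native

    def test_cassette_length_identity(self, genome, library, config):
        pos = genome.features[2].region.start + 40
        base = genome.contigs["chr"][pos]
        edit = EditSpec(kind="point_mutation", start=pos + 1, end=pos + 1,
                        payload="A" if base != "A" else "G")
        cassette, _, _ = design(edit, genome, library, config)
        total = (
            len(cassette.hr1) + len(cassette.fragment5) + len(cassette.restoring5)
            + len(cassette.core.sequence) + len(cassette.restoring3)
            + len(cassette.fragment3) + len(cassette.hr2)
        )
        assert len(cassette.sequence) == total
        spans = sorted((s, e) for _, s, e, _ in cassette.annotations)
        assert spans[0][0] == 0 and spans[-1][1] == total
        assert all(e1 == s2 for (_, e1), (s2, _) in zip(spans, spans[1:]))

    def test_design_is_deterministic(self, genome, library, config, table):
        feat = next(f for f in genome.features if f.region.strand == "+")
        edit = synonymous_edit(genome, table, feat, "own_promoter")
        c1, f1, r1 = design(edit, genome, library, config)
        c2, f2, r2 = design(edit, genome, library, config)
        assert str(c1.sequence) == str(c2.sequence)
        assert str(f1.fragment5_with_overlaps) == str(f2.fragment5_with_overlaps)
        assert r1.provenance["cassette_digest"] == r2.provenance["cassette_digest"]

    def test_rbs_boost_design(self, library, config, table):
        g = generate_fixture(FixtureSpec(seed=35))
        feat = next(f for f in g.features if f.region.strand == "+")
        edit = synonymous_edit(g, table, feat, "marker_promoter", rbs_boost=True)
        cassette, _, report = self._roundtrip(g, edit, library, config)
        assert cassette.core.rbs_mutations  # silent mutations were applied
        assert report.check("marker_orf_intact").status == "pass"

    def test_template_fragments_assemble_to_cassette(self, genome, library, config):
        from scarless import plan_assembly

        pos = genome.features[1].region.start + 33
        base = genome.contigs["chr"][pos]
        edit = EditSpec(kind="point_mutation", start=pos + 1, end=pos + 1,
                        payload="A" if base != "A" else "G")
        cassette, frags, _ = design(edit, genome, library, config)
        ov = frags.overlap_len
        backbone = library["pHA_syn"].seq
        plan = plan_assembly(
            [frags.fragment5_with_overlaps, cassette.core.sequence, frags.fragment3_with_overlaps],
            overlap_len=ov,
            backbone=backbone,
            circular=True,
        )
        # the assembled template plasmid contains the full cassette once
        assert len(scan_motif(plan.assembled, cassette.sequence)) == 1


class TestValidateDesign:
    def test_fault_injected_hr3_fails(self, genome, library, config):
        pos = genome.features[0].region.start + 45
        base = genome.contigs["chr"][pos]
        edit = EditSpec(kind="point_mutation", start=pos + 1, end=pos + 1,
                        payload="A" if base != "A" else "G")
        cassette, _, _ = design(edit, genome, library, config)
        from scarless import NucSeq

        f3 = list(str(cassette.fragment3))
        f3[2] = "A" if f3[2] != "A" else "C"
        cassette.fragment3 = NucSeq("".join(f3))
        report = validate_design(cassette, genome, library, config, edit=edit)
        assert report.check("hr3_copies_identical").status == "fail"

    def test_report_has_unique_check_names(self, genome, library, config):
        pos = genome.features[0].region.start + 45
        base = genome.contigs["chr"][pos]
        edit = EditSpec(kind="point_mutation", start=pos + 1, end=pos + 1,
                        payload="A" if base != "A" else "G")
        _, _, report = design(edit, genome, library, config)
        names = [c.name for c in report.checks]
        assert len(names) == len(set(names))

    def test_native_geometry_probability_via_mask(self, library, config, table):
        g = generate_fixture(FixtureSpec(seed=37))
        feat = next(f for f in g.features if f.region.strand == "+")
        edit = synonymous_edit(g, table, feat, "own_promoter")
        cassette, _, _ = design(edit, g, library, config)
        mask_r, muts_r = integration_identity_mask(cassette, recoded=True)
        mask_n, muts_n = integration_identity_mask(cassette, recoded=False)
        p_r = p_desired_integration(mask_r, muts_r, config.pairing_window)
        p_n = p_desired_integration(mask_n, muts_n, config.pairing_window)
        assert p_r > p_n
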