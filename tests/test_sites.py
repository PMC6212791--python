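"""Motif scanning, switchability, strain methylation and blocking rules."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from metclo.core import DnaMolecule, MethylMark, StrainProfile, reverse_complement
from metclo.digest import cut_events
from metclo.sites import (
    SiteHit,
    apply_strain,
    classify_switchable,
    clear_marks,
    find_motif_sites,
    is_blocked,
)

dna = st.text(alphabet="ACGT", min_size=12, max_size=80)


class TestFindMotifSites:
    def test_top_strand_match(self):
        mol = DnaMolecule("m", "AAGCTCTTCAA", topology="linear")
        hits = find_motif_sites(mol, "GCTCTTC")
        assert [(h.strand, h.start, h.end) for h in hits] == [("+", 2, 9)]

    def test_bottom_strand_match(self):
        mol = DnaMolecule("m", "TTGAAGAGCTT", topology="linear")
        hits = find_motif_sites(mol, "GCTCTTC")
        assert len(hits) == 1 and hits[0].strand == "-"

    def test_origin_spanning_match_on_circle(self):
        mol = DnaMolecule("m", "CTCAAAAAGGT")  # GGTCTC wraps the origin
        hits = find_motif_sites(mol, "GGTCTC")
        assert len(hits) == 1 and hits[0].start == 8

    def test_degenerate_motif_agrees_with_brute_force_expansion(self):
        from metclo.core import expand_iupac

        concrete = set(expand_iupac("GANNTC"))
        assert "GATATC" in concrete and "GGTATC" not in concrete
        for seq, expect in [("GATATC", 1), ("GGTATC", 0)]:
            mol = DnaMolecule("m", "TT" + seq + "TT", topology="linear")
            plus = [h for h in find_motif_sites(mol, "GANNTC") if h.strand == "+"]
            assert len(plus) == expect

    def test_motif_longer_than_molecule_warns_and_returns_nothing(self):
        mol = DnaMolecule("m", "ACGT", topology="linear")
        with pytest.warns(UserWarning):
            assert find_motif_sites(mol, "ACGTACGT") == []

    @given(dna)
    def test_strand_symmetry(self, seq):
        mol = DnaMolecule("m", seq, topology="linear")
        rc = DnaMolecule("r", reverse_complement(seq), topology="linear")
        fwd = find_motif_sites(mol, "GGTCTC")
        rev = find_motif_sites(rc, "GGTCTC")
        n = len(seq)
        mirrored = sorted(
            (n - h.end, "-" if h.strand == "+" else "+") for h in fwd
        )
        assert mirrored == sorted((h.start, h.strand) for h in rev)


class TestSwitchability:
    def test_test_plasmid_has_two_switchable_and_one_plain_site(self, test_plasmid, bsai, osp):
        hits = classify_switchable(test_plasmid, bsai, osp)
        assert sum(h.switchable for h in hits) == 2
        assert sum(not h.switchable for h in hits) == 1

    def test_site_without_methylase_overlap_is_not_switchable(self, bsai, osp):
        mol = DnaMolecule("m", "T" * 10 + "GGTCTC" + "T" * 30)  # no leading A
        hits = classify_switchable(mol, bsai, osp)
        assert hits and not any(h.switchable for h in hits)

    def test_methylase_motif_identical_to_restriction_motif_encloses_all(self, bsai):
        from metclo.core import MethylaseSpec

        # a (hypothetical) methylase recognizing the enzyme site itself
        same = MethylaseSpec("M.same", "GGTCTCA", 6, "m6A", meth_offset_bottom=2)
        mol = DnaMolecule("m", "T" * 10 + "GGTCTCA" + "T" * 30)
        hits = classify_switchable(mol, bsai, same)
        assert all(h.switchable for h in hits if h.strand == "+")

    def test_switchability_ignores_current_marks(self, test_plasmid, bsai, osp, methylases):
        from metclo.fixtures import switch_strain

        marked = apply_strain(test_plasmid, switch_strain(osp), methylases)
        assert [h.switchable for h in classify_switchable(marked, bsai, osp)] == [
            h.switchable for h in classify_switchable(test_plasmid, bsai, osp)
        ]


class TestApplyStrain:
    def test_normal_strain_adds_no_marks(self, test_plasmid, methylases):
        assert not apply_strain(test_plasmid, StrainProfile("DH10B"), methylases).marks

    def test_switch_strain_marks_both_switchable_sites_only(
        self, test_plasmid, bsai, osp, methylases
    ):
        from metclo.fixtures import switch_strain

        marked = apply_strain(test_plasmid, switch_strain(osp), methylases)
        n = len(marked)
        hits = classify_switchable(marked, bsai, osp)
        for h in hits:
            inside = [m for m in marked.marks if h.covers(m.position, n, True)]
            assert bool(inside) == h.switchable

    def test_apply_strain_is_idempotent(self, test_plasmid, osp, methylases):
        from metclo.fixtures import switch_strain

        once = apply_strain(test_plasmid, switch_strain(osp), methylases)
        twice = apply_strain(once, switch_strain(osp), methylases)
        assert once.marks == twice.marks

    def test_dam_marks_gatc_on_both_strands(self, methylases):
        mol = DnaMolecule("m", "TTGATCTTTT")
        marked = apply_strain(mol, StrainProfile("dam+", dam_active=True), methylases)
        assert {(m.position, m.strand) for m in marked.marks} == {(3, "+"), (4, "-")}

    def test_unknown_methylase_is_a_config_error(self, test_plasmid, methylases):
        from metclo.core import InputError

        with pytest.raises(InputError):
            apply_strain(test_plasmid, StrainProfile("x", frozenset({"M.nope"})), methylases)


class TestClearAndBlock:
    def test_clear_marks_is_idempotent_and_total(self, test_plasmid, osp, methylases):
        from metclo.fixtures import switch_strain

        marked = apply_strain(test_plasmid, switch_strain(osp), methylases)
        cleared = clear_marks(marked)
        assert not cleared.marks
        assert clear_marks(cleared).marks == frozenset()
        assert cleared.sequence == test_plasmid.sequence

    def test_unmarked_site_is_not_blocked(self, test_plasmid, bsai, osp):
        for h in classify_switchable(test_plasmid, bsai, osp):
            assert not is_blocked(h, test_plasmid, bsai)

    def test_mark_inside_footprint_blocks(self, test_plasmid, bsai, osp, methylases):
        from metclo.fixtures import switch_strain

        marked = apply_strain(test_plasmid, switch_strain(osp), methylases)
        hits = classify_switchable(marked, bsai, osp)
        assert [is_blocked(h, marked, bsai) for h in hits] == [
            h.switchable for h in hits
        ]

    def test_mark_in_spacer_region_does_not_block(self, bsai):
        # mark sits just downstream of the footprint, in the spacer/overhang window
        seq = "T" * 10 + "GGTCTC" + "TATTT" + "T" * 20
        pos = 16  # first spacer base
        mol = DnaMolecule("m", seq, topology="linear", marks=[MethylMark(17, "+", "m6A")])
        site = find_motif_sites(mol, bsai.recognition, owner="BsaI")[0]
        assert not is_blocked(site, mol, bsai)
        assert len(cut_events(mol, bsai)) == 1  # digestion unchanged

    def test_adding_marks_never_increases_cuttable_sites(
        self, test_plasmid, bsai, osp, methylases
    ):
        from metclo.fixtures import switch_strain

        before = len(cut_events(test_plasmid, bsai))
        marked = apply_strain(test_plasmid, switch_strain(osp), methylases)
        assert len(cut_events(marked, bsai)) <= before
        assert len(cut_events(clear_marks(marked), bsai)) == before
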