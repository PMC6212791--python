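"""Digestion geometry, fragment conventions, end compatibility, religation."""

import pytest

from metclo.core import DnaMolecule, FragmentEnd, reverse_complement
from metclo.digest import (
    cut_events,
    digest,
    ends_compatible,
    flip_fragment,
    ligate_cycle,
    validate_shared_cut_pair,
)
from metclo.sites import apply_strain, classify_switchable
from metclo.fixtures import make_donor, random_dna, switch_strain


class TestCutEvents:
    def test_test_plasmid_unmarked_three_events_two_breaks(self, test_plasmid, bsai):
        events = cut_events(test_plasmid, bsai)
        assert len(events) == 3  # head-to-head pair shares one cut interval
        assert len({e.top_cut for e in events}) == 2

    def test_methylated_pair_leaves_only_the_plain_site(
        self, test_plasmid, bsai, osp, methylases
    ):
        marked = apply_strain(test_plasmid, switch_strain(osp), methylases)
        events = cut_events(marked, bsai)
        assert len(events) == 1 and not events[0].site.switchable

    def test_zero_sites_zero_events(self, bsai):
        mol = random_dna(500, seed=3, forbidden=[bsai.recognition])
        assert cut_events(mol, bsai) == []

    def test_overhang_interval_width_is_overhang_len(self, test_plasmid, bsai):
        for e in cut_events(test_plasmid, bsai):
            assert e.bottom_cut - e.top_cut == bsai.overhang_len


class TestDigest:
    def test_test_plasmid_releases_600bp_from_4p3kb_backbone(self, test_plasmid, bsai):
        res = digest(test_plasmid, bsai)
        sizes = sorted(round(f.length, -2) for f in res.fragments)
        assert sizes == [600, 4300]

    def test_methylated_test_plasmid_gives_single_4p9kb_molecule(
        self, test_plasmid, bsai, osp, methylases
    ):
        marked = apply_strain(test_plasmid, switch_strain(osp), methylases)
        res = digest(marked, bsai)
        assert len(res.fragments) == 1
        assert round(res.fragments[0].length, -2) == 4900

    def test_zero_breaks_returns_molecule_undigested(self, bsai):
        mol = random_dna(400, seed=4, forbidden=[bsai.recognition])
        res = digest(mol, bsai)
        assert res.undigested is mol and res.fragments == ()

    def test_linear_one_cut_lengths_sum_to_parent_plus_overhang(self, bsai):
        seq = "T" * 40 + "GGTCTC" + "TAAAT" + "T" * 40
        mol = DnaMolecule("m", seq, topology="linear")
        res = digest(mol, bsai)
        assert len(res.fragments) == 2
        assert sum(f.length for f in res.fragments) == len(mol) + bsai.overhang_len

    def test_circular_body_lengths_conserve_substrate_length(self, test_plasmid, bsai):
        res = digest(test_plasmid, bsai)
        assert sum(len(f.body) for f in res.fragments) == len(test_plasmid)

    def test_digestion_is_a_fixed_point(self, test_plasmid, bsai):
        # every released fragment carries no further intact cuttable site
        for f in digest(test_plasmid, bsai).fragments:
            lin = DnaMolecule("f", f.body, topology="linear", marks=f.marks)
            assert cut_events(lin, bsai) == []

    def test_fragment_set_invariant_under_rotation(self, test_plasmid, bsai):
        from dataclasses import replace

        rotated = replace(
            test_plasmid,
            sequence=test_plasmid.sequence[1234:] + test_plasmid.sequence[:1234],
            marks=frozenset(),
            annotations=(),
        )
        base = replace(test_plasmid, marks=frozenset(), annotations=())
        a = sorted(f.body for f in digest(base, bsai).fragments)
        b = sorted(f.body for f in digest(rotated, bsai).fragments)
        assert a == b

    def test_religating_a_two_cut_digest_reconstructs_the_parent(self, test_plasmid, bsai):
        from metclo.core import canonical_sequence

        f1, f2 = digest(test_plasmid, bsai).fragments
        rebuilt = ligate_cycle([f1, f2])
        assert canonical_sequence(rebuilt) == canonical_sequence(test_plasmid)

    def test_methylation_never_increases_fragment_count(
        self, test_plasmid, bsai, osp, methylases
    ):
        unmarked = len(digest(test_plasmid, bsai).fragments)
        marked = apply_strain(test_plasmid, switch_strain(osp), methylases)
        assert len(digest(marked, bsai).fragments) <= unmarked


class TestEndsCompatible:
    @pytest.mark.parametrize(
        "a,b,expect",
        [
            ("AATT", "AATT", True),  # self-reverse-complement overhang
            ("ATGC", "GCAT", True),
            ("ATGC", "ATGC", False),
            ("AATT", "AAT", False),  # length mismatch
        ],
    )
    def test_five_prime_pairs(self, a, b, expect):
        ea = FragmentEnd("five_prime", a)
        eb = FragmentEnd("five_prime", b)
        assert ends_compatible(ea, eb) is expect
        assert ends_compatible(eb, ea) is expect  # symmetric relation

    def test_blunt_blunt_disabled(self):
        assert not ends_compatible(FragmentEnd(), FragmentEnd())

    def test_mixed_protrusion_types_incompatible(self):
        assert not ends_compatible(
            FragmentEnd("five_prime", "AATT"), FragmentEnd("three_prime", "AATT")
        )


class TestFlip:
    def test_flip_preserves_physical_identity(self, test_plasmid, bsai):
        from metclo.core import canonical_sequence

        f1, f2 = digest(test_plasmid, bsai).fragments
        rebuilt = ligate_cycle([f1, flip_fragment(flip_fragment(f2))])
        assert canonical_sequence(rebuilt) == canonical_sequence(test_plasmid)
        g = flip_fragment(f1)
        assert g.end5 == f1.end3 and g.end3 == f1.end5
        assert len(g.body) == len(f1.body)


class TestSharedCutPair:
    def test_switchable_pair_shares_interval(self, test_plasmid, bsai, osp):
        hits = classify_switchable(test_plasmid, bsai, osp)
        pair = tuple(h for h in hits if h.switchable)
        rep = validate_shared_cut_pair(test_plasmid, bsai, pair)
        assert rep.head_to_head and rep.shared and len(rep.overhang) == 4

    def test_tandem_sites_fail_validation(self, bsai):
        seq = "T" * 10 + "GGTCTC" + "T" * 12 + "GGTCTC" + "T" * 30
        mol = DnaMolecule("m", seq)
        hits = classify_switchable(mol, bsai, _dummy_methylase())
        rep = validate_shared_cut_pair(mol, bsai, tuple(hits[:2]))
        assert not rep.head_to_head

    def test_head_to_head_but_farther_apart_is_not_shared(self, bsai):
        # cut intervals separated by 10 extra bases
        seq = "T" * 10 + "GGTCTC" + "T" * (1 + 4 + 10 + 1) + "GAGACC" + "T" * 30
        mol = DnaMolecule("m", seq)
        hits = classify_switchable(mol, bsai, _dummy_methylase())
        rep = validate_shared_cut_pair(mol, bsai, tuple(hits[:2]))
        assert rep.head_to_head and not rep.shared


def _dummy_methylase():
    from metclo.core import MethylaseSpec

    return MethylaseSpec("M.dummy", "CGATCG", 0, "m5C")


class TestDonorDigest:
    def test_donor_releases_insert_with_requested_overhangs(self, bsai, osp):
        donor = make_donor(bsai, osp, "AATG", "AGGT", insert_len=200, seed=9)
        res = digest(donor, bsai)
        assert len(res.fragments) == 2
        ins = next(
            f for f in res.fragments
            if any(a.label.startswith("insert:") for a in f.annotations)
        )
        assert ins.end5.overhang == "AATG"
        assert ins.end3.overhang == reverse_complement("AGGT")

    def test_explicit_insert_with_internal_site_is_rejected_with_positions(self, bsai, osp):
        from metclo.fixtures import DomesticationError

        bad = "T" * 20 + "GGTCTC" + "T" * 20
        with pytest.raises(DomesticationError, match="positions"):
            make_donor(bsai, osp, "AATG", "AGGT", insert=bad, seed=0)
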