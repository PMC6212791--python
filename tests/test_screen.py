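"""Switch-methylase screening criteria and forbidden-site statistics."""

import itertools

import pytest

from metclo.core import DnaMolecule, EnzymeSpec, MethylaseSpec, expand_iupac
from metclo.io import TESTED_PAIRS
from metclo.screen import (
    check_desirable,
    check_essential,
    empirical_spacing,
    enumerate_composites,
    expected_spacing,
    format_spacing,
    motif_probability,
    screen_table,
)
from metclo.sites import find_motif_sites
from metclo.fixtures import random_dna


class TestComposites:
    def test_eari_mtaqi_yields_the_ctcttcga_composite(self, enzymes, methylases):
        placements = enumerate_composites(enzymes["EarI"], methylases["M.TaqI"])
        assert [p.composite for p in placements] == ["CTCTTCGA"]
        pl = placements[0]
        assert pl.meth_in_footprint  # the bottom-strand adenine under position 4

    def test_no_overlap_means_no_placements(self, enzymes):
        loner = MethylaseSpec("M.none", "AAAAAA", 0, "m6A")
        assert enumerate_composites(enzymes["BsaI"], loner) == []

    def test_identical_motif_gives_full_enclosure_placement(self, enzymes):
        same = MethylaseSpec("M.same", "GGTCTC", 5, "m5C")
        placements = enumerate_composites(enzymes["BsaI"], same)
        assert any(p.offset == 0 and p.orientation == "+" for p in placements)

    def test_composites_rescan_consistently(self, enzymes, methylases):
        # every returned composite must contain both motifs where claimed
        for ename, mname in [("BsaI", "M.Osp807II"), ("LguI", "M.XmnI")]:
            enz, meth = enzymes[ename], methylases[mname]
            for pl in enumerate_composites(enz, meth):
                mol = DnaMolecule("c", pl.composite.replace("M", "A").replace("N", "A"),
                                  topology="linear")
                assert find_motif_sites(mol, enz.recognition)
                assert find_motif_sites(mol, meth.recognition)


class TestEssential:
    def test_enclosed_methylase_motif_fails_e2(self, enzymes):
        same = MethylaseSpec("M.same", "GGTCTC", 5, "m5C")
        e1, e2, e3 = check_essential(enzymes["BsaI"], same)
        assert e1 and not e2

    def test_eari_mtaqi_fails_e3(self, enzymes, methylases):
        e1, e2, e3 = check_essential(enzymes["EarI"], methylases["M.TaqI"])
        assert e1 and e2 and not e3

    @pytest.mark.parametrize(
        "ename,mname",
        [("BsaI", "M.Osp807II"), ("BpiI", "M2.NmeMC58II"), ("LguI", "M.XmnI")],
    )
    def test_the_three_working_pairs_pass_all_essential(self, enzymes, methylases, ename, mname):
        assert check_essential(enzymes[ename], methylases[mname]) == (True, True, True)

    def test_e2_agrees_with_brute_force_enumeration(self, enzymes, methylases):
        """Oracle: expand every concrete restriction site and ask whether each
        one contains a methylase occurrence fully inside the footprint."""
        from metclo.core import iupac_revcomp
        from metclo.screen import _e2

        cases = [
            (enzymes["BsaI"], methylases["M.Osp807II"]),
            (enzymes["LguI"], methylases["M.XmnI"]),
            (enzymes["BsaI"], MethylaseSpec("M.same", "GGTCTC", 5, "m5C")),
            (enzymes["BsaI"], MethylaseSpec("M.sub", "GTCT", 2, "m5C")),
        ]
        for enz, meth in cases:
            forced = True
            for concrete in expand_iupac(enz.recognition):
                found = False
                for M in {meth.recognition, iupac_revcomp(meth.recognition)}:
                    for off in range(len(concrete) - len(M) + 1):
                        window = concrete[off : off + len(M)]
                        if all(w in expand_iupac(c) for w, c in zip(window, M)):
                            found = True
                if not found:
                    forced = False
                    break
            assert _e2(enz, meth) == (not forced)


class TestDesirablesAndTable:
    def test_short_recognition_fails_length_criterion(self, methylases, enzymes):
        des = check_desirable(methylases["M.TaqI"], enzymes["EarI"])
        assert not des.recognition_len_ge_5

    def test_orphan_single_subunit_flag(self, methylases):
        assert check_desirable(methylases["M.Osp807II"]).single_subunit_orphan
        assert not check_desirable(methylases["M.TaqI"]).single_subunit_orphan

    def test_modification_at_footprint_edge_scores_zero(self, enzymes):
        # every overlap placement of CAT puts its methyl-C on a footprint edge
        edge = MethylaseSpec("M.edge", "CAT", 0, "m5C")
        des = check_desirable(edge, enzymes["BsaI"])
        assert des.central_modification == 0

    def test_central_modification_scores_distance_from_edge(self, enzymes, methylases):
        des = check_desirable(methylases["M.Osp807II"], enzymes["BsaI"])
        assert des.central_modification == 2

    def test_screening_panel_recovers_the_three_working_methylases(self, enzymes, methylases):
        carried = []
        for ename, tested in TESTED_PAIRS.items():
            reports = screen_table(methylases, enzymes[ename], tested=tested)
            carried += [
                (r.enzyme, r.methylase)
                for r in reports
                if r.verdict == "candidate" and r.E1_empirical == "pass"
            ]
        assert sorted(carried) == [
            ("BpiI", "M2.NmeMC58II"), ("BsaI", "M.Osp807II"), ("LguI", "M.XmnI"),
        ]

    def test_empty_registry_gives_empty_report(self, enzymes):
        assert screen_table({}, enzymes["BsaI"]) == []

    def test_all_enclosed_entries_rejected_for_e2(self, enzymes):
        reg = {"M.x": MethylaseSpec("M.x", "GGTCTC", 5, "m5C")}
        (rep,) = screen_table(reg, enzymes["BsaI"])
        assert rep.verdict == "rejected(E2)"


class TestMotifProbability:
    def test_six_cutter_probability_at_half_gc(self):
        assert motif_probability("GGTCTC", 0.5) == pytest.approx(0.25**6)

    def test_n_is_probability_one(self):
        assert motif_probability("N", 0.3) == pytest.approx(1.0)

    def test_degenerate_motif_matches_brute_force_enumeration(self):
        motif = "GAANNNNTTC"
        count = sum(
            all(ch in expand_iupac(c) for ch, c in zip("".join(w), motif))
            for w in itertools.product("ACGT", repeat=len(motif))
        )
        assert motif_probability(motif, 0.5) == pytest.approx(count / 4 ** len(motif))
        assert motif_probability(motif, 0.5) == pytest.approx(0.25**6)

    def test_invalid_gc_rejected(self):
        from metclo.core import InputError

        with pytest.raises(InputError):
            motif_probability("GGTCTC", 1.0)


class TestExpectedSpacing:
    def test_single_six_cutter_every_2kb(self):
        assert expected_spacing(["GGTCTC"]) == pytest.approx(2048)
        assert format_spacing(expected_spacing(["GGTCTC"])) == "1 per 2 kb"

    def test_seven_cutter_every_8kb(self):
        assert expected_spacing(["GCTCTTC"]) == pytest.approx(8192)
        assert format_spacing(expected_spacing(["GCTCTTC"])) == "1 per 8 kb"

    def test_three_six_cutters_every_700bp(self):
        spacing = expected_spacing(["GGTCTC", "GAAGAC", "CGTCTC"])
        assert spacing == pytest.approx(4**6 / 6)
        assert format_spacing(spacing) == "1 per 700 bp"

    def test_palindromic_motif_counted_once(self):
        assert expected_spacing(["GAATTC"]) == pytest.approx(4096)

    def test_empirical_count_on_simulated_dna_within_3_sigma(self):
        mol = random_dna(1_000_000, gc=0.5, seed=13, topology="linear")
        stats = empirical_spacing([mol], ["GGTCTC"])
        lam = 1_000_000 / 2048
        assert abs(stats.observed_count - lam) <= 3 * lam**0.5

    def test_constructed_periodic_motif_spacing(self):
        period = "GGTCTC" + "A" * 94
        mol = DnaMolecule("m", period * 20, topology="linear")
        stats = empirical_spacing([mol], ["GGTCTC"])
        assert stats.observed_spacing == pytest.approx(100)

    def test_absent_motif_reports_zero_count(self):
        mol = DnaMolecule("m", "A" * 5000, topology="linear")
        stats = empirical_spacing([mol], ["GGTCTC"])
        assert stats.observed_count == 0
        assert stats.observed_spacing >= len(mol)
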