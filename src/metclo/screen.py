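"""Switch-methylase candidate screening and forbidden-site statistics.

A *switch methylase* for a type IIS enzyme must satisfy three essential
criteria:

E1. Methylation of a composite (overlapping) methylation/restriction site
    must block cutting.  The geometric part -- existence of an overlap
    placement putting a methylated base inside the restriction footprint --
    is computable; actual blocking is biochemistry and is recorded as
    empirical registry evidence, never predicted.
E2. The methylase recognition sequence must not be identical to, or forced
    to occur inside, every occurrence of the restriction site (otherwise all
    sites would be switchable and none could serve as the constitutive
    inner pair).
E3. The methylase specificity bases extending beyond the restriction
    footprint must not intrude into the spacer/adhesive-end window, or they
    would constrain the available fusion-site sequences (the failure mode of
    M.TaqI with EarI: CTCTTCG^ANN).

Desirable properties: activity at 37C, recognition length >= 5 bp, orphan
single-subunit enzymes, and modification near the middle of the restriction
footprint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .core import (
    DnaMolecule,
    EnzymeSpec,
    InputError,
    MethylaseSpec,
    iupac_intersect,
    iupac_is_palindrome,
    iupac_revcomp,
    iupac_subset,
    IUPAC,
)
from .sites import find_motif_sites

__all__ = [
    "CompositePlacement",
    "ScreenReport",
    "SiteStats",
    "enumerate_composites",
    "check_essential",
    "check_desirable",
    "screen_table",
    "motif_probability",
    "expected_spacing",
    "empirical_spacing",
    "format_spacing",
]


@dataclass(frozen=True)
class CompositePlacement:
    """One way the methylase motif can overlap the restriction site.

    ``offset``: start of the methylase footprint relative to the restriction
    footprint start (may be negative).  ``orientation``: '+' if the methylase
    motif reads on the same strand as the restriction recognition, '-'
    otherwise.  ``composite``: the minimal IUPAC sequence satisfying both
    motifs, spanning their union.  ``meth_positions``: modified-base
    positions (composite coordinates, both strands merged) and
    ``meth_in_footprint``: the subset inside the restriction footprint.
    """

    offset: int
    orientation: str
    composite: str
    meth_positions: tuple[int, ...]
    meth_in_footprint: tuple[int, ...]
    footprint: tuple[int, int]  # restriction footprint in composite coords


def _placement_marks(methylase: MethylaseSpec, orientation: str, L: int) -> list[int]:
    """Modified-base positions (either strand) within one motif occurrence,
    in left-to-right coordinates of the occurrence on the reference strand."""
    mt, mb = methylase.meth_offset_top, methylase.meth_offset_bottom
    pos = []
    if orientation == "+" or methylase.is_palindromic:
        pos.append(mt)
        if mb is not None:
            pos.append(L - 1 - mb)
    if orientation == "-" or methylase.is_palindromic:
        pos.append(L - 1 - mt)
        if mb is not None:
            pos.append(mb)
    return sorted(set(pos))


def enumerate_composites(
    enzyme: EnzymeSpec, methylase: MethylaseSpec
) -> list[CompositePlacement]:
    """All offsets/orientations where the two IUPAC motifs are simultaneously
    satisfiable with at least one methylase-modified base inside the
    restriction footprint (the restriction motif is fixed on the reference
    strand at offset 0)."""
    R = enzyme.recognition
    Lr = len(R)
    out = []
    orientations = ["+"] if methylase.is_palindromic else ["+", "-"]
    for orientation in orientations:
        M = methylase.recognition if orientation == "+" else iupac_revcomp(methylase.recognition)
        Lm = len(M)
        for offset in range(-Lm + 1, Lr):
            lo, hi = min(0, offset), max(Lr, offset + Lm)
            merged = []
            ok = True
            for i in range(lo, hi):
                r = R[i] if 0 <= i < Lr else "N"
                m = M[i - offset] if offset <= i < offset + Lm else "N"
                x = iupac_intersect(r, m)
                if x is None:
                    ok = False
                    break
                merged.append(x)
            if not ok:
                continue
            marks = [offset + p - lo for p in _placement_marks(methylase, orientation, Lm)]
            fp = (-lo, Lr - lo)
            inside = tuple(p for p in marks if fp[0] <= p < fp[1])
            if not inside:
                continue
            out.append(
                CompositePlacement(
                    offset=offset,
                    orientation=orientation,
                    composite="".join(merged),
                    meth_positions=tuple(marks),
                    meth_in_footprint=inside,
                    footprint=fp,
                )
            )
    return out


def _e2(enzyme: EnzymeSpec, methylase: MethylaseSpec) -> bool:
    """E2 passes unless some placement of the methylase motif fully inside
    the restriction footprint is forced by every restriction-site occurrence
    (position-wise IUPAC subset test, either orientation)."""
    R = enzyme.recognition
    for M in {methylase.recognition, iupac_revcomp(methylase.recognition)}:
        for off in range(0, len(R) - len(M) + 1):
            window = R[off : off + len(M)]
            if iupac_subset(window, M):
                return False
    return True


def _e3(enzyme: EnzymeSpec, methylase: MethylaseSpec,
        placements: Sequence[CompositePlacement]) -> bool:
    """E3 passes iff some E1 placement keeps every methylase specificity base
    (non-N motif position outside the restriction footprint) out of the
    spacer + adhesive-end window downstream of the recognition."""
    for pl in placements:
        fs, fe = pl.footprint
        window = range(fe, fe + enzyme.cut_window)
        M = (methylase.recognition if pl.orientation == "+"
             else iupac_revcomp(methylase.recognition))
        start = pl.offset - min(0, pl.offset)
        bad = False
        for j, code in enumerate(M):
            pos = start + j
            if fs <= pos < fe or code == "N":
                continue
            if pos in window:
                bad = True
                break
        if not bad:
            return True
    return False


@dataclass(frozen=True)
class Desirables:
    active_37C: bool
    recognition_len_ge_5: bool
    single_subunit_orphan: bool
    central_modification: int  # distance of modified base from nearest footprint edge

    @property
    def count(self) -> int:
        return int(self.active_37C) + int(self.recognition_len_ge_5) + int(self.single_subunit_orphan)


@dataclass(frozen=True)
class ScreenReport:
    enzyme: str
    methylase: str
    placements: tuple[CompositePlacement, ...]
    E1_geometric: bool
    E1_empirical: str  # pass | fail | untested
    E2: bool
    E3: bool
    desirables: Desirables
    verdict: str  # 'candidate' or 'rejected(<reason>)'


def check_essential(enzyme: EnzymeSpec, methylase: MethylaseSpec) -> tuple[bool, bool, bool]:
    placements = enumerate_composites(enzyme, methylase)
    e1 = bool(placements)
    return e1, _e2(enzyme, methylase), e1 and _e3(enzyme, methylase, placements)


def check_desirable(
    methylase: MethylaseSpec, enzyme: Optional[EnzymeSpec] = None
) -> Desirables:
    central = 0
    if enzyme is not None:
        for pl in enumerate_composites(enzyme, methylase):
            fs, fe = pl.footprint
            for p in pl.meth_in_footprint:
                central = max(central, min(p - fs, fe - 1 - p))
    return Desirables(
        active_37C=methylase.active_37C,
        recognition_len_ge_5=len(methylase.recognition) >= 5,
        single_subunit_orphan=methylase.single_subunit and methylase.orphan_no_restriction,
        central_modification=central,
    )


def screen_one(enzyme: EnzymeSpec, methylase: MethylaseSpec) -> ScreenReport:
    placements = tuple(enumerate_composites(enzyme, methylase))
    e1, e2, e3 = check_essential(enzyme, methylase)
    if methylase.name in enzyme.blocked_by or enzyme.name in methylase.empirically_blocks:
        emp = "pass"
    else:
        emp = "untested"
    des = check_desirable(methylase, enzyme)
    if e1 and e2 and e3:
        verdict = "candidate"
    else:
        reasons = [c for c, ok in (("E1", e1), ("E2", e2), ("E3", e3)) if not ok]
        verdict = f"rejected({','.join(reasons)})"
    return ScreenReport(
        enzyme=enzyme.name, methylase=methylase.name, placements=placements,
        E1_geometric=e1, E1_empirical=emp, E2=e2, E3=e3,
        desirables=des, verdict=verdict,
    )


def screen_table(
    registry: dict[str, MethylaseSpec],
    enzyme: EnzymeSpec,
    tested: Sequence[str] = (),
) -> list[ScreenReport]:
    """Screen every registry methylase against ``enzyme``; ``tested`` names
    with no blocking evidence are reported as empirical failures.  Reports
    sort by (essential pass, empirical evidence, desirable count, central
    score), ties broken by name."""
    reports = []
    for name in sorted(registry):
        rep = screen_one(enzyme, registry[name])
        if rep.E1_empirical == "untested" and name in tested:
            rep = ScreenReport(**{**rep.__dict__, "E1_empirical": "fail"})
        reports.append(rep)
    emp_rank = {"pass": 2, "untested": 1, "fail": 0}
    return sorted(
        reports,
        key=lambda r: (
            -(r.verdict == "candidate"),
            -emp_rank[r.E1_empirical],
            -r.desirables.count,
            -r.desirables.central_modification,
            r.methylase,
        ),
    )


# --------------------------------------------------------------------------
# forbidden-site frequency statistics


def motif_probability(motif: str, gc: float) -> float:
    """Per-position probability that a random sequence with the given GC
    fraction matches the IUPAC motif: product over positions of the summed
    base probabilities, with p(G)=p(C)=gc/2 and p(A)=p(T)=(1-gc)/2."""
    if not 0 < gc < 1:
        raise InputError("gc fraction must be in (0, 1)")
    pbase = {"G": gc / 2, "C": gc / 2, "A": (1 - gc) / 2, "T": (1 - gc) / 2}
    prob = 1.0
    for code in motif.upper():
        if code not in IUPAC:
            raise InputError(f"bad IUPAC code {code!r}")
        prob *= sum(pbase[b] for b in IUPAC[code])
    return prob


def expected_spacing(motifs: Sequence[str], gc: float = 0.5) -> float:
    """Expected distance in bp between forbidden-site occurrences on random
    DNA: reciprocal of the summed per-bp hit probabilities.  Non-palindromic
    motifs are counted on both strands (x2); palindromic motifs once.
    Overlap between distinct motifs is ignored (independence approximation;
    negligible for the short non-degenerate motifs this is used on)."""
    if not motifs:
        raise InputError("no motifs")
    rate = 0.0
    for motif in motifs:
        p = motif_probability(motif, gc)
        rate += p if iupac_is_palindrome(motif) else 2 * p
    return 1.0 / rate


def format_spacing(spacing_bp: float) -> str:
    """Round to the reporting granularity used for forbidden-site
    frequencies: nearest kb above 1 kb, nearest 100 bp below."""
    if spacing_bp >= 1000:
        return f"1 per {round(spacing_bp / 1000)} kb"
    return f"1 per {int(round(spacing_bp / 100) * 100)} bp"


@dataclass(frozen=True)
class SiteStats:
    motifs: tuple[str, ...]
    gc: float
    per_bp_probability: float
    expected_spacing: float
    observed_count: Optional[int] = None
    scanned_length: Optional[int] = None

    @property
    def observed_spacing(self) -> Optional[float]:
        if self.observed_count is None or self.scanned_length is None:
            return None
        if self.observed_count == 0:
            return float(self.scanned_length)  # lower bound: > total length
        return self.scanned_length / self.observed_count


def empirical_spacing(
    mols: Sequence[DnaMolecule], motifs: Sequence[str], gc: float = 0.5
) -> SiteStats:
    """Observed forbidden-site spacing over a set of molecules (both strands,
    all motifs), for cross-checking the analytic expectation."""
    total = sum(len(m) for m in mols)
    if total == 0:
        raise InputError("no sequence to scan")
    count = 0
    for mol in mols:
        for motif in motifs:
            count += len(find_motif_sites(mol, motif))
    return SiteStats(
        motifs=tuple(m.upper() for m in motifs),
        gc=gc,
        per_bp_probability=1.0 / expected_spacing(motifs, gc),
        expected_spacing=expected_spacing(motifs, gc),
        observed_count=count,
        scanned_length=total,
    )
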