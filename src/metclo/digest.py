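"""Methylation-aware type IIS digestion into sticky-ended fragments, and the
end-joining compatibility relation used by the one-pot simulator.

Cut geometry
------------
For a site on the '+' strand with footprint ``[b, e)`` the enzyme cuts the
top strand at ``e + spacer`` and the bottom strand at ``e + spacer +
overhang_len``; a '-' strand site mirrors this (top cut at ``b - spacer -
overhang_len``, bottom at ``b - spacer``).  Either way ``top_cut <
bottom_cut`` (5' protrusions) and the overhang sequence is the top strand
over ``[top_cut, bottom_cut)``.

Fragment body convention
------------------------
A fragment's ``body`` is the top strand from its 5' cut position to the next
cut position, so on a circular substrate the body lengths of all fragments
sum exactly to the substrate length (each overhang is counted once, in the
fragment whose body starts with it).  The physical duplex extends
``overhang_len`` bases past the body on the bottom strand wherever the 3'
end is sticky; ``Fragment.length`` reports that physical extent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

from .core import (
    Annotation,
    DnaMolecule,
    EnzymeSpec,
    FragmentEnd,
    InputError,
    MethylMark,
    Segment,
    reverse_complement,
)
from .sites import SiteHit, find_motif_sites, is_blocked

__all__ = [
    "CutEvent",
    "Fragment",
    "DigestionResult",
    "cut_events",
    "digest",
    "ends_compatible",
    "flip_fragment",
    "ligate_chain",
    "ligate_cycle",
    "validate_shared_cut_pair",
    "GeometryReport",
]


@dataclass(frozen=True)
class CutEvent:
    site: SiteHit
    top_cut: int
    bottom_cut: int  # top-strand coordinate of the bottom-strand cut

    @property
    def overhang_interval(self) -> tuple[int, int]:
        return self.top_cut, self.bottom_cut


@dataclass(frozen=True)
class Fragment:
    """A sticky-ended digestion (or ligation-intermediate) product."""

    body: str
    end5: FragmentEnd
    end3: FragmentEnd
    marks: frozenset[MethylMark] = frozenset()
    annotations: tuple[Annotation, ...] = ()
    segments: tuple[Segment, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "marks", frozenset(self.marks))
        object.__setattr__(self, "annotations", tuple(self.annotations))
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def length(self) -> int:
        """Physical extent: body plus the bottom-strand protrusion at the 3'
        end (the convention under which a one-cut linear digest's two
        fragment lengths sum to parent length + overhang length)."""
        return len(self.body) + len(self.end3.overhang)

    @property
    def source_id(self) -> str:
        return self.segments[0].source_id if self.segments else ""


def _site_cuts(site: SiteHit, enzyme: EnzymeSpec, n: int, circular: bool) -> tuple[int, int]:
    v = enzyme.overhang_len
    if site.strand == "+":
        tc = site.end + enzyme.spacer
    else:
        tc = site.start - enzyme.spacer - v
    bc = tc + v
    if circular:
        return tc % n, (tc % n) + v
    return tc, bc


def cut_events(
    mol: DnaMolecule, enzyme: EnzymeSpec, rule: str = "any_mark"
) -> list[CutEvent]:
    """One CutEvent per unblocked, geometrically intact recognition site.

    On linear molecules a site whose footprint or cut interval falls off
    either end is inactive (it was severed by a previous cut or truncation).
    Emits a warning when two events' overhang intervals overlap without
    coinciding (such sites can destroy each other's cut products).
    """
    n = len(mol)
    events = []
    for site in find_motif_sites(mol, enzyme.recognition, owner=enzyme.name):
        if is_blocked(site, mol, enzyme, rule=rule):
            continue
        tc, bc = _site_cuts(site, enzyme, n, mol.is_circular)
        if not mol.is_circular:
            if site.start < 0 or site.end > n or tc < 1 or bc > n:
                continue
        events.append(CutEvent(site=site, top_cut=tc, bottom_cut=bc))
    # geometry check: overlapping but non-identical overhang intervals
    ivs = sorted({(e.top_cut, e.bottom_cut) for e in events})
    for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
        if a2 < b1 and (a1, b1) != (a2, b2):
            warnings.warn(
                f"{mol.id}: cut intervals [{a1},{b1}) and [{a2},{b2}) overlap "
                "inconsistently; sites may destroy each other"
            )
    return events


def _fragment_between(
    mol: DnaMolecule, tc_from: int, tc_to: int, v: int, end5: FragmentEnd, end3: FragmentEnd
) -> Fragment:
    """Build the fragment whose body spans [tc_from, tc_to) on the top strand."""
    n = len(mol)
    body = mol.subseq(tc_from, tc_to)
    B = len(body)
    if B == 0:
        body = mol.sequence if mol.is_circular else ""
        B = len(body)

    def rel(pos: int) -> Optional[int]:
        d = (pos - tc_from) % n if mol.is_circular else pos - tc_from
        return d if 0 <= d < B else None

    marks = set()
    for m in mol.marks:
        p = rel(m.position)
        if p is not None:
            marks.add(replace(m, position=p))
    anns = []
    for a in mol.annotations:
        s, e = rel(a.start), rel((a.end - 1) % n if mol.is_circular else a.end - 1)
        if s is not None and e is not None and e >= s:
            anns.append(replace(a, start=s, end=e + 1))
    segs = [Segment(mol.id, 0, B, "+", mol.role)]
    for g in mol.segments:
        s, e = rel(g.start), rel((g.end - 1) % n if mol.is_circular else g.end - 1)
        if s is not None and e is not None and e >= s:
            segs.append(replace(g, start=s, end=e + 1))
    return Fragment(
        body=body, end5=end5, end3=end3,
        marks=frozenset(marks), annotations=tuple(anns), segments=tuple(segs),
    )


@dataclass(frozen=True)
class DigestionResult:
    fragments: tuple[Fragment, ...]
    events: tuple[CutEvent, ...]
    undigested: Optional[DnaMolecule] = None  # set when zero breaks occurred


def digest(mol: DnaMolecule, enzyme: EnzymeSpec, rule: str = "any_mark") -> DigestionResult:
    """Digest to completion (fixed point).

    Coincident cut intervals from head-to-head site pairs merge into a single
    double-strand break.  A circular molecule with k distinct breaks yields k
    fragments; a linear one k+1; zero breaks returns the molecule unchanged
    in ``undigested``.
    """
    events = cut_events(mol, enzyme, rule=rule)
    v = enzyme.overhang_len
    breaks = sorted({e.top_cut for e in events})
    if not breaks:
        return DigestionResult(fragments=(), events=tuple(events), undigested=mol)

    frags: list[Fragment] = []
    if mol.is_circular:
        for i, tc in enumerate(breaks):
            nxt = breaks[(i + 1) % len(breaks)]
            e5 = FragmentEnd("five_prime", mol.subseq(tc, tc + v))
            e3 = FragmentEnd("five_prime", reverse_complement(mol.subseq(nxt, nxt + v)))
            frags.append(_fragment_between(mol, tc, nxt, v, e5, e3))
    else:
        bounds = [0] + breaks + [len(mol)]
        for i in range(len(bounds) - 1):
            a, b = bounds[i], bounds[i + 1]
            e5 = mol.end5 if i == 0 else FragmentEnd("five_prime", mol.subseq(a, a + v))
            e3 = (
                mol.end3
                if i == len(bounds) - 2
                else FragmentEnd("five_prime", reverse_complement(mol.subseq(b, b + v)))
            )
            frags.append(_fragment_between(mol, a, b, v, e5, e3))
    # fixed point: re-digesting the pieces finds nothing new, because sites
    # whose footprint or cut window was severed are inactive on linear pieces;
    # assert-by-construction rather than recursing (single simultaneous round).
    return DigestionResult(fragments=tuple(frags), events=tuple(events), undigested=None)


def ends_compatible(a: FragmentEnd, b: FragmentEnd) -> bool:
    """True iff two sticky ends can ligate: same protrusion type, equal
    overhang length, and mutually reverse-complementary overhangs.
    Blunt-blunt joining is disabled (T4 blunt ligation is suppressed under
    cycling conditions and never intended in this assembly chemistry)."""
    if a.protrusion == "blunt" or b.protrusion == "blunt":
        return False
    if a.protrusion != b.protrusion or len(a.overhang) != len(b.overhang):
        return False
    return a.overhang == reverse_complement(b.overhang)


def flip_fragment(f: Fragment) -> Fragment:
    """The same physical duplex read from the other strand."""
    v5, v3 = len(f.end5.overhang), len(f.end3.overhang)
    B = len(f.body)
    core = f.body[v5:]
    new_body = f.end3.overhang + reverse_complement(core)
    marks = set()
    for m in f.marks:
        q = B + v3 - 1 - m.position
        if 0 <= q < len(new_body):
            marks.add(replace(m, position=q, strand="-" if m.strand == "+" else "+"))
    segs = []
    for g in f.segments:
        s, e = B + v3 - g.end, B + v3 - g.start
        s, e = max(0, s), min(len(new_body), e)
        if e > s:
            segs.append(replace(g, start=s, end=e, orient="-" if g.orient == "+" else "+"))
    anns = []
    for a in f.annotations:
        s, e = B + v3 - a.end, B + v3 - a.start
        s, e = max(0, s), min(len(new_body), e)
        if e > s:
            anns.append(replace(a, start=s, end=e, strand="-" if a.strand == "+" else "+"))
    return Fragment(
        body=new_body, end5=f.end3, end3=f.end5,
        marks=frozenset(marks), annotations=tuple(anns), segments=tuple(segs),
    )


def _shift(f: Fragment, off: int):
    marks = [replace(m, position=m.position + off) for m in f.marks]
    anns = [replace(a, start=a.start + off, end=a.end + off) for a in f.annotations]
    segs = [replace(g, start=g.start + off, end=g.end + off) for g in f.segments]
    return marks, anns, segs


def ligate_chain(frags: list[Fragment]) -> Fragment:
    """Join fragments end-to-end (each junction must be compatible)."""
    if not frags:
        raise InputError("nothing to ligate")
    for a, b in zip(frags, frags[1:]):
        if not ends_compatible(a.end3, b.end5):
            raise InputError("incompatible junction in chain")
    body, marks, anns, segs = "", [], [], []
    for f in frags:
        m, a, g = _shift(f, len(body))
        body += f.body
        marks += m
        anns += a
        segs += g
    return Fragment(
        body=body, end5=frags[0].end5, end3=frags[-1].end3,
        marks=frozenset(marks), annotations=tuple(anns), segments=tuple(segs),
    )


def ligate_cycle(frags: list[Fragment], product_id: str = "product") -> DnaMolecule:
    """Circularize an ordered chain of fragments (the closing junction must
    also be compatible); returns the product molecule with per-fragment
    provenance segments."""
    chain = ligate_chain(frags)
    if not ends_compatible(chain.end3, chain.end5):
        raise InputError("chain ends are not mutually compatible; cannot circularize")
    # keep only top-level provenance (one segment per input fragment)
    offs, segs = 0, []
    for f in frags:
        src = f.segments[0] if f.segments else Segment("?", 0, len(f.body))
        segs.append(Segment(src.source_id, offs, offs + len(f.body), src.orient, src.role))
        offs += len(f.body)
    return DnaMolecule(
        id=product_id,
        sequence=chain.body,
        topology="circular",
        marks=chain.marks,
        annotations=chain.annotations,
        role="product",
        segments=tuple(segs),
    )


@dataclass(frozen=True)
class GeometryReport:
    head_to_head: bool
    shared: bool
    overhang: str = ""
    message: str = ""


def validate_shared_cut_pair(
    mol: DnaMolecule, enzyme: EnzymeSpec, pair: tuple[SiteHit, SiteHit]
) -> GeometryReport:
    """Check the nicking-assay geometry: two head-to-head sites whose cut
    intervals coincide exactly, so that even single-strand nicking at either
    site produces a double-strand break there."""
    a, b = pair
    if a.strand == b.strand:
        return GeometryReport(False, False, message="sites are tandem, not head-to-head")
    plus, minus = (a, b) if a.strand == "+" else (b, a)
    n = len(mol)
    ca = _site_cuts(plus, enzyme, n, mol.is_circular)
    cb = _site_cuts(minus, enzyme, n, mol.is_circular)
    # facing check: each site's cut interval lies off its footprint toward the other
    gap_plus = (cb[0] - plus.end) % n if mol.is_circular else cb[0] - plus.end
    gap_minus = (minus.start - ca[1]) % n if mol.is_circular else minus.start - ca[1]
    facing = 0 <= gap_plus <= n // 2 and 0 <= gap_minus <= n // 2
    if not facing:
        return GeometryReport(False, False, message="sites do not face each other")
    if ca == cb:
        return GeometryReport(True, True, overhang=mol.subseq(ca[0], ca[1]))
    return GeometryReport(True, False, message=f"cut intervals {ca} vs {cb} not shared")
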