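"""Site scanning, switchability classification, strain methylation and
per-site blocking decisions.

A *methylation-switchable* restriction site is one whose footprint overlaps a
methylase occurrence such that a methylated base falls **inside** the
restriction recognition footprint.  Switchability is purely a property of the
sequence geometry; whether a site is *blocked* additionally depends on the
current methylation marks.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional

from .core import (
    DnaMolecule,
    EnzymeSpec,
    InputError,
    MethylMark,
    MethylaseSpec,
    StrainProfile,
    iupac_is_palindrome,
    iupac_revcomp,
    iupac_to_regex,
)

__all__ = [
    "SiteHit",
    "find_motif_sites",
    "classify_switchable",
    "potential_marks",
    "apply_strain",
    "clear_marks",
    "is_blocked",
    "DAM",
    "DCM",
]

# Native E. coli maintenance methylases, modelled like any other methylase.
from .core import MethylaseSpec as _M

DAM = _M("Dam", "GATC", 1, "m6A", meth_offset_bottom=1)
DCM = _M("Dcm", "CCWGG", 1, "m5C", meth_offset_bottom=1)


@dataclass(frozen=True)
class SiteHit:
    """A located recognition-site occurrence.

    ``start`` / ``length`` give the footprint in top-strand coordinates
    (``start`` may be near the end of a circle with the footprint wrapping).
    For strand '-', the motif matches the bottom strand; the footprint is
    still reported in top-strand coordinates.
    """

    owner: str
    strand: str
    start: int
    length: int
    switchable: bool = False
    blocked: bool = False

    @property
    def end(self) -> int:
        return self.start + self.length

    def covers(self, pos: int, n: int, circular: bool) -> bool:
        if circular:
            return (pos - self.start) % n < self.length
        return self.start <= pos < self.end


def find_motif_sites(
    mol: DnaMolecule,
    motif: str,
    strands: str = "both",
    owner: str = "",
) -> list[SiteHit]:
    """All occurrences of an IUPAC ``motif`` on ``mol``.

    Origin-spanning occurrences on circles are found and reported once, with
    ``start`` given modulo the length.  Bottom-strand occurrences are reported
    with strand '-' and top-strand footprint coordinates.  Palindromic motifs
    are reported once (strand '+') per footprint.
    """
    motif = motif.upper()
    L = len(motif)
    n = len(mol)
    if L > n:
        warnings.warn(f"motif {motif} longer than molecule {mol.id}; no hits")
        return []
    search = mol.sequence + (mol.sequence[: L - 1] if mol.is_circular and L > 1 else "")
    palindrome = iupac_is_palindrome(motif)
    hits: dict[tuple[int, str], SiteHit] = {}

    def scan(pattern: str, strand: str):
        rx = re.compile("(?=(" + iupac_to_regex(pattern) + "))")
        for m in rx.finditer(search):
            start = m.start() % n
            key = (start, "+" if palindrome else strand)
            if key not in hits:
                hits[key] = SiteHit(owner=owner, strand=key[1], start=start, length=L)

    if strands in ("both", "top"):
        scan(motif, "+")
    if strands in ("both", "bottom") and not (palindrome and strands == "both"):
        scan(iupac_revcomp(motif), "-")
    elif strands == "both" and palindrome:
        scan(iupac_revcomp(motif), "+")  # same footprints; dedup by key
    return sorted(hits.values(), key=lambda h: (h.start, h.strand))


def potential_marks(mol: DnaMolecule, methylase: MethylaseSpec) -> set[MethylMark]:
    """Every mark the methylase would deposit on ``mol`` (without applying).

    For a top-strand occurrence at ``[k, k+L)``: the top mark sits at
    ``k + meth_offset_top``; the bottom mark (if the enzyme methylates both
    strands) at ``k + L - 1 - meth_offset_bottom``.  Bottom-strand
    occurrences are the mirror image.  Hemimethylating enzymes mark only the
    strand their motif occurs on.
    """
    L = len(methylase.recognition)
    n = len(mol)
    out: set[MethylMark] = set()
    for hit in find_motif_sites(mol, methylase.recognition, owner=methylase.name):
        k = hit.start
        mt, mb = methylase.meth_offset_top, methylase.meth_offset_bottom
        if hit.strand == "+" or methylase.is_palindromic:
            out.add(MethylMark((k + mt) % n, "+", methylase.modification, methylase.name))
            if mb is not None:
                out.add(MethylMark((k + L - 1 - mb) % n, "-", methylase.modification, methylase.name))
        if hit.strand == "-" or methylase.is_palindromic:
            # motif reads 5'->3' on the bottom strand, right-to-left in top coords
            out.add(MethylMark((k + L - 1 - mt) % n, "-", methylase.modification, methylase.name))
            if mb is not None:
                out.add(MethylMark((k + mb) % n, "+", methylase.modification, methylase.name))
    return out


def classify_switchable(
    mol: DnaMolecule, enzyme: EnzymeSpec, methylase: MethylaseSpec
) -> list[SiteHit]:
    """Restriction-site hits flagged switchable iff some methylase occurrence
    (either strand) places a methylated base inside the restriction footprint.

    Independent of the molecule's current marks: switchability is geometry.
    """
    n = len(mol)
    marks = potential_marks(mol, methylase)
    hits = []
    for h in find_motif_sites(mol, enzyme.recognition, owner=enzyme.name):
        sw = any(h.covers(m.position, n, mol.is_circular) for m in marks)
        hits.append(replace(h, switchable=sw))
    return hits


def apply_strain(
    mol: DnaMolecule,
    strain: StrainProfile,
    registry: dict[str, MethylaseSpec],
) -> DnaMolecule:
    """Return the molecule as prepared in ``strain``: marks added at every
    occurrence of each expressed methylase (existing marks preserved).
    Idempotent: applying the same strain twice adds nothing new."""
    specs = []
    for name in sorted(strain.methylases):
        if name not in registry:
            raise InputError(f"strain {strain.name!r} references unknown methylase {name!r}")
        specs.append(registry[name])
    if strain.dam_active:
        specs.append(DAM)
    if strain.dcm_active:
        specs.append(DCM)
    marks = set(mol.marks)
    for spec in specs:
        marks |= potential_marks(mol, spec)
    return mol.with_marks(marks)


def clear_marks(mol: DnaMolecule) -> DnaMolecule:
    """Demethylate: model of propagating the plasmid through a strain with no
    switch methylase, which dilutes out all marks."""
    return mol.with_marks(frozenset())


def is_blocked(
    site: SiteHit,
    mol: DnaMolecule,
    enzyme: Optional[EnzymeSpec] = None,
    rule: str = "any_mark",
) -> bool:
    """Decide whether a restriction site is uncuttable under the current marks.

    rule='any_mark' (default): any mark on either strand within the
    recognition footprint blocks.  rule='empirical': only marks deposited by
    a methylase listed in ``enzyme.blocked_by`` block (for enzymes whose
    blocking was screened empirically and some overlapping methylations are
    known not to protect).
    """
    n = len(mol)
    for m in mol.marks:
        if not site.covers(m.position, n, mol.is_circular):
            continue
        if rule == "any_mark":
            return True
        if rule == "empirical":
            if enzyme is None:
                raise InputError("empirical rule requires the enzyme spec")
            if m.source is not None and m.source in enzyme.blocked_by:
                return True
    return False
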