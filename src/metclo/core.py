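"""Core data model: double-stranded DNA molecules with per-base, per-strand
methylation marks, and the enzyme/methylase/strain chemistry definitions.

Coordinate conventions used throughout the package
--------------------------------------------------
* All features live in **top-strand coordinates**, 0-based, half-open.
* Bottom-strand features keep top-strand coordinates plus a strand flag.
* On circular molecules every index is reduced modulo the length, and
  features may span the origin.
* A *cut position* ``i`` denotes the phosphodiester bond between bases
  ``i-1`` and ``i`` (so cutting a circle at positions ``i`` and ``j``
  yields top-strand pieces ``[i, j)`` and ``[j, i)``).

Methylation is binary per (position, strand): a base either carries a
modification or it does not.  This mirrors the on/off behaviour of in-vivo
methylation assays, where a site prepared in a methylase-expressing strain
is either cleavable or fully protected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "IUPAC",
    "COMPLEMENT",
    "DnaMolecule",
    "MethylMark",
    "EnzymeSpec",
    "MethylaseSpec",
    "StrainProfile",
    "Annotation",
    "reverse_complement",
    "canonicalize",
    "iupac_to_regex",
    "iupac_revcomp",
    "iupac_is_palindrome",
    "iupac_subset",
    "iupac_intersect",
    "expand_iupac",
]

# IUPAC nucleotide codes -> set of concrete bases
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_SET_TO_CODE = {v: k for k, v in IUPAC.items()}

COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


class InputError(ValueError):
    """Raised on malformed user input (sequences, motifs, configs)."""


def _check_alphabet(seq: str, alphabet: Iterable[str], what: str) -> None:
    bad = set(seq.upper()) - set(alphabet)
    if bad:
        raise InputError(f"{what} contains non-IUPAC characters: {sorted(bad)!r}")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; degenerate IUPAC codes map to their
    complements (e.g. ``R`` -> ``Y``)."""
    seq = seq.upper()
    _check_alphabet(seq, COMPLEMENT, "sequence")
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def iupac_revcomp(motif: str) -> str:
    return reverse_complement(motif)


def iupac_is_palindrome(motif: str) -> bool:
    """Degenerate-aware palindrome test: the motif describes the same set of
    duplexes as its own reverse complement."""
    return motif.upper() == iupac_revcomp(motif)


def iupac_to_regex(motif: str) -> str:
    """Translate an IUPAC motif into a regex character-class pattern."""
    motif = motif.upper()
    _check_alphabet(motif, IUPAC, "motif")
    out = []
    for b in motif:
        s = sorted(IUPAC[b])
        out.append(s[0] if len(s) == 1 else "[" + "".join(s) + "]")
    return "".join(out)


def iupac_subset(a: str, b: str) -> bool:
    """True if every concrete sequence matching ``a`` also matches ``b``
    (position-by-position set inclusion; motifs must be the same length)."""
    if len(a) != len(b):
        return False
    return all(IUPAC[x.upper()] <= IUPAC[y.upper()] for x, y in zip(a, b))


def iupac_intersect(a: str, b: str) -> Optional[str]:
    """Position-wise intersection of two same-length IUPAC motifs, or None if
    they are not simultaneously satisfiable."""
    if len(a) != len(b):
        raise InputError("intersection requires equal-length motifs")
    out = []
    for x, y in zip(a.upper(), b.upper()):
        s = IUPAC[x] & IUPAC[y]
        if not s:
            return None
        out.append(_SET_TO_CODE[frozenset(s)])
    return "".join(out)


def expand_iupac(motif: str) -> list[str]:
    """All concrete sequences matching a degenerate motif (use on short motifs
    only; the expansion is exponential in the number of degenerate positions)."""
    seqs = [""]
    for b in motif.upper():
        seqs = [s + c for s in seqs for c in sorted(IUPAC[b])]
    return seqs


# --------------------------------------------------------------------------
# marks, annotations


@dataclass(frozen=True)
class MethylMark:
    """A methylated base: top-strand position, strand, and modification type.

    ``source`` records which methylase deposited the mark (informational;
    excluded from equality so re-applying a strain is idempotent).
    """

    position: int
    strand: str  # '+' or '-'
    modification: str  # m6A | m5C | m4C
    source: Optional[str] = field(default=None, compare=False)

    def __post_init__(self):
        if self.strand not in "+-":
            raise InputError(f"bad strand {self.strand!r}")
        if self.modification not in ("m6A", "m5C", "m4C"):
            raise InputError(f"bad modification {self.modification!r}")


@dataclass(frozen=True)
class Annotation:
    label: str
    start: int
    end: int  # half-open; may be < start on circles (origin-spanning)
    strand: str = "+"


@dataclass(frozen=True)
class FragmentEnd:
    """One extremity of a linear duplex.

    ``overhang`` is the protruding strand read 5'->3'; empty iff blunt.
    """

    protrusion: str = "blunt"  # five_prime | three_prime | blunt
    overhang: str = ""

    def __post_init__(self):
        if (self.protrusion == "blunt") != (self.overhang == ""):
            raise InputError("overhang must be empty iff blunt")


@dataclass(frozen=True)
class Segment:
    """Provenance of a stretch of a ligation product: which source molecule it
    came from, where it sits in the product, and its orientation there."""

    source_id: str
    start: int
    end: int
    orient: str = "+"
    role: str = "generic"


@dataclass(frozen=True)
class DnaMolecule:
    """A double-stranded DNA molecule (the top strand is stored 5'->3').

    Circular molecules compare equal under rotation and strand flip after
    :func:`canonicalize`.  Linear molecules carry two :class:`FragmentEnd`
    descriptors (blunt by default).
    """

    id: str
    sequence: str
    topology: str = "circular"  # circular | linear
    marks: frozenset[MethylMark] = frozenset()
    annotations: tuple[Annotation, ...] = ()
    role: str = "generic"  # donor|acceptor|product|marker|generic
    end5: FragmentEnd = FragmentEnd()
    end3: FragmentEnd = FragmentEnd()
    segments: tuple[Segment, ...] = ()

    def __post_init__(self):
        seq = self.sequence.upper()
        if not seq:
            raise InputError("empty sequence")
        _check_alphabet(seq, "ACGT", f"molecule {self.id!r}")
        object.__setattr__(self, "sequence", seq)
        if self.topology not in ("circular", "linear"):
            raise InputError(f"bad topology {self.topology!r}")
        object.__setattr__(self, "marks", frozenset(self.marks))
        object.__setattr__(self, "annotations", tuple(self.annotations))
        object.__setattr__(self, "segments", tuple(self.segments))
        n = len(seq)
        for m in self.marks:
            if not 0 <= m.position < n:
                raise InputError(f"mark position {m.position} outside molecule")
            base = seq[m.position]
            want = {"m6A": "AT", "m5C": "CG", "m4C": "CG"}[m.modification]
            # top-strand modification sits on the base itself; bottom-strand on its complement
            ok = base == want[0] if m.strand == "+" else base == want[1]
            if not ok:
                raise InputError(
                    f"{m.modification} mark on {m.strand} strand at {m.position} "
                    f"is inconsistent with top-strand base {base}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def base_at(self, pos: int) -> str:
        return self.sequence[pos % len(self)]

    def subseq(self, start: int, end: int) -> str:
        """Top-strand sequence of [start, end); wraps the origin on circles."""
        n = len(self)
        if self.is_circular:
            start %= n
            end %= n
            if end > start:
                return self.sequence[start:end]
            return self.sequence[start:] + self.sequence[:end]
        if not (0 <= start <= end <= n):
            raise InputError(f"interval [{start},{end}) outside linear molecule")
        return self.sequence[start:end]

    def with_marks(self, marks: Iterable[MethylMark]) -> "DnaMolecule":
        return replace(self, marks=frozenset(marks))


# --------------------------------------------------------------------------
# chemistry


@dataclass(frozen=True)
class EnzymeSpec:
    """A type IIS restriction enzyme: asymmetric recognition motif plus
    downstream cut geometry.

    ``spacer`` is the number of unspecified bases between the recognition
    3' end and the top-strand cut; the bottom strand is cut ``overhang_len``
    further along, producing a 5' protrusion (e.g. BsaI = GGTCTC(1/5):
    spacer 1, overhang 4).
    """

    name: str
    recognition: str
    spacer: int
    overhang_len: int
    blocked_by: tuple[str, ...] = ()

    def __post_init__(self):
        _check_alphabet(self.recognition, IUPAC, "recognition motif")
        object.__setattr__(self, "recognition", self.recognition.upper())
        if self.spacer < 0:
            raise InputError("spacer must be >= 0")
        if self.overhang_len < 1:
            raise InputError("overhang_len must be >= 1")
        object.__setattr__(self, "blocked_by", tuple(self.blocked_by))

    @property
    def site_len(self) -> int:
        return len(self.recognition)

    @property
    def cut_window(self) -> int:
        """Bases downstream of the recognition covered by spacer + overhang."""
        return self.spacer + self.overhang_len


@dataclass(frozen=True)
class MethylaseSpec:
    """A site-specific DNA methyltransferase.

    ``meth_offset_top`` is the index of the modified base within a top-strand
    occurrence of the motif; ``meth_offset_bottom`` is the index of the
    modified base within the motif's bottom-strand complement (read 5'->3' on
    the bottom strand).  A methylase with no bottom offset is hemimethylating:
    it marks only the strand on which its motif occurs.
    """

    name: str
    recognition: str
    meth_offset_top: int
    modification: str  # m6A | m5C | m4C
    meth_offset_bottom: Optional[int] = None
    active_37C: bool = True
    single_subunit: bool = False
    orphan_no_restriction: bool = False
    empirically_blocks: tuple[str, ...] = ()
    synthetic: bool = False  # True for constructed stand-in motifs

    def __post_init__(self):
        _check_alphabet(self.recognition, IUPAC, "recognition motif")
        object.__setattr__(self, "recognition", self.recognition.upper())
        L = len(self.recognition)
        want = {"m6A": "A", "m5C": "C", "m4C": "C"}[self.modification]
        if not 0 <= self.meth_offset_top < L:
            raise InputError("meth_offset_top outside motif")
        if want not in IUPAC[self.recognition[self.meth_offset_top]]:
            raise InputError(
                f"{self.name}: top offset {self.meth_offset_top} cannot be {want}"
            )
        if self.meth_offset_bottom is not None:
            if not 0 <= self.meth_offset_bottom < L:
                raise InputError("meth_offset_bottom outside motif")
            bottom = iupac_revcomp(self.recognition)
            if want not in IUPAC[bottom[self.meth_offset_bottom]]:
                raise InputError(
                    f"{self.name}: bottom offset {self.meth_offset_bottom} cannot be {want}"
                )
        object.__setattr__(self, "empirically_blocks", tuple(self.empirically_blocks))

    @property
    def is_palindromic(self) -> bool:
        return iupac_is_palindrome(self.recognition)


@dataclass(frozen=True)
class StrainProfile:
    """An E. coli host: which switch methylases it expresses, plus the native
    Dam/Dcm systems (off by default; the shipped enzymes are insensitive)."""

    name: str
    methylases: frozenset[str] = frozenset()
    dam_active: bool = False
    dcm_active: bool = False

    def __post_init__(self):
        object.__setattr__(self, "methylases", frozenset(self.methylases))


NORMAL_STRAIN = StrainProfile("DH10B")


# --------------------------------------------------------------------------
# canonical form


def _least_rotation(s: str) -> int:
    """Booth's algorithm: index of the lexicographically minimal rotation."""
    s2 = s + s
    n = len(s2)
    f = [-1] * n
    k = 0
    for j in range(1, n):
        sj = s2[j]
        i = f[j - k - 1]
        while i != -1 and sj != s2[k + i + 1]:
            if sj < s2[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s2[k + i + 1]:
            if sj < s2[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def _rotate(mol: DnaMolecule, r: int) -> DnaMolecule:
    n = len(mol)
    r %= n
    seq = mol.sequence[r:] + mol.sequence[:r]
    marks = frozenset(
        replace(m, position=(m.position - r) % n) for m in mol.marks
    )
    anns = tuple(
        replace(a, start=(a.start - r) % n, end=(a.end - r) % n) for a in mol.annotations
    )
    segs = tuple(
        replace(s, start=(s.start - r) % n, end=(s.end - r) % n) for s in mol.segments
    )
    return replace(mol, sequence=seq, marks=marks, annotations=anns, segments=segs)


def _flip(mol: DnaMolecule) -> DnaMolecule:
    """Strand flip of a circular molecule (top strand becomes the reverse
    complement; features move with the physical bases)."""
    n = len(mol)
    seq = reverse_complement(mol.sequence)
    marks = frozenset(
        replace(m, position=n - 1 - m.position, strand="-" if m.strand == "+" else "+")
        for m in mol.marks
    )

    def flip_iv(start, end):
        return (n - end) % n, (n - start) % n

    anns = []
    for a in mol.annotations:
        s, e = flip_iv(a.start, a.end)
        anns.append(replace(a, start=s, end=e, strand="-" if a.strand == "+" else "+"))
    segs = []
    for g in mol.segments:
        s, e = flip_iv(g.start, g.end)
        segs.append(replace(g, start=s, end=e, orient="-" if g.orient == "+" else "+"))
    return replace(mol, sequence=seq, marks=marks, annotations=tuple(anns), segments=tuple(segs))


def canonicalize(mol: DnaMolecule) -> DnaMolecule:
    """Rotate a circular molecule to its lexicographically minimal rotation
    over both strands (linear molecules are returned unchanged).  The result
    is a deterministic representative of the rotation/flip equivalence class,
    so two physically identical circles canonicalize to equal sequences."""
    if not mol.is_circular:
        return mol
    fwd = _rotate(mol, _least_rotation(mol.sequence))
    flipped = _flip(mol)
    rev = _rotate(flipped, _least_rotation(flipped.sequence))
    return fwd if fwd.sequence <= rev.sequence else rev


def canonical_sequence(mol: DnaMolecule) -> str:
    return canonicalize(mol).sequence
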