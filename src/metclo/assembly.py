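"""One-pot restriction-ligation simulation.

The simulator digests every input molecule, builds the compatibility graph
of sticky fragment ends, enumerates circular ligation products (bounded
depth-first search, each fragment used at most once by default), and keeps
the products that carry zero cleavable sites for the reaction enzyme under
their current methylation marks -- the only species that survive cycling of
restriction and ligation.  Selection is modelled as a filter: a surviving
product must carry the acceptor's positive-marker annotation and must not
carry the negative marker (LacZ-alpha in the shipped vector designs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import DnaMolecule, EnzymeSpec, InputError, canonical_sequence
from .digest import (
    Fragment,
    digest,
    ends_compatible,
    flip_fragment,
    ligate_cycle,
    cut_events,
)
from .core import reverse_complement
from .sites import clear_marks as _clear_marks

__all__ = [
    "OnePotOptions",
    "AssemblyOutcome",
    "JunctionReport",
    "one_pot",
    "junction_report",
    "release_insert",
    "cross_reactivity_check",
    "StillMethylatedError",
]

MARKER_PREFIX = "marker:"
NEGMARK_PREFIX = "negmark:"


@dataclass(frozen=True)
class OnePotOptions:
    max_cycle_len: Optional[int] = None  # default: number of input molecules + 1
    max_fragment_copies: int = 1  # >1 surfaces tandem-multimer artifacts
    apply_selection: bool = True
    max_cycles: int = 100_000  # hard cap on enumeration, with warning


@dataclass(frozen=True)
class AssemblyOutcome:
    resistant_products: tuple[DnaMolecule, ...]
    nonresistant_cycles_seen: int
    warnings: tuple[str, ...] = ()

    @property
    def failed(self) -> bool:
        return not self.resistant_products


@dataclass(frozen=True)
class JunctionReport:
    junctions: tuple[tuple[str, str, str], ...]  # (upstream id, fusion seq, downstream id)

    def __len__(self):
        return len(self.junctions)


def _enumerate_cycles(frags: list[Fragment], max_len: int, max_copies: int, cap: int):
    """Yield tuples of oriented fragments forming compatible circles.

    Each fragment index participates at most ``max_copies`` times per cycle
    regardless of orientation.  Rotational duplicates are avoided by anchoring
    every cycle at its minimal participating index in '+' orientation;
    reversed traversals (the same molecule read from the other strand) are
    excluded by the same anchoring.
    """
    oriented = [(i, o, f if o == "+" else flip_fragment(f)) for i, f in enumerate(frags) for o in "+-"]
    count = 0
    for start_idx, start_o, start_f in oriented:
        if start_o != "+":
            continue
        if start_f.end5.protrusion == "blunt":
            continue
        stack = [(start_f, [(start_idx, start_o, start_f)], {start_idx: 1})]
        while stack:
            cur, chain, used = stack.pop()
            if ends_compatible(chain[-1][2].end3, start_f.end5) and len(chain) >= 1:
                count += 1
                if count > cap:
                    return
                yield [c[2] for c in chain]
            if len(chain) >= max_len:
                continue
            for j, o, g in reversed(oriented):
                if j < start_idx or used.get(j, 0) >= max_copies:
                    continue
                if ends_compatible(chain[-1][2].end3, g.end5):
                    u2 = dict(used)
                    u2[j] = u2.get(j, 0) + 1
                    stack.append((g, chain + [(j, o, g)], u2))


def one_pot(
    vector: DnaMolecule,
    donors: Sequence[DnaMolecule],
    enzyme: EnzymeSpec,
    opts: OnePotOptions = OnePotOptions(),
) -> AssemblyOutcome:
    """Simulate a one-pot restriction-ligation assembly.

    The vector is expected to arrive already prepared (methylation marks
    applied by the caller via :func:`metclo.sites.apply_strain`); donors are
    typically unmarked.  Returns every enzyme-resistant circular product that
    passes selection, in deterministic (canonical-sequence) order.
    """
    inputs = [vector, *donors]
    max_len = opts.max_cycle_len or (len(inputs) + 1)
    warnings_: list[str] = []

    frags: list[Fragment] = []
    candidates: dict[str, DnaMolecule] = {}
    for mol in inputs:
        res = digest(mol, enzyme)
        frags.extend(res.fragments)
        if res.undigested is not None:
            candidates.setdefault(canonical_sequence(mol), mol)

    n_seen = 0
    produced = 0
    for chain in _enumerate_cycles(frags, max_len, opts.max_fragment_copies, opts.max_cycles):
        produced += 1
        product = ligate_cycle(chain, product_id=f"assembly_{produced}")
        candidates.setdefault(canonical_sequence(product), product)
    if produced >= opts.max_cycles:
        warnings_.append(f"cycle enumeration capped at {opts.max_cycles}")

    vec_markers = {a.label for a in vector.annotations if a.label.startswith(MARKER_PREFIX)}
    resistant = []
    for key in sorted(candidates):
        prod = candidates[key]
        if cut_events(prod, enzyme):
            n_seen += 1
            continue
        if opts.apply_selection:
            labels = {a.label for a in prod.annotations}
            if any(l.startswith(NEGMARK_PREFIX) for l in labels):
                n_seen += 1
                continue
            if vec_markers and not (labels & vec_markers):
                n_seen += 1
                continue
        resistant.append(prod)

    if not resistant:
        warnings_.append("assembly failed: no resistant product containing the backbone")
    elif len(resistant) > 1:
        warnings_.append(f"ambiguous assembly: {len(resistant)} resistant products")
    return AssemblyOutcome(
        resistant_products=tuple(resistant),
        nonresistant_cycles_seen=n_seen,
        warnings=tuple(warnings_),
    )


def junction_report(product: DnaMolecule, overhang_len: int = 4) -> JunctionReport:
    """Ordered junction list of a one-pot product, starting from the backbone
    (acceptor-derived) segment; each junction reports the fusion-site
    sequence read from the product at the downstream segment's start."""
    if not product.segments:
        raise InputError("product has no provenance segments")
    segs = sorted(product.segments, key=lambda s: s.start)
    anchor = next((i for i, s in enumerate(segs) if s.role == "acceptor"), 0)
    segs = segs[anchor:] + segs[:anchor]
    juncs = []
    for i, seg in enumerate(segs):
        nxt = segs[(i + 1) % len(segs)]
        fusion = product.subseq(nxt.start, nxt.start + overhang_len)
        juncs.append((seg.source_id, fusion, nxt.source_id))
    return JunctionReport(junctions=tuple(juncs))


class StillMethylatedError(InputError):
    pass


def release_insert(product: DnaMolecule, enzyme: EnzymeSpec) -> Fragment:
    """Release the assembled insert from a product that has been passed
    through a normal strain (all marks cleared): digestion must cut at
    exactly the two flanking, formerly methylated switchable sites, and the
    insert-bearing fragment (the one without the backbone marker) is
    returned."""
    if product.marks:
        raise StillMethylatedError(
            "product still carries methylation marks; clear_marks (i.e. "
            "re-prepare in a normal strain) before release"
        )
    res = digest(product, enzyme)
    breaks = {e.top_cut for e in res.events}
    if len(breaks) != 2:
        raise InputError(f"expected exactly 2 flanking cuts, found {len(breaks)}")
    inserts = [
        f for f in res.fragments
        if not any(a.label.startswith(MARKER_PREFIX) for a in f.annotations)
    ]
    if len(inserts) != 1:
        raise InputError("could not identify a unique insert-bearing fragment")
    return inserts[0]


def cross_reactivity_check(
    fusion_sites: Sequence[str], threshold: int = 3
) -> list[tuple[str, str, int]]:
    """Flag fusion-site pairs at risk of mis-ligation.

    An overhang ``x`` is intended to anneal only with the reverse complement
    of itself.  A pot containing sites S also contains their complements, so
    ``x`` can mis-anneal either with ``rc(y)`` directly (x ~ y) or with a
    ``y``-carrying end (x ~ rc(y)).  Ordered pairs with >= ``threshold``
    Watson-Crick matches out of the overhang length on either comparison are
    returned as (x, y, n_matches)."""
    sites = [s.upper() for s in fusion_sites]
    if len({len(s) for s in sites}) > 1:
        raise InputError("mixed overhang lengths")
    risky = []
    for x in sites:
        for y in sites:
            if x == y:
                continue
            m1 = sum(a == b for a, b in zip(x, reverse_complement(y)))
            m2 = sum(a == b for a, b in zip(x, y))
            m = max(m1, m2)
            if m >= threshold:
                risky.append((x, y, m))
    return sorted(set(risky))
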