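"""Synthetic plasmid generators reproducing the canonical assay geometries,
so every simulation path is testable without any downloaded sequence.

All generators are seed-deterministic and validate their own geometry
(rejection sampling with bounded retries) before returning:

* ``make_methylation_test_plasmid`` -- a circular test plasmid with a
  head-to-head methylation-switchable site pair sharing one cut interval
  plus one non-switchable site a set distance away, the design used to
  assay in-vivo blocking (two fragments when prepared in a normal strain,
  one linear band when prepared in the switch-methylase strain).
* ``make_donor`` / ``make_acceptor`` -- donor plasmids with inward-facing
  switchable sites flanking a domesticated insert, and Start/Middle/End
  acceptor vectors whose outer switchable pair overlaps the switch-methylase
  site while the inner pair releasing the negative marker does not.
* ``make_hierarchy_fixture`` / ``run_plan`` -- a mutually consistent donor +
  acceptor set for an n-part multi-stage plan, and the simulator that
  executes the plan bottom-up.

Junction safety: generated insert payloads, linkers and spacers keep a few
A/T-only bases next to every fusion site, which makes it impossible for the
G/C-containing recognition motifs of the shipped enzymes to arise across a
ligation junction; payload interiors are domesticated by rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .core import (
    Annotation,
    DnaMolecule,
    EnzymeSpec,
    InputError,
    MethylaseSpec,
    StrainProfile,
    reverse_complement,
    IUPAC,
)
from .digest import digest, validate_shared_cut_pair
from .sites import apply_strain, classify_switchable, clear_marks, find_motif_sites
from .assembly import OnePotOptions, one_pot, release_insert
from .planner import (
    AdaptorScheme,
    AssemblyPlan,
    DEFAULT_SCHEME,
    Part,
    Reaction,
    assign_markers,
    extended_scheme,
    plan_multiplicative,
)
from .screen import enumerate_composites

__all__ = [
    "DomesticationError",
    "random_dna",
    "make_methylation_test_plasmid",
    "make_donor",
    "make_acceptor",
    "make_hierarchy_fixture",
    "run_plan",
    "HierarchyFixture",
    "switch_strain",
]

MAX_RETRIES = 1000


class DomesticationError(InputError):
    pass


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def switch_strain(methylase: MethylaseSpec) -> StrainProfile:
    """The methylase-overexpressing host used to prepare acceptor vectors."""
    return StrainProfile(f"DH10B-{methylase.name}", frozenset({methylase.name}))


def _draw(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(["A", "C", "G", "T"], size=length, p=p))


def _at_edges(seq: str, rng: np.random.Generator, width: int = 3) -> str:
    """Force A/T-only bases at both ends (junction-safety margin)."""
    if len(seq) <= 2 * width:
        return "".join(rng.choice(["A", "T"], size=len(seq)))
    left = "".join(rng.choice(["A", "T"], size=width))
    right = "".join(rng.choice(["A", "T"], size=width))
    return left + seq[width:-width] + right


def _scan_string(seq: str, motifs: Sequence[str], circular: bool) -> list[int]:
    mol = DnaMolecule("tmp", seq, "circular" if circular else "linear")
    hits = []
    for m in motifs:
        hits.extend(h.start for h in find_motif_sites(mol, m))
    return sorted(hits)


def random_dna(
    length: int,
    gc: float = 0.5,
    seed: Union[int, np.random.Generator] = 0,
    forbidden: Sequence[str] = (),
    topology: str = "circular",
    mol_id: str = "random",
) -> DnaMolecule:
    """Reproducible random DNA at the requested GC content; windows matching
    any forbidden motif (either strand) are resampled until clean."""
    if length <= 0:
        raise InputError("length must be positive")
    rng = _rng(seed)
    seq = list(_draw(rng, length, gc))
    circular = topology == "circular"
    for _ in range(MAX_RETRIES):
        hits = _scan_string("".join(seq), forbidden, circular)
        if not hits:
            return DnaMolecule(mol_id, "".join(seq), topology)
        width = max(len(m) for m in forbidden)
        for h in hits:
            for j in range(h, h + width):
                seq[j % length] = _draw(rng, 1, gc)
    raise DomesticationError(
        f"could not generate {length} bp free of {list(forbidden)} "
        f"after {MAX_RETRIES} retries"
    )


def _payload(rng: np.random.Generator, length: int, gc: float, forbidden: Sequence[str]) -> str:
    """A domesticated insert payload with A/T junction margins."""
    for _ in range(MAX_RETRIES):
        seq = _at_edges(_draw(rng, length, gc), rng)
        if not _scan_string(seq, forbidden, circular=False):
            return seq
    raise DomesticationError(f"no clean {length} bp payload after {MAX_RETRIES} tries")


def _concretize(motif: str, rng: np.random.Generator) -> str:
    return "".join(
        b if len(IUPAC[b]) == 1 else str(rng.choice(sorted(IUPAC[b]))) for b in motif
    )


def _switchable_cassette(
    enzyme: EnzymeSpec, methylase: MethylaseSpec, rng: np.random.Generator
) -> tuple[str, int]:
    """A concrete '+'-strand switchable composite: the enzyme recognition
    with the methylase overlap extension, extension strictly upstream.
    Returns (sequence, index of the recognition start)."""
    placements = [
        pl
        for pl in enumerate_composites(enzyme, methylase)
        if pl.footprint[1] == len(pl.composite)  # no downstream intrusion
    ]
    if not placements:
        raise InputError(
            f"no composite placement of {methylase.name} upstream of {enzyme.name}"
        )
    pl = sorted(placements, key=lambda p: (len(p.composite), p.offset))[0]
    return _concretize(pl.composite, rng), pl.footprint[0]


def _expected_switchable(mol, enzyme, methylase, n_switch, n_plain) -> bool:
    hits = classify_switchable(mol, enzyme, methylase)
    sw = sum(h.switchable for h in hits)
    return sw == n_switch and len(hits) == n_switch + n_plain


def make_methylation_test_plasmid(
    enzyme: EnzymeSpec,
    methylase: MethylaseSpec,
    backbone: int = 4300,
    spacing: int = 600,
    seed: Union[int, np.random.Generator] = 0,
    gc: float = 0.5,
) -> DnaMolecule:
    """The blocking-assay test plasmid: a head-to-head switchable pair that
    shares a single cut interval, plus one non-switchable site whose cut
    lies ``spacing`` bp away on a circle of ``backbone + spacing`` bp.
    Unmarked digestion gives fragments of ``spacing`` and ``backbone`` bp;
    after preparation in the switch strain, one linear molecule."""
    rng = _rng(seed)
    s, v, Lr = enzyme.spacer, enzyme.overhang_len, enzyme.site_len
    recog = _concretize(enzyme.recognition, rng)
    total = backbone + spacing
    forbidden = [enzyme.recognition, methylase.recognition]
    for _ in range(50):
        cass, fp = _switchable_cassette(enzyme, methylase, rng)
        overhang = _draw(rng, v, gc)
        head = cass + "T" * s + overhang + "T" * s + reverse_complement(cass)
        shared_cut = fp + Lr + s  # top-cut of both head-to-head sites
        # place the plain site so its top-cut is `spacing` downstream
        plain_pos = spacing + shared_cut - Lr - s
        fill1_len = plain_pos - 1 - len(head)
        fill2_len = total - plain_pos - Lr
        if fill1_len < 10 or fill2_len < 10:
            raise InputError("spacing/backbone too small for this cassette")
        fill1 = _payload(rng, fill1_len, gc, forbidden)
        fill2 = _payload(rng, fill2_len, gc, forbidden)
        seq = head + fill1 + "T" + recog + fill2
        assert len(seq) == total
        mol = DnaMolecule(f"pTEST_{enzyme.name}", seq, "circular", role="generic")
        if not _expected_switchable(mol, enzyme, methylase, 2, 1):
            continue
        hits = classify_switchable(mol, enzyme, methylase)
        pair = tuple(h for h in hits if h.switchable)
        if not validate_shared_cut_pair(mol, enzyme, pair).shared:
            continue
        res = digest(mol, enzyme)
        if len(res.fragments) != 2:
            continue
        return mol
    raise DomesticationError("test-plasmid generation failed geometry validation")


def make_donor(
    enzyme: EnzymeSpec,
    methylase: MethylaseSpec,
    fusion5: str,
    fusion3: str,
    insert: Optional[str] = None,
    insert_len: int = 600,
    marker: str = "kan",
    backbone_len: int = 1500,
    seed: Union[int, np.random.Generator] = 0,
    gc: float = 0.5,
    mol_id: str = "donor",
) -> DnaMolecule:
    """A circular donor plasmid: the insert flanked by inward-facing
    switchable sites releasing overhangs ``fusion5`` / ``fusion3``.

    An explicitly supplied insert is never edited: internal enzyme sites
    raise :class:`DomesticationError` listing the offending positions."""
    rng = _rng(seed)
    s = enzyme.spacer
    if len(fusion5) != enzyme.overhang_len or len(fusion3) != enzyme.overhang_len:
        raise InputError("fusion sites must match the enzyme overhang length")
    if insert is not None:
        bad = _scan_string(insert, [enzyme.recognition], circular=False)
        if bad:
            raise DomesticationError(
                f"explicit insert contains {enzyme.name} sites at positions {bad}"
            )
    for _ in range(50):
        payload = insert if insert is not None else _payload(
            rng, insert_len, gc, [enzyme.recognition]
        )
        cassL, _ = _switchable_cassette(enzyme, methylase, rng)
        cassR, _ = _switchable_cassette(enzyme, methylase, rng)
        backbone = _payload(rng, backbone_len, gc, [enzyme.recognition, methylase.recognition])
        left = cassL + "T" * s + fusion5
        right = fusion3 + "T" * s + reverse_complement(cassR)
        seq = left + payload + right + backbone
        mol = DnaMolecule(
            mol_id,
            seq,
            "circular",
            annotations=(
                Annotation(f"insert:{mol_id}", len(left), len(left) + len(payload)),
                Annotation(f"marker:{marker}", len(left + payload + right), len(seq)),
            ),
            role="donor",
        )
        if not _expected_switchable(mol, enzyme, methylase, 2, 0):
            if insert is not None:
                raise DomesticationError("explicit insert breaks donor site geometry")
            continue
        res = digest(mol, enzyme)
        if len(res.fragments) != 2:
            continue
        ins = [f for f in res.fragments if any(a.label.startswith("insert:") for a in f.annotations)]
        if len(ins) == 1 and ins[0].end5.overhang == fusion5.upper() and \
                ins[0].end3.overhang == reverse_complement(fusion3):
            return mol
    raise DomesticationError(f"donor {mol_id} failed geometry validation")


def make_acceptor(
    vtype: str,
    release_ends: tuple[str, str],
    scheme: AdaptorScheme = DEFAULT_SCHEME,
    enzyme: Optional[EnzymeSpec] = None,
    methylase: Optional[MethylaseSpec] = None,
    marker: str = "amp",
    lacz_len: int = 400,
    backbone_len: int = 1800,
    seed: Union[int, np.random.Generator] = 0,
    gc: float = 0.5,
    mol_id: Optional[str] = None,
) -> DnaMolecule:
    """A Start/Middle/End acceptor vector.

    Each flank carries an outer switchable site and an inner non-switchable
    site head-to-head; the inner pair releases the negative selection marker
    generating ends p and q, the outer pair (blocked after preparation in the
    switch strain) later releases the assembled fragment with the
    vector-type's adaptor letters.  Where the outer letter equals the inner
    one (p on a Start left flank, q on an End right flank) the two sites
    share a single cut interval."""
    from .io import default_enzymes, default_methylases  # late import, avoids cycle

    if enzyme is None:
        enzyme = default_enzymes()["BsaI"]
    if methylase is None:
        methylase = default_methylases()[enzyme.blocked_by[0]]
    rng = _rng(seed)
    s = enzyme.spacer
    recog = _concretize(enzyme.recognition, rng)
    lo, hi = release_ends
    p, q = scheme.p, scheme.q
    mol_id = mol_id or f"acceptor_{vtype}_{lo}{hi}"
    forbidden = [enzyme.recognition, methylase.recognition]
    for _ in range(200):
        cassL, _ = _switchable_cassette(enzyme, methylase, rng)
        cassR, _ = _switchable_cassette(enzyme, methylase, rng)
        linkL = "".join(rng.choice(["A", "T"], size=scheme.linker_len))
        linkR = "".join(rng.choice(["A", "T"], size=scheme.linker_len))
        if lo == p:
            flankL = cassL + "T" * s + scheme.seq(p) + "T" * s + reverse_complement(recog)
        else:
            flankL = (cassL + "T" * s + scheme.seq(lo) + linkL + scheme.seq(p)
                      + "T" * s + reverse_complement(recog))
        if hi == q:
            flankR = recog + "T" * s + scheme.seq(q) + "T" * s + reverse_complement(cassR)
        else:
            flankR = (recog + "T" * s + scheme.seq(q) + linkR + scheme.seq(hi)
                      + "T" * s + reverse_complement(cassR))
        lacz = _payload(rng, lacz_len, gc, forbidden)
        backbone = _payload(rng, backbone_len, gc, forbidden)
        seq = flankL + lacz + flankR + backbone
        lz0 = len(flankL)
        mol = DnaMolecule(
            mol_id,
            seq,
            "circular",
            annotations=(
                Annotation("negmark:lacZalpha", lz0, lz0 + lacz_len),
                Annotation(f"marker:{marker}", len(flankL) + lacz_len + len(flankR), len(seq)),
            ),
            role="acceptor",
        )
        if not _expected_switchable(mol, enzyme, methylase, 2, 2):
            continue
        res_unmarked = digest(mol, enzyme)
        if len(res_unmarked.events) != 4:
            continue
        marked = apply_strain(mol, switch_strain(methylase), {methylase.name: methylase})
        res = digest(marked, enzyme)
        if len(res.fragments) != 2:
            continue
        bb = [f for f in res.fragments if any(a.label.startswith("marker:") for a in f.annotations)]
        if len(bb) != 1:
            continue
        if bb[0].end5.overhang != scheme.seq(q) or \
                bb[0].end3.overhang != reverse_complement(scheme.seq(p)):
            continue
        return mol
    raise DomesticationError(f"acceptor {mol_id} failed geometry validation")


# --------------------------------------------------------------------------
# hierarchical fixtures


@dataclass
class HierarchyFixture:
    plan: AssemblyPlan
    donors: dict[str, DnaMolecule]
    acceptors: dict[int, DnaMolecule]
    enzyme: EnzymeSpec
    methylase: MethylaseSpec
    scheme: AdaptorScheme
    part_payloads: dict[str, str] = field(default_factory=dict)


def make_hierarchy_fixture(
    n_parts: int,
    part_len: int = 1000,
    cap: Optional[int] = None,
    seed: int = 0,
    enzyme: Optional[EnzymeSpec] = None,
    methylase: Optional[MethylaseSpec] = None,
    scheme: Optional[AdaptorScheme] = None,
    donor_backbone: int = 1500,
    acceptor_backbone: int = 1800,
    lacz_len: int = 400,
) -> HierarchyFixture:
    """A complete, mutually consistent donor/acceptor set for an ``n_parts``
    multiplicative plan, desk-scale by default (1 kb parts)."""
    from .io import default_enzymes, default_methylases

    if n_parts < 2:
        raise InputError("need at least 2 parts")
    if enzyme is None:
        enzyme = default_enzymes()["BsaI"]
    if methylase is None:
        methylase = default_methylases()[enzyme.blocked_by[0]]
    rng = np.random.default_rng(seed)
    if scheme is None:
        cap_eff = cap or min(n_parts, 6)
        scheme = extended_scheme(cap_eff - 1)
    parts = [Part(f"P{i:02d}", part_len) for i in range(1, n_parts + 1)]
    plan = plan_multiplicative(parts, scheme, cap)
    assign_markers(plan, ["kan", "amp"])

    donors: dict[str, DnaMolecule] = {}
    acceptors: dict[int, DnaMolecule] = {}
    payloads: dict[str, str] = {}
    for r in plan.reactions():
        ends = scheme.chain_letters(len(r.children))
        for child, (lo, hi) in zip(r.children, ends):
            if isinstance(child, Reaction):
                if child.release_ends != (lo, hi):
                    raise InputError("plan/vector letter mismatch")
                continue
            donors[child.name] = make_donor(
                enzyme,
                methylase,
                scheme.seq(lo),
                scheme.seq(hi),
                insert_len=child.length or part_len,
                marker="kan",
                backbone_len=donor_backbone,
                seed=rng,
                mol_id=child.name,
            )
            a = next(x for x in donors[child.name].annotations if x.label.startswith("insert:"))
            payloads[child.name] = donors[child.name].sequence[a.start : a.end]
        acceptors[r.index] = make_acceptor(
            r.vector.vtype,
            r.release_ends,
            scheme,
            enzyme,
            methylase,
            marker=r.marker or "amp",
            lacz_len=lacz_len,
            backbone_len=acceptor_backbone,
            seed=rng,
            mol_id=f"pACC_{r.index}",
        )
    return HierarchyFixture(plan, donors, acceptors, enzyme, methylase, scheme, payloads)


def run_plan(fix: HierarchyFixture, opts: OnePotOptions = OnePotOptions()):
    """Execute every reaction of the plan bottom-up in simulation.

    Acceptors are prepared in the switch-methylase strain; child products
    pass through a normal strain (marks cleared) before the next stage.
    Returns (per-reaction products, final released insert fragment)."""
    registry = {fix.methylase.name: fix.methylase}
    strain = switch_strain(fix.methylase)
    products: dict[int, DnaMolecule] = {}
    for r in fix.plan.reactions():
        inputs = []
        for child in r.children:
            if isinstance(child, Reaction):
                inputs.append(clear_marks(products[child.index]))
            else:
                inputs.append(fix.donors[child.name])
        vector = apply_strain(fix.acceptors[r.index], strain, registry)
        outcome = one_pot(vector, inputs, fix.enzyme, opts)
        if len(outcome.resistant_products) != 1:
            raise InputError(
                f"reaction {r.index}: expected a unique product, got "
                f"{len(outcome.resistant_products)} ({outcome.warnings})"
            )
        products[r.index] = outcome.resistant_products[0]
    final = products[fix.plan.root.index]
    released = release_insert(clear_marks(final), fix.enzyme)
    return products, released
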