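"""Standard vector grammar and multi-stage assembly planning.

The standard vector set is a fusion-site grammar over ordered adaptor
letters ``p, a, b, c, d, e, q``: within every reaction the insert chain runs
p -> ... -> q, and the vector type determines which letters flank the
*released* fragment afterwards (Start: p-a; Middle: a-b .. d-e; End: x-q).
With five internal letters, between 2 and 6 fragments fit in one reaction.
Hierarchies are planned either multiplicatively (balanced stages; the
28-fragment x 7.7 kb build decomposes as 4x7 then 1x4) or by iterative
linear addition of up to 5 blocks per round into a Start vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

from .core import InputError
from .assembly import cross_reactivity_check

__all__ = [
    "AdaptorScheme",
    "DEFAULT_SCHEME",
    "extended_scheme",
    "VectorDef",
    "Part",
    "Reaction",
    "AssemblyPlan",
    "max_parts_per_reaction",
    "plan_multiplicative",
    "plan_linear_addition",
    "predict_sizes",
    "assign_markers",
]


@dataclass(frozen=True)
class AdaptorScheme:
    """Ordered adaptor letters and their fusion-site sequences.

    ``letters`` runs p, <internal...>, q.  All fusion sequences must be
    distinct, of equal length, and pass the cross-reactivity check at the
    configured threshold.  ``linker_len`` is the length of the spacer placed
    between two distinct fusion sites on a vector flank (it becomes part of
    the released fragment: the adaptor scar).
    """

    letters: tuple[str, ...]
    sites: dict[str, str]
    linker_len: int = 4
    cross_threshold: int = 3

    def __post_init__(self):
        if len(self.letters) < 3:
            raise InputError("scheme needs p, at least one internal letter, and q")
        seqs = [self.sites[l].upper() for l in self.letters]
        object.__setattr__(self, "sites", {l: s.upper() for l, s in self.sites.items()})
        if len(set(seqs)) != len(seqs):
            raise InputError("fusion sequences must be distinct")
        if len({len(s) for s in seqs}) != 1:
            raise InputError("fusion sequences must share one length")
        risky = cross_reactivity_check(seqs, threshold=self.cross_threshold)
        if risky:
            raise InputError(f"fusion sites fail cross-reactivity check: {risky}")

    @property
    def p(self) -> str:
        return self.letters[0]

    @property
    def q(self) -> str:
        return self.letters[-1]

    @property
    def internal(self) -> tuple[str, ...]:
        return self.letters[1:-1]

    @property
    def overhang_len(self) -> int:
        return len(self.sites[self.p])

    def seq(self, letter: str) -> str:
        return self.sites[letter]

    def chain_letters(self, k: int) -> list[tuple[str, str]]:
        """Flanking letter pairs for k inserts chaining p -> q."""
        if k < 1:
            raise InputError("need at least one insert")
        if k > max_parts_per_reaction(self):
            raise InputError(
                f"{k} inserts exceed this scheme's capacity of {max_parts_per_reaction(self)}"
            )
        letters = [self.p, *self.internal[: k - 1], self.q]
        return [(letters[i], letters[i + 1]) for i in range(k)]


# Fusion-site sequences for the shipped scheme.  These are NOT the deposited
# vectors' sequences (which are only in the paper's supplementary GenBank
# files): they are a non-canonical default set chosen to be mutually
# non-cross-reactive; substitute the published sequences for exact
# compatibility with the deposited vector set.
DEFAULT_SCHEME = AdaptorScheme(
    letters=("p", "a", "b", "c", "d", "e", "q"),
    sites={
        "p": "GGAG",
        "a": "AATG",
        "b": "AGGT",
        "c": "GCTT",
        "d": "CGCT",
        "e": "TGCC",
        "q": "ACTA",
    },
)

# extra internal letters for outsized reactions (e.g. seven parts per pot,
# as in the 28-fragment hierarchical build, which used custom vectors)
_EXTRA_SITES = ("TCAC", "CCAG", "ATCG", "GTAA", "CAGC", "TGTG")


def extended_scheme(n_internal: int, base: AdaptorScheme = DEFAULT_SCHEME) -> AdaptorScheme:
    """A scheme with ``n_internal`` internal adaptors, extending the shipped
    letter chain with validated extra fusion sites (f, g, ...)."""
    if n_internal <= len(base.internal):
        return base
    extra_needed = n_internal - len(base.internal)
    if extra_needed > len(_EXTRA_SITES):
        raise InputError(f"cannot extend scheme to {n_internal} internal adaptors")
    letters = list(base.letters[:-1])
    sites = dict(base.sites)
    for i in range(extra_needed):
        letter = chr(ord(base.internal[-1]) + 1 + i)
        letters.append(letter)
        sites[letter] = _EXTRA_SITES[i]
    letters.append(base.q)
    return AdaptorScheme(tuple(letters), sites, base.linker_len, base.cross_threshold)


@dataclass(frozen=True)
class VectorDef:
    """Geometry summary of a Start/Middle/End acceptor vector.

    ``release_ends`` are the adaptor letters flanking the fragment released
    from an assembled (then demethylated) product; the inner, non-switchable
    site pair always releases the negative marker generating ends p, q.
    """

    vtype: str  # Start | Middle | End
    release_ends: tuple[str, str]
    marker: str = "amp"
    ori: str = "high"
    scheme: AdaptorScheme = DEFAULT_SCHEME

    def __post_init__(self):
        lo, hi = self.release_ends
        p, q, internal = self.scheme.p, self.scheme.q, self.scheme.internal
        ok = {
            "Start": lo == p and hi in internal,
            "Middle": lo in internal and hi in internal
            and internal.index(hi) == internal.index(lo) + 1,
            "End": lo in internal and hi == q,
        }.get(self.vtype)
        if ok is None:
            raise InputError(f"unknown vector type {self.vtype!r}")
        if not ok:
            raise InputError(
                f"release ends {self.release_ends} illegal for a {self.vtype} vector"
            )

    @property
    def shared_flanks(self) -> tuple[bool, bool]:
        """Whether the outer and inner cut intervals coincide on each flank
        (they do exactly when the outer release letter equals the inner
        letter: p on a Start left flank, q on an End right flank)."""
        return (self.release_ends[0] == self.scheme.p,
                self.release_ends[1] == self.scheme.q)


def max_parts_per_reaction(scheme: AdaptorScheme) -> int:
    """Length of the longest p->q chain through the ordered internal
    adaptors: one insert per edge p-a, a-b, ..., e-q."""
    return len(scheme.internal) + 1


@dataclass(frozen=True)
class Part:
    name: str
    length: int = 0


@dataclass
class Reaction:
    stage: int
    index: int
    vector: VectorDef
    children: list  # Part | Reaction, in assembly order
    enzyme: str = "BsaI"
    prep_strain: str = "DH10B-M.Osp807II"
    marker: Optional[str] = None
    predicted_insert: Optional[int] = None

    @property
    def release_ends(self) -> tuple[str, str]:
        return self.vector.release_ends

    def child_ends(self, scheme: AdaptorScheme) -> list[tuple[str, str]]:
        return scheme.chain_letters(len(self.children))


@dataclass
class AssemblyPlan:
    root: Reaction
    scheme: AdaptorScheme

    def reactions(self) -> list[Reaction]:
        """All reactions, bottom stage first, left to right within a stage."""
        out: list[Reaction] = []

        def walk(r: Reaction):
            for c in r.children:
                if isinstance(c, Reaction):
                    walk(c)
            out.append(r)

        walk(self.root)
        return sorted(out, key=lambda r: (r.stage, r.index))

    def leaves(self) -> list[Part]:
        out: list[Part] = []

        def walk(node):
            if isinstance(node, Part):
                out.append(node)
            else:
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out

    @property
    def n_stages(self) -> int:
        return self.root.stage


def _release_for_position(i: int, k: int, scheme: AdaptorScheme) -> tuple[str, tuple[str, str]]:
    pairs = scheme.chain_letters(k)
    lo, hi = pairs[i]
    if i == 0:
        return "Start", (scheme.p, pairs[0][1])
    if i == k - 1:
        return "End", (lo, scheme.q)
    return "Middle", (lo, hi)


def plan_multiplicative(
    parts: Sequence[Part],
    scheme: AdaptorScheme = DEFAULT_SCHEME,
    cap: Optional[int] = None,
) -> AssemblyPlan:
    """Balanced multi-stage plan: the smallest number of stages s with
    cap**s >= n, groups split left-heavy on remainders, vector types chosen
    so every stage's released products chain p -> ... -> q into the next."""
    n = len(parts)
    cap = cap or max_parts_per_reaction(scheme)
    if not 2 <= cap <= max_parts_per_reaction(scheme):
        raise InputError(f"cap {cap} outside 2..{max_parts_per_reaction(scheme)}")
    if n < 2:
        raise InputError("fewer than 2 parts: no plan needed")
    counter = {"i": 0}

    def build(items: list, vtype: str, ends: tuple[str, str]) -> Union[Part, Reaction]:
        if len(items) == 1:
            return items[0]
        s = 1
        while cap**s < len(items):  # smallest s with cap**s >= n (exact arithmetic)
            s += 1
        k = math.ceil(len(items) / cap ** (s - 1))
        base, rem = divmod(len(items), k)
        sizes = [base + 1] * rem + [base] * (k - rem)  # left-heavy
        groups, pos = [], 0
        for sz in sizes:
            groups.append(items[pos : pos + sz])
            pos += sz
        children = []
        for i, grp in enumerate(groups):
            cvt, cends = _release_for_position(i, k, scheme)
            children.append(build(grp, cvt, cends))
        stage = 1 + max((c.stage for c in children if isinstance(c, Reaction)), default=0)
        counter["i"] += 1
        return Reaction(
            stage=stage,
            index=counter["i"],
            vector=VectorDef(vtype, ends, scheme=scheme),
            children=children,
        )

    root = build(list(parts), "Start", (scheme.p, scheme.internal[0]))
    assert isinstance(root, Reaction)
    # re-index reactions deterministically: bottom-up, left-to-right
    plan = AssemblyPlan(root=root, scheme=scheme)
    for i, r in enumerate(plan.reactions(), 1):
        r.index = i
    return plan


def plan_linear_addition(
    base_ends: tuple[str, str],
    block_ends: Sequence[tuple[str, str]],
    scheme: AdaptorScheme = DEFAULT_SCHEME,
) -> AssemblyPlan:
    """One linear-addition round: a previously assembled fragment with ends
    (p, x) plus a chain of standard blocks ending at q, reassembled in a
    Start vector so the product again releases with ends (p, a) and the
    round can be iterated.  At most max_parts - 1 blocks fit per round."""
    if base_ends[0] != scheme.p:
        raise InputError("base fragment must start with adaptor p")
    limit = max_parts_per_reaction(scheme) - 1
    if len(block_ends) > limit:
        raise InputError(f"capacity error: at most {limit} blocks per round")
    if not block_ends:
        raise InputError("no blocks to add")
    cur = base_ends[1]
    for lo, hi in block_ends:
        if lo != cur:
            raise InputError(f"chain error: block starts at {lo!r}, expected {cur!r}")
        cur = hi
    if cur != scheme.q:
        raise InputError(f"chain error: last block must end at q, ends at {cur!r}")
    children = [Part(f"base({base_ends[0]}-{base_ends[1]})")] + [
        Part(f"block{i+1}({lo}-{hi})") for i, (lo, hi) in enumerate(block_ends)
    ]
    root = Reaction(
        stage=1,
        index=1,
        vector=VectorDef("Start", (scheme.p, scheme.internal[0]), scheme=scheme),
        children=children,
    )
    return AssemblyPlan(root=root, scheme=scheme)


def predict_sizes(plan: AssemblyPlan, part_lengths: Optional[dict] = None) -> dict[int, int]:
    """Per-reaction released-insert lengths.

    A leaf part contributes its payload plus one leading fusion site; a
    reaction adds one (fusion site + linker) flank overhead per non-shared
    flank minus the scar already counted -- concretely: released length =
    sum(children) + (v + linker) for Start/End vectors (one shared flank)
    and + 2*(v + linker) for Middle vectors.  Constants come from the
    instantiated scheme, not hard-coded."""
    v = plan.scheme.overhang_len
    ell = plan.scheme.linker_len
    lengths = dict(part_lengths or {})
    out: dict[int, int] = {}

    def size(node) -> int:
        if isinstance(node, Part):
            return lengths.get(node.name, node.length) + v
        total = sum(size(c) for c in node.children)
        shared = node.vector.shared_flanks
        total += (v + ell) * (2 - sum(shared))
        out[node.index] = total
        node.predicted_insert = total
        return total

    size(plan.root)
    return out


def assign_markers(plan: AssemblyPlan, markers: Sequence[str]) -> AssemblyPlan:
    """Alternate antibiotic markers by stage so every reaction's vector
    marker differs from all of its children's (donors carry markers[0])."""
    if len(markers) < 2:
        raise InputError("need at least 2 marker classes")
    for r in plan.reactions():
        r.marker = markers[r.stage % len(markers)]
        r.vector = replace(r.vector, marker=r.marker)
        for c in r.children:
            child_marker = markers[0] if isinstance(c, Part) else markers[c.stage % len(markers)]
            if child_marker == r.marker:
                raise InputError("marker alternation failed")
    return plan
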