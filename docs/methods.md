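# Methods

This note records the model the package implements, the conventions and
parameter choices behind it, and what the simulations do and do not capture.

## Sequence and methylation model

A `DnaMolecule` is a blunt abstraction of a double-stranded DNA molecule:
the top strand stored 5′→3′, a `circular`/`linear` topology flag, and a set
of methylation marks, each a `(position, strand, modification)` triple with
positions always in top-strand coordinates (0-based, half-open intervals;
indices reduced modulo the length on circles, so features may span the
origin). Methylation is **binary** per base and strand. Real methylation is
stochastic and can be partial, but the assay this models — preparing a
plasmid in a constitutively methylase-overexpressing host and asking whether
a restriction site still cuts — behaves as on/off, and the simulator
inherits that.

Circular identity: two circles are the same molecule iff one is a rotation
or strand-flip of the other. `canonicalize` rotates to the lexicographically
minimal rotation over both strands (Booth's least-rotation algorithm, O(n)),
giving a deterministic representative used for product deduplication and
round-trip tests. Marks, annotations and provenance segments are remapped so
they stay attached to their physical bases.

## Enzymes, methylases, blocking

`EnzymeSpec` describes a type IIS enzyme as recognition motif + `spacer` +
`overhang_len`: a '+'-strand site with footprint `[b, e)` cuts the top
strand at `e + spacer` and the bottom strand `overhang_len` further
(5′ protrusions; '−'-strand sites mirror this). Shipped geometries: BsaI
GGTCTC(1/5), BpiI GAAGAC(2/6), LguI GCTCTTC(1/3), EarI CTCTTC(1/3).

`MethylaseSpec` gives the motif plus the modified-base offset in a
top-strand occurrence and, for enzymes that methylate both strands, the
offset within the bottom-strand complement; an absent bottom offset means
hemimethylating (marks only the strand the motif occurs on). Palindromic
(degenerate-aware) motifs deposit both strands' marks from a single
occurrence.

A site is **switchable** iff some methylase occurrence places a modified
base inside the restriction footprint — a pure sequence-geometry property,
independent of current marks. A site is **blocked** (default rule) iff any
mark on either strand lies within the footprint. Whether a given
hemimethylated or fully methylated composite site actually resists a given
enzyme is biochemistry, not geometry: the registry carries empirical
evidence (`blocked_by` / `empirically_blocks`), an `empirical` blocking rule
honours only evidenced marks, and the default one-mark-blocks rule is a
deliberate, overridable simplification (the screening assays tested fully
in-vivo-methylated substrates only).

### The shipped registry is partly synthetic

The motif diagrams for the screened methylase panel exist only in figure
form. Where REBASE publishes the motif (M.TaqI TCGA m6A, M.SacI GAGCTC m5C,
M.XmnI GAANNNNTTC m6A) the registry uses it; for M.Osp807II, M.Rsp7740I,
M2.NmeMC58II and M.AspJHL3I the registry ships **constructed stand-in
motifs** (flagged `synthetic`) that reproduce the documented behaviour: a
one-base extension of the partner enzyme's site on the far side from the
cut, placing a methylatable adenine (or cytosine) inside the footprint, so
the geometric screening criteria and the strain-dependent blocking behave as
reported. Conclusions that depend on the exact base-level motif of those
four enzymes (e.g. scanning real genomes for their sites) require replacing
the stand-ins with REBASE transcriptions.

## Digestion and ligation

Digestion computes all unblocked, geometrically intact sites and applies
every resulting double-strand break simultaneously; head-to-head site pairs
whose cut intervals coincide merge into one break (the geometry used in
nick-detection assays, checked by `validate_shared_cut_pair`). Fragment
convention: a fragment's `body` runs top-strand-cut to top-strand-cut, so
body lengths sum exactly to the substrate length; the physical extent
(`Fragment.length`) adds the 3′-end bottom-strand protrusion. Sticky ends
store the protruding strand 5′→3′; two ends ligate iff same protrusion type,
equal length, and mutually reverse-complementary. Blunt–blunt ligation is
disabled. Single-strand nicking is not simulated (cut/no-cut only);
partial digestion, star activity and kinetics are out of scope.

## One-pot simulation

All inputs are digested; circular products are enumerated by bounded DFS
over the end-compatibility graph (each fragment used at most once by
default — ligase cycling favours minimal circles; a repeat option surfaces
tandem multimers as diagnostics), anchored to avoid rotational and
strand-reversal duplicates and deduplicated canonically. Cycle length is
capped at (number of input molecules + 1), and enumeration at 100 000 cycles
with a warning. A product survives the pot iff it has **zero cleavable
sites under its current marks**; selection is a filter requiring the
acceptor's `marker:` annotation and forbidding any `negmark:` annotation
(the in-silico stand-in for antibiotic + blue/white selection — colony
counts and transformation efficiencies are biology and are not modelled).
Everything is deterministic; there is no randomness in the engine.

The core correctness property, tested across 100 seeded fixtures and a full
two-stage 28-part build: the unique resistant product is uncuttable while
marked, and after `clear_marks` (passage through a normal strain) digestion
cuts at exactly the two flanking switchable sites, releasing an insert that
is the ordered concatenation of the part payloads joined on fusion sites.
For small pots the DFS enumeration is verified against a brute-force oracle
over all fragment permutations and orientations.

## Vector grammar and planners

Vector flank geometry (chosen here; the deposited vectors' exact layout is
not printed anywhere machine-readable): on each flank the outer switchable
and inner non-switchable sites face head-to-head with both cut intervals
between the footprints. When the outer release letter equals the inner
letter (p on a Start left flank, q on an End right flank) the two sites
share a single cut interval, avoiding a duplicated fusion sequence;
otherwise the two fusion sites are separated by a short linker
(`linker_len`, default 4 bp) that becomes part of the released fragment —
the adaptor scar. Released-insert sizes follow: a leaf contributes payload +
one fusion site; a reaction adds (overhang + linker) once for Start/End and
twice for Middle vectors. These constants are derived from the instantiated
scheme, never hard-coded.

The shipped adaptor sequences (`p, a–e, q` → GGAG, AATG, AGGT, GCTT, CGCT,
TGCC, ACTA) are non-canonical defaults chosen to pass the cross-reactivity
check (an ordered pair is risky when one overhang matches the other or its
reverse complement at ≥ 3 of 4 positions — both comparisons, because a pot
contains every fusion site together with its complement). Users targeting
the published vector set substitute its sequences. `extended_scheme` adds
validated internal letters for outsized pots: the seven-per-pot stage used
in the 218 kb-scale experiment needs six internal adaptors, one more than
the standard five-letter chain, so that plan is built on an extended scheme
rather than the shipped standard set.

`plan_multiplicative` uses the smallest stage count s with cap^s ≥ n (exact
integer arithmetic), splits remainders left-heavy (earlier groups get the
extra parts; deterministic plans), assigns Start/Middle/End vectors so each
stage's products chain p→…→q, and alternates antibiotic markers by stage so
a vector never shares its children's marker. `plan_linear_addition` models
one extension round: base (p, x) plus ≤ 5 chained blocks ending at q in a
Start vector, yielding (p, a) again for iteration.

## Screening and statistics

Essential criteria: E1 splits into a geometric part (a composite placement
exists with a modified base in the footprint — computed by IUPAC
intersection over all offsets and orientations) and an empirical part
(registry evidence; of the six candidates screened, three blocked and three
did not, and that outcome is data, not prediction). E2 fails iff a methylase
placement inside the footprint is *forced* by every restriction-site
occurrence (position-wise IUPAC subset test, verified against brute-force
expansion). E3 requires some E1 placement whose specificity bases stay out
of the spacer + overhang window — the constraint M.TaqI violates for EarI
(composite CTCTTCG^A intrudes into the 3-nt adhesive end, which is why that
older system constrains its adaptor sequences). Desirables: 37 °C activity,
motif length ≥ 5, orphan single-subunit enzymes, and modification distance
from the footprint edge.

Forbidden-site statistics: per-bp probability is the product over motif
positions of summed base probabilities with p(G)=p(C)=gc/2; non-palindromic
motifs count on both strands (×2), palindromic once; distinct motifs are
summed under an independence approximation (overlap between distinct short
motifs contributes < 1 % here). Expected spacing is the reciprocal rate;
reported raw and at reporting granularity (nearest kb above 1 kb, nearest
100 bp below). Empirical spacings on simulated DNA agree within 3σ Poisson.

## Fixtures: what they emulate and what they do not

Generators reproduce the *topologies* of the real constructs — the
test-plasmid geometry (switchable head-to-head pair sharing one cut
interval, plain site ~600 bp away on a ~4.9 kb circle), donors with
inward-facing switchable sites, the full Start/Middle/End flank layout, and
n-part hierarchies — with random, domesticated filler in place of real
backbone and payload sequence. Payload interiors are cleaned of enzyme sites
by bounded rejection sampling (default 1000 retries; explicitly supplied
inserts are never silently edited — offending positions are reported
instead), and every generated payload, linker and spacer keeps a few
A/T-only bases beside each fusion site, which provably prevents the G/C-rich
shipped recognition motifs from arising across ligation junctions. Every
fixture validates its own geometry before returning and is
seed-deterministic.

Consequently, passing tests demonstrate the combinatorial and geometric
correctness of the method — site switching, selective digestion, ordered
one-pot assembly, hierarchical re-release — on sequences with the right
structure. They say nothing about biological efficiency (colony numbers,
success rates, ligase fidelity beyond the mismatch-count check) or about the
behaviour of the real deposited plasmid sequences, which can be analysed by
loading their GenBank files through `metclo.io`.

### Problem sizes

Default fixture scales keep the suite quick while preserving topology:
1 kb parts, ~1.5–1.8 kb backbones, 250–400 bp payloads in the
high-iteration property tests. The stage-one simulation in the acceptance
script runs at the full 7 × 7.7 kb scale; the two-stage 28-part end-to-end
test runs at 28 × 1 kb.

## Numerical and tie-break choices

* Motif scans report each occurrence once (palindromic motifs on '+' only);
  origin-spanning hits are found by scanning an extended window.
* Cut positions index the bond before the base; overlapping-but-unequal cut
  intervals trigger a geometry warning (mutual site destruction).
* Product ordering and all file outputs are deterministic given inputs and
  seed; ambiguity (> 1 resistant product) and failure (none with the
  backbone) are outcomes with warnings, not exceptions.
* Seeds feed `numpy.random.default_rng`; fixture builders accept either a
  seed or a shared generator, and derived seeds stay below 2^31.

## Known limitations

* Binary methylation and the one-mark-blocks default overstate protection if
  an enzyme tolerates hemimethylation; use the `empirical` rule with
  registry evidence where that matters.
* Four registry methylase motifs are synthetic stand-ins (see above).
* The independence approximation in multi-motif spacing ignores overlaps
  between distinct motifs.
* Fragments shorter than the overhang length and marks inside 3′-overhang
  regions are edge cases the fragment model drops rather than tracks.
* No modelling of star activity, partial digestion, ligase kinetics, or
  transformation efficiency.
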