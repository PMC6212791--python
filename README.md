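# metclo

Design and simulation tools for **methylation-switched, single-enzyme Golden
Gate assembly** — hierarchical DNA construction in which one type IIS
restriction enzyme (BsaI, BpiI or LguI) is used at *every* stage, and the
sites that must survive a given stage are switched off by in-vivo
methylation instead of by switching enzymes.

## The problem and the model

Type IIS enzymes cut outside their asymmetric recognition sequence
(BsaI: `GGTCTC(1/5)`, BpiI: `GAAGAC(2/6)`, LguI: `GCTCTTC(1/3)`), producing
programmable 3–4 nt 5′ overhangs ("fusion sites") that dictate ligation
order in a one-pot restriction–ligation reaction. Classical hierarchical
schemes (MoClo, GoldenBraid) alternate two enzymes between stages, so every
part must be free of *both* recognition sequences — on random 50 % GC DNA a
forbidden site every ~1 kb.

The alternative modelled here uses a single enzyme plus a *switch
methylase*: a DNA methyltransferase whose recognition sequence partially
overlaps the enzyme's, such that methylation of the composite site blocks
cutting. A site is then:

* **methylation-switchable** — its footprint overlaps a methylase site so
  that a methylated base falls *inside* the restriction footprint; it is
  "off" in a methylase-expressing host and "on" after one passage through a
  normal host;
* **non-switchable** — constitutively cuttable.

Assembly vectors carry, on each flank of a LacZα negative marker, an outer
switchable site and an inner non-switchable site head-to-head. Prepared in
the switch-methylase strain, only the inner pair cuts (releasing LacZα with
ends `p`/`q`); the assembled product is flanked by methylated — hence
uncuttable — sites, making it the only stable circle in the pot. Passaged
through a normal strain, those flanking sites reactivate and the assembled
fragment is released for the next stage with adaptor letters determined by
the vector type (`Start`: p–a, `Middle`: a–b … d–e, `End`: a–e → q). The
ordered chain p, a–e, q gives 2–6 fragments per reaction, multiplicative
stage counts of ⌈log_cap n⌉, and iterative linear addition of up to 5
standard blocks per round.

With one 6-bp cutter the forbidden-site frequency on random 50 % GC DNA is

p(site) = 2·(1/4)^6 per bp → one site per 2048 bp ("1 per 2 kb"),

and one per 8192 bp for the 7-bp cutter LguI — the package computes these
analytically for arbitrary IUPAC motifs and GC content and cross-checks them
by scanning simulated sequence.

## What is in the package

| module | contents |
| --- | --- |
| `metclo.core` | `DnaMolecule` (circular/linear duplex with per-base, per-strand methylation marks), `EnzymeSpec`, `MethylaseSpec`, `StrainProfile`, canonical circular form |
| `metclo.sites` | IUPAC motif scanning (both strands, origin-spanning), switchability classification, strain methylation, blocking rules |
| `metclo.digest` | methylation-aware type IIS digestion into sticky-ended fragments, end compatibility, religation, shared-cut-interval validation |
| `metclo.assembly` | one-pot product enumeration, resistance + selection filtering, junction reports, insert release, fusion-site cross-reactivity check |
| `metclo.planner` | adaptor schemes, Start/Middle/End vector grammar, multiplicative and linear-addition planners, insert-size prediction, marker alternation |
| `metclo.screen` | switch-methylase screening (essential criteria E1–E3, desirables), forbidden-site statistics |
| `metclo.io` | GenBank/FASTA I/O (marks as `modified_base` features), registry TSVs |
| `metclo.fixtures` | seed-deterministic synthetic test plasmids, donors, acceptors, full n-part hierarchies, and the plan executor |

The shipped registry covers BsaI/BpiI/LguI/EarI and the screened methylase
panel; methylase motifs that are not printed in any machine-readable source
are synthetic stand-ins flagged in the `synthetic` column of
`src/metclo/data/methylases.tsv`.

## Worked example

Generate the blocking-assay test plasmid (head-to-head switchable pair
sharing one cut interval + one plain site), digest it before and after
simulated preparation in the M.Osp807II strain:

```
$ metclo --seed 2 fixtures fx --kind test_plasmid
$ metclo digest fx/pTEST_BsaI.gb
pTEST_BsaI: 2 fragment(s) (3 cut event(s))
  4304 bp  5'ATAG / 3'TAGG
  604 bp  5'CCTA / 3'CTAT
$ metclo --seed 2 methylate fx/pTEST_BsaI.gb fx/marked.gb --methylase M.Osp807II
4 methylation mark(s) -> fx/marked.gb
$ metclo digest fx/marked.gb
pTEST_BsaI: 1 fragment(s) (1 cut event(s))
  4904 bp  5'ATAG / 3'CTAT
```

Unmethylated, the enzyme cuts at both loci — a ~600 bp fragment falls out of
the ~4.3 kb backbone (three cut events, but the head-to-head pair shares one
physical cut interval, hence two breaks). Methylated, only the
non-switchable site cuts: a single ~4.9 kb linear molecule.

Plan the 28 × 7.7 kb two-stage build and check site statistics:

```
$ metclo plan -n 28 --cap 7 --part-length 7700 | tail -3
stage 1  R4  End(c-q)  marker=amp  insert=53936 bp  <- P22, P23, P24, P25, P26, P27, P28
stage 2  R5  Start(p-a)  marker=kan  insert=215768 bp  <- R1, R2, R3, R4
5 reactions over 2 stage(s)
$ metclo stats --motif GGTCTC
expected spacing: 2048.0 bp (1 per 2 kb)
```

Four stage-one pots of seven parts give ~54 kb intermediates; the stage-two
pot joins them into a ~216 kb insert. The same numbers come from library
calls (`plan_multiplicative`, `predict_sizes`, `expected_spacing`), and
`metclo.fixtures.run_plan` executes any such plan end-to-end in simulation.

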