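"""Reading and writing standard formats: GenBank/FASTA molecules with
methylation marks, and the enzyme/methylase registry tables.

The shipped registry transcribes the screened enzyme/methylase panel.  Cut
geometries and the real methylase motifs (M.TaqI TCGA, M.SacI GAGCTC,
M.XmnI GAANNNNTTC) follow their REBASE descriptions; the remaining methylase
motifs are synthetic stand-ins (flagged in the ``synthetic`` column) built to
have the documented overlap geometry with their partner enzymes, because the
authoritative motif diagrams are distributed only as figures.  Replace them
with REBASE transcriptions for work against real sequences.
"""

from __future__ import annotations

import csv
import warnings
from importlib import resources
from pathlib import Path
from typing import Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .core import (
    Annotation,
    DnaMolecule,
    EnzymeSpec,
    InputError,
    MethylMark,
    MethylaseSpec,
)

__all__ = [
    "read_genbank",
    "write_genbank",
    "write_fasta_fragments",
    "load_enzymes",
    "load_methylases",
    "default_enzymes",
    "default_methylases",
    "TESTED_PAIRS",
]

# which methylases the screening panel actually assayed against each enzyme
TESTED_PAIRS: dict[str, tuple[str, ...]] = {
    "BsaI": ("M.Osp807II",),
    "BpiI": ("M.Rsp7740I", "M2.NmeMC58II"),
    "LguI": ("M.SacI", "M.AspJHL3I", "M.XmnI"),
}

_MOD_QUAL = {"m6A": "m6a", "m5C": "m5c", "m4C": "m4c"}
_QUAL_MOD = {v: k for k, v in _MOD_QUAL.items()}


def read_genbank(path: Union[str, Path]) -> DnaMolecule:
    """Parse a single-record GenBank file into a :class:`DnaMolecule`.

    Topology comes from the LOCUS line; ``modified_base`` features with a
    ``mod_base`` qualifier of m6a/m5c/m4c become methylation marks; all other
    features become plain annotations labelled by their best qualifier."""
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # biopython raises assorted types
        raise InputError(f"unparseable GenBank file {path}: {exc}") from exc
    topology = record.annotations.get("topology", "linear")
    marks, anns = [], []
    for feat in record.features:
        if feat.type == "source":
            continue
        start, end = int(feat.location.start), int(feat.location.end)
        strand = "-" if feat.location.strand == -1 else "+"
        if feat.type == "modified_base":
            mod = feat.qualifiers.get("mod_base", [""])[0].lower()
            if mod in _QUAL_MOD:
                marks.append(MethylMark(start, strand, _QUAL_MOD[mod]))
                continue
        label = (
            feat.qualifiers.get("label", [None])[0]
            or feat.qualifiers.get("gene", [None])[0]
            or feat.qualifiers.get("note", [feat.type])[0]
        )
        anns.append(Annotation(label=label, start=start, end=end, strand=strand))
    return DnaMolecule(
        id=record.id or Path(path).stem,
        sequence=str(record.seq),
        topology="circular" if topology == "circular" else "linear",
        marks=frozenset(marks),
        annotations=tuple(anns),
    )


def write_genbank(mol: DnaMolecule, path: Union[str, Path]) -> None:
    """Write a molecule as an annotated GenBank record (marks serialized as
    standard ``modified_base`` features, provenance segments as
    ``misc_feature`` notes)."""
    record = SeqRecord(
        Seq(mol.sequence),
        id=mol.id[:16] or "molecule",
        name=(mol.id or "molecule")[:16],
        description=f"role={mol.role}",
        annotations={
            "molecule_type": "DNA",
            "topology": mol.topology,
        },
    )
    for a in sorted(mol.annotations, key=lambda x: (x.start, x.end, x.label)):
        end = a.end if a.end > a.start else len(mol)  # avoid wrapped locations
        record.features.append(
            SeqFeature(
                SimpleLocation(a.start, end, strand=-1 if a.strand == "-" else 1),
                type="misc_feature",
                qualifiers={"label": [a.label]},
            )
        )
    for m in sorted(mol.marks, key=lambda x: (x.position, x.strand)):
        record.features.append(
            SeqFeature(
                SimpleLocation(m.position, m.position + 1, strand=-1 if m.strand == "-" else 1),
                type="modified_base",
                qualifiers={"mod_base": [_MOD_QUAL[m.modification]]},
            )
        )
    for g in mol.segments:
        record.features.append(
            SeqFeature(
                SimpleLocation(g.start, g.end if g.end > g.start else len(mol),
                               strand=-1 if g.orient == "-" else 1),
                type="misc_feature",
                qualifiers={"note": [f"segment:{g.source_id}:{g.role}"]},
            )
        )
    SeqIO.write([record], str(path), "genbank")


def write_fasta_fragments(fragments, path: Union[str, Path]) -> None:
    """Fragment multiset as multi-record FASTA; sticky ends are described in
    the record descriptions."""
    records = []
    for i, f in enumerate(fragments, 1):
        desc = (
            f"len={f.length} end5={f.end5.protrusion}:{f.end5.overhang or '-'} "
            f"end3={f.end3.protrusion}:{f.end3.overhang or '-'} src={f.source_id}"
        )
        records.append(SeqRecord(Seq(f.body), id=f"fragment_{i}", description=desc))
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------------------
# registries


def _split_list(cell: str) -> tuple[str, ...]:
    cell = (cell or "").strip()
    if cell in ("", "-"):
        return ()
    return tuple(x.strip() for x in cell.split(",") if x.strip())


def load_enzymes(path: Union[str, Path]) -> dict[str, EnzymeSpec]:
    out: dict[str, EnzymeSpec] = {}
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh, delimiter="\t"), 2):
            try:
                spec = EnzymeSpec(
                    name=row["name"].strip(),
                    recognition=row["recognition"].strip(),
                    spacer=int(row["spacer"]),
                    overhang_len=int(row["overhang_len"]),
                    blocked_by=_split_list(row.get("blocked_by", "")),
                )
            except (KeyError, ValueError, InputError) as exc:
                warnings.warn(f"{path}:{i}: skipping malformed enzyme row ({exc})")
                continue
            if spec.name in out:
                raise InputError(f"duplicate enzyme name {spec.name!r}")
            out[spec.name] = spec
    return out


def load_methylases(path: Union[str, Path]) -> dict[str, MethylaseSpec]:
    out: dict[str, MethylaseSpec] = {}
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh, delimiter="\t"), 2):
            try:
                flags = set(_split_list(row.get("flags", "")))
                mb = row.get("meth_offset_bottom", "-").strip()
                spec = MethylaseSpec(
                    name=row["name"].strip(),
                    recognition=row["recognition"].strip(),
                    meth_offset_top=int(row["meth_offset_top"]),
                    meth_offset_bottom=None if mb in ("", "-") else int(mb),
                    modification=row["modification"].strip(),
                    active_37C="active_37C" in flags,
                    single_subunit="single_subunit" in flags,
                    orphan_no_restriction="orphan_no_restriction" in flags,
                    empirically_blocks=_split_list(row.get("empirically_blocks", "")),
                    synthetic=row.get("synthetic", "no").strip().lower() in ("yes", "true", "1"),
                )
            except (KeyError, ValueError, InputError) as exc:
                warnings.warn(f"{path}:{i}: skipping malformed methylase row ({exc})")
                continue
            if spec.name in out:
                raise InputError(f"duplicate methylase name {spec.name!r}")
            out[spec.name] = spec
    return out


def _data_path(name: str) -> Path:
    return Path(str(resources.files("metclo").joinpath("data", name)))


def default_enzymes() -> dict[str, EnzymeSpec]:
    enzymes = load_enzymes(_data_path("enzymes.tsv"))
    methylases = load_methylases(_data_path("methylases.tsv"))
    for enz in enzymes.values():
        for m in enz.blocked_by:
            if m not in methylases:
                raise InputError(f"enzyme {enz.name}: unknown blocker {m!r}")
    return enzymes


def default_methylases() -> dict[str, MethylaseSpec]:
    return load_methylases(_data_path("methylases.tsv"))
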