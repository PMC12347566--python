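"""Readers and writers for the standard formats used throughout rbcskit.

This module is the single home for coordinate and strand conventions:

* ``GeneModel`` coordinates are 1-based inclusive, exactly as they appear in
  GFF3.  Internal interval arithmetic elsewhere in the package uses 0-based
  half-open slices; the conversion happens exactly once, through the
  ``GeneModel.start0`` / ``GeneModel.end0`` properties, which eliminates
  off-by-one drift between modules.
* PDB ATOM records are parsed by fixed columns (x, y, z in columns 31-54),
  never by whitespace splitting.
* FASTA output wraps sequence lines at 60 columns.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlphabetError,
    AnnotationError,
    CoordinateError,
    FormatError,
    ParseError,
)

NUCLEOTIDE_ALPHABET = set("ACGTURYSWKMBDHVN-")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*-")

COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVNacgturyswkmbdhvn",
                           "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named sequence (nucleotide or amino acid; '*' permitted as stop)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record has an empty id")
        if not self.sequence:
            raise FormatError(f"sequence record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A located gene: 1-based inclusive coordinates on a named chromosome."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    species: str = ""
    is_family_member: bool = True

    def __post_init__(self) -> None:
        if self.start < 1:
            raise CoordinateError(f"{self.gene_id}: start {self.start} < 1")
        if self.end < self.start:
            raise CoordinateError(
                f"{self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in ("+", "-"):
            raise CoordinateError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def start0(self) -> int:
        """0-based half-open start (for Python slicing)."""
        return self.start - 1

    @property
    def end0(self) -> int:
        """0-based half-open end (for Python slicing)."""
        return self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AtomRecord:
    """One ATOM record from a PDB file."""

    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for v in (self.x, self.y, self.z):
            if not math.isfinite(v):
                raise FormatError("atom coordinates must be finite")
        if not self.element:
            raise FormatError("atom element must be non-empty")


class Tree:
    """A rooted phylogeny with optional branch-group labels.

    Thin wrapper around a :class:`dendropy.Tree`.  Branch groups may be
    encoded in Newick with a ``#group`` suffix on a node label
    (``(a#fg:1,b:1);`` puts the edge above leaf ``a`` in group ``fg``);
    they are stripped from the label and stored in :attr:`branch_groups`.
    """

    def __init__(self, dtree: dendropy.Tree,
                 branch_groups: dict[str, str] | None = None) -> None:
        self.dendropy_tree = dtree
        self.branch_groups: dict[str, str] = dict(branch_groups or {})
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            raise ParseError("leaf labels must be unique")
        for edge in dtree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ParseError("branch lengths must be non-negative")

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.dendropy_tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels())

    def branch_lengths(self) -> dict[str, float]:
        """Edge length above each leaf, keyed by leaf label (0 if absent)."""
        return {
            lf.taxon.label: (lf.edge.length or 0.0)
            for lf in self.dendropy_tree.leaf_node_iter()
        }

    def total_length(self) -> float:
        return sum(
            e.length or 0.0 for e in self.dendropy_tree.preorder_edge_iter()
        )

    def to_newick(self) -> str:
        s = self.dendropy_tree.as_string(schema="newick",
                                         suppress_rooting=True)
        return s.strip()


def _infer_alphabet(chars: set[str], record_id: str) -> str:
    if chars <= NUCLEOTIDE_ALPHABET:
        return "nucleotide"
    if chars <= PROTEIN_ALPHABET:
        return "protein"
    bad = sorted(chars - PROTEIN_ALPHABET)
    raise AlphabetError(
        f"record {record_id!r} contains characters outside any supported "
        f"alphabet: {bad}"
    )


def _validate_alphabet(rec: SequenceRecord, alphabet: str) -> None:
    chars = set(rec.sequence)
    if alphabet == "auto":
        _infer_alphabet(chars, rec.id)
        return
    allowed = NUCLEOTIDE_ALPHABET if alphabet == "nucleotide" else PROTEIN_ALPHABET
    bad = sorted(chars - allowed)
    if bad:
        raise AlphabetError(
            f"record {rec.id!r} contains characters outside the declared "
            f"{alphabet} alphabet: {bad}"
        )


def read_fasta(path: str | Path, alphabet: str = "auto") -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Wrapped sequence lines are concatenated, input order is preserved and
    sequences are uppercased.  ``alphabet`` is one of ``"auto"``,
    ``"nucleotide"`` or ``"protein"``; characters outside the declared
    alphabet raise :class:`AlphabetError` naming the offending record.
    An empty file raises :class:`FormatError`.
    """
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out = SequenceRecord(
            id=rec.id, sequence=str(rec.seq).upper(), description=_desc(rec)
        )
        _validate_alphabet(out, alphabet)
        records.append(out)
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def _desc(rec: SeqRecord) -> str:
    # Biopython's description repeats the id; keep only the remainder.
    d = rec.description
    if d == rec.id:
        return ""
    if d.startswith(rec.id + " "):
        return d[len(rec.id) + 1:]
    return d


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapping sequence lines at 60 columns."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqs)


def read_gff3(
    path: str | Path,
    feature_type: str = "gene",
    species: str = "",
    sort: bool = False,
) -> list[GeneModel]:
    """Read GeneModels of one feature type from a GFF3 file.

    Only rows whose third column equals ``feature_type`` are returned;
    coordinates stay 1-based inclusive; ``gene_id`` is the ``ID=``
    attribute.  With ``sort=True`` the output is stably sorted by
    (chromosome, start).
    """
    models: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            if cols[2] != feature_type:
                continue
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad coordinates") from exc
            if end < start:
                raise CoordinateError(
                    f"{path}:{lineno}: start {start} > end {end}"
                )
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            if "ID" not in attrs:
                raise AnnotationError(f"{path}:{lineno}: missing ID attribute")
            models.append(
                GeneModel(
                    gene_id=attrs["ID"],
                    chromosome=cols[0],
                    start=start,
                    end=end,
                    strand=cols[6] if cols[6] in ("+", "-") else "+",
                    species=species,
                )
            )
    if sort:
        models.sort(key=lambda g: (g.chromosome, g.start))
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path,
               feature_type: str = "gene", source: str = "rbcskit") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            fh.write(
                f"{g.chromosome}\t{source}\t{feature_type}\t{g.start}\t"
                f"{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


_ELEMENT_TWO_LETTER = {"FE", "ZN", "MG", "MN", "CU", "NA", "CL", "CA", "SE",
                       "NI", "CO", "BR"}


def _element_from_atom_name(atom_name: str) -> str:
    # PDB atom names place the element in columns 13-14; a name starting in
    # column 13 (e.g. "FE") is a two-letter element, otherwise the first
    # alphabetic character after digits is the element.
    raw = atom_name
    if len(raw) >= 2 and raw[:2].strip().upper() in _ELEMENT_TWO_LETTER:
        return raw[:2].strip().upper()
    stripped = raw.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else ""


def read_pdb_atoms(path: str | Path, include_hetatm: bool = False) -> list[AtomRecord]:
    """Parse ATOM records from a PDB file by fixed-column slicing.

    HETATM records are ignored unless ``include_hetatm`` is set; altloc
    codes other than blank or 'A' are skipped.  A file with zero ATOM
    records returns an empty list with a warning.
    """
    atoms: list[AtomRecord] = []
    kinds = ("ATOM  ", "HETATM") if include_hetatm else ("ATOM  ",)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line[:6] not in kinds:
                continue
            altloc = line[16:17]
            if altloc not in (" ", "", "A"):
                continue
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                residue_index = int(line[22:26])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: unparsable coordinate field"
                ) from exc
            element = line[76:78].strip().upper() if len(line) >= 78 else ""
            atom_name = line[12:16]
            if not element:
                element = _element_from_atom_name(atom_name)
            atoms.append(
                AtomRecord(
                    chain_id=line[21:22].strip(),
                    residue_index=residue_index,
                    residue_name=line[17:20].strip(),
                    atom_name=atom_name.strip(),
                    element=element,
                    x=x, y=y, z=z,
                )
            )
    if not atoms:
        warnings.warn(f"{path}: no ATOM records found", stacklevel=2)
    return atoms


def write_pdb(atoms: Iterable[AtomRecord], path: str | Path) -> None:
    """Write AtomRecords as minimal fixed-column PDB ATOM lines."""
    with open(path, "w") as fh:
        for i, a in enumerate(atoms, 1):
            name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
            fh.write(
                f"ATOM  {i:5d} {name:<4s} {a.residue_name:<3s} "
                f"{a.chain_id:1s}{a.residue_index:4d}    "
                f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}\n"
            )
        fh.write("END\n")


def read_newick(text: str) -> Tree:
    """Parse a single Newick string into a :class:`Tree`.

    Branch lengths default to 0 when absent.  ``#group`` suffixes on
    labels are stripped into :attr:`Tree.branch_groups`.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=False,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"could not parse Newick: {exc}") from exc
    groups: dict[str, str] = {}
    for node in dtree.preorder_node_iter():
        label = node.taxon.label if node.taxon else node.label
        if label and "#" in label:
            clean, group = label.split("#", 1)
            groups[clean] = group
            if node.taxon:
                node.taxon.label = clean
            else:
                node.label = clean
    return Tree(dtree, branch_groups=groups)
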