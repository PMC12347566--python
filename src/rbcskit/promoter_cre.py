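"""Promoter cis-regulatory element (CRE) analysis.

Extracts strand-aware upstream regions, scans a degenerate-consensus motif
library on both strands, summarizes presence/absence and function-class
composition, and detects the paired I-box arrangement (two I-box elements
separated by a short spacer close to the transcription start site, an
architecture associated with dominantly expressed RBCS copies).

Coordinate convention: motif hits are reported TSS-relative, where offset
−1 is the base immediately upstream of the annotated gene start and
−L is the 5'-most base of a length-L promoter.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import FormatError, InputError
from .io_core import GeneModel, SequenceRecord, reverse_complement

IUPAC_TABLE = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class Motif:
    """A named degenerate consensus with a functional class label."""

    name: str
    consensus: str
    function_class: str

    def __post_init__(self) -> None:
        bad = set(self.consensus.upper()) - set(IUPAC_TABLE)
        if bad:
            raise FormatError(
                f"motif {self.name!r}: non-IUPAC characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence in TSS-relative coordinates (−1 = base upstream of TSS)."""

    gene_id: str
    motif_name: str
    tss_offset_start: int
    tss_offset_end: int
    strand_of_hit: str

    def __post_init__(self) -> None:
        if self.tss_offset_start > self.tss_offset_end:
            raise InputError("hit start offset must be <= end offset")
        if self.tss_offset_end > -1:
            raise InputError("hit offsets must be negative (upstream of TSS)")


@dataclass(frozen=True)
class MotifPair:
    """Two same-motif hits: `hit_a` upstream of `hit_b`, with spacer and TSS distance."""

    gene_id: str
    hit_a: MotifHit
    hit_b: MotifHit
    spacer_bp: int
    tss_distance_bp: int

    def __post_init__(self) -> None:
        if self.spacer_bp < 0 or self.tss_distance_bp < 0:
            raise InputError("spacer and TSS distance must be non-negative")


# Default consensus library.  The names and function classes follow the CREs
# commonly reported in RBCS promoters; the consensus strings are editable
# surrogates for database motif definitions (ship your own TSV to override).
_DEFAULT_MOTIFS = [
    ("I-box", "GATAAG", "light"),
    ("G-box", "CACGTG", "light"),
    ("MYB", "CAACAG", "drought"),
    ("MYB2", "TAACCA", "drought"),
    ("MYC", "CATTTG", "ABA"),
    ("MYC2", "CATGTG", "ABA"),
    ("STRE", "AGGGG", "stress"),
    ("ARE", "AAACCA", "anaerobic"),
    ("LTR", "CCGAAA", "low-temperature"),
    ("WUN", "AAATTTCCT", "wound"),
    ("WRE3", "CCACCT", "wound"),
]


def default_motif_library() -> list[Motif]:
    return [Motif(n, c, f) for n, c, f in _DEFAULT_MOTIFS]


def load_motif_library(path: str | Path) -> list[Motif]:
    """Load a motif library TSV with columns name, consensus, function_class."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "consensus", "function_class"}
    if not required <= set(df.columns):
        raise FormatError(f"motif library must have columns {sorted(required)}")
    motifs = [
        Motif(str(r["name"]), str(r["consensus"]).upper(), str(r["function_class"]))
        for _, r in df.iterrows()
    ]
    names = [m.name for m in motifs]
    if len(names) != len(set(names)):
        raise FormatError("motif names must be unique in the library")
    return motifs


def write_motif_library(motifs: list[Motif], path: str | Path) -> None:
    pd.DataFrame(
        [(m.name, m.consensus, m.function_class) for m in motifs],
        columns=["name", "consensus", "function_class"],
    ).to_csv(path, sep="\t", index=False)


def extract_upstream(
    genome: SequenceRecord, gene: GeneModel, length: int = 2000
) -> SequenceRecord:
    """Extract the promoter: `length` bp upstream of the gene start, 5'→3'.

    '+' strand genes take genome bases [start−length, start−1]; '−' strand
    genes take [end+1, end+length] reverse-complemented.  The region is
    truncated with a warning when it runs off the chromosome end.
    """
    if gene.chromosome != genome.id:
        raise InputError(
            f"gene {gene.gene_id} is on {gene.chromosome!r}, "
            f"not on chromosome {genome.id!r}"
        )
    seq = genome.sequence
    if gene.strand == "+":
        lo = max(0, gene.start0 - length)
        region = seq[lo:gene.start0]
    else:
        hi = min(len(seq), gene.end0 + length)
        region = reverse_complement(seq[gene.end0:hi])
    if len(region) < length:
        warnings.warn(
            f"{gene.gene_id}: promoter truncated to {len(region)} bp "
            f"(chromosome edge)",
            stacklevel=2,
        )
    return SequenceRecord(
        id=f"{gene.gene_id}_upstream",
        sequence=region if region else "N",
        description=f"{len(region)} bp upstream of {gene.gene_id}",
    ) if region else _empty_promoter(gene)


def _empty_promoter(gene: GeneModel) -> SequenceRecord:
    rec = SequenceRecord.__new__(SequenceRecord)
    rec.id = f"{gene.gene_id}_upstream"
    rec.sequence = ""
    rec.description = "0 bp upstream (gene at chromosome edge)"
    return rec


def _iupac_regex(consensus: str) -> re.Pattern[str]:
    pattern = "".join(
        c if len(IUPAC_TABLE[c]) == 1 else f"[{IUPAC_TABLE[c]}]"
        for c in consensus.upper()
    )
    return re.compile(f"(?=({pattern}))")  # lookahead: overlapping hits


def iupac_reverse_complement(consensus: str) -> str:
    return consensus.upper().translate(_IUPAC_COMPLEMENT)[::-1]


def scan_motifs(
    promoter: SequenceRecord,
    library: list[Motif],
    gene_id: str | None = None,
    collapse_palindromes: bool = False,
) -> list[MotifHit]:
    """Scan a promoter (5'→3', gene-relative) for all library motifs.

    Exact IUPAC-degenerate matching on both strands; overlapping hits are
    all reported, with TSS-relative offsets.  Palindromic motifs match at
    the same position on both strands and are reported once per strand
    unless ``collapse_palindromes`` is set (then only the '+' hit is kept).
    """
    gene_id = gene_id or promoter.id
    seq = promoter.sequence.upper()
    L = len(seq)
    hits: list[MotifHit] = []
    for motif in library:
        w = len(motif.consensus)
        for strand, pattern in (
            ("+", _iupac_regex(motif.consensus)),
            ("-", _iupac_regex(iupac_reverse_complement(motif.consensus))),
        ):
            for m in pattern.finditer(seq):
                i = m.start()
                hits.append(
                    MotifHit(
                        gene_id=gene_id,
                        motif_name=motif.name,
                        tss_offset_start=i - L,
                        tss_offset_end=i + w - 1 - L,
                        strand_of_hit=strand,
                    )
                )
    if collapse_palindromes:
        seen: set[tuple[str, int, int]] = set()
        kept = []
        for h in sorted(hits, key=lambda h: (h.motif_name, h.tss_offset_start,
                                             h.strand_of_hit)):
            key = (h.motif_name, h.tss_offset_start, h.tss_offset_end)
            if key in seen:
                continue
            seen.add(key)
            kept.append(h)
        hits = kept
    hits.sort(key=lambda h: (h.tss_offset_start, h.motif_name, h.strand_of_hit))
    return hits


def find_paired_ibox(
    hits: list[MotifHit],
    spacer_min: int = 20,
    spacer_max: int = 30,
    max_tss_distance: int = 168,
    motif_name: str = "I-box",
    spacer_mode: str = "gap",
) -> list[MotifPair]:
    """Find same-motif pairs matching the paired-I-box architecture.

    A pair is two non-overlapping hits of ``motif_name`` (hit_a upstream of
    hit_b) whose spacer lies in [spacer_min, spacer_max] and whose
    downstream element ends within ``max_tss_distance`` bp of the TSS.
    ``spacer_mode`` 'gap' measures end-of-a to start-of-b; 'start' measures
    start-to-start.  Pairs are reported nearest-to-TSS first.
    """
    if spacer_mode not in ("gap", "start"):
        raise InputError("spacer_mode must be 'gap' or 'start'")
    relevant = sorted(
        (h for h in hits if h.motif_name == motif_name),
        key=lambda h: h.tss_offset_start,
    )
    pairs: list[MotifPair] = []
    seen: set[tuple[int, int, int, int]] = set()
    for i, a in enumerate(relevant):
        for b in relevant[i + 1:]:
            if b.tss_offset_start <= a.tss_offset_end:
                continue  # overlapping or identical position
            if spacer_mode == "gap":
                spacer = b.tss_offset_start - a.tss_offset_end - 1
            else:
                spacer = b.tss_offset_start - a.tss_offset_start
            tss_distance = -b.tss_offset_end - 1
            if not (spacer_min <= spacer <= spacer_max):
                continue
            if tss_distance > max_tss_distance:
                continue
            key = (a.tss_offset_start, a.tss_offset_end,
                   b.tss_offset_start, b.tss_offset_end)
            if key in seen:
                continue  # strand duplicates of palindromic motifs
            seen.add(key)
            pairs.append(
                MotifPair(
                    gene_id=a.gene_id,
                    hit_a=a,
                    hit_b=b,
                    spacer_bp=spacer,
                    tss_distance_bp=tss_distance,
                )
            )
    pairs.sort(key=lambda p: p.tss_distance_bp)
    return pairs


def cre_composition(
    hits_by_gene: dict[str, list[MotifHit]],
    library: list[Motif],
    gene_species: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Presence/absence matrix and per-species function-class percentages.

    Returns ``(presence, composition)``: a binary gene × motif matrix and a
    species × function_class table of percentages of motif occurrences
    (rows sum to 100).  With no ``gene_species`` map all genes are pooled
    under species "all".
    """
    by_name = {m.name: m for m in library}
    for hits in hits_by_gene.values():
        for h in hits:
            if h.motif_name not in by_name:
                raise InputError(f"hit motif {h.motif_name!r} not in library")
    genes = sorted(hits_by_gene)
    motif_names = [m.name for m in library]
    presence = pd.DataFrame(0, index=genes, columns=motif_names, dtype=int)
    counts: dict[tuple[str, str], int] = {}
    for gene, hits in hits_by_gene.items():
        species = (gene_species or {}).get(gene, "all")
        for h in hits:
            presence.loc[gene, h.motif_name] = 1
            cls = by_name[h.motif_name].function_class
            counts[(species, cls)] = counts.get((species, cls), 0) + 1
    species_list = sorted({s for s, _ in counts} | set((gene_species or {}).values()))
    classes = sorted({m.function_class for m in library})
    comp = pd.DataFrame(0.0, index=species_list or ["all"], columns=classes)
    for (species, cls), n in counts.items():
        comp.loc[species, cls] = n
    totals = comp.sum(axis=1)
    nonzero = totals > 0
    comp.loc[nonzero] = comp.loc[nonzero].div(totals[nonzero], axis=0) * 100.0
    return presence, comp
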