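"""Candidate-substitution screening on the RuBisCO complex.

Three steps of the screen, plus a superposition utility:

1. :func:`interface_contacts` — small-subunit residues whose heavy atoms
   come within a distance cutoff (default 4 Å) of any large-subunit chain.
2. :func:`map_residue_to_column` — translate a residue position in one
   sequence into an alignment column (and back), so a structural position
   can be compared across species.
3. :func:`classify_divergence` — call a column a C3/C4-divergent candidate
   when some residue is carried by at least half of the C4 species and by
   no C3 species (strict) or by at most k C3 species (relaxed).
4. :func:`kabsch_rmsd` — least-squares superposition RMSD between paired
   point sets (proper rotation enforced).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InputError
from .io_core import AtomRecord, SequenceRecord

GAP_CHARACTERS = set("-.")


@dataclass(frozen=True)
class ContactResidue:
    """A small-subunit residue with its minimum heavy-atom distance to the
    large subunit."""

    chain_id: str
    residue_index: int
    residue_name: str
    min_interchain_distance: float

    def __post_init__(self) -> None:
        if self.min_interchain_distance <= 0:
            raise InputError("contact distance must be > 0")


@dataclass(frozen=True)
class DivergenceCall:
    """Classification of one alignment column against the C3/C4 partition."""

    alignment_column: int
    reference_position: int | None
    c4_residues: tuple[str, ...]
    c3_residues: tuple[str, ...]
    candidate_residue: str | None
    mode: str
    is_candidate: bool


def interface_contacts(
    atoms: list[AtomRecord],
    small_chains: set[str] | list[str],
    large_chains: set[str] | list[str],
    cutoff: float = 4.0,
) -> list[ContactResidue]:
    """Small-subunit residues within ``cutoff`` Å of any large-subunit atom.

    Hydrogens are excluded; a residue is included iff the minimum Euclidean
    distance over (its heavy atoms × all large-chain heavy atoms) is
    ≤ ``cutoff``.  Distances are reported to 3 dp.
    """
    small = set(small_chains)
    large = set(large_chains)
    if not small or not large:
        raise InputError("both chain sets must be non-empty")
    if small & large:
        raise InputError(f"chain sets overlap: {sorted(small & large)}")
    present = {a.chain_id for a in atoms}
    missing = (small | large) - present
    if missing:
        raise InputError(f"chains absent from structure: {sorted(missing)}")

    heavy = [a for a in atoms if a.element.upper() not in ("H", "D")]
    large_xyz = np.array(
        [(a.x, a.y, a.z) for a in heavy if a.chain_id in large]
    )
    contacts: list[ContactResidue] = []
    residues: dict[tuple[str, int], list[AtomRecord]] = {}
    for a in heavy:
        if a.chain_id in small:
            residues.setdefault((a.chain_id, a.residue_index), []).append(a)
    for (chain, idx) in sorted(residues):
        group = residues[(chain, idx)]
        xyz = np.array([(a.x, a.y, a.z) for a in group])
        dmin = float(cdist(xyz, large_xyz).min())
        if dmin <= cutoff:
            contacts.append(
                ContactResidue(
                    chain_id=chain,
                    residue_index=idx,
                    residue_name=group[0].residue_name,
                    min_interchain_distance=round(dmin, 3),
                )
            )
    return contacts


def _row(alignment: list[SequenceRecord], seq_id: str) -> str:
    for rec in alignment:
        if rec.id == seq_id:
            return rec.sequence
    raise InputError(f"sequence {seq_id!r} not in alignment")


def map_residue_to_column(
    alignment: list[SequenceRecord], seq_id: str, residue_position: int
) -> int:
    """1-based alignment column holding the ``residue_position``-th residue
    of ``seq_id`` (gaps skipped)."""
    row = _row(alignment, seq_id)
    if residue_position < 1:
        raise InputError("residue_position must be >= 1")
    count = 0
    for col, char in enumerate(row, start=1):
        if char not in GAP_CHARACTERS:
            count += 1
            if count == residue_position:
                return col
    raise InputError(
        f"{seq_id!r}: position {residue_position} beyond ungapped length {count}"
    )


def map_column_to_residue(
    alignment: list[SequenceRecord], seq_id: str, column: int
) -> int | None:
    """Inverse of :func:`map_residue_to_column`; None for gap columns."""
    row = _row(alignment, seq_id)
    if not (1 <= column <= len(row)):
        raise InputError(f"column {column} outside alignment of length {len(row)}")
    if row[column - 1] in GAP_CHARACTERS:
        return None
    return sum(1 for c in row[:column] if c not in GAP_CHARACTERS)


def classify_divergence(
    alignment_column_residues: dict[str, str],
    c4_species: set[str] | list[str],
    c3_species: set[str] | list[str],
    mode: str = "strict",
    k: int = 0,
    alignment_column: int = 0,
    reference_position: int | None = None,
) -> DivergenceCall:
    """Call one alignment column as C3/C4-divergent or not.

    Strict: candidate iff some residue r occurs in ≥ ⌈|C4|/2⌉ of the C4
    species and in zero C3 species.  Relaxed(k): up to ``k`` C3 species may
    carry r.  Gap characters are ignored in the counts.
    """
    c4 = set(c4_species)
    c3 = set(c3_species)
    if not c4:
        raise InputError("C4 species set must be non-empty")
    if c4 & c3:
        raise InputError(f"species in both groups: {sorted(c4 & c3)}")
    if mode not in ("strict", "relaxed"):
        raise InputError("mode must be 'strict' or 'relaxed'")
    allowed_c3 = 0 if mode == "strict" else k

    def residues_of(group: set[str]) -> list[str]:
        out = []
        for sp in sorted(group):
            r = alignment_column_residues.get(sp, "-").upper()
            if r not in GAP_CHARACTERS:
                out.append(r)
        return out

    c4_res = residues_of(c4)
    c3_res = residues_of(c3)
    c3_counts = Counter(c3_res)
    need = math.ceil(len(c4) / 2)

    candidate_residue = None
    for r, n_c4 in Counter(c4_res).most_common():
        if n_c4 >= need and c3_counts.get(r, 0) <= allowed_c3:
            candidate_residue = r
            break
    return DivergenceCall(
        alignment_column=alignment_column,
        reference_position=reference_position,
        c4_residues=tuple(c4_res),
        c3_residues=tuple(c3_res),
        candidate_residue=candidate_residue,
        mode=mode if mode == "strict" else f"relaxed({k})",
        is_candidate=candidate_residue is not None,
    )


def screen_alignment(
    alignment: list[SequenceRecord],
    reference_id: str,
    reference_positions: list[int],
    c4_species: set[str] | list[str],
    c3_species: set[str] | list[str],
    mode: str = "strict",
    k: int = 0,
) -> list[DivergenceCall]:
    """Classify a set of reference-numbered positions across an alignment.

    Positions are given in the ungapped numbering of ``reference_id``
    (e.g. the structural contact residues); each is mapped to its alignment
    column and classified.  Calls are returned in input order.
    """
    calls = []
    for pos in reference_positions:
        col = map_residue_to_column(alignment, reference_id, pos)
        column_residues = {
            rec.id: rec.sequence[col - 1] for rec in alignment
        }
        calls.append(
            classify_divergence(
                column_residues, c4_species, c3_species, mode=mode, k=k,
                alignment_column=col, reference_position=pos,
            )
        )
    return calls


def kabsch_rmsd(coords_a, coords_b) -> float:
    """RMSD after optimal rigid-body superposition (Kabsch algorithm).

    Point correspondence is by order; a proper rotation (det = +1) is
    enforced.  Degenerate (collinear) point sets trigger a warning but the
    result is still defined.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise InputError("coordinate sets must be matching (n, 3) arrays")
    if A.shape[0] < 3:
        raise InputError("at least 3 points are required")
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    if np.linalg.matrix_rank(Ac) < 2 or np.linalg.matrix_rank(Bc) < 2:
        warnings.warn(
            "collinear point set: superposition is degenerate", stacklevel=2
        )
    H = Ac.T @ Bc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = (R @ Ac.T).T - Bc
    return float(np.sqrt((diff ** 2).sum() / A.shape[0]))
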