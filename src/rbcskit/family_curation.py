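"""Family membership screening: homology filter and domain-presence screen.

Candidates are retained when they pass a global-alignment identity/coverage
filter against a reference family member (the identity ≥ 90% / coverage ≥
80% rule used to count family copies across genomes) and when they carry
the family's conserved domains.  Domain presence is approximated by local
alignment against an editable consensus model rather than a profile HMM;
the shipped default consensus strings are synthetic placeholders meant to
be replaced by curated models.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import AlphabetError, FormatError, InputError
from .io_core import PROTEIN_ALPHABET, SequenceRecord


@dataclass(frozen=True)
class HomologyHit:
    """Alignment metrics for one candidate against the reference."""

    query_id: str
    target_id: str
    percent_identity: float
    query_coverage: float
    aligned_length: int

    def __post_init__(self) -> None:
        if not (0 <= self.percent_identity <= 100):
            raise InputError("percent_identity must be in [0, 100]")
        if not (0 <= self.query_coverage <= 100):
            raise InputError("query_coverage must be in [0, 100]")


@dataclass(frozen=True)
class DomainModel:
    """A named domain consensus with a minimum self-score fraction."""

    name: str
    consensus: str
    min_score_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.consensus:
            raise FormatError(f"domain {self.name!r}: empty consensus")
        if not (0 <= self.min_score_fraction <= 1):
            raise InputError("min_score_fraction must be in [0, 1]")


def default_domain_models() -> list[DomainModel]:
    """Editable stand-ins for the two RBCS domains (transit peptide region
    and the RuBisCO small-subunit domain).  Synthetic placeholder consensus
    strings — replace with curated models for real screening."""
    return [
        DomainModel(
            name="rbcs-transit-like",
            consensus="MASSMLSSATVATRSNVAQANMVAPFTGLKSAASFPVSRKQNLD",
        ),
        DomainModel(
            name="rbcs-domain-like",
            consensus=(
                "QVWPPINKKKYETLSYLPDLSQEQLLSEVEYLLRNGWVPCLEFELEHGFVYREHN"
                "KSPGYYDGRYWTMWKLPMFGCTDATQVLAEVEEAKKAYPQAWIRIIGFDNVRQVQ"
            ),
        ),
    ]


def _protein_aligner(mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def _check_protein(rec: SequenceRecord) -> None:
    bad = set(rec.sequence) - PROTEIN_ALPHABET
    if bad:
        raise AlphabetError(
            f"record {rec.id!r} is not a protein sequence "
            f"(offending characters: {sorted(bad)})"
        )


def _identity_and_coverage(
    aligner: PairwiseAligner, reference: str, candidate: str
) -> tuple[float, float, int]:
    """(percent identity over aligned columns, reference coverage %, aligned length)."""
    alignment = aligner.align(reference, candidate)[0]
    matches = 0
    aligned_cols = 0
    ref_covered = 0
    for (r0, r1), (c0, c1) in zip(*alignment.aligned):
        aligned_cols += r1 - r0
        ref_covered += r1 - r0
        for i, j in zip(range(r0, r1), range(c0, c1)):
            if reference[i] == candidate[j]:
                matches += 1
    identity = 100.0 * matches / aligned_cols if aligned_cols else 0.0
    coverage = 100.0 * ref_covered / len(reference)
    return identity, coverage, aligned_cols


def filter_by_homology(
    candidates: list[SequenceRecord],
    reference: SequenceRecord,
    min_identity: float = 90.0,
    min_coverage: float = 80.0,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Retain candidates by global-alignment identity and reference coverage.

    Identity is counted over non-gap aligned columns; coverage is the
    fraction of reference positions aligned to a candidate residue.  A
    candidate is retained iff identity ≥ ``min_identity`` AND coverage ≥
    ``min_coverage``.  Returns the retained records and a per-candidate
    report (columns: candidate, percent_identity, query_coverage,
    aligned_length, retained).
    """
    _check_protein(reference)
    aligner = _protein_aligner("global")
    rows = []
    retained: list[SequenceRecord] = []
    for cand in candidates:
        _check_protein(cand)
        identity, coverage, ncols = _identity_and_coverage(
            aligner, reference.sequence, cand.sequence
        )
        keep = identity >= min_identity and coverage >= min_coverage
        rows.append((cand.id, round(identity, 2), round(coverage, 2),
                     ncols, keep))
        if keep:
            retained.append(cand)
    report = pd.DataFrame(
        rows,
        columns=["candidate", "percent_identity", "query_coverage",
                 "aligned_length", "retained"],
    )
    return retained, report


def screen_domains(
    candidates: list[SequenceRecord],
    domain_models: list[DomainModel],
) -> tuple[list[SequenceRecord], list[tuple[SequenceRecord, str]]]:
    """Split candidates into domain-complete and truncated.

    A candidate is retained iff, for every required domain, its best local
    alignment score against the domain consensus reaches
    ``min_score_fraction`` of the consensus self-score.  Removed candidates
    are returned with the name of the first failing domain.
    """
    if not domain_models:
        raise InputError("at least one domain model is required")
    aligner = _protein_aligner("local")
    self_scores = {
        d.name: aligner.align(d.consensus, d.consensus).score
        for d in domain_models
    }
    retained: list[SequenceRecord] = []
    removed: list[tuple[SequenceRecord, str]] = []
    for cand in candidates:
        _check_protein(cand)
        failure = None
        for dom in domain_models:
            try:
                score = aligner.align(dom.consensus, cand.sequence).score
            except Exception:
                score = float("-inf")
            if score < dom.min_score_fraction * self_scores[dom.name]:
                failure = (
                    f"truncated: {dom.name} score {score:.1f} < "
                    f"{dom.min_score_fraction:.2f} × self-score "
                    f"{self_scores[dom.name]:.1f}"
                )
                break
        if failure is None:
            retained.append(cand)
        else:
            removed.append((cand, failure))
    return retained, removed
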