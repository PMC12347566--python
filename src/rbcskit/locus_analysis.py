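"""Tandem-array detection, copy-number summaries and genome-size correlation.

A tandem duplication array is a run of ≥ 2 family genes on one chromosome
in which consecutive genes are separated by at most ``max_gap_bp``.  The
clustering gap is configurable (default 300 kb, the order of magnitude of
reported RBCS array spans); spans are reported both as the distance between
outermost coordinates (max(end) − min(start)) and as the inclusive +1
variant, since published span conventions differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, UndefinedStatisticError
from .io_core import GeneModel


@dataclass
class TandemArray:
    """≥ 2 clustered family genes on one chromosome, sorted by start."""

    species: str
    chromosome: str
    member_gene_ids: list[str]
    span_bp: int
    span_bp_inclusive: int

    def __post_init__(self) -> None:
        if len(self.member_gene_ids) < 2:
            raise InputError("a tandem array needs at least 2 members")


@dataclass(frozen=True)
class CopyNumberRecord:
    """Per-species copy number with genome size and category labels."""

    species: str
    copy_number: int
    genome_size_mbp: float
    metabolism: str = ""  # "C3" | "C4"
    climate: str = ""     # "warm" | "cold"

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise InputError("copy_number must be >= 0")
        if self.genome_size_mbp <= 0:
            raise InputError("genome_size_mbp must be > 0")


def detect_tandem_arrays(
    genes: list[GeneModel], max_gap_bp: int = 300_000
) -> tuple[list[TandemArray], list[GeneModel]]:
    """Chain clustered family genes into arrays; return (arrays, dispersed).

    Per chromosome, genes are sorted by start and chained while the gap to
    the previous gene (next.start − prev.end − 1, floored at 0 for
    overlaps) is ≤ ``max_gap_bp``.  Chains of length ≥ 2 become arrays;
    singletons are returned as dispersed copies.  Strand is ignored.
    """
    species = {g.species for g in genes}
    if len(species) > 1:
        raise InputError(f"genes from multiple species: {sorted(species)}")
    sp = species.pop() if species else ""

    arrays: list[TandemArray] = []
    dispersed: list[GeneModel] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)

    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end))
        chain: list[GeneModel] = [members[0]]
        for g in members[1:]:
            gap = max(0, g.start - chain[-1].end - 1)
            if gap <= max_gap_bp:
                chain.append(g)
            else:
                _emit(chain, sp, chrom, arrays, dispersed)
                chain = [g]
        _emit(chain, sp, chrom, arrays, dispersed)
    return arrays, dispersed


def _emit(chain, species, chromosome, arrays, dispersed) -> None:
    if len(chain) >= 2:
        lo = min(g.start for g in chain)
        hi = max(g.end for g in chain)
        arrays.append(
            TandemArray(
                species=species,
                chromosome=chromosome,
                member_gene_ids=[g.gene_id for g in chain],
                span_bp=hi - lo,
                span_bp_inclusive=hi - lo + 1,
            )
        )
    else:
        dispersed.extend(chain)


def copy_number_summary(
    records: list[CopyNumberRecord], group_by: str
) -> pd.DataFrame:
    """Arithmetic mean copy number per group (2 dp), with per-group n.

    ``group_by`` is ``"metabolism"`` or ``"climate"``; records with an
    empty label for that category are omitted with a warning.
    """
    if group_by not in ("metabolism", "climate"):
        raise InputError("group_by must be 'metabolism' or 'climate'")
    groups: dict[str, list[int]] = {}
    skipped = 0
    for r in records:
        label = getattr(r, group_by)
        if not label:
            skipped += 1
            continue
        groups.setdefault(label, []).append(r.copy_number)
    if skipped:
        warnings.warn(
            f"{skipped} record(s) without a {group_by} label omitted",
            stacklevel=2,
        )
    rows = [
        (label, round(float(np.mean(values)), 2), len(values))
        for label, values in sorted(groups.items())
    ]
    return pd.DataFrame(rows, columns=[group_by, "mean_copy_number", "n"])


def pearson_correlation(x, y) -> tuple[float, float, float]:
    """Product-moment correlation with Student-t two-sided p-value.

    r is computed by the product-moment formula; the test statistic is
    t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom.  Requires n ≥ 3 and
    nonzero variance in both variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise InputError("pearson_correlation requires n >= 3")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = float(np.sqrt((dx ** 2).sum()))
    sy = float(np.sqrt((dy ** 2).sum()))
    if sx == 0.0 or sy == 0.0:
        raise UndefinedStatisticError(
            "correlation undefined: zero variance in x or y"
        )
    r = float((dx * dy).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, float("inf") if r > 0 else float("-inf"), 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return r, float(t), p
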