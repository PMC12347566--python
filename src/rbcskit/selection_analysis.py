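"""Selection analysis: likelihood-ratio tests over nested codon models and a
Nei–Gojobori (1986) counting dN/dS estimator.

Full maximum-likelihood fitting of branch and branch-site codon models is
out of scope; published model fits enter as :class:`BranchModelRecord`
(model name, parameter count np, log-likelihood lnL), and the LRT
arithmetic — 2ΔL = 2(lnL_alt − lnL_null) against a chi-square with
df = np_alt − np_null — is reproduced exactly.  The in-repo ω estimator is
NG86 with equal-weight pathway averaging and a Jukes–Cantor multiple-hit
correction, adequate for ordering and recovery analyses on simulated
alignments.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .codons import (
    is_stop,
    pathway_differences,
    synonymous_site_fractions,
)
from .errors import InputError, SaturationError
from .io_core import SequenceRecord, Tree

_VALID_NT = set("ACGT")


@dataclass(frozen=True)
class BranchModelRecord:
    """A fitted codon model summarized by its parameter count and lnL."""

    model_name: str
    np: int
    lnL: float
    parameter_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.np < 1:
            raise InputError("np must be >= 1")
        if not np_isfinite(self.lnL):
            raise InputError("lnL must be finite")


def np_isfinite(x: float) -> bool:
    return np.isfinite(x)


@dataclass(frozen=True)
class LRTResult:
    """2ΔL, degrees of freedom and chi-square p-value for a nested pair."""

    two_delta_L: float
    df: int
    p_value: float


@dataclass(frozen=True)
class DnDsEstimate:
    """NG86 pairwise estimate: site counts, difference counts, distances, ω."""

    dN: float
    dS: float
    omega: float | None
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    n_codons_compared: int
    n_codons_excluded: int = 0

    @property
    def omega_defined(self) -> bool:
        return self.omega is not None


def chisq_sf(x: float, df: int) -> float:
    """Upper-tail chi-square probability P(X² ≥ x) on ``df`` degrees of freedom."""
    if x < 0:
        raise InputError(f"chi-square statistic must be >= 0 (got {x})")
    if df < 1 or int(df) != df:
        raise InputError("df must be a positive integer")
    return float(stats.chi2.sf(x, df))


def likelihood_ratio_test(
    alternative: BranchModelRecord, null: BranchModelRecord
) -> LRTResult:
    """LRT for a nested model pair: 2ΔL = 2(lnL_alt − lnL_null), df = Δnp.

    A negative 2ΔL (possible with rounded published lnL values) is clamped
    to 0 with a warning.  Nesting itself is the caller's responsibility;
    np_alt ≤ np_null raises.
    """
    if alternative.np <= null.np:
        raise InputError(
            f"alternative model must have more parameters than the null "
            f"({alternative.np} <= {null.np})"
        )
    two_delta = 2.0 * (alternative.lnL - null.lnL)
    if two_delta < 0:
        warnings.warn(
            f"2ΔL = {two_delta:.4f} < 0 (alternative fits worse); clamped to 0",
            stacklevel=2,
        )
        two_delta = 0.0
    df = alternative.np - null.np
    return LRTResult(
        two_delta_L=round(two_delta, 10),
        df=df,
        p_value=chisq_sf(two_delta, df),
    )


def read_branch_models(path: str | Path) -> dict[str, BranchModelRecord]:
    """Read a model-record TSV (columns model_name, np, lnL) keyed by name."""
    df = pd.read_csv(path, sep="\t")
    required = {"model_name", "np", "lnL"}
    if not required <= set(df.columns):
        raise InputError(f"model table must have columns {sorted(required)}")
    return {
        str(r["model_name"]): BranchModelRecord(
            model_name=str(r["model_name"]), np=int(r["np"]), lnL=float(r["lnL"])
        )
        for _, r in df.iterrows()
    }


def _codons_of(seq: str, label: str) -> list[str]:
    seq = seq.upper()
    if len(seq) % 3:
        raise InputError(f"{label}: length {len(seq)} not divisible by 3")
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]


def _jukes_cantor(p: float, label: str) -> float:
    if p >= 0.75:
        raise SaturationError(
            f"{label} proportion {p:.3f} >= 0.75: Jukes-Cantor correction "
            f"diverges (saturated comparison)"
        )
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def ng86_pairwise(seq_a, seq_b) -> DnDsEstimate:
    """NG86 counting estimate of dN, dS and ω between two aligned CDSs.

    Synonymous site fractions are averaged over the two sequences; multi-hit
    codons are averaged over all stop-free mutational pathways; proportions
    are corrected with Jukes–Cantor.  Codons containing ambiguous or gap
    characters are excluded pairwise (count reported); stop codons raise.
    ω is None (flagged undefined) when dS = 0.
    """
    a = seq_a.sequence if isinstance(seq_a, SequenceRecord) else str(seq_a)
    b = seq_b.sequence if isinstance(seq_b, SequenceRecord) else str(seq_b)
    if len(a) != len(b):
        raise InputError("sequences must be aligned to equal length")
    codons_a = _codons_of(a, "sequence A")
    codons_b = _codons_of(b, "sequence B")

    S = N = Sd = Nd = 0.0
    compared = excluded = 0
    for ca, cb in zip(codons_a, codons_b):
        if not (set(ca) <= _VALID_NT and set(cb) <= _VALID_NT):
            excluded += 1
            continue
        if is_stop(ca) or is_stop(cb):
            raise InputError(f"stop codon in comparison: {ca}/{cb}")
        compared += 1
        sa = sum(synonymous_site_fractions(ca))
        sb = sum(synonymous_site_fractions(cb))
        S += (sa + sb) / 2.0
        N += 3.0 - (sa + sb) / 2.0
        sd, nd = pathway_differences(ca, cb)
        Sd += sd
        Nd += nd
    if compared == 0:
        raise InputError("no comparable codons (all ambiguous or excluded)")

    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jukes_cantor(pS, "synonymous") if S > 0 else 0.0
    dN = _jukes_cantor(pN, "nonsynonymous") if N > 0 else 0.0
    omega = (dN / dS) if dS > 0 else None
    return DnDsEstimate(
        dN=float(dN), dS=float(dS), omega=omega,
        N_sites=N, S_sites=S, Nd=Nd, Sd=Sd,
        n_codons_compared=compared, n_codons_excluded=excluded,
    )


def group_omega_summary(
    alignment: list[SequenceRecord],
    tree: Tree,
    branch_groups: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean within-group pairwise NG86 ω per branch group, plus contrasts.

    Leaves are assigned to groups via ``branch_groups`` (falling back to
    the tree's own labels); groups with < 2 leaves are skipped with a
    warning, and pairs with undefined ω (dS = 0) are skipped with a count.
    Returns ``(summary, contrasts)``: per-group means and all pairwise
    differences of group means.
    """
    groups = dict(tree.branch_groups)
    groups.update(branch_groups or {})
    by_id = {rec.id: rec for rec in alignment}
    members: dict[str, list[str]] = {}
    for leaf in tree.leaf_labels():
        if leaf not in by_id:
            raise InputError(f"leaf {leaf!r} missing from alignment")
        g = groups.get(leaf)
        if g is None:
            raise InputError(f"leaf {leaf!r} has no branch-group label")
        members.setdefault(g, []).append(leaf)

    rows = []
    means: dict[str, float] = {}
    for g in sorted(members):
        leaves = members[g]
        if len(leaves) < 2:
            warnings.warn(
                f"group {g!r} has {len(leaves)} leaf; skipped", stacklevel=2
            )
            continue
        omegas = []
        undefined = 0
        for x, y in itertools.combinations(leaves, 2):
            est = ng86_pairwise(by_id[x], by_id[y])
            if est.omega is None:
                undefined += 1
            else:
                omegas.append(est.omega)
        mean_omega = float(np.mean(omegas)) if omegas else float("nan")
        means[g] = mean_omega
        rows.append((g, mean_omega, len(omegas), undefined, len(leaves)))
    summary = pd.DataFrame(
        rows,
        columns=["group", "mean_omega", "n_pairs", "n_undefined_skipped",
                 "n_leaves"],
    )
    contrasts = pd.DataFrame(
        [
            (g1, g2, means[g1] - means[g2])
            for g1, g2 in itertools.combinations(sorted(means), 2)
        ],
        columns=["group_a", "group_b", "mean_omega_difference"],
    )
    return summary, contrasts
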