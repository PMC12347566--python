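"""Expression shares within a gene family and winter/spring group comparison.

Shares are unit-free within a sample (TPM or FPKM both work); the
winter-vs-spring comparison sums TPM over family members per sample and
applies a pooled-variance Student t-test.  The percent difference uses the
winter mean as denominator: 100 × (W − S) / W, signed (negative when
spring exceeds winter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, UndefinedStatisticError


@dataclass(frozen=True)
class GroupComparison:
    """Winter-vs-spring summary for one tissue."""

    tissue: str
    mean_winter: float
    mean_spring: float
    percent_difference: float
    t_statistic: float
    p_two_sided: float
    n_winter: int
    n_spring: int


def relative_abundance(
    matrix: pd.DataFrame, family_gene_ids: list[str], sample: str
) -> pd.Series:
    """Per-gene share (%) of the family's total TPM in one sample.

    percentage_g = 100 × TPM_g / Σ_family TPM; output sums to 100.
    Raises :class:`UndefinedStatisticError` when the family sum is 0.
    """
    missing = [g for g in family_gene_ids if g not in matrix.index]
    if missing:
        raise InputError(f"genes not in matrix: {missing}")
    if sample not in matrix.columns:
        raise InputError(f"sample {sample!r} not in matrix")
    values = matrix.loc[family_gene_ids, sample].astype(float)
    total = float(values.sum())
    if total <= 0:
        raise UndefinedStatisticError(
            f"family TPM sum is 0 in sample {sample!r}: shares undefined"
        )
    return 100.0 * values / total


def group_percent_difference(w_mean: float, s_mean: float) -> float:
    """100 × (W − S) / W: how much higher winter expression is than spring."""
    if w_mean <= 0:
        raise UndefinedStatisticError(
            "percent difference undefined for winter mean <= 0"
        )
    return 100.0 * (w_mean - s_mean) / w_mean


def students_t_test(group_a, group_b) -> tuple[float, int, float]:
    """Two-sample pooled-variance Student t-test.

    Returns ``(t, df, p_two_sided)`` with df = n_a + n_b − 2.  When the
    pooled variance is zero: equal means give (0, df, 1); unequal means
    give an infinite t with p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise InputError("each group needs at least 2 observations")
    df = na + nb - 2
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0, df, 1.0
        return math.copysign(float("inf"), diff), df, 0.0
    t = diff / math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(stats.t.sf(abs(t), df=df))
    return float(t), df, p


def welch_t_test(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance alternative (not the default convention here)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    df = (va + vb) ** 2 / (
        va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1)
    )
    return float(t), float(df), float(p)


def compare_growth_habits(
    matrix: pd.DataFrame,
    sample_groups: dict[str, str],
    family_gene_ids: list[str] | None = None,
    tissue: str = "",
    welch: bool = False,
) -> GroupComparison:
    """Family-level winter/spring comparison for one expression matrix.

    TPM is summed over family members per sample; the two group
    distributions of summed TPM are compared with a Student t-test (Welch
    behind a flag) and the winter-denominator percent difference.
    """
    genes = family_gene_ids if family_gene_ids is not None else list(matrix.index)
    sums = matrix.loc[genes].sum(axis=0)
    winter = [s for s in matrix.columns if sample_groups.get(s) == "winter"]
    spring = [s for s in matrix.columns if sample_groups.get(s) == "spring"]
    if len(winter) < 2 or len(spring) < 2:
        raise InputError("each growth habit needs at least 2 samples")
    w, s = sums[winter].to_numpy(), sums[spring].to_numpy()
    if welch:
        t, _, p = welch_t_test(w, s)
    else:
        t, _, p = students_t_test(w, s)
    w_mean, s_mean = float(w.mean()), float(s.mean())
    return GroupComparison(
        tissue=tissue,
        mean_winter=w_mean,
        mean_spring=s_mean,
        percent_difference=group_percent_difference(w_mean, s_mean),
        t_statistic=t,
        p_two_sided=p,
        n_winter=len(w),
        n_spring=len(s),
    )
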