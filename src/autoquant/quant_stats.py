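"""Densitometry normalizations and group statistics.

Ratios (marker/loading-control, marker A/marker B), fold changes
relative to a control group, compartment percentages, the two-sided
unpaired t-test (pooled Student by default, Welch optional) and one-way
ANOVA with Šidák-adjusted pairwise comparisons (Bonferroni available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "GroupComparison",
    "normalized_ratio",
    "fold_change",
    "compartment_percentages",
    "unpaired_t_test",
    "one_way_anova",
]


@dataclass
class GroupComparison:
    """Result of one two-group comparison (possibly under an ANOVA)."""

    groups: tuple[str, str]
    means: tuple[float, float]
    sems: tuple[float, float]
    ns: tuple[int, int]
    statistic: float
    df: float
    p: float
    p_adjusted: float
    method: str


def normalized_ratio(numerator, denominator):
    """Elementwise marker/denominator ratio (loading control or paired marker)."""
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if (den <= 0).any():
        raise InputError("denominator intensities must be strictly positive")
    return num / den


def fold_change(values: pd.Series, groups: pd.Series, control: str) -> pd.Series:
    """Rescale values so that the control group's mean is 1."""
    groups = pd.Series(groups).reset_index(drop=True)
    values = pd.Series(values, dtype=float).reset_index(drop=True)
    ctrl = values[groups == control]
    if ctrl.empty:
        raise InputError(f"control group {control!r} is empty")
    m = ctrl.mean()
    if m <= 0:
        raise InputError(f"control group mean must be positive, got {m}")
    return values / m


def compartment_percentages(bands) -> np.ndarray:
    """Express each band as a percentage of the summed intensities."""
    b = np.asarray(bands, dtype=float)
    if (b < 0).any():
        raise InputError("band intensities must be non-negative")
    total = b.sum()
    if total <= 0:
        raise InputError("all band intensities are zero")
    return 100.0 * b / total


def unpaired_t_test(
    a, b, equal_var: bool = True, labels: tuple[str, str] = ("a", "b")
) -> GroupComparison:
    """Two-sided unpaired t-test (pooled Student by default, Welch optional)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each sample needs n >= 2")
    na, nb = len(a), len(b)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            logger.info("both samples constant and equal; p = 1 by convention")
            t_stat, df, p = 0.0, float(na + nb - 2), 1.0
        else:
            t_stat, df, p = np.inf, float(na + nb - 2), 0.0
    elif equal_var:
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_stat = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        df = float(na + nb - 2)
        p = 2 * stats.t.sf(abs(t_stat), df)
    else:
        va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
        t_stat = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
        p = 2 * stats.t.sf(abs(t_stat), df)
    return GroupComparison(
        groups=labels,
        means=(a.mean(), b.mean()),
        sems=(a.std(ddof=1) / np.sqrt(na), b.std(ddof=1) / np.sqrt(nb)),
        ns=(na, nb),
        statistic=float(t_stat),
        df=df,
        p=float(min(1.0, p)),
        p_adjusted=float(min(1.0, p)),
        method="student_t" if equal_var else "welch_t",
    )


def _adjust(p: float, m: int, method: str) -> float:
    if method == "sidak":
        return 1.0 - (1.0 - p) ** m
    if method == "bonferroni":
        return min(1.0, m * p)
    raise ParameterError(f"unknown adjustment {method!r}")


def one_way_anova(
    samples: dict[str, np.ndarray],
    comparisons: list[tuple[str, str]] | None = None,
    adjust: str = "sidak",
) -> tuple[float, float, list[GroupComparison]]:
    """One-way ANOVA with adjusted pairwise comparisons.

    Returns ``(F, omnibus_p, comparisons)``.  Pairwise t statistics use
    the pooled within-group variance (mean square within) with
    ``N - k`` degrees of freedom; p-values are Šidák-adjusted
    (``1 - (1-p)^m``) over the m requested comparisons, or Bonferroni
    when ``adjust='bonferroni'``.  With no explicit list, all pairs are
    compared.
    """
    if len(samples) < 2:
        raise ParameterError("need at least 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in samples.items()}
    for g, v in arrays.items():
        if len(v) < 2:
            raise ParameterError(f"group {g!r} needs n >= 2")
    names = list(arrays)
    values = list(arrays.values())
    N = sum(len(v) for v in values)
    k = len(values)
    grand = np.concatenate(values).mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in values)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in values)
    df_b, df_w = k - 1, N - k
    msw = ss_within / df_w
    if msw == 0:
        f_stat = 0.0 if ss_between == 0 else np.inf
        p_omni = 1.0 if ss_between == 0 else 0.0
    else:
        f_stat = (ss_between / df_b) / msw
        p_omni = float(stats.f.sf(f_stat, df_b, df_w))

    if comparisons is None:
        comparisons = [
            (names[i], names[j]) for i in range(k) for j in range(i + 1, k)
        ]
    m = len(comparisons)
    results = []
    for ga, gb in comparisons:
        if ga not in arrays or gb not in arrays:
            raise ParameterError(f"unknown group in comparison {(ga, gb)}")
        a, b = arrays[ga], arrays[gb]
        na, nb = len(a), len(b)
        if msw == 0:
            t_stat = 0.0 if a.mean() == b.mean() else np.inf
            p = 1.0 if a.mean() == b.mean() else 0.0
        else:
            t_stat = (a.mean() - b.mean()) / np.sqrt(msw * (1 / na + 1 / nb))
            p = float(2 * stats.t.sf(abs(t_stat), df_w))
        results.append(
            GroupComparison(
                groups=(ga, gb),
                means=(a.mean(), b.mean()),
                sems=(a.std(ddof=1) / np.sqrt(na), b.std(ddof=1) / np.sqrt(nb)),
                ns=(na, nb),
                statistic=float(t_stat),
                df=float(df_w),
                p=min(1.0, p),
                p_adjusted=min(1.0, _adjust(min(1.0, p), m, adjust)),
                method=f"anova_{adjust}",
            )
        )
    return float(f_stat), p_omni, results
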