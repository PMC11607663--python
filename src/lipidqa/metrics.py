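"""Lipidome-level descriptors and group statistics.

Built on blank-subtracted, TUS-normalized quantifier areas: the
abundance-corrected average carbon number and unsaturation degree of each
subclass (area-weighted means of NC and DB over detected members), log2
fold changes between subclass averages, pairwise Mann-Whitney U tests with
Bonferroni correction, and squared Pearson correlations of log-normalized
abundance profiles used to compare lipidomes.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "acc_average",
    "log2fc",
    "pairwise_mannwhitney_bonferroni",
    "profile_correlation",
]

#: subclasses excluded from unsaturation averages: the alkyl/alkenyl linkage
#: was not fully resolved, so their DB bookkeeping is ambiguous
ETHER_UNSAT_EXCLUDED = {"LPC O/P", "LPE O/P", "PC O/P", "PE O/P"}


def acc_average(
    areas: pd.Series,
    properties: pd.Series,
    include_zero: bool = False,
) -> float:
    """Abundance-corrected (area-weighted) mean of a per-species property.

    ``areas`` and ``properties`` are aligned on species; ``properties`` is
    typically NC or DB of the subclass members.  Zero-area (undetected)
    members carry no weight.
    """
    areas, properties = areas.align(properties, join="inner")
    if not include_zero:
        mask = areas > 0
        areas, properties = areas[mask], properties[mask]
    total = float(areas.sum())
    if total <= 0:
        raise ValueError("zero total area: no detected members to average over")
    return float((areas * properties).sum() / total)


def log2fc(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """log2 of the ratio of group means; antisymmetric under swap."""
    ma, mb = float(np.mean(group_a)), float(np.mean(group_b))
    if ma <= 0 or mb <= 0:
        raise ValueError("log2 fold change requires positive group means")
    return math.log2(ma / mb)


def pairwise_mannwhitney_bonferroni(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All-pairs two-sided Mann-Whitney U tests, Bonferroni-adjusted.

    Each group needs n ≥ 3.  The adjusted p-value is min(1, p × number of
    pairs); ``significant`` marks adjusted p < ``alpha``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if len(vals) < 3:
            raise ValueError(f"group {name!r} has n < 3")
    pairs = list(itertools.combinations(sorted(groups), 2))
    rows = []
    for a, b in pairs:
        res = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        p_adj = min(1.0, res.pvalue * len(pairs))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "U": float(res.statistic),
                "p_raw": float(res.pvalue),
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


def profile_correlation(
    profile_a: pd.Series,
    profile_b: pd.Series,
    log_scale: bool = True,
) -> float:
    """Squared Pearson correlation (R²) of two abundance profiles.

    Profiles are aligned on their index (subclass totals or species within a
    subclass), converted to percentages of their own totals, zeros dropped
    pairwise, and — by default — log10-transformed before correlating.
    Requires ≥ 3 shared non-zero entries.
    """
    a, b = profile_a.align(profile_b, join="inner")
    mask = (a > 0) & (b > 0)
    a, b = a[mask], b[mask]
    if len(a) < 3:
        raise ValueError("fewer than 3 shared non-zero entries")
    a = 100.0 * a / a.sum()
    b = 100.0 * b / b.sum()
    if log_scale:
        a, b = np.log10(a), np.log10(b)
    r = stats.pearsonr(a, b).statistic
    return float(r * r)
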