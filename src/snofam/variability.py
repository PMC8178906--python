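"""Coefficient-of-variation statistics at member and family level.

The central comparison is family covariation (CV of the summed abundance of
all expressed members across tissues) against the mean covariation of the
individual expressed members.  The signed perpendicular distance of each
family from the x = y diagonal, ``(family_cv - mean_member_cv) / sqrt(2)``,
is negative when member variability exceeds family variability; the class
comparison of those distances uses a two-sided Mann-Whitney U test.

CV uses the sample standard deviation (ddof=1) by default — the tissue
panel is small — and the convention is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import Family


def coefficient_of_variation(values, ddof: int = 1) -> float:
    """CV in percent: 100 * sd / mean.  NaN when the mean is not positive."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV requires at least two values")
    mean = v.mean()
    if mean <= 0:
        return float("nan")
    return float(100.0 * v.std(ddof=ddof) / mean)


@dataclass(frozen=True)
class VariabilityRecord:
    family_id: str
    family_cv: float
    mean_member_cv: float
    diag_distance: float
    n_expressed: int


def family_variability(family: Family, means: pd.DataFrame,
                       statuses: Mapping[str, bool],
                       ddof: int = 1) -> VariabilityRecord | None:
    """Family vs member CV over tissue means; expressed members only.

    Returns None for families with no expressed member.
    """
    expressed = [m for m in family.member_ids if statuses[m]]
    if not expressed:
        return None
    sub = means.loc[expressed]
    family_cv = coefficient_of_variation(sub.sum(axis=0), ddof=ddof)
    member_cvs = [coefficient_of_variation(sub.loc[m], ddof=ddof) for m in expressed]
    mean_member_cv = float(np.mean(member_cvs))
    diag = (family_cv - mean_member_cv) / math.sqrt(2.0)
    return VariabilityRecord(family.family_id, family_cv, mean_member_cv,
                             diag, len(expressed))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    sidedness: str = "two-sided"


def compare_classes_diag(cd: Sequence[float], haca: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U on diagonal distances of the two snoRNA classes."""
    if len(cd) == 0 or len(haca) == 0:
        raise ValueError("both distance samples must be non-empty")
    res = stats.mannwhitneyu(cd, haca, alternative="two-sided")
    return TestResult(float(res.statistic), float(res.pvalue))


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    method: str


def correlate_size_abundance(families: Sequence[Family],
                             statuses: Mapping[str, bool],
                             matrix: pd.DataFrame,
                             method: str = "pearson",
                             expressed_members_only_sum: bool = False,
                             ) -> dict[str, CorrelationResult | None]:
    """Per class, correlate expressed-member count with total family abundance.

    Abundance is the mean over samples of the summed member TPM.  The sum
    runs over all members by default (unexpressed members contribute their
    near-zero TPM); restricting it to expressed members is available as a
    flag.  Returns None for a class with fewer than 3 families or with zero
    variance in either variable.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    xs: dict[str, list[float]] = {}
    ys: dict[str, list[float]] = {}
    for fam in families:
        members = [m for m in fam.member_ids
                   if not expressed_members_only_sum or statuses[m]]
        n_expr = sum(bool(statuses[m]) for m in fam.member_ids)
        total = float(matrix.loc[members].sum(axis=0).mean()) if members else 0.0
        xs.setdefault(fam.box_type, []).append(float(n_expr))
        ys.setdefault(fam.box_type, []).append(total)

    out: dict[str, CorrelationResult | None] = {}
    for box in xs:
        x, y = np.asarray(xs[box]), np.asarray(ys[box])
        if x.size < 3 or x.std() == 0 or y.std() == 0:
            out[box] = None
            continue
        if method == "pearson":
            r, p = stats.pearsonr(x, y)
        else:
            r, p = stats.spearmanr(x, y)
        out[box] = CorrelationResult(float(r), float(p), int(x.size), method)
    return out
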