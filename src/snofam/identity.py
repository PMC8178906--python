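"""Pairwise sequence identity within snoRNA families.

Identity between two copies is defined through a global alignment that
rewards each matched residue with 1 and penalizes nothing (no mismatch or
gap cost).  The optimal score of that alignment equals the length of the
longest common subsequence (LCS) of the two sequences, so only the score is
computed, never a traceback (the score is unique even when optimal
alignments are not).  The percent identity is::

    100 * LCS(a, b) / min(|a|, |b|)

which is 100 for identical sequences and for a sequence nested in a longer
one; *identical-pair* flagging therefore additionally requires string
equality.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import Family


def lcs_length(a: str, b: str) -> int:
    """Length of the longest common subsequence of ``a`` and ``b``.

    Row-sweep dynamic programme: within one row the recurrence
    ``dp[i][j] = max(dp[i-1][j], dp[i-1][j-1] + eq, dp[i][j-1])`` is evaluated
    as a vectorized running maximum, which is exact because dp rows are
    non-decreasing.
    """
    if not a or not b:
        return 0
    av = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    prev = np.zeros(bv.size + 1, dtype=np.int32)
    for ca in av:
        cand = prev[:-1] + (bv == ca)
        curr = np.maximum(prev[1:], cand)
        np.maximum.accumulate(curr, out=curr)
        prev[1:] = curr
    return int(prev[-1])


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity in (0, 100]: 100 * LCS / length of the shorter sequence."""
    if not seq_a or not seq_b:
        raise ValueError("pairwise identity undefined for empty sequences")
    return 100.0 * lcs_length(seq_a, seq_b) / min(len(seq_a), len(seq_b))


@dataclass(frozen=True)
class IdentityMatrix:
    """Symmetric percent-identity matrix over the members of one family."""

    family_id: str
    member_ids: tuple[str, ...]
    matrix: np.ndarray  # shape (n, n), diagonal fixed at 100

    def __post_init__(self) -> None:
        n = len(self.member_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match member count")

    def member_mean(self) -> pd.Series:
        """Mean identity of each member to all other members (self excluded)."""
        n = len(self.member_ids)
        off = self.matrix.sum(axis=1) - np.diag(self.matrix)
        return pd.Series(off / (n - 1), index=list(self.member_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.member_ids),
                            columns=list(self.member_ids))


def family_identity(family: Family, sequences: Mapping[str, str]) -> IdentityMatrix:
    """Score all unordered member pairs of a multi-member family."""
    if family.size < 2:
        raise ValueError(
            f"identity undefined for singleton family {family.family_id}")
    ids = family.member_ids
    n = len(ids)
    mat = np.full((n, n), 100.0)
    for i, j in combinations(range(n), 2):
        score = pairwise_identity(sequences[ids[i]], sequences[ids[j]])
        mat[i, j] = mat[j, i] = score
    return IdentityMatrix(family.family_id, ids, mat)


def has_identical_pair(family: Family, sequences: Mapping[str, str]) -> bool:
    """True iff some member pair has byte-identical sequences."""
    seen: set[str] = set()
    for mid in family.member_ids:
        seq = sequences[mid]
        if seq in seen:
            return True
        seen.add(seq)
    return False


def find_identical_pairs(families: Sequence[Family],
                         sequences: Mapping[str, str]) -> set[str]:
    """Family ids with at least one pair of members at 100% identity and equal
    length, i.e. with identical sequence strings."""
    return {f.family_id for f in families
            if f.size >= 2 and has_identical_pair(f, sequences)}
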