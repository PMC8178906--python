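"""Member abundance ranking and tissue-switch detection.

A family *switches* when at least two distinct expressed members are the
most abundant one in different tissues.  Top calls are made on tissue means
(not individual samples); a tissue where every expressed member averages
zero yields no call and contributes no switch evidence.  Exact ties within
a tissue resolve to the member with the better overall rank, so
floating-point-level ties cannot manufacture spurious switches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .core_io import Family, SamplePanel
from .expression import NO_TISSUE


def rank_members(family: Family, means: pd.DataFrame,
                 statuses: Mapping[str, bool]) -> list[str]:
    """Expressed members sorted by descending total abundance (sum of tissue
    means); ties break by ascending member id."""
    expressed = [m for m in family.member_ids if statuses[m]]
    totals = {m: float(means.loc[m].sum()) for m in expressed}
    return sorted(expressed, key=lambda m: (-totals[m], m))


def call_top_members(family: Family, means: pd.DataFrame,
                     statuses: Mapping[str, bool]) -> dict[str, str]:
    """Per tissue, the expressed member with the highest mean TPM.

    Tissues where all expressed members average zero map to ``"none"``.
    """
    ranked = rank_members(family, means, statuses)
    if not ranked:
        raise ValueError(f"{family.family_id}: no expressed member to rank")
    rank_of = {m: i for i, m in enumerate(ranked)}
    calls: dict[str, str] = {}
    for tissue in means.columns:
        col = means.loc[ranked, tissue]
        top = float(col.max())
        if top <= 0.0:
            calls[tissue] = NO_TISSUE
            continue
        winners = [m for m in ranked if float(col[m]) == top]
        calls[tissue] = min(winners, key=lambda m: rank_of[m])
    return calls


@dataclass(frozen=True)
class SwitchRecord:
    family_id: str
    member_rank: tuple[str, ...]
    top_member_per_tissue: dict[str, str]
    switch: bool
    n_top_members: int


def detect_switch(family: Family, means: pd.DataFrame,
                  statuses: Mapping[str, bool]) -> SwitchRecord:
    """Build the switch record; families with < 2 expressed members never switch."""
    ranked = rank_members(family, means, statuses)
    if not ranked:
        return SwitchRecord(family.family_id, (), {}, False, 0)
    calls = call_top_members(family, means, statuses)
    tops = {m for m in calls.values() if m != NO_TISSUE}
    switch = len(ranked) >= 2 and len(tops) >= 2
    return SwitchRecord(family.family_id, tuple(ranked), calls, switch, len(tops))


def same_tissue_top_fraction(families: Sequence[Family],
                             member_top_tissue: Mapping[str, str],
                             statuses: Mapping[str, bool]) -> dict[str, tuple[int, int]]:
    """Per class (k, n): among the n families with >= 2 expressed members, the
    k whose expressed members are all most expressed in the same tissue."""
    out: dict[str, tuple[int, int]] = {}
    for fam in families:
        expressed = [m for m in fam.member_ids if statuses[m]]
        if len(expressed) < 2:
            continue
        k, n = out.get(fam.box_type, (0, 0))
        tissues = {member_top_tissue[m] for m in expressed}
        coherent = len(tissues) == 1 and NO_TISSUE not in tissues
        out[fam.box_type] = (k + int(coherent), n + 1)
    return out


def heatmap_matrix(records: Sequence[SwitchRecord],
                   panel: SamplePanel) -> pd.DataFrame:
    """Family x tissue matrix of top-member rank indices (1 = overall top
    member), for families with >= 2 expressed members; 0 marks tissues with
    no call."""
    rows = {}
    for rec in records:
        if len(rec.member_rank) < 2:
            continue
        rank_of = {m: i + 1 for i, m in enumerate(rec.member_rank)}
        rows[rec.family_id] = [
            rank_of.get(rec.top_member_per_tissue.get(t, NO_TISSUE), 0)
            for t in panel.tissue_order]
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=list(panel.tissue_order))
    out.index.name = "family_id"
    return out
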