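"""Genomic context of snoRNA copies: conservation, SNP density, host placement.

Host-transcript assignment follows a deterministic rule: the host gene's
transcripts are sorted by exon count (descending) then transcript name
(ascending), and the first transcript in which the snoRNA is fully intronic
(inside the transcript span, overlapping no exon) is chosen.  The distance
to the downstream exon is then the strand-aware gap in nucleotides between
the snoRNA 3' end and the 5'-most edge of the nearest exon downstream in
transcript orientation — for box C/D snoRNAs this is the distance to the 3'
splice site of the host intron, which peaks near 70 nt for well-expressed
copies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .core_io import ConservationTrack, Family, HostModel, SNPSet, SnoRNARecord

CONTEXT_CATEGORIES = ("coding_only", "noncoding_only", "intergenic_only", "mixed")
UNDEFINED_CATEGORY = "undefined"


def conservation_score(snorna: SnoRNARecord, track: ConservationTrack,
                       uncovered_zero: bool = True) -> float:
    """Mean per-nucleotide conservation over the snoRNA interval.

    Nucleotides with no covering track interval contribute 0 by default
    (the average is over *all* nucleotides of the snoRNA); with
    ``uncovered_zero=False`` they are dropped from the denominator instead.
    """
    total, covered = track.covered_score_sum(snorna.chrom, snorna.start, snorna.end)
    denom = snorna.length if uncovered_zero else covered
    if denom == 0:
        return 0.0
    return total / denom


def snp_density(snorna: SnoRNARecord, snps: SNPSet) -> float:
    """SNPs per kilobase of snoRNA: 1000 * count(sites in [start, end)) / length."""
    return 1000.0 * snps.count_in(snorna.chrom, snorna.start, snorna.end) / snorna.length


@dataclass(frozen=True)
class HostPlacement:
    snorna_id: str
    transcript_id: str | None
    intronic: bool
    distance_to_downstream_exon: int | None

    def __post_init__(self) -> None:
        if self.intronic and self.distance_to_downstream_exon is None:
            raise ValueError("intronic placement requires a distance")
        if not self.intronic and self.distance_to_downstream_exon is not None:
            raise ValueError("distance defined only for intronic placements")


def assign_host_transcript(snorna: SnoRNARecord, host: HostModel) -> HostPlacement:
    """Choose the host transcript and measure the downstream-exon distance.

    Returns a non-intronic placement when the snoRNA has no host gene in the
    model or when it overlaps exons of (or falls outside) every transcript.
    """
    gid = snorna.host_gene_id
    if gid is None or gid not in host.genes:
        return HostPlacement(snorna.snorna_id, None, False, None)
    gene = host.genes[gid]
    ordered = sorted(gene.transcripts, key=lambda t: (-t.exon_count, t.name))
    for t in ordered:
        span_s, span_e = t.span
        if not (span_s <= snorna.start and snorna.end <= span_e):
            continue
        if any(es < snorna.end and snorna.start < ee for es, ee in t.exons):
            continue
        if t.strand == "+":
            downstream = [es for es, ee in t.exons if es >= snorna.end]
            distance = min(downstream) - snorna.end
        else:
            downstream = [ee for es, ee in t.exons if ee <= snorna.start]
            distance = snorna.start - max(downstream)
        return HostPlacement(snorna.snorna_id, t.transcript_id, True, int(distance))
    return HostPlacement(snorna.snorna_id, None, False, None)


@dataclass(frozen=True)
class ContextCall:
    family_id: str
    contexts: tuple[str, ...]  # biotype of each considered member
    category: str
    same_host: bool | None  # defined only with >= 2 expressed members


def classify_family_context(family: Family,
                            records: Mapping[str, SnoRNARecord],
                            statuses: Mapping[str, bool] | None = None,
                            expressed_only: bool = False) -> ContextCall:
    """Classify a family's genomic context and same-host status.

    The category is ``<X>_only`` when every considered member (all members,
    or expressed members only) shares context X, and ``mixed`` otherwise;
    any combination involving two distinct contexts — including intergenic
    plus intronic — is mixed.  ``same_host`` is defined only for families
    with at least two expressed members: it is True iff all expressed
    members reside in one (non-intergenic) host gene.
    """
    if expressed_only and statuses is None:
        raise ValueError("expressed_only classification requires statuses")
    considered = [m for m in family.member_ids
                  if not expressed_only or statuses[m]]
    contexts = tuple(records[m].host_biotype for m in considered)
    if not contexts:
        category = UNDEFINED_CATEGORY
    else:
        kinds = set(contexts)
        category = f"{next(iter(kinds))}_only" if len(kinds) == 1 else "mixed"

    same_host: bool | None = None
    if statuses is not None:
        expressed = [m for m in family.member_ids if statuses[m]]
        if len(expressed) >= 2:
            hosts = {records[m].host_gene_id for m in expressed}
            same_host = (None not in hosts) and len(hosts) == 1
    return ContextCall(family.family_id, contexts, category, same_host)


def context_category_counts(calls: Sequence[ContextCall]) -> Counter:
    """Counts per category; categories partition the classified families."""
    return Counter(c.category for c in calls)
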