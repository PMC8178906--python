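"""Synthetic snoRNA-family cohort generator with planted ground truth.

The generator emulates the statistical structure of a human snoRNA family
survey across a tissue panel: heavy-tailed family sizes with many singletons
and the occasional very large family, roughly 35-40% of members expressed
(with singletons almost always expressed), log-normal TPM spanning several
orders of magnitude, multiplicative replicate noise within tissues, planted
top-member switches between tissue blocks, class-specific host-gene
placement (box C/D copies concentrated in one host gene, box H/ACA copies
spread over hosts), member sequences mutated from a family ancestor, and
conservation/SNP tracks tied to expression status.

Planted effects are constructed with explicit separation margins so that,
under the default truncated log-normal replicate noise (CV 20%, factors
clipped to [0.7, 1.45]), the analysis pipeline recovers expression
statuses, the switch set, same-host flags, context categories,
identical-pair flags and intron distances exactly.  Truth tables are
emitted beside the data files and are consistent with them by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import core_io
from .core_io import (Family, Gene, HostModel, SamplePanel, SnoRNARecord,
                      Transcript)

DEFAULT_TISSUES = ("brain", "liver", "prostate", "breast", "ovary", "testis",
                   "skeletal_muscle")

# Replicate noise factors are truncated so planted fold-change margins are
# hard guarantees, not probabilistic ones.
_NOISE_CLIP = (0.7, 1.45)
_JITTER_CLIP = (0.8, 1.25)
_JITTER_SIGMA = 0.18


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Per-class dictionaries are keyed by box type ("CD" / "HACA").  Defaults
    mirror the scale and rates of the human Rfam snoRNA survey the package
    models: a 7-tissue panel in triplicate, ~37-41% expressed members with
    near-universal singleton expression, 18 C/D and 9 H/ACA switch families
    at >= 4-fold effect, 8 + 5 families with an identical member pair, and
    C/D copies clustered in a shared host while H/ACA copies disperse.
    """

    seed: int = 0
    n_families: Mapping[str, int] = field(
        default_factory=lambda: {"CD": 200, "HACA": 100})
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    replicates_per_tissue: int = 3
    tpm_threshold: float = 1.0

    # family-size model: singletons are common, most multi-member families
    # are small (2 + geometric tail), and a few families are very large
    p_singleton: Mapping[str, float] = field(
        default_factory=lambda: {"CD": 0.405, "HACA": 0.286})
    p_large_family: Mapping[str, float] = field(
        default_factory=lambda: {"CD": 0.12, "HACA": 0.10})
    small_family_geom_p: float = 0.35
    large_family_range: tuple[int, int] = (20, 50)
    max_family_size: int = 50

    # expression model
    p_expressed_singleton: float = 0.96
    p_expressed_multi: Mapping[str, float] = field(
        default_factory=lambda: {"CD": 0.341, "HACA": 0.372})

    # abundance model: log10 TPM ~ Normal, floored, spanning >= 3 decades
    log10_tpm_mean: float = 1.2
    log10_tpm_sd: float = 0.9
    min_expressed_tpm: float = 2.0
    replicate_noise_cv: float = 20.0  # percent

    # planted switches
    n_switch_families: Mapping[str, int] = field(
        default_factory=lambda: {"CD": 18, "HACA": 9})
    switch_effect: float = 4.0

    # sequence model
    ancestor_length: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"CD": (70, 130), "HACA": (110, 145)})
    mutation_p: float = 0.10
    n_identical_pairs: Mapping[str, int] = field(
        default_factory=lambda: {"CD": 8, "HACA": 5})

    # host placement / genomic context
    context_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "CD": {"coding_only": 0.50, "noncoding_only": 0.14,
                   "intergenic_only": 0.02, "mixed": 0.34},
            "HACA": {"coding_only": 0.22, "noncoding_only": 0.08,
                     "intergenic_only": 0.15, "mixed": 0.55},
        })
    p_same_host: Mapping[str, float] = field(
        default_factory=lambda: {"CD": 0.60, "HACA": 0.073})

    # conservation / SNP model
    cons_mean_expressed: float = 0.80
    cons_sd_expressed: float = 0.08
    cons_mean_unexpressed: float = 0.30
    cons_sd_unexpressed: float = 0.10
    snp_rate_expressed: float = 0.002   # per nt; conserved copies carry few SNPs
    snp_rate_unexpressed: float = 0.02

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        base = cls()
        merged = {}
        for key, value in raw.items():
            current = getattr(base, key)
            if isinstance(current, Mapping) and isinstance(value, Mapping):
                upd = dict(current)
                upd.update(value)
                merged[key] = upd
            elif key == "tissues":
                merged[key] = tuple(value)
            else:
                merged[key] = value
        return replace(base, **merged)


@dataclass
class SimulationBundle:
    """Paths of the emitted file bundle plus in-memory truth tables."""

    out_dir: Path
    paths: dict[str, Path]
    truth_snorna: pd.DataFrame
    truth_family: pd.DataFrame


def _noise_sigma(cv_percent: float) -> float:
    cv = cv_percent / 100.0
    return math.sqrt(math.log(1.0 + cv * cv))


def _draw_base_tpm(rng: np.random.Generator, cfg: SyntheticConfig) -> float:
    base = 10.0 ** rng.normal(cfg.log10_tpm_mean, cfg.log10_tpm_sd)
    return max(base, cfg.min_expressed_tpm)


def _mutate(rng: np.random.Generator, ancestor: str, p: float) -> str:
    bases = "ACGT"
    out = []
    for ch in ancestor:
        if rng.random() < p:
            alternatives = bases.replace(ch, "")
            out.append(alternatives[rng.integers(0, 3)])
        else:
            out.append(ch)
    return "".join(out)


def plant_switch(expressed_ids: Sequence[str], tissues: Sequence[str],
                 effect: float, rng: np.random.Generator,
                 baseline_tpm: Sequence[float] | None = None,
                 n_top: int | None = None) -> tuple[pd.DataFrame, dict[str, str]]:
    """Pre-noise tissue-mean profiles for a switch family.

    Assigns disjoint tissue blocks in which different members dominate every
    other expressed member by at least ``effect`` fold before noise.
    Returns the member x tissue mean matrix and the planted tissue -> top
    member mapping.  ``effect`` must exceed 1 (a fold change of 1 cannot
    separate members).
    """
    if effect <= 1.0:
        raise ValueError("switch effect must be > 1")
    if len(expressed_ids) < 2:
        raise ValueError("a switch needs at least two expressed members")
    k = n_top if n_top is not None else int(rng.integers(2, 4))
    k = min(k, len(expressed_ids), len(tissues))
    if k < 2:
        raise ValueError("a switch needs at least two dominating members")

    ids = list(expressed_ids)
    top_idx = rng.choice(len(ids), size=k, replace=False)
    top_ids = [ids[i] for i in sorted(top_idx)]
    others = [m for m in ids if m not in top_ids]

    if baseline_tpm is None:
        baseline = {m: float(np.clip(10.0 ** rng.normal(1.0, 0.7), 2.0, 60.0))
                    for m in others}
    else:
        baseline = dict(zip(others, baseline_tpm))
    floor = max(baseline.values(), default=2.0)

    # block partition of the tissue panel: every top member gets >= 1 tissue
    order = list(rng.permutation(len(tissues)))
    cuts = sorted(rng.choice(np.arange(1, len(tissues)), size=k - 1,
                             replace=False))
    blocks = np.split(np.array(order), cuts)

    jitter_lo, jitter_hi = _JITTER_CLIP
    means = pd.DataFrame(0.0, index=ids, columns=list(tissues))
    top_of: dict[str, str] = {}
    for member, block in zip(top_ids, blocks):
        # dominate the block over baseline members even at their jitter ceiling
        high = effect * jitter_hi * floor * rng.uniform(1.0, 2.0)
        for t_idx in block:
            tissue = tissues[int(t_idx)]
            top_of[tissue] = member
        row = np.full(len(tissues), floor)
        row[np.asarray(block, dtype=int)] = high
        means.loc[member] = row
    for member in others:
        jitter = np.clip(np.exp(rng.normal(0.0, _JITTER_SIGMA, len(tissues))),
                         jitter_lo, jitter_hi)
        means.loc[member] = baseline[member] * jitter
    return means, top_of


def _nonswitch_means(expressed_ids: Sequence[str], tissues: Sequence[str],
                     effect: float, rng: np.random.Generator,
                     cfg: SyntheticConfig) -> pd.DataFrame:
    """Pre-noise profiles for a family that must never switch: the overall top
    member dominates every other expressed member by >= effect fold in every
    tissue, which survives jitter and truncated replicate noise."""
    bases = np.array([_draw_base_tpm(rng, cfg) for _ in expressed_ids])
    if len(bases) >= 2:
        order = np.argsort(bases)[::-1]
        second = bases[order[1]]
        if bases[order[0]] < effect * second:
            bases[order[0]] = effect * second
    jitter_lo, jitter_hi = _JITTER_CLIP
    means = pd.DataFrame(0.0, index=list(expressed_ids), columns=list(tissues))
    for i, member in enumerate(expressed_ids):
        jitter = np.clip(np.exp(rng.normal(0.0, _JITTER_SIGMA, len(tissues))),
                         jitter_lo, jitter_hi)
        means.loc[member] = bases[i] * jitter
    return means


@dataclass
class _FamilyPlan:
    family_id: str
    box_type: str
    member_ids: list[str]
    expressed: dict[str, bool]
    is_switch: bool = False
    n_top: int = 0
    category_target: str = "intergenic_only"
    same_host_planted: bool = False
    member_biotype: dict[str, str] = field(default_factory=dict)
    tissue_means: pd.DataFrame | None = None
    top_of: dict[str, str] = field(default_factory=dict)


def _draw_family_sizes(rng: np.random.Generator, cfg: SyntheticConfig,
                       box: str) -> list[int]:
    sizes = []
    lo, hi = cfg.large_family_range
    for _ in range(int(cfg.n_families[box])):
        if rng.random() < cfg.p_singleton[box]:
            sizes.append(1)
        elif rng.random() < cfg.p_large_family[box]:
            sizes.append(int(rng.integers(lo, hi + 1)))
        else:
            size = 2 + int(rng.geometric(cfg.small_family_geom_p)) - 1
            sizes.append(min(size, cfg.max_family_size))
    return sizes


def _plan_families(rng: np.random.Generator, cfg: SyntheticConfig) -> list[_FamilyPlan]:
    plans: list[_FamilyPlan] = []
    for box in ("CD", "HACA"):
        prefix = "SNOCD" if box == "CD" else "SNOHA"
        sizes = _draw_family_sizes(rng, cfg, box)
        for fi, size in enumerate(sizes):
            fid = f"{prefix}F{fi + 1:03d}"
            members = [f"{fid}_{m + 1:02d}" for m in range(size)]
            p = (cfg.p_expressed_singleton if size == 1
                 else cfg.p_expressed_multi[box])
            expressed = {m: bool(rng.random() < p) for m in members}
            plans.append(_FamilyPlan(fid, box, members, expressed))

    for box in ("CD", "HACA"):
        eligible = [p for p in plans if p.box_type == box
                    and sum(p.expressed.values()) >= 2]
        want = int(cfg.n_switch_families[box])
        if want > len(eligible):
            raise ValueError(
                f"infeasible config: {want} switch families requested for "
                f"{box} but only {len(eligible)} families have >= 2 expressed "
                "members")
        chosen = rng.choice(len(eligible), size=want, replace=False)
        for idx in sorted(chosen):
            eligible[int(idx)].is_switch = True
    return plans


def _assign_abundance(rng: np.random.Generator, cfg: SyntheticConfig,
                      plans: list[_FamilyPlan]) -> None:
    tissues = list(cfg.tissues)
    for plan in plans:
        expressed = [m for m in plan.member_ids if plan.expressed[m]]
        if not expressed:
            plan.tissue_means = pd.DataFrame(
                0.0, index=plan.member_ids, columns=tissues)
            continue
        if plan.is_switch:
            means, top_of = plant_switch(expressed, tissues, cfg.switch_effect,
                                         rng)
            plan.top_of = top_of
            plan.n_top = len(set(top_of.values()))
        else:
            means = _nonswitch_means(expressed, tissues, cfg.switch_effect,
                                     rng, cfg)
        # shared family tissue factor: moves all members together so it can
        # never flip within-tissue ranks; normalized so the best tissue keeps
        # expressed members above threshold
        factor = np.clip(np.exp(rng.normal(0.0, 0.35, len(tissues))), 0.4, 2.5)
        factor = factor / factor.max()
        means = means.mul(factor, axis=1)
        full = pd.DataFrame(0.0, index=plan.member_ids, columns=tissues)
        full.loc[means.index] = means
        plan.tissue_means = full


def _assign_sequences(rng: np.random.Generator, cfg: SyntheticConfig,
                      plans: list[_FamilyPlan]) -> tuple[dict[str, str], set[str]]:
    sequences: dict[str, str] = {}
    bases = "ACGT"
    for plan in plans:
        lo, hi = cfg.ancestor_length[plan.box_type]
        length = int(rng.integers(lo, hi + 1))
        ancestor = "".join(bases[i] for i in rng.integers(0, 4, length))
        for m in plan.member_ids:
            sequences[m] = _mutate(rng, ancestor, cfg.mutation_p)

    planted: set[str] = set()
    for box in ("CD", "HACA"):
        multi = [p for p in plans if p.box_type == box and len(p.member_ids) >= 2]
        want = int(cfg.n_identical_pairs[box])
        if want > len(multi):
            raise ValueError(
                f"infeasible config: {want} identical pairs requested for {box} "
                f"but only {len(multi)} multi-member families exist")
        chosen = rng.choice(len(multi), size=want, replace=False)
        for idx in sorted(chosen):
            plan = multi[int(idx)]
            a, b = plan.member_ids[0], plan.member_ids[1]
            sequences[b] = sequences[a]
            planted.add(plan.family_id)

    # random mutation virtually never duplicates a >= 70 nt sequence, but the
    # truth table guarantees exactness, so enforce it
    for plan in plans:
        if plan.family_id in planted or len(plan.member_ids) < 2:
            continue
        seen: dict[str, str] = {}
        for m in plan.member_ids:
            while sequences[m] in seen and seen[sequences[m]] != m:
                sequences[m] = _mutate(rng, sequences[m], 0.05)
            seen[sequences[m]] = m
    return sequences, planted


def _assign_context(rng: np.random.Generator, cfg: SyntheticConfig,
                    plans: list[_FamilyPlan]) -> None:
    for plan in plans:
        probs = cfg.context_probs[plan.box_type]
        cats = sorted(probs)
        weights = np.array([probs[c] for c in cats], dtype=float)
        cat = cats[int(rng.choice(len(cats), p=weights / weights.sum()))]
        plan.category_target = cat

        if cat == "coding_only":
            biotype = {m: "coding" for m in plan.member_ids}
        elif cat == "noncoding_only":
            biotype = {m: "noncoding" for m in plan.member_ids}
        elif cat == "intergenic_only":
            biotype = {m: "intergenic" for m in plan.member_ids}
        else:  # mixed: mostly coding+noncoding hosts, occasional intergenic copy
            choices = ("coding", "noncoding", "intergenic")
            weights_m = np.array([0.55, 0.35, 0.10])
            for _ in range(100):
                biotype = {m: choices[int(rng.choice(3, p=weights_m))]
                           for m in plan.member_ids}
                if len(set(biotype.values())) >= 2:
                    break
            else:
                biotype = {m: "coding" for m in plan.member_ids}
                biotype[plan.member_ids[-1]] = "noncoding"

        expressed = [m for m in plan.member_ids if plan.expressed[m]]
        if (len(expressed) >= 2 and cat != "intergenic_only"
                and rng.random() < cfg.p_same_host[plan.box_type]):
            # all expressed copies share one host gene, hence one biotype
            plan.same_host_planted = True
            host_biotype = biotype[expressed[0]]
            if host_biotype == "intergenic":
                host_biotype = "coding"
            for m in expressed:
                biotype[m] = host_biotype
        plan.member_biotype = biotype


@dataclass
class _Placement:
    chrom: str
    start: int
    end: int
    strand: str
    host_gene_id: str | None
    distance: int | None


def _intron_distance(rng: np.random.Generator, box: str) -> int:
    if box == "CD":
        # mode near 70 nt upstream of the 3' splice site
        return int(np.clip(round(70.0 * math.exp(rng.normal(0.0, 0.6))), 10, 3000))
    return int(np.clip(round(10.0 ** rng.normal(2.3, 0.5)), 20, 8000))


def _build_gene(rng: np.random.Generator, gene_id: str, chrom: str,
                origin: int, strand: str, biotype: str,
                member_ids: Sequence[str], member_len: Mapping[str, int],
                distances: Mapping[str, int],
                ) -> tuple[Gene, dict[str, tuple[int, int]], int]:
    """Lay out a host gene with one intron per snoRNA, in transcript
    orientation, then map to genomic coordinates.

    Returns the gene, the genomic interval of each snoRNA, and the genomic
    length consumed.
    """
    exon_lengths = [int(rng.integers(100, 201)) for _ in range(len(member_ids) + 1)]
    offset = 0
    t_exons: list[tuple[int, int]] = []
    t_snos: dict[str, tuple[int, int]] = {}
    t_exons.append((offset, offset + exon_lengths[0]))
    offset += exon_lengths[0]
    for i, m in enumerate(member_ids):
        gap = int(rng.integers(30, 201))
        s = offset + gap
        e = s + member_len[m]
        t_snos[m] = (s, e)
        next_exon_start = e + distances[m]
        t_exons.append((next_exon_start, next_exon_start + exon_lengths[i + 1]))
        offset = next_exon_start + exon_lengths[i + 1]
    total = offset

    def to_genomic(iv: tuple[int, int]) -> tuple[int, int]:
        if strand == "+":
            return origin + iv[0], origin + iv[1]
        return origin + total - iv[1], origin + total - iv[0]

    g_exons = tuple(sorted(to_genomic(iv) for iv in t_exons))
    g_snos = {m: to_genomic(iv) for m, iv in t_snos.items()}

    primary = Transcript(f"{gene_id}_t1", f"{gene_id}_T_a", strand, g_exons)
    transcripts: list[Transcript] = [primary]

    # decoy with MORE exons but one exon sitting on the first snoRNA: sorted
    # first by the exon-count rule, yet skipped for that snoRNA because the
    # snoRNA is not intronic in it
    if rng.random() < 0.35:
        first = member_ids[0]
        extra = g_snos[first]
        decoy_exons = tuple(sorted(g_exons + (extra,)))
        transcripts.append(
            Transcript(f"{gene_id}_t2", f"{gene_id}_T_overlap", strand, decoy_exons))
    # name tie: same exon count as the primary, later name, so the ascending
    # name rule keeps the primary
    if rng.random() < 0.30:
        last_s, last_e = g_exons[-1]
        tie_exons = g_exons[:-1] + ((last_s, last_e + 50),)
        transcripts.append(
            Transcript(f"{gene_id}_t3", f"{gene_id}_T_b", strand, tie_exons))
    # subset transcript with fewer exons: never chosen while the primary fits
    if len(g_exons) > 2 and rng.random() < 0.40:
        sub = tuple(g_exons[i] for i in range(0, len(g_exons), 2))
        transcripts.append(
            Transcript(f"{gene_id}_t4", f"{gene_id}_T_short", strand, sub))

    gene = Gene(gene_id, chrom, strand, biotype, tuple(transcripts))
    return gene, g_snos, total


def _place_genome(rng: np.random.Generator, cfg: SyntheticConfig,
                  plans: list[_FamilyPlan],
                  sequences: Mapping[str, str],
                  ) -> tuple[dict[str, _Placement], HostModel]:
    chrom = "chr1"
    cursor = 1000
    placements: dict[str, _Placement] = {}
    genes: dict[str, Gene] = {}
    gene_counter = 0

    for plan in plans:
        hosted = [m for m in plan.member_ids
                  if plan.member_biotype[m] != "intergenic"]
        intergenic = [m for m in plan.member_ids
                      if plan.member_biotype[m] == "intergenic"]
        expressed_hosted = [m for m in hosted if plan.expressed[m]]

        groups: list[tuple[list[str], str]] = []
        if plan.same_host_planted:
            shared_biotype = plan.member_biotype[expressed_hosted[0]]
            shared = [m for m in hosted
                      if plan.member_biotype[m] == shared_biotype]
            groups.append((shared, shared_biotype))
            rest = [m for m in hosted if m not in shared]
        else:
            rest = hosted
        for m in rest:  # each remaining copy gets its own host gene
            groups.append(([m], plan.member_biotype[m]))

        for member_group, biotype in groups:
            gene_counter += 1
            gid = f"HOST{gene_counter:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            member_len = {m: len(sequences[m]) for m in member_group}
            distances = {m: _intron_distance(rng, plan.box_type)
                         for m in member_group}
            gene, g_snos, consumed = _build_gene(
                rng, gid, chrom, cursor, strand, biotype, member_group,
                member_len, distances)
            genes[gid] = gene
            for m in member_group:
                s, e = g_snos[m]
                placements[m] = _Placement(chrom, s, e, strand, gid,
                                           distances[m])
            cursor += consumed + int(rng.integers(500, 2001))

        for m in intergenic:
            length = len(sequences[m])
            strand = "+" if rng.random() < 0.5 else "-"
            placements[m] = _Placement(chrom, cursor, cursor + length, strand,
                                       None, None)
            cursor += length + int(rng.integers(500, 2001))

    return placements, HostModel(genes)


def _sample_matrix(rng: np.random.Generator, cfg: SyntheticConfig,
                   plans: list[_FamilyPlan],
                   panel: SamplePanel) -> pd.DataFrame:
    sigma = _noise_sigma(cfg.replicate_noise_cv)
    lo, hi = _NOISE_CLIP
    rows: dict[str, np.ndarray] = {}
    samples = list(panel.samples)
    for plan in plans:
        means = plan.tissue_means
        for m in plan.member_ids:
            values = np.empty(len(samples))
            for j, sample in enumerate(samples):
                tissue = panel.sample_to_tissue[sample]
                if plan.expressed[m]:
                    mu = float(means.loc[m, tissue])
                    noise = float(np.clip(
                        math.exp(rng.normal(-sigma * sigma / 2.0, sigma)), lo, hi))
                    values[j] = mu * noise
                else:
                    # strictly below threshold in every sample, never at the
                    # boundary, so status recovery is convention-independent
                    values[j] = rng.uniform(0.0, 0.45 * cfg.tpm_threshold)
            rows[m] = np.round(values, 4)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    out.index.name = "snorna_id"
    return out


def _conservation_and_snps(rng: np.random.Generator, cfg: SyntheticConfig,
                           plans: list[_FamilyPlan],
                           placements: Mapping[str, _Placement],
                           ) -> tuple[core_io.ConservationTrack, core_io.SNPSet,
                                      dict[str, float], dict[str, int]]:
    intervals: list[tuple[str, int, int, float]] = []
    sites: list[tuple[str, int]] = []
    cons_truth: dict[str, float] = {}
    snp_truth: dict[str, int] = {}
    counter = 0
    for plan in plans:
        for m in plan.member_ids:
            pl = placements[m]
            if plan.expressed[m]:
                score = float(np.clip(
                    rng.normal(cfg.cons_mean_expressed, cfg.cons_sd_expressed),
                    0.5, 1.0))
                rate = cfg.snp_rate_expressed
            else:
                score = float(np.clip(
                    rng.normal(cfg.cons_mean_unexpressed, cfg.cons_sd_unexpressed),
                    0.0, 0.6))
                rate = cfg.snp_rate_unexpressed
            score = round(score, 4)
            cons_truth[m] = score
            length = pl.end - pl.start
            counter += 1
            if counter % 5 == 0 and length >= 2:
                # split into two adjacent equal-score pieces: averaging must
                # be invariant under interval splitting
                mid = pl.start + length // 2
                intervals.append((pl.chrom, pl.start, mid, score))
                intervals.append((pl.chrom, mid, pl.end, score))
            else:
                intervals.append((pl.chrom, pl.start, pl.end, score))
            n_snp = int(rng.binomial(length, rate))
            if n_snp:
                offsets = rng.choice(length, size=n_snp, replace=False)
                sites.extend((pl.chrom, pl.start + int(o)) for o in offsets)
            snp_truth[m] = n_snp
    return (core_io.ConservationTrack(intervals), core_io.SNPSet(sites),
            cons_truth, snp_truth)


def _truth_tables(cfg: SyntheticConfig, plans: list[_FamilyPlan],
                  placements: Mapping[str, _Placement],
                  sequences: Mapping[str, str],
                  identical_planted: set[str],
                  cons_truth: Mapping[str, float],
                  snp_truth: Mapping[str, int],
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    sno_rows = []
    fam_rows = []
    tissues = list(cfg.tissues)
    for plan in plans:
        expressed = [m for m in plan.member_ids if plan.expressed[m]]
        for m in plan.member_ids:
            pl = placements[m]
            if plan.expressed[m]:
                row = plan.tissue_means.loc[m]
                top = max(tissues, key=lambda t: (row[t], -tissues.index(t)))
            else:
                top = "none"
            sno_rows.append({
                "snorna_id": m,
                "family_id": plan.family_id,
                "box_type": plan.box_type,
                "expressed": plan.expressed[m],
                "top_tissue": top,
                "host_gene_id": pl.host_gene_id if pl.host_gene_id else ".",
                "host_biotype": plan.member_biotype[m],
                "intron_distance": pl.distance if pl.distance is not None else ".",
                "conservation": cons_truth[m],
                "n_snps": snp_truth[m],
            })
        kinds = {plan.member_biotype[m] for m in plan.member_ids}
        category = (f"{next(iter(kinds))}_only" if len(kinds) == 1 else "mixed")
        if len(expressed) >= 2:
            hosts = {placements[m].host_gene_id for m in expressed}
            same_host = str((None not in hosts) and len(hosts) == 1)
        else:
            same_host = "."
        fam_rows.append({
            "family_id": plan.family_id,
            "box_type": plan.box_type,
            "n_members": len(plan.member_ids),
            "n_expressed": len(expressed),
            "switch": plan.is_switch,
            "n_top_members": plan.n_top if plan.is_switch else
            (1 if expressed else 0),
            "same_host": same_host,
            "context_category": category,
            "has_identical_pair": plan.family_id in identical_planted,
        })
    return pd.DataFrame(sno_rows), pd.DataFrame(fam_rows)


def simulate(config: SyntheticConfig, out_dir: str | Path) -> SimulationBundle:
    """Generate the full synthetic bundle under ``out_dir``.

    Emits annotation TSV, abundance TSV, sample map, FASTA, GTF, bedGraph,
    BED and two truth tables; all files parse back through
    :mod:`snofam.core_io`, and the same seed yields a byte-identical bundle.
    """
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    plans = _plan_families(rng, config)
    _assign_abundance(rng, config, plans)
    sequences, identical_planted = _assign_sequences(rng, config, plans)
    _assign_context(rng, config, plans)
    placements, host_model = _place_genome(rng, config, plans, sequences)

    panel = SamplePanel.from_pairs(
        (f"{tissue}_{r + 1}", tissue)
        for tissue in config.tissues
        for r in range(config.replicates_per_tissue))
    matrix = _sample_matrix(rng, config, plans, panel)
    track, snps, cons_truth, snp_truth = _conservation_and_snps(
        rng, config, plans, placements)

    records = []
    for plan in plans:
        for m in plan.member_ids:
            pl = placements[m]
            records.append(SnoRNARecord(
                snorna_id=m, name=m, box_type=plan.box_type,
                family_id=plan.family_id, sequence=sequences[m],
                chrom=pl.chrom, start=pl.start, end=pl.end, strand=pl.strand,
                host_gene_id=pl.host_gene_id,
                host_biotype=plan.member_biotype[m]))

    truth_sno, truth_fam = _truth_tables(
        config, plans, placements, sequences, identical_planted,
        cons_truth, snp_truth)

    paths = {
        "annotation": out / "annotation.tsv",
        "abundance": out / "abundance.tsv",
        "samples": out / "samples.tsv",
        "fasta": out / "sequences.fasta",
        "gtf": out / "hosts.gtf",
        "conservation": out / "conservation.bedgraph",
        "snps": out / "snps.bed",
        "truth_snorna": out / "truth_snorna.tsv",
        "truth_family": out / "truth_families.tsv",
    }
    core_io.write_annotation(records, paths["annotation"])
    matrix.to_csv(paths["abundance"], sep="\t", float_format="%.4f")
    core_io.write_sample_panel(panel, paths["samples"])
    core_io.write_fasta(records, paths["fasta"])
    core_io.write_gtf(host_model, paths["gtf"])
    core_io.write_bedgraph(track, paths["conservation"])
    core_io.write_bed(snps, paths["snps"])
    truth_sno.to_csv(paths["truth_snorna"], sep="\t", index=False)
    truth_fam.to_csv(paths["truth_family"], sep="\t", index=False)
    return SimulationBundle(out, paths, truth_sno, truth_fam)
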