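"""Domain types and readers/writers for all external formats.

All genomic coordinates are held internally as 0-based half-open intervals;
conversion to/from 1-based closed coordinates happens only at the GTF
boundary.  snoRNA sequences are normalized at ingest to uppercase DNA
spelling (U -> T) so that identity scoring never treats RNA/DNA spellings of
the same gene as mismatches.

The annotation table is a frozen TSV dialect (UTF-8, tab-separated, "." for
an absent host gene) with one row per snoRNA::

    snorna_id  name  box_type  family_id  sequence  chrom  start  end
    strand  host_gene_id  host_biotype
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BOX_TYPES = ("CD", "HACA")
BIOTYPES = ("coding", "noncoding", "intergenic")
STRANDS = ("+", "-")

ANNOTATION_COLUMNS = [
    "snorna_id", "name", "box_type", "family_id", "sequence",
    "chrom", "start", "end", "strand", "host_gene_id", "host_biotype",
]

_SEQUENCE_ALPHABET = set("ACGTN")


class ValidationError(ValueError):
    """Raised when an input file or in-memory structure violates an invariant."""


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide sequence and convert RNA spelling (U) to DNA (T)."""
    out = seq.strip().upper().replace("U", "T")
    bad = set(out) - _SEQUENCE_ALPHABET
    if bad:
        raise ValidationError(f"sequence contains invalid characters: {sorted(bad)}")
    return out


@dataclass(frozen=True)
class SnoRNARecord:
    """One annotated snoRNA gene: class, family, sequence, location, host."""

    snorna_id: str
    name: str
    box_type: str
    family_id: str
    sequence: str
    chrom: str
    start: int
    end: int
    strand: str
    host_gene_id: str | None = None
    host_biotype: str = "intergenic"

    def __post_init__(self) -> None:
        if self.box_type not in BOX_TYPES:
            raise ValidationError(
                f"{self.snorna_id}: box_type must be one of {BOX_TYPES}, got {self.box_type!r}")
        if self.strand not in STRANDS:
            raise ValidationError(f"{self.snorna_id}: bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"{self.snorna_id}: invalid interval [{self.start}, {self.end})")
        if len(self.sequence) == 0:
            raise ValidationError(f"{self.snorna_id}: empty sequence")
        if self.host_biotype not in BIOTYPES:
            raise ValidationError(
                f"{self.snorna_id}: bad host_biotype {self.host_biotype!r}")
        if (self.host_gene_id is None) != (self.host_biotype == "intergenic"):
            raise ValidationError(
                f"{self.snorna_id}: host_biotype must be 'intergenic' iff "
                "host_gene_id is absent")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def three_prime_end(self) -> int:
        """Genomic coordinate of the 3' end (position just past it on + strand)."""
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class Family:
    """An Rfam-style snoRNA family: presumed copies of one ancestral gene."""

    family_id: str
    box_type: str
    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.member_ids) == 0:
            raise ValidationError(f"{self.family_id}: family with no members")
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ValidationError(f"{self.family_id}: duplicate member ids")

    @property
    def size(self) -> int:
        return len(self.member_ids)

    @property
    def is_singleton(self) -> bool:
        return self.size == 1


@dataclass(frozen=True)
class SamplePanel:
    """Mapping from sample id to tissue, with a canonical tissue order."""

    sample_to_tissue: Mapping[str, str]
    tissue_order: tuple[str, ...]

    def __post_init__(self) -> None:
        tissues_seen = set(self.sample_to_tissue.values())
        if set(self.tissue_order) != tissues_seen:
            raise ValidationError(
                "tissue_order must list exactly the tissues present in the panel")
        for tissue in self.tissue_order:
            if not any(t == tissue for t in self.sample_to_tissue.values()):
                raise ValidationError(f"tissue {tissue!r} has no samples")

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.sample_to_tissue)

    def samples_for(self, tissue: str) -> tuple[str, ...]:
        return tuple(s for s, t in self.sample_to_tissue.items() if t == tissue)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "SamplePanel":
        mapping: dict[str, str] = {}
        order: list[str] = []
        for sample, tissue in pairs:
            if sample in mapping:
                raise ValidationError(f"duplicate sample id {sample!r}")
            mapping[sample] = tissue
            if tissue not in order:
                order.append(tissue)
        return cls(mapping, tuple(order))


class ConservationTrack:
    """Per-chromosome scored intervals (0-based half-open, scores in [0, 1]).

    Intervals on one chromosome must not overlap; they are stored sorted so
    per-base averaging is a binary search plus a short scan.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int, float]]):
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, score in intervals:
            if not (0 <= start < end):
                raise ValidationError(f"bad interval [{start}, {end}) on {chrom}")
            if not (0.0 <= score <= 1.0):
                raise ValidationError(f"score {score} outside [0, 1] on {chrom}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end), float(score)))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._scores: dict[str, np.ndarray] = {}
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            for (s0, e0, _), (s1, e1, _) in zip(ivals, ivals[1:]):
                if s1 < e0:
                    raise ValidationError(
                        f"overlapping intervals on {chrom}: [{s0},{e0}) and [{s1},{e1})")
            self._starts[chrom] = np.array([i[0] for i in ivals], dtype=np.int64)
            self._ends[chrom] = np.array([i[1] for i in ivals], dtype=np.int64)
            self._scores[chrom] = np.array([i[2] for i in ivals], dtype=float)

    def intervals(self) -> list[tuple[str, int, int, float]]:
        out = []
        for chrom in sorted(self._starts):
            for s, e, v in zip(self._starts[chrom], self._ends[chrom], self._scores[chrom]):
                out.append((chrom, int(s), int(e), float(v)))
        return out

    def covered_score_sum(self, chrom: str, start: int, end: int) -> tuple[float, int]:
        """Return (sum of per-base scores, number of covered bases) in [start, end)."""
        if chrom not in self._starts:
            return 0.0, 0
        starts, ends, scores = self._starts[chrom], self._ends[chrom], self._scores[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        total, covered = 0.0, 0
        for i in range(lo, len(starts)):
            if starts[i] >= end:
                break
            ov = min(end, ends[i]) - max(start, starts[i])
            if ov > 0:
                total += ov * scores[i]
                covered += int(ov)
        return total, covered


class SNPSet:
    """Unique single-nucleotide sites, stored per chromosome as sorted positions."""

    def __init__(self, sites: Iterable[tuple[str, int]]):
        by_chrom: dict[str, set[int]] = {}
        for chrom, pos in sites:
            if pos < 0:
                raise ValidationError(f"negative SNP position {pos} on {chrom}")
            by_chrom.setdefault(chrom, set()).add(int(pos))
        self._pos: dict[str, np.ndarray] = {
            chrom: np.array(sorted(ps), dtype=np.int64) for chrom, ps in by_chrom.items()
        }

    def sites(self) -> list[tuple[str, int]]:
        return [(c, int(p)) for c in sorted(self._pos) for p in self._pos[c]]

    def count_in(self, chrom: str, start: int, end: int) -> int:
        pos = self._pos.get(chrom)
        if pos is None:
            return 0
        return int(np.searchsorted(pos, end, "left") - np.searchsorted(pos, start, "left"))

    def __len__(self) -> int:
        return sum(len(p) for p in self._pos.values())


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    name: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # sorted, non-overlapping, 0-based half-open

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript with no exons")
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValidationError(
                    f"{self.transcript_id}: overlapping exons [{s0},{e0}) [{s1},{e1})")
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValidationError(f"{self.transcript_id}: bad exon [{s},{e})")

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    biotype: str  # coding | noncoding
    transcripts: tuple[Transcript, ...]

    @property
    def span(self) -> tuple[int, int]:
        return (min(t.span[0] for t in self.transcripts),
                max(t.span[1] for t in self.transcripts))


@dataclass
class HostModel:
    """Host-gene annotation: genes -> transcripts -> ordered exon intervals."""

    genes: dict[str, Gene] = field(default_factory=dict)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes


# ---------------------------------------------------------------------------
# Annotation TSV


def read_annotation(path: str | Path) -> tuple[list[SnoRNARecord], list[Family]]:
    """Read the annotation TSV and assemble families by grouping family_id.

    Raises :class:`ValidationError` on duplicate snoRNA ids or on a family
    mixing box C/D and box H/ACA members.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"annotation file missing columns: {missing}")

    records: list[SnoRNARecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = row["snorna_id"]
        if sid in seen:
            raise ValidationError(f"duplicate snorna_id {sid!r}")
        seen.add(sid)
        host = row["host_gene_id"]
        records.append(SnoRNARecord(
            snorna_id=sid,
            name=row["name"],
            box_type=row["box_type"],
            family_id=row["family_id"],
            sequence=normalize_sequence(row["sequence"]),
            chrom=row["chrom"],
            start=int(row["start"]),
            end=int(row["end"]),
            strand=row["strand"],
            host_gene_id=None if host in (".", "") else host,
            host_biotype=row["host_biotype"],
        ))
    return records, assemble_families(records)


def assemble_families(records: Sequence[SnoRNARecord]) -> list[Family]:
    members: dict[str, list[str]] = {}
    box: dict[str, str] = {}
    for rec in records:
        fam = rec.family_id
        members.setdefault(fam, []).append(rec.snorna_id)
        if fam in box and box[fam] != rec.box_type:
            raise ValidationError(
                f"family {fam!r} mixes box types {box[fam]} and {rec.box_type}")
        box[fam] = rec.box_type
    return [Family(fid, box[fid], tuple(ids)) for fid, ids in members.items()]


def write_annotation(records: Sequence[SnoRNARecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "snorna_id": r.snorna_id, "name": r.name, "box_type": r.box_type,
            "family_id": r.family_id, "sequence": r.sequence, "chrom": r.chrom,
            "start": r.start, "end": r.end, "strand": r.strand,
            "host_gene_id": r.host_gene_id if r.host_gene_id is not None else ".",
            "host_biotype": r.host_biotype,
        })
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Abundance TSV and sample panel


def read_abundance(path: str | Path, panel: SamplePanel) -> pd.DataFrame:
    """Read a snoRNA x sample TPM matrix; columns must match the panel exactly."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    file_samples = list(df.columns)
    panel_samples = set(panel.samples)
    extra = [s for s in file_samples if s not in panel_samples]
    if extra:
        raise ValidationError(f"samples in file absent from panel: {extra}")
    absent = [s for s in panel.samples if s not in set(file_samples)]
    if absent:
        raise ValidationError(f"panel samples missing from file: {absent}")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate snorna_id rows: {dups}")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        i, j = map(int, np.argwhere(np.isnan(values))[0])
        raise ValidationError(f"missing value at ({df.index[i]}, {df.columns[j]})")
    if (values < 0).any():
        i, j = map(int, np.argwhere(values < 0)[0])
        raise ValidationError(
            f"negative TPM {values[i, j]} at ({df.index[i]}, {df.columns[j]})")
    out = df.astype(float).loc[:, list(panel.samples)]
    out.index.name = "snorna_id"
    return out


def write_abundance(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="snorna_id")


def read_sample_panel(path: str | Path) -> SamplePanel:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["sample_id", "tissue"]:
        raise ValidationError("sample map must have columns sample_id, tissue")
    return SamplePanel.from_pairs(zip(df["sample_id"], df["tissue"]))


def write_sample_panel(panel: SamplePanel, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(panel.samples),
         "tissue": [panel.sample_to_tissue[s] for s in panel.samples]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GTF


_BIOTYPE_TO_GTF = {"coding": "protein_coding", "noncoding": "lncRNA"}


def _gtf_biotype(raw: str) -> str:
    return "coding" if raw == "protein_coding" else "noncoding"


def _prevalidate_gtf(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValidationError(f"malformed GTF line {lineno}: expected 9 fields")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValidationError(
                    f"malformed GTF line {lineno}: non-integer coordinate") from exc
            if start < 1 or end < start:
                raise ValidationError(
                    f"malformed GTF line {lineno}: invalid interval {start}-{end}")


def read_gtf(path: str | Path) -> HostModel:
    """Parse a GTF (1-based closed) into a :class:`HostModel` (0-based half-open)."""
    _prevalidate_gtf(path)
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    genes: dict[str, Gene] = {}
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = g.attributes["gene_id"][0]
        biotype = _gtf_biotype(g.attributes.get("gene_biotype", ["protein_coding"])[0])
        transcripts = []
        for t in db.children(g, featuretype="transcript", order_by="start"):
            tid = t.attributes["transcript_id"][0]
            tname = t.attributes.get("transcript_name", [tid])[0]
            exons = tuple(sorted(
                (e.start - 1, e.end) for e in db.children(t, featuretype="exon")))
            transcripts.append(Transcript(tid, tname, t.strand, exons))
        if not transcripts:
            continue
        genes[gid] = Gene(gid, g.seqid, g.strand, biotype, tuple(transcripts))
    return HostModel(genes)


def write_gtf(model: HostModel, path: str | Path) -> None:
    lines = []
    for gid in model.genes:
        g = model.genes[gid]
        s, e = g.span
        attrs = f'gene_id "{g.gene_id}"; gene_biotype "{_BIOTYPE_TO_GTF[g.biotype]}";'
        lines.append("\t".join(
            [g.chrom, "snofam", "gene", str(s + 1), str(e), ".", g.strand, ".", attrs]))
        for t in g.transcripts:
            ts, te = t.span
            tattrs = (f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; '
                      f'transcript_name "{t.name}";')
            lines.append("\t".join(
                [g.chrom, "snofam", "transcript", str(ts + 1), str(te), ".",
                 t.strand, ".", tattrs]))
            for es, ee in t.exons:
                lines.append("\t".join(
                    [g.chrom, "snofam", "exon", str(es + 1), str(ee), ".",
                     t.strand, ".", tattrs]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# bedGraph / BED


def read_bedgraph(path: str | Path) -> ConservationTrack:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ValidationError(f"malformed bedGraph line {lineno}")
            try:
                intervals.append(
                    (fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
            except ValueError as exc:
                raise ValidationError(f"malformed bedGraph line {lineno}") from exc
    return ConservationTrack(intervals)


def write_bedgraph(track: ConservationTrack, path: str | Path) -> None:
    lines = [f"{c}\t{s}\t{e}\t{v:.4f}" for c, s, e, v in track.intervals()]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bed(path: str | Path) -> SNPSet:
    """Read single-nucleotide sites from BED3; multi-base intervals are expanded."""
    sites: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValidationError(f"malformed BED line {lineno}")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValidationError(f"malformed BED line {lineno}") from exc
            if end <= start:
                raise ValidationError(f"malformed BED line {lineno}: empty interval")
            sites.extend((chrom, p) for p in range(start, end))
    return SNPSet(sites)


def write_bed(snps: SNPSet, path: str | Path) -> None:
    lines = [f"{c}\t{p}\t{p + 1}" for c, p in snps.sites()]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# FASTA convenience


def write_fasta(records: Sequence[SnoRNARecord], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.snorna_id, description=r.name)
         for r in records],
        str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: normalize_sequence(str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")}
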