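"""End-to-end orchestration: ingest -> tissue means -> expression -> identity
-> genomics -> variability -> switches -> summary tables and report.

Produces a per-snoRNA summary (expression, CV, mean pairwise identity,
conservation, SNP density, genomic context, downstream-exon distance), a
per-family summary (membership, switch and same-host flags, family vs
member covariation) and a JSON report of per-class aggregates in which
every percentage names its numerator and denominator explicitly — the
survey statistics this models switch between "all snoRNAs", "families with
>= 2 members" and "families with >= 2 expressed members" as denominators,
so each one is spelled out.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import core_io, expression, genomics, identity, switches, variability
from .core_io import Family, SamplePanel, SnoRNARecord
from .expression import NO_TISSUE

logger = logging.getLogger("snofam")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    threshold: float = expression.DEFAULT_TPM_THRESHOLD
    inclusive: bool = True
    cv_ddof: int = 1
    correlation_method: str = "pearson"
    identity_enabled: bool = True
    uncovered_score_zero: bool = True

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "PipelineConfig":
        flat = {}
        for key, value in (raw or {}).items():
            if isinstance(value, Mapping):  # allow nested {expression: {...}}
                flat.update(value)
            else:
                flat[key] = value
        rename = {"ddof": "cv_ddof", "method": "correlation_method",
                  "enabled": "identity_enabled"}
        kwargs = {}
        for key, value in flat.items():
            key = rename.get(key, key)
            if key in cls.__dataclass_fields__:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class PipelineResult:
    sno_summary: pd.DataFrame
    family_summary: pd.DataFrame
    heatmap: pd.DataFrame
    report: dict
    out_dir: Path | None = None


def _fmt_fraction(k: int, n: int) -> dict:
    return {
        "numerator": int(k),
        "denominator": int(n),
        "percent": round(100.0 * k / n, 1) if n else None,
        "fraction": (k / n) if n else None,
    }


def summarize_classes(sno_summary: pd.DataFrame,
                      family_summary: pd.DataFrame) -> dict:
    """Per-class aggregate block computed from the two summary tables.

    Works on any tables in the summary dialect (including externally derived
    per-snoRNA / per-family tables), requiring only the columns it uses.
    """
    out: dict = {}
    fam_sizes = family_summary.set_index("family_id")["n_members"]
    for box in sorted(sno_summary["box_type"].unique()):
        sno = sno_summary[sno_summary["box_type"] == box]
        fam = family_summary[family_summary["box_type"] == box]
        if len(sno) == 0:
            logger.warning("class %s has no snoRNAs; omitted from report", box)
            continue
        in_multi = sno["family_id"].map(fam_sizes).ge(2)
        expressed = sno["expressed"].astype(bool)

        multi_fam = fam[fam["n_members"] >= 2]
        ge2_expr = fam[fam["n_expressed"] >= 2]
        block = {
            "n_snornas": int(len(sno)),
            "n_families": int(len(fam)),
            "pct_multi_member_snornas_of_all_snornas":
                _fmt_fraction(int(in_multi.sum()), len(sno)),
            "pct_expressed_of_all_snornas":
                _fmt_fraction(int(expressed.sum()), len(sno)),
            "pct_expressed_of_multi_member_snornas":
                _fmt_fraction(int((expressed & in_multi).sum()),
                              int(in_multi.sum())),
            "pct_families_expressing_ge_half_of_multi_member_families":
                _fmt_fraction(
                    int((multi_fam["n_expressed"] >= multi_fam["n_members"] / 2.0)
                        .sum()),
                    len(multi_fam)),
            "n_switch_families": int(fam["switch"].astype(bool).sum()),
            "pct_same_host_of_families_ge2_expressed":
                _fmt_fraction(
                    int((ge2_expr["same_host"].astype(str) == "True").sum()),
                    len(ge2_expr)),
        }
        if "same_top_tissue" in fam.columns:
            block["pct_same_top_tissue_of_families_ge2_expressed"] = _fmt_fraction(
                int((ge2_expr["same_top_tissue"].astype(str) == "True").sum()),
                len(ge2_expr))
        if "context_category" in fam.columns:
            counts = fam["context_category"].value_counts().to_dict()
            block["context_category_counts"] = {
                str(k): int(v) for k, v in sorted(counts.items())}
        if "has_identical_pair" in fam.columns:
            block["n_families_with_identical_pair"] = int(
                fam["has_identical_pair"].astype(bool).sum())
        out[box] = block
    return out


def run_pipeline(annotation: str | Path,
                 abundance: str | Path,
                 samples: str | Path,
                 gtf: str | Path | None = None,
                 conservation: str | Path | None = None,
                 snps: str | Path | None = None,
                 out_dir: str | Path | None = None,
                 config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Run every analysis stage and optionally write the output bundle.

    Optional inputs (GTF, conservation bedGraph, SNP BED) may be absent; the
    dependent summary columns are then omitted entirely, never silently
    zero-filled.
    """
    stage = "ingest"
    try:
        records, families = core_io.read_annotation(annotation)
        panel = core_io.read_sample_panel(samples)
        matrix = core_io.read_abundance(abundance, panel)
        rec_by_id = {r.snorna_id: r for r in records}
        missing = [sid for sid in matrix.index if sid not in rec_by_id]
        if missing:
            raise core_io.ValidationError(
                f"abundance rows without annotation: {missing[:5]}")
        matrix = matrix.reindex([r.snorna_id for r in records], fill_value=0.0)
        host_model = core_io.read_gtf(gtf) if gtf else None
        track = core_io.read_bedgraph(conservation) if conservation else None
        snp_set = core_io.read_bed(snps) if snps else None
        logger.info("ingest: %d snoRNAs, %d families, %d samples",
                    len(records), len(families), len(panel.samples))

        stage = "tissue_means"
        means = expression.tissue_means(matrix, panel)

        stage = "expression"
        expr = expression.expression_records(
            matrix, panel, config.threshold, config.inclusive)
        statuses = expr["expressed"]
        logger.info("expression: %d/%d expressed",
                    int(statuses.sum()), len(statuses))

        stage = "identity"
        sequences = {r.snorna_id: r.sequence for r in records}
        alignment_score = pd.Series(np.nan, index=matrix.index)
        identical_families: set[str] = set()
        pair_values: dict[str, list[float]] = {}
        if config.identity_enabled:
            for fam in families:
                if fam.size < 2:
                    continue
                idm = identity.family_identity(fam, sequences)
                alignment_score.loc[list(fam.member_ids)] = idm.member_mean()
                iu = np.triu_indices(fam.size, k=1)
                pair_values.setdefault(fam.box_type, []).extend(
                    idm.matrix[iu].tolist())
            identical_families = identity.find_identical_pairs(families, sequences)

        stage = "genomics"
        placements = {}
        if host_model is not None:
            placements = {r.snorna_id: genomics.assign_host_transcript(r, host_model)
                          for r in records}
        cons_scores = None
        if track is not None:
            cons_scores = {r.snorna_id: genomics.conservation_score(
                r, track, config.uncovered_score_zero) for r in records}
        snp_dens = None
        if snp_set is not None:
            snp_dens = {r.snorna_id: genomics.snp_density(r, snp_set)
                        for r in records}
        context_all = {f.family_id: genomics.classify_family_context(
            f, rec_by_id, statuses, expressed_only=False) for f in families}
        context_expr = {f.family_id: genomics.classify_family_context(
            f, rec_by_id, statuses, expressed_only=True) for f in families}

        stage = "variability"
        var_records = {}
        for fam in families:
            rec = variability.family_variability(fam, means, statuses,
                                                 ddof=config.cv_ddof)
            if rec is not None:
                var_records[fam.family_id] = rec
        diag = {box: [v.diag_distance for f in families
                      if f.box_type == box and f.family_id in var_records
                      for v in [var_records[f.family_id]]]
                for box in {f.box_type for f in families}}
        mwu = None
        if diag.get("CD") and diag.get("HACA"):
            mwu = variability.compare_classes_diag(diag["CD"], diag["HACA"])
        correlations = variability.correlate_size_abundance(
            families, statuses, matrix, method=config.correlation_method)

        stage = "switches"
        switch_records = {f.family_id: switches.detect_switch(f, means, statuses)
                          for f in families}
        member_top = expr["tissue_most_expressed_in"]
        coherent = switches.same_tissue_top_fraction(
            families, member_top, statuses)
        heatmap = switches.heatmap_matrix(
            [switch_records[f.family_id] for f in families], panel)

        stage = "summaries"
        sno_summary = _build_sno_summary(
            records, expr, means, alignment_score, cons_scores, snp_dens,
            placements, config)
        family_summary = _build_family_summary(
            families, matrix, statuses, member_top, var_records,
            switch_records, context_all, context_expr, identical_families)
        report = _build_report(
            sno_summary, family_summary, mwu, correlations, coherent,
            pair_values, config)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    result = PipelineResult(sno_summary, family_summary, heatmap, report)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sno_summary.to_csv(out / "sno_summary.tsv", sep="\t", index=False,
                           float_format="%.6g")
        family_summary.to_csv(out / "family_summary.tsv", sep="\t", index=False,
                              float_format="%.6g")
        heatmap.to_csv(out / "heatmap.tsv", sep="\t")
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        result.out_dir = out
    return result


def _build_sno_summary(records, expr, means, alignment_score, cons_scores,
                       snp_dens, placements, config) -> pd.DataFrame:
    rows = []
    for r in records:
        sid = r.snorna_id
        tissue_row = means.loc[sid]
        try:
            cv = variability.coefficient_of_variation(tissue_row,
                                                      ddof=config.cv_ddof)
        except ValueError:
            cv = float("nan")
        row = {
            "snorna_id": sid,
            "name": r.name,
            "box_type": r.box_type,
            "family_id": r.family_id,
            "expressed": bool(expr.loc[sid, "expressed"]),
            "average_tpm": float(expr.loc[sid, "average_tpm"]),
            "min_tpm": float(expr.loc[sid, "min_tpm"]),
            "max_tpm": float(expr.loc[sid, "max_tpm"]),
            "tissue_most_expressed_in": expr.loc[sid, "tissue_most_expressed_in"],
            "cv": cv,
            "alignment_score": float(alignment_score.loc[sid]),
            "genomic_context": r.host_biotype,
            "host_gene_id": r.host_gene_id if r.host_gene_id else ".",
        }
        if cons_scores is not None:
            row["conservation_score"] = cons_scores[sid]
        if snp_dens is not None:
            row["snp_per_nt_1000"] = snp_dens[sid]
        if placements:
            pl = placements[sid]
            row["host_transcript_id"] = pl.transcript_id if pl.intronic else "."
            row["distance_to_downstream_exon"] = (
                pl.distance_to_downstream_exon if pl.intronic else ".")
        rows.append(row)
    return pd.DataFrame(rows)


def _build_family_summary(families, matrix, statuses, member_top, var_records,
                          switch_records, context_all, context_expr,
                          identical_families) -> pd.DataFrame:
    rows = []
    for fam in families:
        members = list(fam.member_ids)
        n_expr = int(sum(bool(statuses[m]) for m in members))
        var = var_records.get(fam.family_id)
        sw = switch_records[fam.family_id]
        ctx_all = context_all[fam.family_id]
        if n_expr >= 2:
            tops = {member_top[m] for m in members if statuses[m]}
            same_top = str(len(tops) == 1 and NO_TISSUE not in tops)
        else:
            same_top = "."
        rows.append({
            "family_id": fam.family_id,
            "box_type": fam.box_type,
            "n_members": fam.size,
            "n_expressed": n_expr,
            "fraction_expressed": n_expr / fam.size,
            "average_sum_tpm": float(matrix.loc[members].sum(axis=0).mean()),
            "switch": sw.switch,
            "n_top_members": sw.n_top_members,
            "same_host": str(ctx_all.same_host) if ctx_all.same_host is not None
                         else ".",
            "family_covariation": var.family_cv if var else float("nan"),
            "mean_member_covariation": var.mean_member_cv if var else float("nan"),
            "diag_distance": var.diag_distance if var else float("nan"),
            "context_category": ctx_all.category,
            "context_category_expressed": context_expr[fam.family_id].category,
            "has_identical_pair": fam.family_id in identical_families,
            "same_top_tissue": same_top,
        })
    return pd.DataFrame(rows)


def _build_report(sno_summary, family_summary, mwu, correlations, coherent,
                  pair_values, config) -> dict:
    report = {
        "parameters": {
            "tpm_threshold": config.threshold,
            "threshold_inclusive": config.inclusive,
            "cv_ddof": config.cv_ddof,
            "correlation_method": config.correlation_method,
        },
        "classes": summarize_classes(sno_summary, family_summary),
    }
    for box, (k, n) in sorted(coherent.items()):
        report["classes"].setdefault(box, {})[
            "pct_same_top_tissue_of_families_ge2_expressed"] = _fmt_fraction(k, n)
    if mwu is not None:
        report["diag_distance_mannwhitney"] = {
            "U": mwu.statistic, "p_value": mwu.p_value,
            "sidedness": mwu.sidedness}
    report["size_abundance_correlation"] = {
        box: ({"r": res.r, "p_value": res.p_value, "n": res.n,
               "method": res.method} if res else None)
        for box, res in sorted(correlations.items())}
    report["pairwise_identity_mean"] = {
        box: (round(float(np.mean(vals)), 4) if vals else None)
        for box, vals in sorted(pair_values.items())}
    return report
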