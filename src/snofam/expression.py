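"""Tissue-mean reduction and expression-status classification.

A snoRNA counts as *expressed* when its abundance reaches the TPM threshold
(default 1) in at least one individual sample.  The comparison is inclusive
(>=) by default and can be made strict; the status can also be driven by
tissue means instead of samples for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import Family, SamplePanel

DEFAULT_TPM_THRESHOLD = 1.0
NO_TISSUE = "none"


@dataclass(frozen=True)
class ExpressionRecord:
    snorna_id: str
    expressed: bool
    avg_tpm: float
    min_tpm: float
    max_tpm: float
    top_tissue: str


def tissue_means(matrix: pd.DataFrame, panel: SamplePanel) -> pd.DataFrame:
    """Collapse the sample-level TPM matrix to per-tissue arithmetic means."""
    missing = [s for s in panel.samples if s not in matrix.columns]
    if missing:
        raise ValueError(f"matrix missing panel samples: {missing}")
    cols = {
        tissue: matrix.loc[:, list(panel.samples_for(tissue))].mean(axis=1)
        for tissue in panel.tissue_order
    }
    out = pd.DataFrame(cols, index=matrix.index)
    out.index.name = "snorna_id"
    return out


def expression_status(row, threshold: float = DEFAULT_TPM_THRESHOLD,
                      inclusive: bool = True) -> bool:
    """True iff the max of the sample TPM vector reaches the threshold."""
    values = np.asarray(row, dtype=float)
    if values.size == 0:
        raise ValueError("empty TPM vector")
    top = float(values.max())
    return top >= threshold if inclusive else top > threshold


def expression_statuses(matrix: pd.DataFrame,
                        threshold: float = DEFAULT_TPM_THRESHOLD,
                        inclusive: bool = True) -> pd.Series:
    """Vectorized :func:`expression_status` over all rows of a matrix."""
    top = matrix.max(axis=1)
    return (top >= threshold) if inclusive else (top > threshold)


def top_tissue(snorna_id: str, means: pd.DataFrame,
               tissue_order: tuple[str, ...] | None = None) -> str:
    """Tissue with the highest mean TPM; ties go to the canonical tissue order.

    A row that is zero in every tissue returns the sentinel ``"none"``.
    """
    row = means.loc[snorna_id]
    order = list(tissue_order) if tissue_order is not None else list(means.columns)
    if float(row.max()) <= 0.0:
        return NO_TISSUE
    best = max(order, key=lambda t: (row[t], -order.index(t)))
    return best


def expression_records(matrix: pd.DataFrame, panel: SamplePanel,
                       threshold: float = DEFAULT_TPM_THRESHOLD,
                       inclusive: bool = True) -> pd.DataFrame:
    """Per-snoRNA expression summary over all samples.

    Columns: expressed, average_tpm, min_tpm, max_tpm, tissue_most_expressed_in.
    """
    means = tissue_means(matrix, panel)
    statuses = expression_statuses(matrix, threshold, inclusive)
    out = pd.DataFrame({
        "expressed": statuses,
        "average_tpm": matrix.mean(axis=1),
        "min_tpm": matrix.min(axis=1),
        "max_tpm": matrix.max(axis=1),
        "tissue_most_expressed_in": [
            top_tissue(sid, means, panel.tissue_order) for sid in matrix.index],
    }, index=matrix.index)
    out.index.name = "snorna_id"
    return out


def family_expression_summary(family: Family,
                              statuses: pd.Series | dict) -> tuple[int, int, float]:
    """(n_members, n_expressed, fraction_expressed) for one family."""
    n = family.size
    n_expr = sum(bool(statuses[m]) for m in family.member_ids)
    return n, n_expr, n_expr / n
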