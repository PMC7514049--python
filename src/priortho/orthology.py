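"""Ortholog QC filtering, candidate gene sets and cross-species gene-property
correlations.

The QC rule mirrors the Biomart-style attributes of a 1:1 ortholog call:
percent identity of the target gene to its counterpart > 70, gene-order
conservation (GOC) score > 70, orthology confidence = 1, and orthology type
one-to-one.  Thresholds are strict inequalities; boundary values fail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

QC_COLUMNS = ("identity_pct", "goc_score", "confidence", "orthology_type")
ONE2ONE = "ortholog_one2one"


@dataclass
class CandidateGeneSet:
    """A named set of (cattle) gene ids with provenance, e.g. the orthologs
    of human genes prioritized by SMR or by COJO."""

    name: str
    gene_ids: set
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.gene_ids)


def gene_size_kbp(genes: pd.DataFrame) -> pd.Series:
    """(end - start) / 1000, start/end as stored (strand-agnostic)."""
    return (genes["end_bp"] - genes["start_bp"]) / 1000.0


def filter_orthologs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Return exactly the QC-passing ortholog pairs.

    Idempotent; raises a schema error naming any missing QC column.
    """
    missing = [c for c in QC_COLUMNS if c not in pairs.columns]
    if missing:
        raise ValueError(f"ortholog table missing QC column(s): {missing}")
    keep = ((pairs["identity_pct"] > 70.0)
            & (pairs["goc_score"] > 70.0)
            & (pairs["confidence"] == 1)
            & (pairs["orthology_type"] == ONE2ONE))
    return pairs.loc[keep].reset_index(drop=True)


def filter_multi_tissue(candidates: CandidateGeneSet, pairs: pd.DataFrame,
                        min_tissues: int = 3) -> CandidateGeneSet:
    """Restrict a candidate set to genes whose human ortholog shows
    expression evidence in ``min_tissues`` or more tissues (inclusive)."""
    if min_tissues < 1:
        raise ValueError("min_tissues must be >= 1")
    if "n_tissues_smr" not in pairs.columns:
        raise ValueError("ortholog table missing n_tissues_smr")
    sub = pairs[pairs["cattle_id"].isin(candidates.gene_ids)]
    if sub["n_tissues_smr"].isna().any():
        raise ValueError("n_tissues_smr not populated for all candidate genes")
    keep = set(sub.loc[sub["n_tissues_smr"] >= min_tissues, "cattle_id"])
    return CandidateGeneSet(
        name=f"{candidates.name}-MT", gene_ids=keep,
        provenance=f"{candidates.provenance}; >= {min_tissues} tissues")


def correlate_gene_property(values_a, values_b):
    """Pearson correlation of a paired gene property across species.

    Pairs with a missing value on either side are dropped (pairwise
    complete).  Returns ``(r, p, n_dropped)``; raises on zero variance.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("property vectors must be paired (equal length)")
    ok = ~(np.isnan(a) | np.isnan(b))
    n_dropped = int((~ok).sum())
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined: zero variance on one side")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p), n_dropped
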