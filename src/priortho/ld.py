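"""Linkage-disequilibrium utilities: pairwise r², windowed LD scores,
per-gene LD scores, and plink-style greedy clumping.

The LD score of a SNP is the sum of squared dosage correlations with every
other SNP that shares at least one window segment with it; chromosomes are
tiled by ``segment_bp`` windows starting every ``overlap_bp`` (200 kbp
windows with 100 kbp overlap by default).  A pair co-occurring in two
overlapping segments contributes once (deduplicated) unless
``dedup_pairs=False``.  SNPs below the minor-allele-count filter are
excluded from both sides of the sum.

Clumping reduces a summary table to "near-independent" index SNPs: scan by
ascending p; promote an unassigned SNP with p < p1 to index; assign to it
every unassigned SNP with p < p2 within ``dist_bp`` on the same chromosome
and r² >= r2 with the index.  p-ties break by (chrom, pos) ascending, so
the result is invariant to input row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import GenotypeMatrix

logger = logging.getLogger(__name__)


class MonomorphicSnpError(ValueError):
    """LD is undefined for a monomorphic dosage vector."""


def _corr_pairwise(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        raise MonomorphicSnpError(
            "r^2 undefined: monomorphic SNP among non-missing individuals")
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def pairwise_r2(genotypes: GenotypeMatrix, snp_i: str, snp_j: str) -> float:
    """Squared Pearson correlation of two dosage vectors, excluding
    individuals missing either dosage.  Symmetric and sign-invariant."""
    r = _corr_pairwise(genotypes.column(snp_i), genotypes.column(snp_j))
    return min(r * r, 1.0)


def _standardize(dosages: np.ndarray) -> np.ndarray:
    """Column-standardize complete dosages so Z_i . Z_j / n = r_ij."""
    mu = dosages.mean(axis=0)
    sd = dosages.std(axis=0)
    sd[sd == 0] = np.nan
    return (dosages - mu) / sd


def ld_scores(genotypes: GenotypeMatrix, segment_bp: int = 200_000,
              overlap_bp: int = 100_000, min_mac: int = 3,
              dedup_pairs: bool = True) -> pd.DataFrame:
    """Windowed LD scores (snp_id, chrom, pos_bp, mac, ld_score).

    Requires complete dosages and per-chromosome position-sorted SNPs.
    With ``dedup_pairs=False`` a pair contributes once per shared segment
    (segment-summing convention) instead of once overall.
    """
    if segment_bp <= 0 or overlap_bp <= 0 or segment_bp % overlap_bp != 0:
        raise ValueError("segment_bp must be a positive multiple of overlap_bp")
    if np.isnan(genotypes.dosages).any():
        raise ValueError("ld_scores requires complete dosages")
    ratio = segment_bp // overlap_bp
    meta = genotypes.snp_meta
    keep = meta["mac"].to_numpy() >= min_mac
    out = []
    for chrom, idx in meta.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        pos_all = meta.loc[idx, "pos_bp"].to_numpy()
        if np.any(np.diff(pos_all) < 0):
            raise ValueError(f"SNPs on chromosome {chrom} are not position-sorted")
        idx = idx[keep[idx]]
        if len(idx) == 0:
            continue
        pos = meta.loc[idx, "pos_bp"].to_numpy()
        z = _standardize(genotypes.dosages[:, idx].astype(np.float64))
        n = z.shape[0]
        bins = pos // overlap_bp
        m = len(idx)
        scores = np.zeros(m)
        for i in range(m):
            j_hi = np.searchsorted(bins, bins[i] + ratio, side="left")
            js = np.arange(i + 1, j_hi)
            if len(js) == 0:
                continue
            r = (z[:, i] @ z[:, js]) / n
            r2 = np.minimum(r * r, 1.0)
            if dedup_pairs:
                w = 1.0
            else:
                # segment k covers bins [k, k+ratio-1]; a pair with bins
                # b_i <= b_j shares segments max(0, b_j-ratio+1) .. b_i
                w = bins[i] - np.maximum(0, bins[js] - ratio + 1) + 1
            contrib = r2 * w
            scores[i] += np.nansum(contrib)
            np.add.at(scores, js, np.where(np.isnan(contrib), 0.0, contrib))
        out.append(pd.DataFrame({
            "snp_id": meta.loc[idx, "snp_id"].to_numpy(),
            "chrom": chrom,
            "pos_bp": pos,
            "mac": meta.loc[idx, "mac"].to_numpy(),
            "ld_score": scores,
        }))
    if not out:
        return pd.DataFrame(columns=["snp_id", "chrom", "pos_bp", "mac", "ld_score"])
    return pd.concat(out, ignore_index=True)


def gene_ld_score(gene, ld_table: pd.DataFrame):
    """Mean LD score over SNPs with start <= pos <= end on the gene's
    chromosome; NaN (missing, not zero) for genes containing no SNP."""
    sub = ld_table[(ld_table["chrom"] == gene["chrom"])
                   & (ld_table["pos_bp"] >= gene["start_bp"])
                   & (ld_table["pos_bp"] <= gene["end_bp"])]
    if len(sub) == 0:
        return float("nan")
    return float(sub["ld_score"].mean())


def gene_ld_scores(genes: pd.DataFrame, ld_table: pd.DataFrame) -> pd.Series:
    """Vectorized per-gene mean LD score, indexed by gene_id."""
    vals = {}
    for chrom, sub in ld_table.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy()
        order = np.argsort(pos)
        pos = pos[order]
        score = sub["ld_score"].to_numpy()[order]
        cum = np.concatenate([[0.0], np.cumsum(score)])
        g = genes[genes["chrom"] == chrom]
        lo = np.searchsorted(pos, g["start_bp"].to_numpy(), side="left")
        hi = np.searchsorted(pos, g["end_bp"].to_numpy(), side="right")
        for gid, a, b in zip(g["gene_id"], lo, hi):
            vals[gid] = (cum[b] - cum[a]) / (b - a) if b > a else np.nan
    return pd.Series({gid: vals.get(gid, np.nan) for gid in genes["gene_id"]})


@dataclass
class ClumpResult:
    """Index SNPs in promotion order with their clump membership."""

    index_snps: list[str]
    clump_members: dict[str, list[str]]
    index_info: dict[str, dict] = field(default_factory=dict)
    n_dropped: int = 0

    def all_assigned(self) -> set[str]:
        out = set(self.index_snps)
        for members in self.clump_members.values():
            out.update(members)
        return out


def clump(summary: pd.DataFrame, ld_reference: GenotypeMatrix,
          p1: float = 5e-8, p2: float = 5e-8, r2: float = 0.2,
          dist_bp: int = 500_000) -> ClumpResult:
    """Greedy p-value clumping against an LD reference.

    Summary SNPs absent from the reference are dropped with a logged
    count.  Rows with undefined p (e.g. monomorphic in the GWAS sample)
    are ignored.
    """
    for name, v in (("p1", p1), ("p2", p2), ("r2", r2)):
        if not 0.0 < v <= 1.0:
            raise ValueError(f"{name} must lie in (0, 1], got {v}")
    if dist_bp <= 0:
        raise ValueError("dist_bp must be positive")

    known = set(ld_reference.snp_meta["snp_id"])
    df = summary[["snp_id", "chrom", "pos_bp", "p"]].dropna(subset=["p"])
    n_dropped = int((~df["snp_id"].isin(known)).sum())
    if n_dropped:
        logger.info("clump: dropped %d summary SNPs absent from LD reference",
                    n_dropped)
    df = df[df["snp_id"].isin(known)]
    df = df.sort_values(["p", "chrom", "pos_bp"], kind="mergesort").reset_index(drop=True)

    snp_ids = df["snp_id"].to_numpy()
    chroms = df["chrom"].to_numpy()
    pos = df["pos_bp"].to_numpy()
    pvals = df["p"].to_numpy()
    assigned = np.zeros(len(df), dtype=bool)

    Z = _standardize(ld_reference.columns(snp_ids).astype(np.float64))
    n_ind = Z.shape[0]

    index_snps: list[str] = []
    members: dict[str, list[str]] = {}
    info: dict[str, dict] = {}
    for i in range(len(df)):
        if pvals[i] >= p1:
            break
        if assigned[i]:
            continue
        assigned[i] = True
        index_snps.append(snp_ids[i])
        info[snp_ids[i]] = {"chrom": chroms[i], "pos_bp": int(pos[i]),
                            "p": float(pvals[i])}
        cand = np.flatnonzero((~assigned) & (pvals < p2) & (chroms == chroms[i])
                              & (np.abs(pos - pos[i]) <= dist_bp))
        if len(cand) == 0:
            members[snp_ids[i]] = []
            continue
        r = (Z[:, i] @ Z[:, cand]) / n_ind
        hit = cand[np.nan_to_num(r * r) >= r2]
        assigned[hit] = True
        # members reported in (chrom, pos) order for determinism
        hit = hit[np.argsort(pos[hit], kind="mergesort")]
        members[snp_ids[i]] = snp_ids[hit].tolist()
    return ClumpResult(index_snps, members, info, n_dropped)
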