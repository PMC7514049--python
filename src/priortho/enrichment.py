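"""Randomized-sampling enrichment machinery.

Candidate gene sets are compared against matched control sets: the
ortholog universe is stratified into quantiles of gene size, SNP count or
gene LD score, and each control replicate samples, per stratum, exactly as
many genes as the candidate set has there.  Enrichment is measured as the
number of unique near-independent significant SNPs (clump index SNPs)
falling within a window of any gene in the set, and the empirical p-value
is the proportion of control replicates reaching an equal-or-higher count
(no +1 correction by default, mirroring a proportion-of-samples
definition; a flag enables (r+1)/(n+1)).

The module also houses SNP-selection rules for the variance-component
stage: top-by-significance SNPs near a gene set, k random SNPs per gene,
and allele-frequency-matched control SNPs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .overlap import stratify_by_quantile
from .synthetic_data import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    candidate_set_name: str
    window_bp: int
    stratify_by: str
    observed_count: int
    null_counts: list[int]
    empirical_p: float
    direction: str = "greater"
    seed: int | None = None


@dataclass
class SnpSelection:
    name: str
    snp_ids: list[str]
    selection_rule: str
    allele_freq: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.snp_ids)


def _merged_intervals(genes: pd.DataFrame, gene_ids, window_bp: int):
    """Per-chromosome merged [start-w, end+w] intervals for a gene set."""
    sub = genes[genes["gene_id"].isin(set(gene_ids))]
    out = {}
    for chrom, g in sub.groupby("chrom", sort=False):
        lo = (g["start_bp"].to_numpy() - window_bp)
        hi = (g["end_bp"].to_numpy() + window_bp)
        order = np.argsort(lo)
        lo, hi = lo[order], hi[order]
        m_lo, m_hi = [], []
        for a, b in zip(lo, hi):
            if m_hi and a <= m_hi[-1]:
                m_hi[-1] = max(m_hi[-1], b)
            else:
                m_lo.append(a)
                m_hi.append(b)
        out[chrom] = (np.asarray(m_lo), np.asarray(m_hi))
    return out


def count_signals_near_genes(gene_set, genes: pd.DataFrame,
                             index_snps: pd.DataFrame,
                             window_bp: int) -> int:
    """Unique index SNPs with start-w <= pos <= end+w for any gene in the
    set (a SNP near several genes counts once)."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if len(index_snps) == 0:
        return 0
    iv = _merged_intervals(genes, gene_set, window_bp)
    total = 0
    for chrom, snps in index_snps.groupby("chrom", sort=False):
        if chrom not in iv:
            continue
        lo, hi = iv[chrom]
        pos = snps["pos_bp"].to_numpy()
        k = np.searchsorted(lo, pos, side="right") - 1
        inside = (k >= 0) & (pos <= hi[np.clip(k, 0, None)])
        total += int(inside.sum())
    return total


def index_snp_frame(clump_result) -> pd.DataFrame:
    """(snp_id, chrom, pos_bp) frame from a ClumpResult."""
    rows = [{"snp_id": s, "chrom": clump_result.index_info[s]["chrom"],
             "pos_bp": clump_result.index_info[s]["pos_bp"]}
            for s in clump_result.index_snps]
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos_bp"])


def sample_matched_controls(candidates, universe_ids, stratify_values,
                            k: int = 10, rng=None,
                            exclude_candidates: bool = False) -> set[str]:
    """Sample a control gene set matching the candidate set's per-stratum
    counts exactly, without replacement within stratum.  Candidates remain
    eligible as controls unless ``exclude_candidates``."""
    rng = np.random.default_rng(rng)
    universe_ids = np.asarray(list(universe_ids))
    candidates = set(candidates)
    if not candidates <= set(universe_ids.tolist()):
        raise ValueError("candidates must be a subset of the universe")
    labels = stratify_by_quantile(stratify_values, k=k)
    control: set[str] = set()
    for s in sorted(set(labels.tolist())):
        members = universe_ids[labels == s]
        n_cand = sum(1 for g in members if g in candidates)
        if n_cand == 0:
            continue
        pool = members if not exclude_candidates else \
            np.asarray([g for g in members if g not in candidates])
        if n_cand > len(pool):
            raise ValueError(
                f"stratum {s}: cannot sample {n_cand} controls from "
                f"{len(pool)} eligible genes")
        control.update(rng.choice(pool, size=n_cand, replace=False).tolist())
    return control


def enrichment_test(candidates, universe_ids, stratify_values,
                    genes: pd.DataFrame, index_snps: pd.DataFrame,
                    window_bp: int, stratify_by: str = "gene_size",
                    n_reps: int = 1000, seed=None, direction: str = "greater",
                    k: int = 10, plus_one: bool = False,
                    name: str = "candidates") -> EnrichmentResult:
    """Matched-resampling enrichment test for GWAS signals near a gene set.

    ``empirical_p`` is the proportion of the ``n_reps`` control replicates
    whose signal count is >= (direction "greater") or <= ("less") the
    candidate count.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    rng = np.random.default_rng(seed)
    observed = count_signals_near_genes(candidates, genes, index_snps, window_bp)
    null_counts = []
    for _ in range(n_reps):
        ctrl = sample_matched_controls(candidates, universe_ids,
                                       stratify_values, k=k, rng=rng)
        null_counts.append(
            count_signals_near_genes(ctrl, genes, index_snps, window_bp))
    arr = np.asarray(null_counts)
    r = int((arr >= observed).sum() if direction == "greater"
            else (arr <= observed).sum())
    p = (r + 1) / (n_reps + 1) if plus_one else r / n_reps
    return EnrichmentResult(name, window_bp, stratify_by, observed,
                            null_counts, float(p), direction, seed)


def subset_comparison(larger_set, subset_size: int, reference_set,
                      genes: pd.DataFrame, index_snps: pd.DataFrame,
                      window_bp: int = 100_000, n_reps: int = 100,
                      seed=None, name: str = "subset") -> EnrichmentResult:
    """Downsampling comparison: draw ``subset_size`` genes from the larger
    set repeatedly and report the proportion of draws whose signal count is
    equal-or-lower than the reference set's observed count."""
    larger = np.asarray(sorted(set(larger_set)))
    if subset_size > len(larger):
        raise ValueError("subset_size exceeds the larger set")
    rng = np.random.default_rng(seed)
    ref_count = count_signals_near_genes(reference_set, genes, index_snps,
                                         window_bp)
    draws = []
    for _ in range(n_reps):
        sub = rng.choice(larger, size=subset_size, replace=False)
        draws.append(count_signals_near_genes(sub, genes, index_snps, window_bp))
    arr = np.asarray(draws)
    p = float((arr <= ref_count).sum() / n_reps)
    return EnrichmentResult(name, window_bp, "none", ref_count, draws, p,
                            "less", seed)


def _eligible_snps(gene_set, genes: pd.DataFrame, snp_meta: pd.DataFrame,
                   window_bp: int, min_mac: int):
    iv = _merged_intervals(genes, gene_set, window_bp)
    mask = np.zeros(len(snp_meta), dtype=bool)
    pos_all = snp_meta["pos_bp"].to_numpy()
    chrom_all = snp_meta["chrom"].to_numpy()
    for chrom, (lo, hi) in iv.items():
        sel = np.flatnonzero(chrom_all == chrom)
        pos = pos_all[sel]
        k = np.searchsorted(lo, pos, side="right") - 1
        inside = (k >= 0) & (pos <= hi[np.clip(k, 0, None)])
        mask[sel[inside]] = True
    mask &= snp_meta["mac"].to_numpy() >= min_mac
    return snp_meta.loc[mask]


def select_top_snps(gene_set, genes: pd.DataFrame, summary: pd.DataFrame,
                    validation_geno: GenotypeMatrix, window_bp: int = 100_000,
                    n_top: int = 80, min_mac: int = 20,
                    name: str = "top") -> SnpSelection:
    """Most significant summary SNPs within gene +/- window that carry at
    least ``min_mac`` minor-allele copies in the validation genotypes,
    ranked by ascending p with (chrom, pos) tie-breaks."""
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    elig = _eligible_snps(gene_set, genes, validation_geno.snp_meta,
                          window_bp, min_mac)
    sub = summary[summary["snp_id"].isin(set(elig["snp_id"]))].dropna(subset=["p"])
    sub = sub.sort_values(["p", "chrom", "pos_bp"], kind="mergesort")
    chosen = sub["snp_id"].drop_duplicates().head(n_top).tolist()
    if len(chosen) < n_top:
        warnings.warn(f"select_top_snps: only {len(chosen)} of {n_top} "
                      "eligible SNPs available", stacklevel=2)
    freq = validation_geno.snp_meta.set_index("snp_id")["allele_freq"]
    return SnpSelection(name, chosen, "top_by_p",
                        {s: float(freq[s]) for s in chosen})


def sample_snps_per_gene(gene_set, genes: pd.DataFrame,
                         snp_meta: pd.DataFrame, k: int = 5,
                         window_bp: int = 100_000, min_mac: int = 20,
                         rng=None, name: str = "random") -> SnpSelection:
    """k SNPs uniformly without replacement from the eligible SNPs of each
    gene's flanked window (all if fewer), union deduplicated."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(rng)
    pos_all = snp_meta["pos_bp"].to_numpy()
    chrom_all = snp_meta["chrom"].to_numpy()
    mac_ok = snp_meta["mac"].to_numpy() >= min_mac
    ids = snp_meta["snp_id"].to_numpy()
    chosen: list[str] = []
    seen: set[str] = set()
    sub = genes[genes["gene_id"].isin(set(gene_set))].sort_values("gene_id")
    for _, g in sub.iterrows():
        m = ((chrom_all == g["chrom"]) & mac_ok
             & (pos_all >= g["start_bp"] - window_bp)
             & (pos_all <= g["end_bp"] + window_bp))
        pool = ids[m]
        take = pool if len(pool) <= k else rng.choice(pool, size=k, replace=False)
        for s in take:
            if s not in seen:
                seen.add(s)
                chosen.append(s)
    freq = snp_meta.set_index("snp_id")["allele_freq"]
    return SnpSelection(name, chosen, "random_k_per_gene",
                        {s: float(freq[s]) for s in chosen})


def _maf(freq: np.ndarray) -> np.ndarray:
    return np.minimum(freq, 1.0 - freq)


def af_matched_control_snps(candidate_selection: SnpSelection,
                            pool_meta: pd.DataFrame, bin_width: float = 0.05,
                            rng=None, name: str = "af_matched") -> SnpSelection:
    """Control SNPs matching the candidates' minor-allele-frequency
    histogram, sampled without replacement per MAF bin from a pool
    disjoint from the candidates; an underfull bin borrows from the
    nearest bins (logged)."""
    rng = np.random.default_rng(rng)
    pool = pool_meta[~pool_meta["snp_id"].isin(set(candidate_selection.snp_ids))]
    pool_ids = pool["snp_id"].to_numpy()
    pool_bins = np.floor(_maf(pool["allele_freq"].to_numpy()) / bin_width).astype(int)
    cand_maf = _maf(np.asarray(list(candidate_selection.allele_freq.values())))
    cand_bins, cand_counts = np.unique(
        np.floor(cand_maf / bin_width).astype(int), return_counts=True)
    taken = np.zeros(len(pool_ids), dtype=bool)
    chosen: list[str] = []
    max_bin = int(max(pool_bins.max(initial=0), cand_bins.max(initial=0)))
    for b, need in zip(cand_bins, cand_counts):
        avail = np.flatnonzero((pool_bins == b) & ~taken)
        if len(avail) >= need:
            pick = rng.choice(avail, size=int(need), replace=False)
        else:
            logger.info("af_matched_control_snps: bin %d short by %d, "
                        "borrowing from neighbours", b, need - len(avail))
            pick = avail
            for dist in range(1, max_bin + 2):
                if len(pick) >= need:
                    break
                extra = np.flatnonzero(np.isin(pool_bins, [b - dist, b + dist])
                                       & ~taken)
                short = int(need) - len(pick)
                if len(extra) > short:
                    extra = rng.choice(extra, size=short, replace=False)
                pick = np.concatenate([pick, extra])
            if len(pick) < need:
                raise ValueError("pool exhausted: cannot frequency-match controls")
        taken[pick.astype(int)] = True
        chosen.extend(pool_ids[pick.astype(int)].tolist())
    freq = pool.set_index("snp_id")["allele_freq"]
    return SnpSelection(name, chosen, "af_matched_control",
                        {s: float(freq[s]) for s in chosen})
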