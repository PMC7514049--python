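"""Cross-species overlap of trait-associated genes.

Lead SNPs are mapped to genes within an inclusive window (10 kbp by
default, measured to the nearer of gene start/end, with gene-body overlap
always qualifying).  The overlap of the two species' associated gene sets
within the QC-passing ortholog universe forms a 2x2 contingency table,
tested by Fisher's exact test and — stratified by gene-size deciles to
control the large-gene bias — by the Cochran–Mantel–Haenszel (CMH) test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cond_odds_ratio

logger = logging.getLogger(__name__)


@dataclass
class ContingencyTable:
    """a = associated in both species; b = cattle only; c = human only;
    d = neither (all within the ortholog universe)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    def sample_odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return float("inf") if self.a * self.d > 0 else float("nan")
        return self.a * self.d / (self.b * self.c)


@dataclass
class FisherResult:
    odds_ratio: float              # sample estimate ad/(bc)
    p_value: float                 # two-sided, minimum-likelihood method
    conditional_mle: float         # conditional-MLE odds ratio


@dataclass
class CmhResult:
    common_odds_ratio: float
    mh_chi_squared: float
    p_value: float
    n_strata: int


def map_lead_snps_to_genes(lead_snps: pd.DataFrame, genes: pd.DataFrame,
                           window_bp: int = 10_000) -> set[str]:
    """Genes whose body contains a lead SNP or whose start/end lies within
    ``window_bp`` (inclusive) of one; union over SNPs, deduplicated.

    ``lead_snps`` needs (chrom, pos_bp); ``genes`` needs (gene_id, chrom,
    start_bp, end_bp), both in the same coordinate system.
    """
    hit: set[str] = set()
    for chrom, snps in lead_snps.groupby("chrom", sort=False):
        pos = np.sort(snps["pos_bp"].to_numpy())
        g = genes[genes["chrom"] == chrom]
        lo = g["start_bp"].to_numpy() - window_bp
        hi = g["end_bp"].to_numpy() + window_bp
        has = np.searchsorted(pos, lo, side="left") < np.searchsorted(pos, hi, side="right")
        hit.update(g.loc[has, "gene_id"])
    return hit


def build_contingency(set_cattle, set_human, universe) -> ContingencyTable:
    """Cross-tabulate two associated gene sets (already mapped onto the same
    id space) against the ortholog universe."""
    universe = set(universe)
    set_cattle = set(set_cattle)
    set_human = set(set_human)
    stray = (set_cattle | set_human) - universe
    if stray:
        raise ValueError(f"gene(s) outside the universe: {sorted(stray)[:5]}")
    a = len(set_cattle & set_human)
    b = len(set_cattle - set_human)
    c = len(set_human - set_cattle)
    d = len(universe) - a - b - c
    return ContingencyTable(a, b, c, d)


def fisher_exact(table: ContingencyTable) -> FisherResult:
    """Two-sided Fisher's exact test with the sample odds ratio ad/(bc)
    (conditional MLE also exposed)."""
    if table.a + table.b < 1 or table.c + table.d < 1:
        raise ValueError("each row of the table must have at least one count")
    arr = table.as_array()
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    cmle = float(_cond_odds_ratio(arr).statistic)
    return FisherResult(table.sample_odds_ratio(), float(p), cmle)


def stratify_by_quantile(values, k: int = 10):
    """Near-equal-count quantile strata by rank (1 = smallest).

    Returns integer labels 1..k aligned with ``values``; missing values get
    label 0 (their own stratum, logged).  Ties are resolved by stable order
    of appearance, so earlier rows land in the lower stratum.
    """
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    n_missing = int((~ok).sum())
    if n_missing:
        logger.info("stratify_by_quantile: %d missing values -> stratum 0",
                    n_missing)
    vv = v[ok]
    n = len(vv)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(np.unique(vv)) < k:
        raise ValueError("k exceeds the number of distinct property values")
    order = np.argsort(vv, kind="mergesort")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(1, n + 1)
    labels_ok = np.ceil(ranks * k / n).astype(int)
    labels = np.zeros(len(v), dtype=int)
    labels[ok] = labels_ok
    return labels


def stratified_tables(set_cattle, set_human, universe_ids, strata):
    """Per-stratum 2x2 tables; strata partition the universe and the
    per-stratum margins sum to the pooled table."""
    universe_ids = list(universe_ids)
    strata = np.asarray(strata)
    if len(strata) != len(universe_ids):
        raise ValueError("strata must align with universe_ids")
    out = []
    for s in sorted(set(strata.tolist())):
        ids = {g for g, lab in zip(universe_ids, strata) if lab == s}
        out.append((s, build_contingency(set(set_cattle) & ids,
                                         set(set_human) & ids, ids)))
    return out


def cmh_test(tables, continuity_correction: bool = False) -> CmhResult:
    """Cochran–Mantel–Haenszel test over stratified 2x2 tables.

    Common OR = sum(a_i d_i / n_i) / sum(b_i c_i / n_i); the MH
    chi-squared uses no continuity correction by default.  Accepts a list
    of ContingencyTable or (label, ContingencyTable) pairs.
    """
    tabs = [t[1] if isinstance(t, tuple) else t for t in tables]
    tabs = [t for t in tabs if t.n > 0]
    use = [t for t in tabs
           if (t.a + t.b) > 0 and (t.c + t.d) > 0
           and (t.a + t.c) > 0 and (t.b + t.d) > 0]
    if not use:
        raise ValueError("all strata degenerate: no informative margins")
    num = sum(t.a * t.d / t.n for t in use)
    den = sum(t.b * t.c / t.n for t in use)
    common_or = num / den if den > 0 else float("inf")
    s_a = sum(t.a for t in use)
    s_e = sum((t.a + t.b) * (t.a + t.c) / t.n for t in use)
    s_v = sum((t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d)
              / (t.n ** 2 * (t.n - 1)) for t in use if t.n > 1)
    if s_v <= 0:
        raise ValueError("zero Mantel-Haenszel variance: strata uninformative")
    diff = abs(s_a - s_e)
    if continuity_correction:
        diff = max(diff - 0.5, 0.0)
    chi2 = diff ** 2 / s_v
    return CmhResult(common_or, float(chi2), float(stats.chi2.sf(chi2, df=1)),
                     len(use))
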