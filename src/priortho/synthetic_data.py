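"""Synthetic two-species GWAS data generator.

Emulates the statistical structure of a cross-species gene-prioritization
study: a pair of genomes with 1:1 orthologous genes whose sizes are
correlated across species, diploid genotypes with block linkage
disequilibrium (LD), per-SNP GWAS summary statistics with effects planted
in a configurable candidate-gene subset, and an independent validation
population carrying deregressed-breeding-value (dEBV) pseudo-phenotypes
whose noise shrinks with the effective daughter contribution (EDC).

LD is produced by a founder-haplotype mosaic: each gamete copies segments
of a small founder pool, switching founders with a per-bp probability.
This yields block LD that decays with distance — the property the
clumping, LD-score and set-test stages exercise — without simulating an
ancestral recombination graph.

Every operation derives its random stream deterministically from
``SimConfig.seed`` plus a fixed per-stage tag, so the same config yields
bit-identical tables regardless of which operations are invoked or in
which order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimConfig",
    "FounderPool",
    "GenotypeMatrix",
    "GwasSimResult",
    "simulate_gene_map",
    "simulate_genotypes",
    "simulate_gwas_summary",
    "simulate_validation_population",
]

# fixed stage tags: children of SeedSequence(seed) per stage
_TAG_GENES = 11
_TAG_FOUNDERS = 23
_TAG_GWAS_GENO = 37
_TAG_GWAS_PHENO = 41
_TAG_VALID_GENO = 53
_TAG_VALID_PHENO = 59


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(tag)]))


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the synthetic generator.

    Defaults describe a desk-scale study: a handful of multi-megabase
    chromosomes, a few hundred genes with log-normal sizes coupled across
    species by a Gaussian copula, thousands of sequence variants in
    founder-mosaic LD, and a moderately heritable trait whose causal
    variants sit preferentially inside candidate genes.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_len_bp: int = 5_000_000
    n_genes: int = 400
    gene_size_logmean: float = 10.0       # log-bp; e^10 ~ 22 kbp median gene
    gene_size_logsd: float = 1.0
    cross_species_size_corr: float = 0.85
    qc_fail_fraction: float = 0.15
    n_snps_per_chrom: int = 2_000
    n_founder_haplotypes: int = 30
    recomb_rate_per_bp: float = 5e-6      # mean founder-segment length 200 kbp
    n_individuals_gwas: int = 1_000
    n_individuals_validation: int = 500
    candidate_fraction: float = 0.10
    h2_trait: float = 0.5
    n_causal_snps: int = 50
    prop_causal_in_candidates: float = 0.9
    edc_shape: float = 2.0
    edc_scale: float = 50.0               # EDC ~ Gamma(2, 50): mean 100
    debv_noise_scale: float = 10.0        # Var(eps_i) = scale * Var(TBV) / edc_i

    def validate(self) -> None:
        for name in ("n_chrom", "chrom_len_bp", "n_genes", "n_snps_per_chrom",
                     "n_individuals_gwas", "n_individuals_validation",
                     "n_causal_snps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_founder_haplotypes < 2:
            raise ValueError("n_founder_haplotypes must be >= 2")
        for name in ("cross_species_size_corr", "qc_fail_fraction",
                     "candidate_fraction", "h2_trait",
                     "prop_causal_in_candidates"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.recomb_rate_per_bp < 0:
            raise ValueError("recomb_rate_per_bp must be >= 0")
        if self.edc_shape <= 0 or self.edc_scale <= 0:
            raise ValueError("edc gamma parameters must be positive")
        if self.debv_noise_scale < 0:
            raise ValueError("debv_noise_scale must be >= 0")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class FounderPool:
    """Per-chromosome SNP positions and founder haplotypes."""

    chroms: list[str]
    positions: dict[str, np.ndarray]       # chrom -> sorted 1-based pos
    haplotypes: dict[str, np.ndarray]      # chrom -> (H, m) uint8


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with per-SNP metadata.

    ``dosages`` holds additive alt-allele counts in {0,1,2}; missing values
    are NaN (the generator produces none, but readers may).  ``snp_meta``
    carries snp_id, chrom, pos_bp, ref, alt, allele_freq, mac and a
    monomorphic flag; monomorphic sites are flagged, never dropped.
    """

    individual_ids: list[str]
    snp_meta: pd.DataFrame
    dosages: np.ndarray
    founders: FounderPool | None = None
    _col: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._col:
            self._col = {s: i for i, s in enumerate(self.snp_meta["snp_id"])}

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self._col[snp_id]]

    def columns(self, snp_ids) -> np.ndarray:
        idx = [self._col[s] for s in snp_ids]
        return self.dosages[:, idx]


def _snp_metadata(chrom_labels, positions, dosages) -> pd.DataFrame:
    n = dosages.shape[0]
    alt_count = np.nansum(dosages, axis=0)
    n_called = np.sum(~np.isnan(dosages), axis=0)
    freq = np.divide(alt_count, 2.0 * n_called, out=np.full(dosages.shape[1], np.nan),
                     where=n_called > 0)
    mac = np.minimum(alt_count, 2 * n_called - alt_count).astype(int)
    snp_id = [f"{c}:{p}" for c, p in zip(chrom_labels, positions)]
    return pd.DataFrame({
        "snp_id": snp_id,
        "chrom": np.asarray(chrom_labels, dtype=object),
        "pos_bp": np.asarray(positions, dtype=np.int64),
        "ref": "A",
        "alt": "G",
        "allele_freq": freq,
        "mac": mac,
        "monomorphic": (freq == 0.0) | (freq == 1.0),
    })


# ---------------------------------------------------------------------------
# gene map and orthology


def simulate_gene_map(config: SimConfig):
    """Generate per-species gene annotations and a 1:1 ortholog table.

    Gene sizes are log-normal; the two species' log-sizes share a Gaussian
    copula with correlation ``cross_species_size_corr``.  A
    ``qc_fail_fraction`` of ortholog pairs violates exactly one QC
    criterion (identity, gene-order conservation, confidence or orthology
    type).  Coordinates are 1-based inclusive.

    Returns ``(genes_human, genes_cattle, orthologs)`` as DataFrames.
    """
    config.validate()
    rng = _rng(config.seed, _TAG_GENES)
    n = config.n_genes
    rho = config.cross_species_size_corr

    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal(n)
    sizes = {}
    for sp, z in (("human", z1), ("cattle", z2)):
        s = np.exp(config.gene_size_logmean + config.gene_size_logsd * z)
        s = np.maximum(1, np.round(s)).astype(np.int64)
        if np.any(s >= config.chrom_len_bp):
            raise ValueError(
                "sampled gene size exceeds chromosome length; "
                "reduce gene_size_logmean/logsd or enlarge chrom_len_bp")
        sizes[sp] = s

    frames = {}
    for sp, prefix in (("human", "HSA_G"), ("cattle", "BTA_G")):
        s = sizes[sp]
        chrom = rng.integers(1, config.n_chrom + 1, size=n)
        start = (rng.random(n) * (config.chrom_len_bp - s - 1)).astype(np.int64) + 1
        frames[sp] = pd.DataFrame({
            "gene_id": [f"{prefix}{i:05d}" for i in range(n)],
            "species": sp,
            "chrom": chrom.astype(str),
            "start_bp": start,
            "end_bp": start + s,
        })

    identity = rng.uniform(72.0, 99.9, n)
    goc = rng.uniform(72.0, 100.0, n)
    conf = np.ones(n, dtype=int)
    otype = np.full(n, "ortholog_one2one", dtype=object)
    n_fail = int(round(config.qc_fail_fraction * n))
    fail_idx = rng.choice(n, size=n_fail, replace=False)
    mode = rng.integers(0, 4, size=n_fail)
    identity[fail_idx[mode == 0]] = rng.uniform(30.0, 70.0, int((mode == 0).sum()))
    goc[fail_idx[mode == 1]] = rng.uniform(30.0, 70.0, int((mode == 1).sum()))
    conf[fail_idx[mode == 2]] = 0
    otype[fail_idx[mode == 3]] = "ortholog_one2many"

    orthologs = pd.DataFrame({
        "human_id": frames["human"]["gene_id"],
        "cattle_id": frames["cattle"]["gene_id"],
        "identity_pct": identity,
        "goc_score": goc,
        "confidence": conf,
        "orthology_type": otype,
        "n_tissues_smr": rng.poisson(2.0, n),
    })
    return frames["human"], frames["cattle"], orthologs


# ---------------------------------------------------------------------------
# genotypes


def _make_founders(config: SimConfig) -> FounderPool:
    rng = _rng(config.seed, _TAG_FOUNDERS)
    chroms, positions, haplotypes = [], {}, {}
    for c in range(1, config.n_chrom + 1):
        label = str(c)
        pos = np.sort(rng.choice(config.chrom_len_bp, size=config.n_snps_per_chrom,
                                 replace=False)) + 1
        p = rng.uniform(0.05, 0.95, config.n_snps_per_chrom)
        haps = (rng.random((config.n_founder_haplotypes, config.n_snps_per_chrom))
                < p).astype(np.uint8)
        chroms.append(label)
        positions[label] = pos
        haplotypes[label] = haps
    return FounderPool(chroms, positions, haplotypes)


def _mosaic_gametes(pos, haps, n_gametes, rate, rng) -> np.ndarray:
    """Drop gametes as founder mosaics: copy a founder, switch with
    probability 1 - exp(-rate * distance) between adjacent SNPs."""
    m = len(pos)
    n_founders = haps.shape[0]
    switch = np.empty((n_gametes, m), dtype=bool)
    switch[:, 0] = True
    if m > 1:
        s = 1.0 - np.exp(-rate * np.diff(pos))
        switch[:, 1:] = rng.random((n_gametes, m - 1)) < s
    seg = np.cumsum(switch, axis=1)            # segment counter, starts at 1
    choice = rng.integers(0, n_founders, size=(n_gametes, int(seg.max()) + 1))
    fidx = np.take_along_axis(choice, seg, axis=1)
    return haps[fidx, np.arange(m)[None, :]]


def simulate_genotypes(config: SimConfig, *, n_individuals: int | None = None,
                       founder_pool: FounderPool | None = None,
                       stream: str = "gwas") -> GenotypeMatrix:
    """Simulate diploid dosages under the founder-mosaic LD model.

    ``stream`` selects an independent random stream ("gwas" or
    "validation") so the validation population is drawn from the same
    founder pool but with independent recombination/noise.
    """
    config.validate()
    tag = _TAG_GWAS_GENO if stream == "gwas" else _TAG_VALID_GENO
    rng = _rng(config.seed, tag)
    if founder_pool is None:
        founder_pool = _make_founders(config)
    if n_individuals is None:
        n_individuals = (config.n_individuals_gwas if stream == "gwas"
                         else config.n_individuals_validation)

    blocks, chrom_labels, all_pos = [], [], []
    for label in founder_pool.chroms:
        pos = founder_pool.positions[label]
        haps = founder_pool.haplotypes[label]
        gam = _mosaic_gametes(pos, haps, 2 * n_individuals,
                              config.recomb_rate_per_bp, rng)
        blocks.append((gam[0::2] + gam[1::2]).astype(np.float32))
        chrom_labels.extend([label] * len(pos))
        all_pos.extend(pos.tolist())
    dosages = np.concatenate(blocks, axis=1)
    prefix = "G" if stream == "gwas" else "V"
    ids = [f"{prefix}{i:05d}" for i in range(n_individuals)]
    meta = _snp_metadata(chrom_labels, all_pos, dosages)
    return GenotypeMatrix(ids, meta, dosages, founders=founder_pool)


# ---------------------------------------------------------------------------
# GWAS summary statistics


@dataclass
class GwasSimResult:
    """Summary table plus the simulation truth behind it."""

    summary: pd.DataFrame          # snp_id chrom pos_bp a1 a2 freq b se p n
    effects: np.ndarray            # per-SNP true allele substitution effects
    causal_snp_ids: list[str]
    phenotype: np.ndarray
    sigma_e2: float


def single_snp_regression(dosages: np.ndarray, y: np.ndarray):
    """Per-SNP least-squares of y on dosage.

    Returns ``(beta, se, p)`` with p from the chi-squared(1) tail of
    (beta/se)^2, the convention of GWAS summary files, so the row-wise
    identity chi2 = (b/se)^2 = qchisq(1-p, 1) holds exactly.
    """
    n = len(y)
    dosages = np.asarray(dosages, dtype=np.float64)
    xc = dosages - np.nanmean(dosages, axis=0)
    yc = np.asarray(y, dtype=np.float64) - np.mean(y)
    sxx = np.nansum(xc * xc, axis=0)
    sxy = np.nansum(xc * yc[:, None], axis=0)
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 0, sxy / sxx, np.nan)
        sigma2 = (syy - beta * sxy) / max(n - 2, 1)
        sigma2 = np.maximum(sigma2, 0.0)
        se = np.sqrt(np.where(sxx > 0, sigma2 / sxx, np.nan))
        z2 = (beta / se) ** 2
    p = stats.chi2.sf(z2, df=1)
    return beta, se, p


def simulate_gwas_summary(genotypes: GenotypeMatrix, gene_map: pd.DataFrame,
                          candidate_gene_ids, config: SimConfig) -> GwasSimResult:
    """Plant causal effects (preferentially inside candidate genes), build a
    phenotype with narrow-sense heritability ``h2_trait``, and compute a
    COJO-style per-SNP summary table by single-SNP regression."""
    config.validate()
    rng = _rng(config.seed, _TAG_GWAS_PHENO)
    meta = genotypes.snp_meta
    candidate_gene_ids = set(candidate_gene_ids)
    genes = gene_map[gene_map["gene_id"].isin(candidate_gene_ids)]
    missing = candidate_gene_ids - set(genes["gene_id"])
    if missing:
        raise ValueError(f"candidate genes absent from gene map: {sorted(missing)[:5]}")

    poly = ~meta["monomorphic"].to_numpy()
    in_candidate = np.zeros(len(meta), dtype=bool)
    pos = meta["pos_bp"].to_numpy()
    for _, g in genes.iterrows():
        in_candidate |= ((meta["chrom"].to_numpy() == g["chrom"])
                         & (pos >= g["start_bp"]) & (pos <= g["end_bp"]))
    pool_in = np.flatnonzero(in_candidate & poly)
    pool_out = np.flatnonzero(~in_candidate & poly)

    effects = np.zeros(genotypes.n_snps)
    causal_ids: list[str] = []
    if config.h2_trait > 0:
        n_in = int(rng.binomial(config.n_causal_snps, config.prop_causal_in_candidates))
        if n_in > 0 and len(pool_in) == 0:
            raise ValueError("no polymorphic SNP available inside candidate genes")
        n_in = min(n_in, len(pool_in))
        inside = rng.choice(pool_in, size=n_in, replace=False) if n_in else \
            np.empty(0, dtype=int)
        # the remainder is uniform genome-wide (candidate genes included)
        rest_pool = np.setdiff1d(np.flatnonzero(poly), inside)
        n_rest = min(config.n_causal_snps - n_in, len(rest_pool))
        rest = rng.choice(rest_pool, size=n_rest, replace=False) if n_rest else \
            np.empty(0, dtype=int)
        chosen = np.concatenate([inside, rest]).astype(int)
        effects[chosen] = rng.standard_normal(len(chosen))
        causal_ids = meta["snp_id"].to_numpy()[chosen].tolist()

    X = genotypes.dosages
    g = (X - np.nanmean(X, axis=0)) @ effects
    var_g = float(np.var(g))
    if config.h2_trait > 0 and var_g > 0:
        sigma_e2 = var_g * (1.0 - config.h2_trait) / config.h2_trait
    else:
        sigma_e2 = 1.0
    y = g + rng.normal(0.0, np.sqrt(sigma_e2), size=genotypes.n_individuals)

    beta, se, p = single_snp_regression(X, y)
    summary = pd.DataFrame({
        "snp_id": meta["snp_id"],
        "chrom": meta["chrom"],
        "pos_bp": meta["pos_bp"],
        "a1": meta["alt"],
        "a2": meta["ref"],
        "freq": meta["allele_freq"],
        "b": beta,
        "se": se,
        "p": p,
        "n": genotypes.n_individuals,
    })
    return GwasSimResult(summary, effects, causal_ids, y, sigma_e2)


# ---------------------------------------------------------------------------
# validation population


def simulate_validation_population(genotypes_template: GenotypeMatrix,
                                   causal_effects: np.ndarray,
                                   config: SimConfig):
    """Draw an independent validation cohort from the template's founder
    pool with dEBV phenotypes: debv_i = TBV_i + eps_i, Var(eps_i) =
    debv_noise_scale * Var(TBV) / edc_i, edc_i ~ Gamma(shape, scale).

    Returns ``(GenotypeMatrix, phenotypes)``; the phenotype frame keeps the
    simulation-truth ``tbv`` column alongside (individual_id, debv, edc).
    """
    config.validate()
    if genotypes_template.founders is None:
        raise ValueError("template GenotypeMatrix carries no founder pool")
    if len(causal_effects) != genotypes_template.n_snps:
        raise ValueError("causal_effects must align with the template SNP set")
    geno = simulate_genotypes(config,
                              n_individuals=config.n_individuals_validation,
                              founder_pool=genotypes_template.founders,
                              stream="validation")
    rng = _rng(config.seed, _TAG_VALID_PHENO)
    X = geno.dosages
    tbv = (X - np.nanmean(X, axis=0)) @ np.asarray(causal_effects, dtype=float)
    var_tbv = float(np.var(tbv))
    base = config.debv_noise_scale * (var_tbv if var_tbv > 0 else 1.0)
    edc = rng.gamma(config.edc_shape, config.edc_scale,
                    size=config.n_individuals_validation)
    eps = rng.normal(0.0, np.sqrt(base / edc))
    phen = pd.DataFrame({
        "individual_id": geno.individual_ids,
        "debv": tbv + eps,
        "edc": edc,
        "tbv": tbv,
    })
    return geno, phen
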