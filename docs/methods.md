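# Methods

## Scope and model

`priortho` analyses the transfer of trait-gene information between two
species through 1:1 orthologs. The observable units are: per-SNP GWAS
summary rows (alleles, frequency, b, se, p, N); gene annotations with
1-based inclusive coordinates (start = beginning of the 5' UTR, end = end
of the 3' UTR, size in kbp = (end − start)/1000); an ortholog table with
QC attributes; an individual-level LD reference; and a validation
population with deregressed breeding values (dEBVs) weighted by effective
daughter contributions (EDCs).

The pipeline's statistical core:

1. **Ortholog QC.** A pair passes iff identity > 70, GOC > 70,
   confidence = 1 and type is one-to-one. The inequalities are strict:
   boundary values fail. Filtering is idempotent.
2. **LD scores.** Chromosomes are tiled by `segment_bp` windows starting
   every `overlap_bp` (defaults 200/100 kbp, so a SNP pair shares a
   segment iff their 100 kbp bins differ by at most one). A SNP's score is
   Σ r² over every *distinct* other SNP sharing a segment. A pair falling
   in two overlapping segments is counted once; the alternative
   once-per-segment convention sits behind `dedup_pairs=False` because
   tools differ on it and neither choice affects rank-based downstream
   use. SNPs with minor-allele count < 3 are excluded from both sides.
3. **Clumping.** Greedy on ascending p (ties broken by (chrom, pos) so the
   result is invariant to row order): promote unassigned SNPs with p < p1
   to index, absorb unassigned SNPs with p < p2 within `dist_bp` on the
   same chromosome and r² ≥ `r2` with the index. Defaults 5e-8 / 5e-8 /
   0.2 / 0.5 Mbp.
4. **Gene-based test.** T = Σχ²₁ over retained SNPs in gene ± 50 kbp,
   χ² taken from p via the χ²₁ quantile so the test runs on p-only files
   ((b/se)² is a flag, and the generator guarantees the two agree row-wise
   to 1e-6 relative). Retention is greedy LD pruning at r² ≤ `r2_max`
   (0.9 for low-LD genomes, 0.5 recommended for long-LD livestock
   genomes). The null is Σλχ²₁ with λ the eigenvalues of the retained-SNP
   dosage correlation matrix; eigenvalues below 1e-8·λmax are truncated
   for stability with near-duplicate SNPs. The tail probability comes
   from Imhof's inversion integral (quad with tight tolerances; the
   analytically exact scaled-χ² form is used when all λ are equal within
   1e-10 relative); if the quadrature fails to converge — deep tails with
   few, very unequal weights — a Satterthwaite moment-matched scaled χ²
   is used and flagged in the result.
5. **Overlap tests.** Lead SNPs map to a gene if the SNP is in the gene
   body or within 10 kbp (inclusive) of either end; a SNP inside the body
   always qualifies. Fisher's exact test reports the sample odds ratio
   ad/(bc) (the conditional MLE is also exposed) and the two-sided
   minimum-likelihood p. The CMH test uses the Mantel–Haenszel common OR
   Σ(aᵢdᵢ/nᵢ)/Σ(bᵢcᵢ/nᵢ) and χ² without continuity correction (a flag
   restores it); strata are gene-size deciles assigned by rank with ties
   going to the lower stratum, missing values forming their own logged
   stratum.
6. **Enrichment.** Controls are sampled per stratum to match the
   candidate histogram exactly, without replacement, candidates eligible
   (a flag excludes them). The empirical p is the plain proportion of
   replicates with an equal-or-more-extreme count — no +1 correction, to
   mirror the proportion-of-samples definition; `plus_one=True` gives the
   (r+1)/(n+1) variant. Matching is one stratifier at a time (size, SNP
   count or LD score), as joint matching over-constrains small strata.
7. **GREML.** G = (1/m)·W Wᵀ with w_ij = (x_ij − 2pⱼ)/√(2pⱼ(1−pⱼ)), p
   from the sample, missing dosages mean-imputed per SNP. V = σ²g₁G₁ +
   σ²g₂G₂ + σ²ₑD with D = diag(1/EDC); EDC weighting enters the residual
   covariance only. Average-information REML with one initial EM step,
   step-halving on likelihood decreases, components floored at ~0 and
   pinned after two consecutive negative updates; convergence at relative
   log-likelihood change < 1e-8 or parameter change < 1e-6, cap 200
   iterations. A singular AI matrix (e.g. duplicated GRMs) is reported as
   non-convergence with a message, never silently. Traces tr(P·C) are
   computed as elementwise sums of symmetric matrices, so each iteration
   costs one n³ inverse plus O(n²) work. "Percentage of genetic
   variance" means 100·σ²g₁/(σ²g₁+σ²g₂): GRM₂ is a population-structure
   control built from genome-wide background SNPs (excluding GRM₁'s), so
   the ratio isolates the candidate set's share of the genetic variance.
   The minor-allele-count rule (≥ 20 copies) is the operative filter; the
   two MAF values it implies for n = 975 (20/(2·975) ≈ 0.0103 and the
   20/975·2 ≈ 0.04 arithmetic sometimes quoted alongside such rules) are
   both reported by `implied_maf_thresholds`.

## Synthetic data generator

The generator emulates the *statistical structure* the pipeline needs, not
cattle demography:

- **Gene maps.** Log-normal sizes (default logmean 10, logsd 1 ≈ 22 kbp
  median) coupled across species by a Gaussian copula at the configured
  correlation (default 0.85, the strength typical of mammalian ortholog
  size conservation); only size is coupled because cross-species LD-score
  coupling is empirically near zero. Genes may overlap within a species;
  placement is uniform per chromosome.
- **LD.** Founder-haplotype mosaics: each gamete copies one of
  `n_founder_haplotypes` (default 30) founders, switching founders between
  adjacent SNPs with probability 1 − exp(−rate·distance) (default rate
  5e-6/bp, mean segment 200 kbp). This produces block LD that decays with
  distance — what clumping, LD scores and the set test exercise — without
  an ancestral recombination graph. It does **not** reproduce realistic
  allele-frequency spectra, recombination hotspots, selection or breed
  structure, so passing tests demonstrate algorithmic correctness and
  statistical calibration, not transferability of any biological effect
  size.
- **Summary statistics.** `n_causal_snps` effects drawn N(0,1); each sits
  inside a candidate gene with probability `prop_causal_in_candidates`,
  the rest uniform genome-wide (candidate genes included, so a zero
  proportion yields a genuinely unenriched genome). Environmental noise is
  scaled to the target narrow-sense h². Each SNP's b/se/p comes from
  single-SNP least squares with p from the χ²₁ tail of (b/se)², the
  convention of GWAS summary files.
- **Validation population.** Independent individuals from the same founder
  pool; dEBVᵢ = TBVᵢ + εᵢ with Var(εᵢ) = s·Var(TBV)/EDCᵢ and
  EDC ~ Gamma(2, 50) (mean 100, the order of progeny-test bulls). The
  noise scale s (default 10, mean reliability ≈ 0.9) and the Gamma
  parameters are free knobs: no public distributional description of
  dEBV/EDC exists to calibrate against, so they are chosen once as
  plausible and documented here.

Determinism: every operation derives its stream from `SimConfig.seed`
plus a fixed per-stage tag, so identical configs give bit-identical
tables regardless of call order, and the GWAS and validation cohorts use
independent streams over a shared founder pool.

## Validation design

Published-scale overlap statistics are recomputed exactly from the
contingency counts they summarize (cells (10, 67, 358, 13307) give
OR 5.55, p 3.7e-5; cells (30, 47, 1523, 12142) give OR 5.09, p 3.1e-10).
Everything stochastic is validated by construction:

- clumping against a brute-force reference that re-derives assignments
  from the definition with per-pair r², exact set equality on random
  200-SNP instances;
- gene-based p-values against 100,000-draw Monte-Carlo tails of Σλχ²₁,
  within 3 Monte-Carlo standard errors;
- enrichment calibration on synthetic genomes with signals present but
  *unrelated* to a randomly chosen candidate set (causal SNPs uniform
  genome-wide). A literal global null (h² = 0) leaves no index SNP at any
  sensible threshold, making every empirical p exactly 1, so calibration
  instead relaxes the index threshold to 0.05 — the count is then just a
  statistic, not a claim of significance — and checks the empirical p over
  200 generator seeds against U(0,1) (KS, α = 0.01). Power uses 15 strong
  causal SNPs planted entirely inside 25 candidate genes at n = 800 with
  the genuine 5e-8 threshold;
- GREML against a 2:2:6 variance split at n = 1,000 (mean recovered share
  of genetic variance within [40, 60]% over 20 replicates, truth 50%) and
  a pure-noise null (components within 2 AI-based SEs of zero);
- the CMH test's type-I error at α = 0.05 over 1,000 null stratified
  tables drawn from the hypergeometric with random margins.

Problem sizes throughout (hundreds of individuals, thousands of SNPs,
hundreds of genes, 200-replicate resampling) are chosen so the full suite
runs on a laptop-class single core in minutes while keeping every check
statistically meaningful; the acceptance script uses the same designs at
slightly reduced replication.

## Known limitations

- The founder-mosaic LD model has no mutation/drift dynamics; allele
  frequencies come from the founder draw, so rare-variant behaviour is
  under-represented relative to sequence data.
- The Imhof quadrature can fail in deep tails with few, highly unequal
  eigenvalues; the Satterthwaite fallback is approximate there (the
  `method` field records which path produced each p).
- The empirical enrichment p has resolution 1/n_reps and no +1
  correction by default; with few index SNPs it is conservative because
  of count ties.
- The two-GRM GREML assumes the phenotype is a dEBV with residual
  variance proportional to 1/EDC; it does not model covariances between
  the candidate and background genetic effects beyond GRM orthogonality
  by SNP exclusion.
- Orthology is consumed as a table; paralogy, liftover and live
  annotation queries are out of scope.
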