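"""Two-GRM weighted GREML variance partitioning.

The model is y = 1*mu + W g1 + W g2 + e with g1 ~ N(0, G1 s2_g1),
g2 ~ N(0, G2 s2_g2) and e ~ N(0, D s2_e), where G1 is built from the SNPs
of interest, G2 from background SNPs sampled genome-wide (a population-
structure control), and D = diag(1/EDC) weights the residual of each
deregressed breeding value by the inverse of its effective daughter
contribution.  GRMs use the per-SNP-standardized formula
G_jk = (1/m) sum_i (x_ji - 2 p_i)(x_ki - 2 p_i) / (2 p_i (1 - p_i)).

Restricted likelihood is maximized by average-information (AI) REML with
EM fallback steps and step-halving; variance components are constrained
non-negative, pinned to zero when an update goes negative twice
consecutively.  The headline quantity is the percentage of genetic
variance attributed to the candidate GRM, 100 * s2_g1 / (s2_g1 + s2_g2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import SnpSelection, af_matched_control_snps, \
    sample_snps_per_gene, select_top_snps
from .synthetic_data import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class Grm:
    individual_ids: list[str]
    matrix: np.ndarray
    n_snps_used: int
    snp_ids: list[str] | None = None


@dataclass
class VarCompResult:
    sigma2_g1: float
    sigma2_g2: float
    sigma2_e: float
    mu: float
    pct_genetic_variance: float
    loglik_restricted: float
    n_iterations: int
    converged: bool
    se: np.ndarray = field(default=None, repr=False)   # AI-based SEs, order (g1, g2, e)
    message: str = ""


def mac_filter(genotypes: GenotypeMatrix, min_copies: int = 20) -> list[str]:
    """SNP ids with minor-allele count >= min_copies ("at least 20 copies
    of the minor allele"); monomorphic sites never pass."""
    meta = genotypes.snp_meta
    keep = (meta["mac"] >= min_copies) & ~meta["monomorphic"]
    return meta.loc[keep, "snp_id"].tolist()


def implied_maf_thresholds(min_copies: int = 20, n_individuals: int = 975):
    """The two MAF values implied by a minor-allele-count rule: the
    count-based one, min_copies / (2n), and the printed-arithmetic variant
    min_copies / n * 2.  The count rule is what governs filtering."""
    return {"count_based": min_copies / (2 * n_individuals),
            "printed_arithmetic": min_copies / n_individuals * 2}


def compute_grm(genotypes: GenotypeMatrix, snp_ids) -> Grm:
    """Per-SNP standardized GRM from the listed SNPs; sample allele
    frequencies; missing dosages mean-imputed per SNP before centering."""
    snp_ids = list(snp_ids)
    X = genotypes.columns(snp_ids).astype(np.float64).copy()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    p = X.mean(axis=0) / 2.0
    bad = (p <= 0.0) | (p >= 1.0)
    if bad.any():
        raise ValueError(
            f"monomorphic SNP(s) in GRM list: {[snp_ids[i] for i in np.flatnonzero(bad)[:5]]}")
    W = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    G = (W @ W.T) / len(snp_ids)
    return Grm(list(genotypes.individual_ids), G, len(snp_ids), snp_ids)


def sample_background_snps(snp_meta: pd.DataFrame, exclude_ids,
                           n: int = 50_000, rng=None,
                           min_mac: int = 20) -> list[str]:
    """Uniform sample without replacement of MAC-passing SNPs outside the
    exclusion set; takes all (with a warning) when the pool is short."""
    rng = np.random.default_rng(rng)
    exclude = set(exclude_ids)
    pool = snp_meta.loc[(snp_meta["mac"] >= min_mac)
                        & ~snp_meta["monomorphic"]
                        & ~snp_meta["snp_id"].isin(exclude), "snp_id"].to_numpy()
    if len(pool) <= n:
        if len(pool) < n:
            warnings.warn(f"background pool has only {len(pool)} SNPs "
                          f"(requested {n}); taking all", stacklevel=2)
        return pool.tolist()
    return rng.choice(pool, size=n, replace=False).tolist()


# ---------------------------------------------------------------------------
# AI-REML


def _loglik(theta, comps, y, X):
    V = sum(t * C for t, C in zip(theta, comps))
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return None
    n = len(y)
    logdet_V = 2.0 * np.sum(np.log(np.diag(L)))
    Vinv_y = np.linalg.solve(V, y)
    Vinv_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vinv_X
    logdet_X = np.log(np.linalg.det(XtViX)) if XtViX.size > 1 else np.log(XtViX[0, 0])
    beta = np.linalg.solve(XtViX, X.T @ Vinv_y)
    Py = Vinv_y - Vinv_X @ beta
    ll = -0.5 * (logdet_V + logdet_X + float(y @ Py))
    Vinv = np.linalg.inv(V)
    P = Vinv - Vinv_X @ np.linalg.solve(XtViX, Vinv_X.T)
    return {"ll": ll, "Py": Py, "P": P, "beta": beta}


def _reml(y, comps, max_iter=200, ll_tol=1e-8, par_tol=1e-6):
    """AI-REML over variance components for V = sum theta_i comps_i.

    Returns (theta, mu, ll, n_iter, converged, se, message).
    """
    n = len(y)
    X = np.ones((n, 1))
    vy = float(np.var(y))
    k = len(comps)
    theta = np.full(k, vy / k)
    floor = 1e-8 * vy
    pinned = np.zeros(k, dtype=bool)
    neg_count = np.zeros(k, dtype=int)

    state = _loglik(theta, comps, y, X)
    if state is None:
        raise ValueError("initial V not positive definite")
    message = ""
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        P, Py = state["P"], state["Py"]
        free = np.flatnonzero(~pinned)
        # dL/dtheta_i = -0.5 (tr(P C_i) - y' P C_i P y); traces via
        # elementwise products since P and C_i are symmetric
        score = np.array([
            -0.5 * (float(np.sum(P * comps[i])) - float(Py @ comps[i] @ Py))
            for i in free])
        CPy = [comps[i] @ Py for i in free]
        AI = 0.5 * np.array([[float(CPy[a] @ P @ CPy[b])
                              for b in range(len(free))]
                             for a in range(len(free))])
        if len(free) == 0:
            message = "all components pinned at zero"
            break
        cond = np.linalg.cond(AI)
        if not np.isfinite(cond) or cond > 1e12:
            message = "singular AI matrix (non-identifiable model)"
            break

        use_em = it <= 1
        if use_em:
            delta = np.array([
                (theta[f] ** 2 / n) * (float(Py @ comps[f] @ Py)
                                       - float(np.sum(P * comps[f])))
                for f in free])
        else:
            delta = np.linalg.solve(AI, score)

        accepted = False
        step = 1.0
        for _ in range(12):
            trial = theta.copy()
            trial[free] = theta[free] + step * delta
            went_neg = trial < 0
            trial = np.maximum(trial, floor)
            trial[pinned] = 0.0
            new_state = _loglik(trial, comps, y, X)
            if new_state is not None and new_state["ll"] >= state["ll"] - 1e-10:
                neg_count[went_neg & ~pinned] += 1
                neg_count[~went_neg] = 0
                newly = (neg_count >= 2) & ~pinned
                trial[newly] = 0.0
                pinned |= newly
                d_par = np.max(np.abs(trial - theta) / np.maximum(theta, vy * 1e-3))
                d_ll = abs(new_state["ll"] - state["ll"]) / max(abs(state["ll"]), 1.0)
                theta = trial
                state = new_state if not newly.any() else _loglik(theta, comps, y, X)
                accepted = True
                if d_ll < ll_tol or d_par < par_tol:
                    converged = True
                break
            step *= 0.5
        if not accepted:
            message = "step-halving failed to improve restricted likelihood"
            break
        if converged:
            break
    else:
        message = "maximum iterations reached"

    # SEs from the AI matrix at the final point; pinned components are
    # included so boundary estimates still carry an uncertainty scale
    se = np.full(k, np.nan)
    if state is not None:
        P, Py = state["P"], state["Py"]
        CPy = [comps[i] @ Py for i in range(k)]
        AI = 0.5 * np.array([[float(CPy[a] @ P @ CPy[b]) for b in range(k)]
                             for a in range(k)])
        try:
            se[:] = np.sqrt(np.diag(np.linalg.inv(AI)))
        except np.linalg.LinAlgError:
            free = np.flatnonzero(~pinned)
            if len(free):
                sub = AI[np.ix_(free, free)]
                try:
                    se[free] = np.sqrt(np.diag(np.linalg.inv(sub)))
                except np.linalg.LinAlgError:
                    pass
    mu = float(state["beta"][0]) if state is not None else np.nan
    return theta, mu, state["ll"], it, converged, se, message


def greml_two_grm(phenotypes: pd.DataFrame, grm1: Grm, grm2: Grm | None,
                  max_iter: int = 200) -> VarCompResult:
    """Fit the two-GRM EDC-weighted GREML model and report the share of
    genetic variance captured by GRM1.

    ``phenotypes`` needs (individual_id, debv, edc); individuals are
    aligned by id across the phenotype frame and both GRMs.  With
    ``grm2=None`` the model reduces to single-GRM GREML.
    """
    ids = list(phenotypes["individual_id"])
    if len(ids) < 30:
        raise ValueError("need at least 30 phenotyped individuals")
    if (phenotypes["edc"] <= 0).any():
        raise ValueError("edc must be positive")

    def _align(grm: Grm) -> np.ndarray:
        index = {v: i for i, v in enumerate(grm.individual_ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise ValueError(f"GRM missing individuals: {missing[:5]}")
        sel = np.array([index[i] for i in ids])
        return grm.matrix[np.ix_(sel, sel)]

    y = phenotypes["debv"].to_numpy(dtype=float)
    D = np.diag(1.0 / phenotypes["edc"].to_numpy(dtype=float))
    comps = [_align(grm1)] + ([_align(grm2)] if grm2 is not None else []) + [D]
    theta, mu, ll, it, converged, se, message = _reml(y, comps, max_iter=max_iter)

    if grm2 is not None:
        s1, s2, se_ = theta[0], theta[1], theta[2]
        tot = s1 + s2
        pct = 100.0 * s1 / tot if tot > 0 else float("nan")
        se_out = se
    else:
        s1, s2, se_ = theta[0], 0.0, theta[1]
        pct = 100.0 if s1 > 0 else float("nan")
        se_out = np.array([se[0], np.nan, se[1]])
    return VarCompResult(float(s1), float(s2), float(se_), mu, float(pct),
                         float(ll), it, converged, se_out, message)


def variance_control_experiment(hypothesis: str,
                                candidate_selection: SnpSelection,
                                control_gene_sets,
                                genes: pd.DataFrame,
                                summary: pd.DataFrame,
                                phenotypes: pd.DataFrame,
                                genotypes: GenotypeMatrix,
                                n_background: int = 5_000,
                                window_bp: int = 100_000,
                                min_mac: int = 20,
                                seed=None):
    """Compare the candidate SNP set's share of genetic variance against
    per-control-set selections.

    ``hypothesis`` is "top_snps" (controls take the most significant SNPs
    in each control gene set, sized to the candidate selection) or
    "random_snps" (controls take allele-frequency-matched random SNPs).
    Returns ``(candidate_pct, control_pcts, prop_controls_ge)``;
    non-converged fits are excluded with a logged count.
    """
    if hypothesis not in ("top_snps", "random_snps"):
        raise ValueError("hypothesis must be 'top_snps' or 'random_snps'")
    rng = np.random.default_rng(seed)
    meta = genotypes.snp_meta

    def _fit(selection: SnpSelection):
        if len(selection) == 0:
            return None
        g1 = compute_grm(genotypes, selection.snp_ids)
        bg = sample_background_snps(meta, selection.snp_ids, n=n_background,
                                    rng=rng, min_mac=min_mac)
        g2 = compute_grm(genotypes, bg)
        return greml_two_grm(phenotypes, g1, g2)

    cand_fit = _fit(candidate_selection)
    if cand_fit is None or not cand_fit.converged:
        raise ValueError("candidate-set GREML fit did not converge")
    n_cand = len(candidate_selection)

    control_pcts: list[float] = []
    n_failed = 0
    for ctrl_genes in control_gene_sets:
        if hypothesis == "top_snps":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sel = select_top_snps(ctrl_genes, genes, summary, genotypes,
                                      window_bp=window_bp, n_top=n_cand,
                                      min_mac=min_mac, name="control")
        else:
            # AF-matched random draw from the control gene set's windows
            from .enrichment import _eligible_snps
            pool = _eligible_snps(ctrl_genes, genes, meta, window_bp, min_mac)
            try:
                sel = af_matched_control_snps(candidate_selection, pool,
                                              rng=rng, name="control")
            except ValueError:
                n_failed += 1
                continue
        fit = _fit(sel)
        if fit is None or not fit.converged:
            n_failed += 1
            continue
        control_pcts.append(fit.pct_genetic_variance)
    if n_failed:
        logger.info("variance_control_experiment: %d control fits excluded",
                    n_failed)
    if control_pcts:
        prop_ge = float(np.mean([c >= cand_fit.pct_genetic_variance
                                 for c in control_pcts]))
    else:
        prop_ge = float("nan")
    return cand_fit.pct_genetic_variance, control_pcts, prop_ge
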