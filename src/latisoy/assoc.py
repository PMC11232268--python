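"""Association machinery: mixed-model GWAS, rrBLUP genomic selection with
cross-validation, and latent-factor genotype-environment association.

The GWAS follows the EMMAX approximation: variance components are estimated
once by REML on the null model (kinship + fixed covariates), then each SNP
is tested by generalized least squares with those components held fixed.
Genomic selection is ridge-regression BLUP (y = Xb + Zu + e with i.i.d.
marker effects u); its REML uses the eigendecomposition of ZZ'.  The
genotype-environment association is a ridge / least-squares formulation of
the latent factor mixed model: K latent factors estimated from the
genotype matrix after removing the environmental projection, per-SNP
z-scores combined across re-estimation runs by the median, recalibrated by
the genomic inflation factor, and thresholded on Benjamini-Hochberg
q-values.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import DomainError, GenotypeMatrix

log = logging.getLogger(__name__)

CHI2_MEDIAN_1DF = 0.4549364231195724  # median of chi-square with 1 df


def _as_dosage_array(gm) -> np.ndarray:
    """Accept a GenotypeMatrix or array; return float matrix (nan = missing)."""
    if isinstance(gm, GenotypeMatrix):
        x = gm.dosages.astype(float)
        x[x < 0] = np.nan
        return x
    return np.asarray(gm, dtype=float)


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

@dataclass
class KinshipMatrix:
    values: np.ndarray
    method: str = "simple_matching"
    bent: bool = False


def kinship_simple_matching(gm) -> KinshipMatrix:
    """Mean simple-matching similarity of dosage codes across SNPs.

    Per SNP the coefficient between accessions i and j is
    ``1 - |d_i - d_j| / 2``; the matrix is averaged over SNPs, has unit
    diagonal, and is bent to positive semi-definite (eigenvalue clipping)
    if numerically indefinite.
    """
    x = _as_dosage_array(gm)
    if np.isnan(x).any():
        raise DomainError("kinship requires an imputed (complete) matrix")
    n, p = x.shape
    # mean |d_i - d_j| via expansion over the three dosage codes
    K = np.zeros((n, n))
    for a in (0, 1, 2):
        ia = (x == a).astype(float)
        for b in (0, 1, 2):
            ib = (x == b).astype(float)
            K += (1.0 - abs(a - b) / 2.0) * (ia @ ib.T)
    K /= p
    bent = False
    w = np.linalg.eigvalsh(K)
    if w[0] < -1e-8:
        wv, U = np.linalg.eigh(K)
        K = (U * np.clip(wv, 0, None)) @ U.T
        bent = True
        log.info("kinship bent to PSD (min eigenvalue %.3g)", w[0])
    return KinshipMatrix(K, "simple_matching", bent)


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    if n_tests < 1:
        raise DomainError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# EMMAX-style mixed-model GWAS
# ---------------------------------------------------------------------------

def genotype_pcs(gm, n_pcs: int = 5) -> np.ndarray:
    """Top principal components of the centred dosage matrix (accessions)."""
    x = _as_dosage_array(gm)
    col_mean = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), col_mean, x) - col_mean
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    return u[:, :n_pcs] * s[:n_pcs]


def _reml_delta(y: np.ndarray, X: np.ndarray, eigvals: np.ndarray,
                U: np.ndarray):
    """REML estimate of delta = sigma_e^2 / sigma_g^2 on the rotated model.

    ``eigvals, U`` come from the covariance structure's eigendecomposition;
    the profiled restricted likelihood is optimized over log10(delta).
    """
    n, q = X.shape
    ys = U.T @ y
    Xs = U.T @ X

    def neg_restricted_ll(log_delta: float) -> float:
        delta = 10.0 ** log_delta
        w = eigvals + delta
        Xw = Xs / w[:, None]
        XtWX = Xs.T @ Xw
        beta = np.linalg.solve(XtWX, Xw.T @ ys)
        r = ys - Xs @ beta
        rss = float(r @ (r / w))
        sign, logdet_xwx = np.linalg.slogdet(XtWX)
        _, logdet_xx = np.linalg.slogdet(X.T @ X)
        ll = -0.5 * ((n - q) * math.log(2 * math.pi * rss / (n - q))
                     + (n - q) + np.log(w).sum() + logdet_xwx - logdet_xx)
        return -ll

    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(-6.0, 6.0),
                                   method="bounded",
                                   options={"xatol": 1e-6})
    return 10.0 ** res.x


@dataclass
class GWASResult:
    table: pd.DataFrame          # snp, beta, se, p
    threshold: float
    delta: float                 # sigma_e^2 / sigma_g^2 from the null model

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["p"] < self.threshold]


def mlm_gwas(gm, pheno, K: KinshipMatrix = None, n_pcs: int = 5,
             alpha: float = 0.05) -> GWASResult:
    """Single-variance-component mixed-model association scan.

    Spectral decomposition of the kinship once; REML of
    ``delta = sigma_e^2/sigma_g^2`` on the null model (intercept + PCs);
    per-SNP generalized least squares with the components fixed (the EMMAX
    approximation); two-sided Wald p-values.  The significance threshold is
    Bonferroni ``alpha / n_SNPs``.
    """
    X_geno = _as_dosage_array(gm)
    col_mean = np.nanmean(X_geno, axis=0)
    X_geno = np.where(np.isnan(X_geno), col_mean, X_geno)
    y = np.asarray(pheno, dtype=float)
    n, p = X_geno.shape
    if len(y) != n:
        raise DomainError("phenotype length != accession count")
    if n < 30:
        raise DomainError("mlm_gwas requires >= 30 phenotyped accessions")
    fixed = [np.ones((n, 1))]
    if n_pcs > 0:
        fixed.append(genotype_pcs(X_geno, n_pcs))
    X0 = np.hstack(fixed)
    if np.linalg.matrix_rank(X0) < X0.shape[1]:
        raise DomainError("singular fixed-effect design (collinear PCs or "
                          "intercept)")
    Kmat = K.values if isinstance(K, KinshipMatrix) else \
        (np.eye(n) if K is None else np.asarray(K))
    eigvals, U = np.linalg.eigh(Kmat)
    eigvals = np.clip(eigvals, 0, None)
    delta = _reml_delta(y, X0, eigvals, U)
    w = eigvals + delta
    sw = np.sqrt(w)
    yt = (U.T @ y) / sw
    X0t = (U.T @ X0) / sw[:, None]
    Gt = (U.T @ X_geno) / sw[:, None]
    # residualize on the fixed effects once
    Q, _ = np.linalg.qr(X0t)
    yr = yt - Q @ (Q.T @ yt)
    Gr = Gt - Q @ (Q.T @ Gt)
    gg = (Gr ** 2).sum(axis=0)
    gg_safe = np.where(gg > 0, gg, np.nan)
    beta = (Gr.T @ yr) / gg_safe
    df = n - X0.shape[1] - 1
    rss = (yr @ yr) - beta ** 2 * gg_safe
    sigma2 = rss / df
    se = np.sqrt(sigma2 / gg_safe)
    tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    snp_ids = (list(gm.variants["id"]) if isinstance(gm, GenotypeMatrix)
               else [f"snp{i}" for i in range(p)])
    table = pd.DataFrame({"snp": snp_ids, "beta": beta, "se": se,
                          "p": pvals})
    return GWASResult(table, bonferroni_threshold(p, alpha), delta)


# ---------------------------------------------------------------------------
# rrBLUP
# ---------------------------------------------------------------------------

@dataclass
class RRBLUPFit:
    predictions: np.ndarray
    sigma_u2: float
    sigma_e2: float
    lambda_: float
    beta: np.ndarray
    marker_effects: np.ndarray


def rrblup_fit_predict(train_gm, train_y, test_gm,
                       fixed_train: np.ndarray = None,
                       fixed_test: np.ndarray = None,
                       lambda_: float = None,
                       center: bool = True) -> RRBLUPFit:
    """Ridge-regression BLUP: fit on training accessions, predict test ones.

    REML estimates of the marker-effect and residual variances via the
    eigendecomposition of ZZ' (unless ``lambda_`` is fixed); BLUP marker
    effects ``u = Z'(ZZ' + lambda I)^{-1} (y - X b)``; predictions are
    ``X_test b + Z_test u``, identical to kernel ridge regression at
    ``lambda = sigma_e^2 / sigma_u^2``.
    """
    Z = _as_dosage_array(train_gm)
    Zt = _as_dosage_array(test_gm)
    y = np.asarray(train_y, dtype=float)
    n, p = Z.shape
    if np.isnan(Z).any() or np.isnan(Zt).any():
        raise DomainError("rrBLUP requires imputed matrices")
    if center:
        mu = Z.mean(axis=0)
        Z = Z - mu
        Zt = Zt - mu
    if not np.any(Z.std(axis=0) > 0):
        raise DomainError("zero marker variance in training set")
    X = fixed_train if fixed_train is not None else np.ones((n, 1))
    Xt = fixed_test if fixed_test is not None else np.ones((Zt.shape[0], 1))
    G = Z @ Z.T
    eigvals, U = np.linalg.eigh(G)
    eigvals = np.clip(eigvals, 0, None)
    if lambda_ is None:
        lambda_ = _reml_delta(y, X, eigvals, U)
    w = eigvals + lambda_
    # GLS fixed effects under V = ZZ' + lambda I (up to sigma_u^2)
    ys = U.T @ y
    Xs = U.T @ X
    Xw = Xs / w[:, None]
    beta = np.linalg.solve(Xs.T @ Xw, Xw.T @ ys)
    resid = y - X @ beta
    Vinv_r = U @ ((U.T @ resid) / w)
    u_hat = Z.T @ Vinv_r
    q = X.shape[1]
    rss = float((U.T @ resid) @ ((U.T @ resid) / w))
    sigma_u2 = rss / (n - q)
    sigma_e2 = lambda_ * sigma_u2
    preds = Xt @ beta + Zt @ u_hat
    return RRBLUPFit(preds, sigma_u2, sigma_e2, float(lambda_), beta, u_hat)


@dataclass
class GSResult:
    scenario: str
    fold_r: list
    trait: str = "BBD"
    env: str = ""

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.fold_r))


def _fold_assignments(n: int, k: int, reps: int, seed: int) -> np.ndarray:
    """(reps, n) fold indices; folds balanced to within one accession."""
    rng = np.random.default_rng(seed)
    out = np.empty((reps, n), dtype=int)
    base = np.arange(n) % k
    for r in range(reps):
        out[r] = rng.permutation(base)
    return out


def cross_validate_gs(gm, pheno, scenarios: Mapping[str, Sequence[int]],
                      k: int = 5, reps: int = 20, seed: int = 0,
                      env: str = "") -> list:
    """20x fivefold (by default) CV accuracy per SNP scenario.

    One fold partition per repetition, shared across all scenarios; the
    per-fold statistic is the Pearson correlation between observed and
    predicted phenotypes; folds with zero phenotype variance are skipped
    (logged).  Returns one :class:`GSResult` per scenario.
    """
    if not scenarios:
        raise DomainError("scenarios must be nonempty")
    X = _as_dosage_array(gm)
    y = np.asarray(pheno, dtype=float)
    n = X.shape[0]
    for name, idx in scenarios.items():
        if len(idx) == 0:
            raise DomainError(f"scenario {name!r} has an empty SNP subset")
    folds = _fold_assignments(n, k, reps, seed)
    results = []
    for name, idx in scenarios.items():
        sub = X[:, np.asarray(idx)]
        rs = []
        for r in range(reps):
            for fold in range(k):
                test = folds[r] == fold
                train = ~test
                if np.std(y[train]) == 0 or np.std(y[test]) == 0:
                    log.warning("cv fold %d/%d skipped: zero phenotype "
                                "variance", r, fold)
                    continue
                fit = rrblup_fit_predict(sub[train], y[train], sub[test])
                rs.append(float(np.corrcoef(y[test], fit.predictions)[0, 1]))
        results.append(GSResult(name, rs, env=env))
    return results


# ---------------------------------------------------------------------------
# Latent-factor genotype-environment association
# ---------------------------------------------------------------------------

@dataclass
class GEAResult:
    table: pd.DataFrame   # snp, z, p_raw, p_recal, q
    lambda_gc: float
    K: int

    @property
    def outliers(self) -> pd.DataFrame:
        return self.table[self.table["q"] < 0.05]


def _env_factors(X: np.ndarray, env: np.ndarray, K: int,
                 rng: np.random.Generator, subsample: float = 0.8):
    """Latent factors from a SNP subsample after removing the env projection."""
    p = X.shape[1]
    cols = rng.choice(p, size=max(2, int(subsample * p)), replace=False)
    sub = X[:, cols]
    e = (env - env.mean())
    denom = float(e @ e)
    proj = np.outer(e, (e @ sub) / denom) if denom > 0 else 0.0
    resid = sub - proj
    u, s, _ = np.linalg.svd(resid - resid.mean(axis=0), full_matrices=False)
    return u[:, :K] * s[:K]


def lfmm_gea(gm, env, K: int, reps: int = 10, seed: int = 0) -> GEAResult:
    """Ridge-formulation latent factor GEA with genomic-control recalibration.

    Per run, K latent factors are estimated from a random SNP subsample
    (after projecting out the environmental variable); each SNP's genotype
    is regressed on the environment conditional on the factors, giving a
    z-score.  Z-scores are combined across runs by the median, the genomic
    inflation factor ``lambda = median(z^2) / 0.4549`` recalibrates the
    p-values against chi-square(1), and Benjamini-Hochberg q-values flag
    outliers at q < 0.05.
    """
    X = _as_dosage_array(gm)
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_mean, X)
    env = np.asarray(env, dtype=float)
    n, p = X.shape
    if len(env) != n:
        raise DomainError("env length != accession count")
    if K >= min(n, p):
        raise DomainError(f"K={K} must be < min(n, p) = {min(n, p)}")
    rng = np.random.default_rng(seed)
    Xc = X - X.mean(axis=0)
    zs = np.empty((reps, p))
    for r in range(reps):
        if K > 0:
            F = _env_factors(Xc, env, K, rng)
            design = np.column_stack([np.ones(n), env, F])
        else:
            design = np.column_stack([np.ones(n), env])
        Q, R = np.linalg.qr(design)
        # z for the env coefficient of each SNP's regression on the design
        coef = np.linalg.solve(R, Q.T @ Xc)
        resid = Xc - design @ coef
        df = n - design.shape[1]
        sigma2 = (resid ** 2).sum(axis=0) / df
        XtX_inv_env = np.linalg.inv(R.T @ R)[1, 1]
        se = np.sqrt(sigma2 * XtX_inv_env)
        with np.errstate(invalid="ignore", divide="ignore"):
            zs[r] = np.where(se > 0, coef[1] / se, 0.0)
    z = np.median(zs, axis=0)
    lam = float(np.median(z ** 2) / CHI2_MEDIAN_1DF)
    if lam <= 0:
        lam = 1.0
    p_raw = stats.chi2.sf(z ** 2, df=1)
    p_recal = stats.chi2.sf(z ** 2 / lam, df=1)
    q = bh_qvalues(np.clip(p_recal, 1e-300, 1.0))
    snp_ids = (list(gm.variants["id"]) if isinstance(gm, GenotypeMatrix)
               else [f"snp{i}" for i in range(p)])
    table = pd.DataFrame({"snp": snp_ids, "z": z, "p_raw": p_raw,
                          "p_recal": p_recal, "q": q})
    return GEAResult(table, lam, K)


def select_k(gm, k_grid: Sequence[int], mask_frac: float = 0.05,
             seed: int = 0) -> int:
    """Rank selection by masked-imputation cross-validation.

    Masks ``mask_frac`` of entries, imputes with a rank-K truncated-SVD
    approximation of the mean-filled matrix for each candidate K, and
    returns the K minimizing held-out squared error (the cross-entropy
    analog of admixture rank selection).  Deterministic given the seed.
    """
    if len(k_grid) == 0:
        raise DomainError("k_grid must be nonempty")
    X = _as_dosage_array(gm)
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_mean, X)
    rng = np.random.default_rng(seed)
    mask = rng.random(X.shape) < mask_frac
    Xm = X.copy()
    Xm[mask] = np.nan
    fill = np.nanmean(Xm, axis=0)
    fill = np.where(np.isnan(fill), np.nanmean(X), fill)
    Xf = np.where(np.isnan(Xm), fill, Xm)
    mu = Xf.mean(axis=0)
    u, s, vt = np.linalg.svd(Xf - mu, full_matrices=False)
    best = None
    for K in k_grid:
        if K >= len(s):
            continue
        approx = (u[:, :K] * s[:K]) @ vt[:K] + mu
        err = float(((approx - X)[mask] ** 2).mean())
        if best is None or err < best[1]:
            best = (K, err)
    if best is None:
        raise DomainError("no valid K in grid")
    return best[0]


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise DomainError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
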