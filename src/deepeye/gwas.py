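"""Univariate linear-mixed-model genome-wide association.

Model: y = W a + x b + u + e with u ~ N(0, vr * tau^-1 K) and
e ~ N(0, tau^-1 I), W an intercept.  The kinship K is eigendecomposed
once and all vectors rotated into its eigenbasis, after which each value
of the variance ratio vr gives a weighted least-squares problem with
closed-form profile likelihood; vr is maximized per model over
log10(vr) in [-5, 5] by a coarse grid plus local grid refinement,
vectorized across SNPs.  P-values come from the likelihood-ratio test of
b = 0 against a single null fit per dataset (the GEMMA-style LRT
construction), referred to chi-square with 1 df.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KinshipMatrix",
    "maf",
    "maf_filter",
    "centered_kinship",
    "lmm_scan",
    "bonferroni_threshold",
    "select_top_fraction",
    "genomic_control_lambda",
]


@dataclass
class KinshipMatrix:
    """Centered relatedness matrix with its eigendecomposition cached."""

    K: np.ndarray
    eigenvalues: np.ndarray | None = None
    eigenvectors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        if self.K.ndim != 2 or self.K.shape[0] != self.K.shape[1]:
            raise ValueError("K must be square")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("K must be symmetric")
        if self.eigenvalues is None:
            s, u = np.linalg.eigh(self.K)
            if s.min() < -1e-10 * max(s.max(), 1.0):
                raise ValueError("K is not positive semidefinite")
            self.eigenvalues = np.maximum(s, 0.0)
            self.eigenvectors = u


def maf(dosage: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per site from dosages (NaN = missing)."""
    d = np.asarray(dosage, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f = np.nanmean(d, axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


def maf_filter(dosage: np.ndarray, maf_min: float = 0.05) -> np.ndarray:
    """Indices of sites with MAF >= maf_min (strict '< maf_min' exclusion)."""
    return np.flatnonzero(maf(dosage) >= maf_min)


def centered_kinship(dosage: np.ndarray) -> KinshipMatrix:
    """Centered relatedness matrix K = Xc Xc^T / p.

    Columns (SNPs) are mean-centered; missing dosages are mean-imputed
    per site beforehand (consistent with upstream imputation of the
    callset)."""
    X = np.asarray(dosage, dtype=float).copy()
    if X.shape[1] == 0:
        raise ValueError("no SNPs to build kinship from")
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    Xc = X - X.mean(axis=0)
    K = Xc @ Xc.T / X.shape[1]
    return KinshipMatrix(K)


def _grid_loglik(
    delta: float, S: np.ndarray, yr: np.ndarray, wr: np.ndarray, Xr: np.ndarray | None
):
    """Profile ML log-likelihood at a single variance ratio, all SNPs at once.

    ``wr`` is the rotated intercept column (U' 1).  Returns (loglik per
    SNP, beta per SNP, se per SNP) for the design [intercept, snp]; with
    Xr None, the intercept-only null value.
    """
    n = yr.size
    w = 1.0 / (delta * S + 1.0)
    logdet = np.sum(np.log(delta * S + 1.0))
    sw = w @ (wr * wr)
    swy = w @ (wr * yr)
    swyy = w @ (yr * yr)
    const = 0.5 * n * np.log(n / (2 * np.pi)) - 0.5 * n
    if Xr is None:
        rss = swyy - swy * swy / sw
        ll = const - 0.5 * logdet - 0.5 * n * np.log(rss)
        return ll, None, None
    # Xr: (n, p) rotated genotype columns.  The SNP's contribution is the
    # regression gain over the intercept-only residual, so the LRT against
    # the null at the same variance ratio is non-negative by construction.
    swx = (w * wr) @ Xr
    swxx = w @ (Xr * Xr)
    swxy = (w * yr) @ Xr
    ryy = swyy - swy * swy / sw  # intercept-only weighted RSS
    rxx = swxx - swx * swx / sw
    rxy = swxy - swx * swy / sw
    rxx = np.where(rxx > 1e-12, rxx, np.nan)
    gain = rxy * rxy / rxx
    frac = np.clip(gain / ryy, 0.0, 1.0 - 1e-15)
    ll = const - 0.5 * logdet - 0.5 * n * (np.log(ryy) + np.log1p(-frac))
    beta = rxy / rxx
    sigma2 = ryy * (1.0 - frac) / n
    se = np.sqrt(sigma2 / rxx)
    return ll, beta, se


def _fit_null(S: np.ndarray, yr: np.ndarray, wr: np.ndarray, log10_bounds=(-5.0, 5.0), grid_n=50):
    grid = np.logspace(log10_bounds[0], log10_bounds[1], grid_n)
    lls = np.array([_grid_loglik(d, S, yr, wr, None)[0] for d in grid])
    b = int(np.argmax(lls))
    lo = np.log10(grid[max(b - 1, 0)])
    hi = np.log10(grid[min(b + 1, grid_n - 1)])
    for _ in range(30):
        mids = np.linspace(lo, hi, 9)
        vals = np.array([_grid_loglik(10.0**m, S, yr, wr, None)[0] for m in mids])
        k = int(np.argmax(vals))
        lo2 = mids[max(k - 1, 0)]
        hi2 = mids[min(k + 1, 8)]
        lo, hi = lo2, hi2
        if hi - lo < 1e-8:
            break
    dstar = 10.0 ** ((lo + hi) / 2)
    ll = _grid_loglik(dstar, S, yr, wr, None)[0]
    return float(ll), float(dstar)


def lmm_scan(
    trait: np.ndarray,
    dosage: np.ndarray,
    kinship: KinshipMatrix,
    chrom: np.ndarray | None = None,
    pos: np.ndarray | None = None,
    maf_min: float = 0.05,
    log10_bounds: tuple[float, float] = (-5.0, 5.0),
    grid_n: int = 50,
    refine_rounds: int = 3,
) -> pd.DataFrame:
    """Per-SNP LMM likelihood-ratio scan.

    Returns a DataFrame sorted by genomic coordinate with columns chrom,
    pos, maf, beta, se, vr (variance-ratio MLE), lrt, p_lrt.  Constant
    SNPs after filtering are skipped (NaN rows).
    """
    y = np.asarray(trait, dtype=float)
    if np.isnan(y).any():
        raise ValueError("trait must be complete for all samples")
    X = np.asarray(dosage, dtype=float).copy()
    n, p = X.shape
    if y.size != n:
        raise ValueError("trait length must match sample count")
    col_mean = np.nanmean(X, axis=0)
    nr, nc = np.nonzero(np.isnan(X))
    X[nr, nc] = col_mean[nc]

    keep = maf_filter(X, maf_min)
    site_maf = maf(X)
    constant = X.std(axis=0) == 0
    test = np.array([i for i in keep if not constant[i]], dtype=int)

    S = kinship.eigenvalues
    U = kinship.eigenvectors
    yr = U.T @ y
    wr = U.T @ np.ones(n)
    Xr = U.T @ X[:, test]

    ll0, delta0 = _fit_null(S, yr, wr, log10_bounds, grid_n)

    grid = np.logspace(log10_bounds[0], log10_bounds[1], grid_n)
    # include the null's optimum so the alternative always nests the null
    grid = np.append(grid, delta0)
    nt = test.size
    best_ll = np.full(nt, -np.inf)
    best_beta = np.zeros(nt)
    best_se = np.zeros(nt)
    best_log10 = np.zeros(nt)
    for d in grid:
        ll, beta, se = _grid_loglik(d, S, yr, wr, Xr)
        upd = ll > best_ll
        best_ll[upd] = ll[upd]
        best_beta[upd] = beta[upd]
        best_se[upd] = se[upd]
        best_log10[upd] = np.log10(d)

    # local per-SNP grid refinement, vectorized via per-SNP weight matrices
    step = (log10_bounds[1] - log10_bounds[0]) / (grid_n - 1)
    width = step
    for _ in range(refine_rounds):
        for off in np.linspace(-width, width, 9):
            d = 10.0 ** np.clip(best_log10 + off, *log10_bounds)
            w = 1.0 / (d[:, None] * S[None, :] + 1.0)  # (p, n)
            logdet = np.log(d[:, None] * S[None, :] + 1.0).sum(axis=1)
            sw = w @ (wr * wr)
            swy = w @ (wr * yr)
            swyy = w @ (yr * yr)
            xt = Xr.T  # (p, n)
            swx = (w * xt) @ wr
            swxx = (w * xt * xt).sum(axis=1)
            swxy = (w * xt) @ yr
            ryy = swyy - swy * swy / sw
            rxx = swxx - swx * swx / sw
            rxy = swxy - swx * swy / sw
            rxx = np.where(rxx > 1e-12, rxx, np.nan)
            gain = rxy * rxy / rxx
            frac = np.clip(gain / ryy, 0.0, 1.0 - 1e-15)
            cn = 0.5 * n * np.log(n / (2 * np.pi)) - 0.5 * n
            ll = cn - 0.5 * logdet - 0.5 * n * (np.log(ryy) + np.log1p(-frac))
            beta = rxy / rxx
            se = np.sqrt(ryy * (1.0 - frac) / n / rxx)
            upd = ll > best_ll
            best_ll[upd] = ll[upd]
            best_beta[upd] = beta[upd]
            best_se[upd] = se[upd]
            best_log10[upd] = np.log10(d[upd])
        width /= 4.0

    lrt = 2.0 * (best_ll - ll0)
    if np.any(lrt < -1e-6):
        raise AssertionError("LRT statistic below -1e-6: alternative must nest the null")
    lrt = np.maximum(lrt, 0.0)
    p_lrt = stats.chi2.sf(lrt, df=1)

    chrom = np.asarray(chrom) if chrom is not None else np.repeat("chr1", p)
    pos = np.asarray(pos, dtype=np.int64) if pos is not None else np.arange(1, p + 1)
    out = pd.DataFrame(
        {
            "chrom": chrom[test],
            "pos": pos[test],
            "maf": site_maf[test],
            "beta": best_beta,
            "se": best_se,
            "vr": 10.0**best_log10,
            "lrt": lrt,
            "p_lrt": p_lrt,
            "site_index": test,
        }
    )
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def bonferroni_threshold(n_tests: int, fwer: float = 0.05) -> float:
    """Family-wise error threshold fwer / M."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return fwer / n_tests


def select_top_fraction(assoc: pd.DataFrame, q: float = 1e-4) -> tuple[pd.DataFrame, int]:
    """The k = floor(q * M) most significant associations.

    Ties at the boundary break by genomic order (chrom, pos ascending).
    Returns (outlier rows in genomic order, k)."""
    M = len(assoc)
    k = int(np.floor(q * M))
    if k == 0:
        warnings.warn(f"q * M = {q * M:.3g} < 1: empty outlier set")
        return assoc.iloc[0:0], 0
    ranked = assoc.sort_values(["p_lrt", "chrom", "pos"], kind="mergesort")
    sel = ranked.iloc[:k]
    return sel.sort_values(["chrom", "pos"], kind="mergesort"), k


def genomic_control_lambda(p_values: np.ndarray) -> float:
    """Genomic-inflation factor: median LRT chi-square over its null median."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, df=1))
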