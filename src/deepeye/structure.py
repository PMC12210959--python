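"""Genetic structure summaries for outlier-versus-genome-wide comparison:
sliding-window LD pruning, variance-standardized PCA, and the PC1-on-trait
regression.

The comparison at the heart of this module: if a trait is driven by a
minority of SNPs shared across non-sister species, the leading principal
component of those SNPs separates samples by trait much better than the
leading PC of genome-wide variation does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["PcaResult", "ld_prune", "pca", "pc1_trait_regression"]


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray


def _r2(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_prune(
    dosage: np.ndarray,
    window_snps: int = 50,
    step_snps: int = 10,
    r2_max: float = 0.1,
) -> np.ndarray:
    """Sliding-window LD pruning (plink --indep-pairwise style).

    Windows of ``window_snps`` SNPs advance by ``step_snps``.  Within a
    window, pairs of retained SNPs are scanned in index order; whenever a
    pair's squared dosage correlation exceeds ``r2_max`` the LATER SNP is
    removed, until no retained pair in the window violates the bound.
    Returns indices of retained SNPs (sites must be in genomic order).
    """
    X = np.asarray(dosage, dtype=float)
    m = X.shape[1]
    retained = np.ones(m, dtype=bool)
    start = 0
    while True:
        stop = min(start + window_snps, m)
        idx = [i for i in range(start, stop) if retained[i]]
        if len(idx) > 1:
            sub = X[:, idx]
            sd = sub.std(axis=0)
            ok = sd > 0
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(sub, rowvar=False)
            r2 = np.where(np.outer(ok, ok), r * r, 0.0)
            # removing the later SNP never re-creates an earlier violation,
            # so one lexicographic pass settles the window
            alive = np.ones(len(idx), dtype=bool)
            for a in range(len(idx)):
                if not alive[a]:
                    continue
                for b in range(a + 1, len(idx)):
                    if alive[b] and r2[a, b] > r2_max:
                        alive[b] = False
            for k, keep_it in enumerate(alive):
                if not keep_it:
                    retained[idx[k]] = False
        if stop >= m:
            break
        start += step_snps
    return np.flatnonzero(retained)


def pca(
    dosage: np.ndarray,
    ids: list[str],
    n_components: int = 10,
    standardize: bool = True,
    trait: pd.Series | None = None,
) -> PcaResult:
    """PCA of the sample x SNP dosage matrix.

    Columns are mean-centered and (by default) scaled by sqrt(2 f (1 - f))
    with f the allele frequency — the variance-standardized relationship
    convention of the usual GWAS tooling.  Missing dosages are mean-imputed
    per SNP; zero-variance SNPs are dropped with a warning.  PC1's sign is
    anchored to positive correlation with ``trait`` when given, else with
    the sample input order.
    """
    X = np.asarray(dosage, dtype=float).copy()
    col_mean = np.nanmean(X, axis=0)
    nr, nc = np.nonzero(np.isnan(X))
    X[nr, nc] = col_mean[nc]
    var_ok = X.std(axis=0) > 0
    if not var_ok.all():
        warnings.warn(f"dropping {int((~var_ok).sum())} zero-variance SNPs")
        X = X[:, var_ok]
        col_mean = col_mean[var_ok]
    if X.shape[1] == 0:
        raise ValueError("no variable SNPs for PCA")
    Z = X - X.mean(axis=0)
    if standardize:
        f = X.mean(axis=0) / 2.0
        Z = Z / np.sqrt(2.0 * f * (1.0 - f))
    n, m = Z.shape
    C = Z @ Z.T / m
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    k = min(n_components, n)
    scores = evecs[:, :k] * np.sqrt(evals[:k])

    anchor = (
        trait.reindex(ids).to_numpy(dtype=float)
        if trait is not None
        else np.arange(n, dtype=float)
    )
    for c in range(k):
        if np.std(scores[:, c]) > 0 and np.corrcoef(scores[:, c], anchor)[0, 1] < 0:
            scores[:, c] *= -1
            evecs[:, c] *= -1
    cols = [f"PC{i + 1}" for i in range(k)]
    total = evals.sum()
    return PcaResult(
        scores=pd.DataFrame(scores, index=ids, columns=cols),
        eigenvalues=evals[:k],
        variance_fraction=evals[:k] / total if total > 0 else evals[:k],
    )


def pc1_trait_regression(pca_result: PcaResult, trait: pd.Series) -> dict:
    """OLS of the trait on PC1; returns R^2, p and slope."""
    pc1 = pca_result.scores["PC1"]
    if pc1.std() == 0:
        raise ValueError("PC1 is constant")
    y = trait.reindex(pc1.index).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("trait missing for some samples")
    X = sm.add_constant(pc1.to_numpy())
    fit = sm.OLS(y, X).fit()
    return {
        "r2": float(fit.rsquared),
        "p": float(fit.pvalues[1]),
        "slope": float(fit.params[1]),
    }
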