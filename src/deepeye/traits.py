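"""Eye-size trait handling and phylogenetic signal.

Relative eye size is eye diameter divided by standard length (the field's
size correction for the association analysis); within-clade linear
regression residuals provide an alternative size adjustment for comparing
clades.  Phylogenetic signal is quantified by Pagel's lambda under a
Brownian-motion model: lambda multiplies the off-diagonal entries of the
shared-branch-length covariance matrix, and is estimated by maximum
likelihood with the mean and rate profiled out analytically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from skbio import TreeNode

__all__ = [
    "PhyloSignalResult",
    "relative_eye_size",
    "clade_residuals",
    "shared_branch_covariance",
    "pagel_lambda",
]


def relative_eye_size(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``relative_eye_size`` = eye_diameter / standard_length.

    Rows with a missing measurement get NaN and ``measurement_missing``
    True; they stay in the table but are excluded from downstream stats.
    A non-positive standard length (where present) is an error.
    """
    out = table.copy()
    eye = out["eye_diameter_cm"]
    sl = out["standard_length_cm"]
    if (sl.dropna() <= 0).any():
        bad = out.index[sl.notna() & (sl <= 0)].tolist()
        raise ValueError(f"non-positive standard length at rows {bad}")
    out["measurement_missing"] = eye.isna() | sl.isna()
    out["relative_eye_size"] = eye / sl
    return out


def clade_residuals(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Within-clade OLS of eye diameter on standard length.

    Adds ``residual_eye_size`` (observed - fitted, in measurement units).
    Clades with fewer than 3 complete rows get NaN residuals with a
    warning.  Returns the augmented table and the per-clade mean absolute
    residual.
    """
    out = table.copy()
    out["residual_eye_size"] = np.nan
    means = {}
    for clade, sub in out.groupby("clade"):
        ok = sub["eye_diameter_cm"].notna() & sub["standard_length_cm"].notna()
        sub = sub[ok]
        if len(sub) < 3:
            warnings.warn(f"clade '{clade}' has <3 complete samples; residuals skipped")
            continue
        x = sub["standard_length_cm"].to_numpy(dtype=float)
        y = sub["eye_diameter_cm"].to_numpy(dtype=float)
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        out.loc[sub.index, "residual_eye_size"] = resid
        means[clade] = float(np.abs(resid).mean())
    return out, pd.Series(means, name="mean_abs_residual")


def shared_branch_covariance(tree: TreeNode, tips: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix from a rooted tree.

    C[i, j] = summed branch length from the root to the most recent common
    ancestor of tips i and j; C[i, i] = root-to-tip distance.  Branch
    lengths must be non-negative (None on the root counts as 0).
    """
    tree = tree.copy()
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise ValueError("negative branch length in tree")
    tip_names = [t.name for t in tree.tips()]
    if tips is None:
        tips = tip_names
    index = {name: i for i, name in enumerate(tips)}
    if set(tip_names) != set(tips):
        raise ValueError("tip set of tree does not match requested tips")
    n = len(tips)
    C = np.zeros((n, n))

    def _fill(node, depth):
        depth = depth + node.length
        if node.is_tip():
            i = index[node.name]
            C[i, i] = depth
            return [i]
        below = [_fill(ch, depth) for ch in node.children]
        for a in range(len(below)):
            for b in range(a + 1, len(below)):
                for i in below[a]:
                    for j in below[b]:
                        C[i, j] = C[j, i] = depth
        return [i for grp in below for i in grp]

    _fill(tree, -tree.length)  # root's own length does not count
    return C, list(tips)


@dataclass
class PhyloSignalResult:
    """Maximum-likelihood Pagel's lambda fit."""

    lambda_hat: float
    sigma2_hat: float
    mu_hat: float
    loglik: float
    loglik_lambda0: float
    loglik_lambda1: float
    flat_likelihood: bool = False


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def _profile_loglik(
    C: np.ndarray, y: np.ndarray, lam: float, reml: bool = False
) -> tuple[float, float, float]:
    """Profiled Brownian log-likelihood at a given lambda.

    mu and sigma^2 have closed-form GLS solutions given lambda; returns
    (loglik, mu_hat, sigma2_hat).  With ``reml`` the restricted likelihood
    is used (sigma^2 over n - 1, plus the log|1'V^-1 1| term).  A tiny
    diagonal jitter is applied if the Cholesky factorization fails.
    """
    n = y.size
    V = _lambda_cov(C, lam)
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        warnings.warn("covariance not positive definite; adding diagonal jitter")
        V = V + np.eye(n) * (1e-10 * np.trace(C) / n)
        L = linalg.cholesky(V, lower=True)
    ones = np.ones(n)
    a = linalg.solve_triangular(L, y, lower=True)
    b = linalg.solve_triangular(L, ones, lower=True)
    mu = float(b @ a / (b @ b))
    r = a - mu * b
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    if reml:
        sigma2 = float(r @ r / (n - 1))
        sigma2 = max(sigma2, np.finfo(float).tiny)
        ll = -0.5 * (
            (n - 1) * np.log(2 * np.pi * sigma2)
            + logdet
            + np.log(b @ b)
            + (n - 1)
        )
    else:
        sigma2 = float(r @ r / n)
        sigma2 = max(sigma2, np.finfo(float).tiny)
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return ll, mu, sigma2


def pagel_lambda(
    tree: TreeNode,
    trait: pd.Series | dict | np.ndarray,
    tips: list[str] | None = None,
    grid_points: int = 101,
    reml: bool = False,
) -> PhyloSignalResult:
    """Maximum-likelihood estimate of Pagel's lambda on [0, 1].

    The trait is modeled as y ~ Normal(mu 1, sigma^2 C_lambda) with
    C_lambda the shared-branch covariance whose off-diagonal entries are
    multiplied by lambda.  Optimization is a grid over [0, 1] followed by
    golden-section refinement; mu and sigma^2 are profiled in closed form.

    ``trait`` maps tip names to values (Series/dict), or is an array in
    ``tips`` order.
    """
    C, order = shared_branch_covariance(tree, tips)
    if isinstance(trait, pd.Series):
        y = trait.reindex(order).to_numpy(dtype=float)
    elif isinstance(trait, dict):
        y = np.array([trait[t] for t in order], dtype=float)
    else:
        y = np.asarray(trait, dtype=float)
    if y.size != len(order) or np.isnan(y).any():
        raise ValueError("one trait value required per tip")
    if y.size < 4:
        raise ValueError("at least 4 tips required")
    if np.allclose(y, y[0]):
        warnings.warn("identical tip values: lambda is undefined")
        ll, mu, s2 = _profile_loglik(C, y, 0.0, reml)
        return PhyloSignalResult(0.0, s2, mu, ll, ll, ll, flat_likelihood=True)

    grid = np.linspace(0.0, 1.0, grid_points)
    lls = np.array([_profile_loglik(C, y, g, reml)[0] for g in grid])
    best = int(np.argmax(lls))

    # golden-section refinement in the bracket around the best grid point
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid_points - 1)]
    invphi = (np.sqrt(5.0) - 1) / 2
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = _profile_loglik(C, y, c, reml)[0]
    fd = _profile_loglik(C, y, d, reml)[0]
    for _ in range(60):
        if b - a < 1e-10:
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = _profile_loglik(C, y, c, reml)[0]
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = _profile_loglik(C, y, d, reml)[0]
    lam = float((a + b) / 2)
    ll, mu, s2 = _profile_loglik(C, y, lam, reml)
    cand = [(ll, lam, mu, s2)]
    for g in (0.0, 1.0, grid[best]):
        llg, mug, s2g = _profile_loglik(C, y, g, reml)
        cand.append((llg, float(g), mug, s2g))
    ll, lam, mu, s2 = max(cand, key=lambda t: t[0])
    ll0 = _profile_loglik(C, y, 0.0, reml)[0]
    ll1 = _profile_loglik(C, y, 1.0, reml)[0]
    flat = bool(np.ptp(lls) < 1e-10)
    if flat:
        warnings.warn("log-likelihood is flat in lambda (star-like tree)")
    return PhyloSignalResult(lam, s2, mu, ll, ll0, ll1, flat_likelihood=flat)
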