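"""Distance-based genetic relationships: allele-sharing distances,
neighbor-joining, windowed-bootstrap support, outgroup rooting, and the
genetic-distance-versus-trait-difference regression.

Distances are per-site allele differences on diploid dosages
(d_ij = mean over jointly non-missing sites of |g_i - g_j| / 2), so window
averages are on a common scale.  Bootstrap support resamples 100-kb windows
of the genome with replacement, weighting each window by its jointly
non-missing site counts, and records the fraction of replicate NJ trees
containing each internal bipartition of the full-data tree.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sstats
from skbio import TreeNode

__all__ = [
    "pairwise_distance",
    "neighbor_joining",
    "bipartitions",
    "window_bootstrap_support",
    "root_by_outgroup",
    "distance_trait_regression",
]


def _pair_sums(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum of |g_i - g_j|/2 and count of jointly non-missing sites, per pair."""
    n = dosage.shape[0]
    num = np.zeros((n, n))
    cnt = np.zeros((n, n))
    ok = ~np.isnan(dosage)
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            c = int(both.sum())
            s = np.abs(dosage[i, both] - dosage[j, both]).sum() / 2.0
            num[i, j] = num[j, i] = s
            cnt[i, j] = cnt[j, i] = c
    return num, cnt


def pairwise_distance(dosage: np.ndarray, ids: list[str]) -> pd.DataFrame:
    """Allele-sharing distance matrix from a samples x sites dosage matrix.

    Missing genotypes are NaN; each pair uses only its jointly non-missing
    sites.  A pair with none is an error.
    """
    dosage = np.asarray(dosage, dtype=float)
    if dosage.shape[0] < 2 or dosage.shape[1] < 1:
        raise ValueError("need >=2 samples and >=1 site")
    num, cnt = _pair_sums(dosage)
    off = ~np.eye(len(ids), dtype=bool)
    if np.any(cnt[off] == 0):
        i, j = np.argwhere((cnt == 0) & off)[0]
        raise ValueError(f"samples {ids[i]} and {ids[j]} share no non-missing site")
    with np.errstate(invalid="ignore"):
        d = num / np.where(cnt > 0, cnt, 1)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=ids, columns=ids)


def neighbor_joining(D: pd.DataFrame, clamp_negative: bool = True) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Exactly recovers additive distances.  Negative branch lengths are
    clamped to zero with the deficit moved to the sister edge (the raw
    length is kept on each node as ``raw_length``).  Ties in the
    Q-criterion break by (i, j) index order, so the result is
    deterministic.  Returns an unrooted tree represented with a trifurcate
    root (or the unique 3-taxon star).
    """
    ids = list(D.index)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = D.to_numpy(dtype=float).copy()
    nodes = [TreeNode(name=i) for i in ids]
    for nd in nodes:
        nd.raw_length = None
    active = list(range(n))

    def _set_len(node, length):
        node.raw_length = float(length)
        node.length = float(length)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        a, b = np.unravel_index(np.argmin(q), q.shape)  # first minimum in scan order
        if a > b:
            a, b = b, a
        i, j = active[a], active[b]
        vi = 0.5 * sub[a, b] + (r[a] - r[b]) / (2 * (m - 2))
        vj = sub[a, b] - vi
        parent = TreeNode()
        parent.raw_length = None
        _set_len(nodes[i], vi)
        _set_len(nodes[j], vj)
        if clamp_negative:
            if nodes[i].length < 0:
                nodes[j].length += nodes[i].length
                nodes[i].length = 0.0
            if nodes[j].length < 0:
                nodes[i].length += nodes[j].length
                nodes[j].length = 0.0
        parent.extend([nodes[i], nodes[j]])
        # distances from the new node to every other active node
        for c in range(m):
            k = active[c]
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = 0.5 * (sub[a, c] + sub[b, c] - sub[a, b])
        nodes[i] = parent
        active.remove(j)

    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    root = TreeNode()
    _set_len(nodes[i], 0.5 * (dij + dik - djk))
    _set_len(nodes[j], 0.5 * (dij + djk - dik))
    _set_len(nodes[k], 0.5 * (dik + djk - dij))
    if clamp_negative:
        for nd in (nodes[i], nodes[j], nodes[k]):
            if nd.length < 0:
                nd.length = 0.0
    root.extend([nodes[i], nodes[j], nodes[k]])
    return root


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Internal (non-trivial) bipartitions of an unrooted tree.

    Each split is normalized as the side NOT containing the
    lexicographically smallest tip name.
    """
    all_tips = frozenset(t.name for t in tree.tips())
    ref = min(all_tips)
    out: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        below = frozenset(t.name for t in node.tips())
        side = frozenset(all_tips - below) if ref in below else below
        if 1 < len(side) < len(all_tips) - 1:
            out.add(side)
    return out


def window_bootstrap_support(
    dosage: np.ndarray,
    ids: list[str],
    chrom: np.ndarray,
    pos: np.ndarray,
    window_bp: int = 100_000,
    replicates: int = 100,
    seed: int = 0,
) -> tuple[TreeNode, pd.DataFrame]:
    """NJ tree with bootstrap support from genomic-window resampling.

    Per-window pairwise difference sums and jointly non-missing counts are
    precomputed; each replicate draws windows with replacement and forms
    the count-weighted average distance matrix (so sparse windows do not
    dominate), then rebuilds the NJ tree.  Support of an internal edge of
    the full-data tree is the fraction of replicate trees containing its
    bipartition, stored on each internal node as ``support``.
    """
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=np.int64)
    keys = np.array([f"{c}:{p // window_bp}" for c, p in zip(chrom, pos)])
    nums, cnts = [], []
    dropped = 0
    for key in pd.unique(keys):
        cols = keys == key
        num, cnt = _pair_sums(np.asarray(dosage, dtype=float)[:, cols])
        off = ~np.eye(len(ids), dtype=bool)
        if cnt[off].sum() == 0:
            dropped += 1
            warnings.warn(f"window {key} has no pairwise-complete data; dropped")
            continue
        nums.append(num)
        cnts.append(cnt)
    if len(nums) < 2:
        raise ValueError("need at least 2 non-empty windows")
    nums_a = np.stack(nums)
    cnts_a = np.stack(cnts)

    def _dist(widx):
        num = nums_a[widx].sum(axis=0)
        cnt = cnts_a[widx].sum(axis=0)
        off = ~np.eye(len(ids), dtype=bool)
        if np.any(cnt[off] == 0):
            return None
        d = num / np.where(cnt > 0, cnt, 1)
        np.fill_diagonal(d, 0.0)
        return pd.DataFrame(d, index=ids, columns=ids)

    full = _dist(np.arange(len(nums)))
    if full is None:
        raise ValueError("a sample pair has no jointly non-missing data overall")
    tree = neighbor_joining(full)

    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {bp: 0 for bp in bipartitions(tree)}
    used = 0
    for _ in range(replicates):
        widx = rng.integers(0, len(nums), size=len(nums))
        drep = _dist(widx)
        if drep is None:
            continue
        used += 1
        reps = bipartitions(neighbor_joining(drep))
        for bp in counts:
            if bp in reps:
                counts[bp] += 1

    all_tips = frozenset(ids)
    ref = min(all_tips)
    rows = []
    for node in tree.non_tips(include_self=False):
        below = frozenset(t.name for t in node.tips())
        side = frozenset(all_tips - below) if ref in below else below
        if side in counts and used > 0:
            node.support = counts[side] / used
            rows.append({"bipartition": ";".join(sorted(side)), "support": node.support})
        else:
            node.support = None
    return tree, pd.DataFrame(rows)


def root_by_outgroup(tree: TreeNode, outgroup: str) -> TreeNode:
    """Root the tree on the outgroup's pendant edge (at its midpoint)."""
    try:
        tip = tree.find(outgroup)
    except Exception as exc:
        raise KeyError(f"outgroup leaf '{outgroup}' not in tree") from exc
    if not tip.is_tip():
        raise KeyError(f"'{outgroup}' is not a leaf")
    return tree.root_at(tip, above=True, branch_attrs=[])


def distance_trait_regression(D: pd.DataFrame, trait: pd.Series) -> dict:
    """OLS of pairwise absolute trait differences on genetic distances.

    All unordered sample pairs enter the regression; the nominal p-value
    ignores the non-independence of pairs (reported as-is, a caveat of this
    kind of Mantel-style summary).
    """
    ids = list(D.index)
    t = trait.reindex(ids)
    if t.isna().any():
        raise ValueError("trait missing for some samples in the distance matrix")
    iu = np.triu_indices(len(ids), k=1)
    x = D.to_numpy(dtype=float)[iu]
    tv = t.to_numpy(dtype=float)
    y = np.abs(tv[:, None] - tv[None, :])[iu]
    if np.allclose(y, y[0]):
        warnings.warn("constant trait differences; R^2 = 0")
        return {"r2": 0.0, "p": 1.0, "slope": 0.0, "n_pairs": x.size}
    res = sstats.linregress(x, y)
    return {
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
        "slope": float(res.slope),
        "n_pairs": int(x.size),
    }
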