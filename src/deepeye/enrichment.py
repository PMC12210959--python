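"""Functional-annotation enrichment among association outliers and
derived-allele segregation tests.

The enrichment test is a MAF-matched permutation: random SNP sets drawn
from the genome-wide callset, matched to the outlier set's minor-allele
frequency histogram in non-overlapping bins, give the null distribution of
per-effect counts.  The empirical P is the fraction of draws whose count
STRICTLY exceeds the observed one (ties favor non-significance), reported
as < 1/n_perm when no draw exceeds it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "SegregationResult",
    "EFFECT_LABELS",
    "maf_bins",
    "draw_matched_set",
    "maf_matched_permutation",
    "map_outliers_to_genes",
    "derived_af_by_species",
    "segregation_test",
]

#: the annotation-effect vocabulary tested for overrepresentation
EFFECT_LABELS = (
    "3_prime_UTR_variant",
    "downstream_gene_variant",
    "upstream_gene_variant",
    "intergenic_region",
    "intron_variant",
    "synonymous_variant",
    "missense_variant",
    "splice_region_variant&intron_variant",
)


@dataclass
class EnrichmentResult:
    """Per-effect observed count, permutation null, fold ratio and empirical P."""

    table: pd.DataFrame  # effect-indexed: observed, null_mean, ratio, p_empirical, p_string
    null_counts: pd.DataFrame  # n_perm x effects
    n_perm: int = 0
    bin_width: float = 0.05


def maf_bins(maf_values: np.ndarray, bin_width: float = 0.05) -> np.ndarray:
    """Bin index per SNP for MAF in (0, 0.5]: bin b covers (b*w, (b+1)*w]."""
    maf_values = np.asarray(maf_values, dtype=float)
    if np.any((maf_values <= 0) | (maf_values > 0.5)):
        raise ValueError("MAF values must lie in (0, 0.5]")
    return np.maximum(np.ceil(maf_values / bin_width).astype(int) - 1, 0)


def _effect_sets(effects) -> list[set[str]]:
    out = []
    for e in effects:
        if isinstance(e, str):
            out.append({x for x in e.split(";") if x})
        else:
            out.append(set(e))
    return out


def draw_matched_set(
    control_bins: np.ndarray, bin_counts: dict[int, int], rng: np.random.Generator
) -> np.ndarray:
    """One random control-SNP index set matching the given per-bin counts
    (sampling without replacement within each bin)."""
    picks = []
    for b, k in bin_counts.items():
        pool = np.flatnonzero(control_bins == b)
        if pool.size < k:
            raise ValueError(f"MAF bin {b} has {pool.size} control SNPs, needs {k}")
        picks.append(rng.choice(pool, size=k, replace=False))
    return np.concatenate(picks) if picks else np.array([], dtype=int)


def maf_matched_permutation(
    test: pd.DataFrame,
    control: pd.DataFrame,
    bin_width: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    labels: tuple[str, ...] = EFFECT_LABELS,
    block: int = 100,
    with_replacement: bool = False,
    add_one_smoothing: bool = False,
) -> EnrichmentResult:
    """MAF-matched permutation test of annotation-effect overrepresentation.

    ``test`` and ``control`` need columns ``maf`` and ``effects``
    (semicolon-joined labels or sets); the control set is the full callset
    and may contain the test SNPs.  Each permutation draws, within each MAF
    bin, as many control SNPs (without replacement) as the test set holds
    there, and counts SNPs per effect (a SNP counts once per label it
    carries).  Fold ratio = observed / mean(null count).

    ``with_replacement`` switches to within-bin sampling with replacement;
    ``add_one_smoothing`` reports (exceedances + 1) / (n_perm + 1) instead
    of the strictly-greater proportion.
    """
    rng = np.random.default_rng(seed)
    t_bins = maf_bins(test["maf"].to_numpy(), bin_width)
    c_bins = maf_bins(control["maf"].to_numpy(), bin_width)
    bin_counts = pd.Series(t_bins).value_counts().to_dict()
    for b, k in bin_counts.items():
        avail = int((c_bins == b).sum())
        if avail < k:
            raise ValueError(f"MAF bin {b} underpopulated: {avail} control SNPs for {k} test SNPs")

    lab_index = {l: i for i, l in enumerate(labels)}
    t_sets = _effect_sets(test["effects"])
    observed = np.zeros(len(labels), dtype=int)
    for s in t_sets:
        for l in s:
            if l in lab_index:
                observed[lab_index[l]] += 1

    c_sets = _effect_sets(control["effects"])
    L = np.zeros((len(control), len(labels)), dtype=np.int8)
    for i, s in enumerate(c_sets):
        for l in s:
            if l in lab_index:
                L[i, lab_index[l]] = 1

    bin_pools = {b: np.flatnonzero(c_bins == b) for b in bin_counts}
    null = np.zeros((n_perm, len(labels)), dtype=np.int64)
    done = 0
    while done < n_perm:
        nb = min(block, n_perm - done)
        for b, k in bin_counts.items():
            pool = bin_pools[b]
            if with_replacement:
                sel = rng.integers(0, pool.size, size=(nb, k))
            elif k < pool.size:
                keys = rng.random((nb, pool.size))
                sel = np.argpartition(keys, k - 1, axis=1)[:, :k]
            else:
                sel = np.tile(np.arange(pool.size), (nb, 1))
            null[done : done + nb] += L[pool[sel]].sum(axis=1)
        done += nb

    exceed = (null > observed[None, :]).sum(axis=0)
    if add_one_smoothing:
        p_emp = (exceed + 1) / (n_perm + 1)
    else:
        p_emp = exceed / n_perm
    null_mean = null.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(null_mean > 0, observed / null_mean, np.nan)
    p_string = [f"< {1 / n_perm:g}" if e == 0 else f"{e / n_perm:g}" for e in exceed]
    table = pd.DataFrame(
        {
            "observed": observed,
            "null_mean": null_mean,
            "ratio": ratio,
            "p_empirical": p_emp,
            "p_string": p_string,
        },
        index=list(labels),
    )
    return EnrichmentResult(
        table=table,
        null_counts=pd.DataFrame(null, columns=list(labels)),
        n_perm=n_perm,
        bin_width=bin_width,
    )


def map_outliers_to_genes(
    outliers: pd.DataFrame, genes: pd.DataFrame, tss_window: int = 25_000
) -> list[str]:
    """Genes whose TSS lies within +/- ``tss_window`` bp (inclusive) of an
    outlier SNP on the same chromosome; deduplicated, sorted."""
    hits: set[str] = set()
    for chrom, sub in outliers.groupby("chrom"):
        g = genes[genes["chrom"] == chrom]
        if g.empty:
            continue
        tss = g["tss"].to_numpy(dtype=np.int64)
        for p in sub["pos"].to_numpy(dtype=np.int64):
            near = np.abs(tss - p) <= tss_window
            hits.update(g.loc[near, "gene_id"])
    return sorted(hits)


def derived_af_by_species(panel, site_indices, min_samples: int = 2) -> pd.DataFrame:
    """Derived-allele frequency per species at the given sites.

    Species with fewer than ``min_samples`` samples are reported as NaN.
    Rows are sites (chrom:pos), columns species."""
    rows = {}
    species = panel.species_names
    for s in site_indices:
        key = f"{panel.chrom[s]}:{panel.pos[s]}"
        rows[key] = {}
        for sp in species:
            rowsel = panel.haplotype_indices(sp)
            if rowsel.size // 2 < min_samples:
                rows[key][sp] = np.nan
            else:
                rows[key][sp] = float(panel.haplotypes[rowsel, s].mean())
    return pd.DataFrame(rows).T.reindex(columns=species)


@dataclass
class SegregationResult:
    """Derived-allele dominance grouping and the gene-class association test."""

    site_groups: pd.Series  # per site: 'big', 'small', or 'unassigned'
    contingency: pd.DataFrame  # gene class x dominance group counts
    chi2: float
    p: float
    dof: int
    goodness_of_fit: pd.DataFrame = field(default_factory=pd.DataFrame)


def segregation_test(
    af_table: pd.DataFrame,
    group_map: dict[str, str],
    site_gene_class: dict[str, str] | pd.Series,
) -> SegregationResult:
    """Test whether derived-allele dominance segregates with eye-size group
    differently across gene classes.

    Per site, species where the derived allele is dominant (AF > 0.5) are
    collected; the site is assigned to the eye-size group ('big'/'small')
    holding the majority of those species (ties or none -> unassigned;
    species mapped to 'excluded' are ignored).  Gene classes then form a
    contingency table against dominance groups, tested by Pearson
    chi-square without continuity correction.  A per-class 1-df 50:50
    goodness-of-fit chi-square is also reported.
    """
    if isinstance(site_gene_class, dict):
        site_gene_class = pd.Series(site_gene_class)
    site_gene_class = site_gene_class.rename("gene_class")
    assign = {}
    for site, row in af_table.iterrows():
        dominant = [sp for sp, af in row.items() if pd.notna(af) and af > 0.5]
        votes = pd.Series([group_map.get(sp, "excluded") for sp in dominant])
        votes = votes[votes != "excluded"]
        if votes.empty:
            assign[site] = "unassigned"
            continue
        counts = votes.value_counts()
        if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
            assign[site] = "unassigned"
        else:
            assign[site] = counts.index[0]
    site_groups = pd.Series(assign, name="dominance_group")

    assigned = site_groups[site_groups != "unassigned"]
    classes = site_gene_class.reindex(assigned.index)
    tab = pd.crosstab(classes, assigned)
    tab = tab.reindex(columns=sorted(set(group_map.values()) - {"excluded"}), fill_value=0)
    if tab.size == 0 or tab.to_numpy().sum() == 0:
        raise ValueError("no classified site to test")
    obs = tab.to_numpy(dtype=float)
    if min(obs.shape) < 2 or np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        chi2, p, dof = np.nan, np.nan, 0
    else:
        chi2, p, dof, _ = stats.chi2_contingency(obs, correction=False)

    gof_rows = []
    for cls, row in tab.iterrows():
        n = row.sum()
        if n == 0:
            continue
        g_stat, g_p = stats.chisquare(row.to_numpy(dtype=float))
        gof_rows.append({"gene_class": cls, "n_sites": int(n), "chi2": g_stat, "p": g_p})
    return SegregationResult(
        site_groups=site_groups,
        contingency=tab,
        chi2=float(chi2),
        p=float(p),
        dof=int(dof),
        goodness_of_fit=pd.DataFrame(gof_rows),
    )
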