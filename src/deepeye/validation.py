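"""Study-condition validation experiments.

Each function sets up one of the package's canonical synthetic study
conditions, runs the relevant method end to end and returns summary
statistics.  The experiments double as the acceptance checks: the test
suite asserts on their outputs and ``scripts/acceptance.py`` reports them.

Problem sizes are desk-scale choices documented in the methods note: the
mixed-model experiments use the 3-species / FST 0.1 / n = 60 / 5,000-SNP
panel; the within-population sweep scan uses a 20-Mb chromosome with 8,000
sites so that the sweep footprint stays below the top-1% tail it must
reach; the cross-population scan uses a 5-Mb chromosome where the
window-null quantile criterion is insensitive to footprint size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import expression as ex
from . import enrichment as enr
from . import gwas, scan, simulate, structure, traits

__all__ = [
    "lmm_null_calibration",
    "lmm_power",
    "nj_recovery",
    "pagel_lambda_recovery",
    "ihs_sweep_detection",
    "xpehh_sweep_detection",
    "enrichment_type_one",
    "enrichment_power",
    "de_null_calibration",
    "de_effect_recovery",
    "pca_outlier_contrast",
]


def _structured_panel(seed: int):
    spec = simulate.SimPanelSpec(
        seed=seed, n_species=3, samples_per_species=20, n_sites=5000,
        chrom_lengths={"chr1": 5_000_000}, fst=0.1,
    )
    return simulate.simulate_structured_panel(spec)[0]


def lmm_null_calibration(seed: int = 1) -> dict:
    """Mixed-model p-values under a purely polygenic trait: KS uniformity
    and the genomic-inflation factor."""
    panel = _structured_panel(seed)
    X = panel.dosages().astype(float)
    K = gwas.centered_kinship(X)
    y = simulate.simulate_trait(
        panel,
        simulate.TraitSimSpec(polygenic_var=0.2, residual_var=1.0, seed=seed + 1000),
        kinship=K.K,
    ).to_numpy()
    assoc = gwas.lmm_scan(y, X, K, panel.chrom, panel.pos)
    return {
        "n_snps": int(len(assoc)),
        "ks_p": float(stats.kstest(assoc["p_lrt"], "uniform").pvalue),
        "lambda_gc": gwas.genomic_control_lambda(assoc["p_lrt"].to_numpy()),
        "min_lrt": float(assoc["lrt"].min()),
    }


def lmm_power(seeds=range(20), variance_share: float = 0.4) -> dict:
    """Fraction of replicates in which a single strong causal SNP (expected
    variance share ``variance_share``, comfortably above 25%) is the top
    association."""
    hits = 0
    realized = []
    for seed in seeds:
        panel = _structured_panel(seed)
        X = panel.dosages().astype(float)
        K = gwas.centered_kinship(X)
        f = X.mean(axis=0) / 2
        usable = np.flatnonzero((f > 0.3) & (f < 0.7))
        j = int(usable[len(usable) // 2])
        noise = 1.0 + 0.2 * float(np.mean(np.diag(K.K)))
        beta = np.sqrt(variance_share / (1 - variance_share) * noise / X[:, j].var())
        y = simulate.simulate_trait(
            panel,
            simulate.TraitSimSpec(
                causal_sites={j: float(beta)}, polygenic_var=0.2,
                residual_var=1.0, seed=seed + 2000,
            ),
            kinship=K.K,
        ).to_numpy()
        realized.append(float(np.corrcoef(X[:, j], y)[0, 1] ** 2))
        assoc = gwas.lmm_scan(y, X, K, panel.chrom, panel.pos)
        hits += int(assoc.loc[assoc["p_lrt"].idxmin(), "site_index"] == j)
    n = len(list(seeds))
    return {
        "top_hit_fraction": hits / n,
        "n_seeds": n,
        "median_realized_r2": float(np.median(realized)),
    }


def nj_recovery(n_trees: int = 100, seed: int = 0) -> dict:
    """Exact topology and branch-length recovery of NJ on random additive
    trees with 5-20 leaves."""
    from . import phylo

    ok = 0
    worst = 0.0
    for k in range(n_trees):
        n = 5 + (seed + k) % 16
        tree = simulate.random_tree(n, seed=seed + k)
        C, tips = traits.shared_branch_covariance(tree)
        D = np.diag(C)[:, None] + np.diag(C)[None, :] - 2 * C
        Dm = pd.DataFrame(D, index=tips, columns=tips)
        out = phylo.neighbor_joining(Dm)
        nodes = {t.name: t for t in out.tips()}
        err = max(
            abs(nodes[tips[i]].distance(nodes[tips[j]]) - D[i, j])
            for i in range(n)
            for j in range(i + 1, n)
        )
        worst = max(worst, err)
        ok += err <= 1e-9
    return {"recovery_rate": ok / n_trees, "n_trees": n_trees, "max_path_error": worst}


def pagel_lambda_recovery(n_tips: int = 100, n_reps: int = 50, seed: int = 0) -> dict:
    """Median lambda estimate for Brownian (lambda = 1) traits, and after
    tip permutation (signal destroyed)."""
    tree = simulate.random_tree(n_tips, seed=seed)
    rng = np.random.default_rng(seed + 1)
    lams, perms = [], []
    for rep in range(n_reps):
        y = simulate.simulate_bm_trait(tree, 1.0, sigma2=1.0, seed=seed + 100 + rep)
        lams.append(traits.pagel_lambda(tree, y).lambda_hat)
        yp = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        perms.append(traits.pagel_lambda(tree, yp).lambda_hat)
    return {
        "median_lambda_bm": float(np.median(lams)),
        "median_lambda_permuted": float(np.median(perms)),
        "n_reps": n_reps,
    }


def _sweep_panel_within(seed: int):
    spec = simulate.SimPanelSpec(
        seed=seed, n_species=1, samples_per_species=30, n_sites=8000,
        chrom_lengths={"chr1": 20_000_000}, fst=0.0,
    )
    panel, _ = simulate.simulate_structured_panel(spec)
    f = panel.derived_frequency()
    mid = panel.n_sites // 2
    cand = np.flatnonzero((f > 0.05) & (f < 0.25))
    j = int(cand[np.argmin(np.abs(cand - mid))])
    sw = simulate.SweepSpec(
        "sp1", "chr1", int(panel.pos[j]), carrier_fraction=0.8,
        decay_length=50_000, seed=seed,
    )
    return simulate.implant_sweep(panel, sw), int(panel.pos[j])


def ihs_sweep_detection(seeds=range(20)) -> dict:
    """Within-population scan: is the implanted core in the genome-wide
    top 1% of |iHS|, with the expected negative sign, and are the
    frequency bins standardized exactly."""
    top, neg, evaluated = 0, 0, 0
    max_bin_mean = 0.0
    max_bin_sd_err = 0.0
    cfg = scan.EHHConfig()
    for seed in seeds:
        panel, core_pos = _sweep_panel_within(seed)
        ihs = scan.ihs_scan(panel, cfg)
        ok = ihs.dropna(subset=["ihs_std"])
        for _, grp in ok.groupby(np.floor(ok["freq_derived"] / cfg.freq_bin_width)):
            if len(grp) >= 2:
                max_bin_mean = max(max_bin_mean, abs(float(grp["ihs_std"].mean())))
                max_bin_sd_err = max(
                    max_bin_sd_err, abs(float(grp["ihs_std"].std(ddof=0)) - 1.0)
                )
        row = ihs[ihs["pos"] == core_pos]
        if row.empty or not np.isfinite(row["ihs_std"].iloc[0]):
            continue
        evaluated += 1
        z = float(row["ihs_std"].iloc[0])
        neg += z < 0
        top += abs(z) >= float(ihs["ihs_std"].abs().quantile(0.99))
    return {
        "top1_fraction": top / evaluated if evaluated else float("nan"),
        "negative_fraction": neg / evaluated if evaluated else float("nan"),
        "n_evaluated": evaluated,
        "max_bin_mean": max_bin_mean,
        "max_bin_sd_error": max_bin_sd_err,
    }


def xpehh_sweep_detection(seeds=range(20), n_windows: int = 10_000) -> dict:
    """Cross-population scan: sweep fixed in population B must be flagged
    in the lower tail of the 30-kb window null; also checks the exact
    antisymmetry and identical-panel invariants on the first seed."""
    flagged = correct_tail = n = 0
    identical_max = np.nan
    antisym_max = np.nan
    for k, seed in enumerate(seeds):
        spec = simulate.SimPanelSpec(
            seed=seed, n_species=2, samples_per_species=(25, 25), n_sites=6000,
            chrom_lengths={"chr1": 5_000_000}, fst=0.05,
        )
        panel, _ = simulate.simulate_structured_panel(spec)
        rows_b = panel.haplotype_indices("sp2")
        f = panel.haplotypes[rows_b].mean(axis=0)
        mid = panel.n_sites // 2
        cand = np.flatnonzero((f > 0.02) & (f < 0.3))
        j = int(cand[np.argmin(np.abs(cand - mid))])
        core_pos = int(panel.pos[j])
        swept = simulate.implant_sweep(
            panel,
            simulate.SweepSpec("sp2", "chr1", core_pos, carrier_fraction=1.0,
                               decay_length=50_000, seed=seed),
        )
        pa = swept.subset_species(["sp1"])
        pb = swept.subset_species(["sp2"])
        xp = scan.xpehh_scan(pa, pb)
        if k == 0:
            same = scan.xpehh_scan(pa, pa)
            identical_max = float(np.nanmax(np.abs(same["xpehh_raw"])))
            rev = scan.xpehh_scan(pb, pa)
            both = np.isfinite(xp["xpehh_raw"]) & np.isfinite(rev["xpehh_raw"])
            antisym_max = float(
                np.max(np.abs(xp["xpehh_raw"][both].to_numpy() + rev["xpehh_raw"][both].to_numpy()))
            )
        null = scan.window_empirical_null(
            xp, panel.chrom_lengths, n_windows=n_windows, seed=seed
        )
        out = scan.rank_candidate_windows(
            xp, pd.DataFrame({"chrom": ["chr1"], "pos": [core_pos]}), null
        )
        r = out.iloc[0]
        n += 1
        flagged += bool(r["flagged"])
        correct_tail += bool(r["quantile_min"] < 0.05)
    return {
        "flagged_fraction": flagged / n,
        "correct_tail_fraction": correct_tail / n,
        "n_seeds": n,
        "identical_panels_max_abs_raw": identical_max,
        "swap_antisymmetry_max_error": antisym_max,
    }


def _label_table(n, label_p, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "maf": rng.uniform(0.01, 0.5, n),
            "effects": np.where(rng.random(n) < label_p, "missense_variant", "intron_variant"),
        }
    )


def enrichment_type_one(n_reps: int = 200, n_perm: int = 1000, seed: int = 0) -> dict:
    """Empirical-p uniformity when the test set is itself a matched draw
    from the control set."""
    control = _label_table(5000, 0.3, seed)
    rng = np.random.default_rng(seed + 1)
    pvals = []
    for rep in range(n_reps):
        idx = rng.choice(len(control), 190, replace=False)
        res = enr.maf_matched_permutation(
            control.iloc[idx], control, n_perm=n_perm, seed=seed + 10 + rep
        )
        pvals.append(res.table.loc["missense_variant", "p_empirical"])
    return {
        "ks_p": float(stats.kstest(pvals, "uniform").pvalue),
        "n_reps": n_reps,
    }


def enrichment_power(seeds=range(50), n_perm: int = 1000) -> dict:
    """Detection of a 5-fold planted label enrichment in a 190-SNP test set
    against a 100,000-SNP control set."""
    hits = 0
    for seed in seeds:
        control = _label_table(100_000, 0.05, seed)
        rng = np.random.default_rng(seed + 500)
        idx = rng.choice(len(control), 190, replace=False)
        test = control.iloc[idx].copy()
        test["effects"] = np.where(
            rng.random(190) < 0.25, "missense_variant", "intron_variant"
        )
        res = enr.maf_matched_permutation(test, control, n_perm=n_perm, seed=seed + 900)
        hits += res.table.loc["missense_variant", "p_empirical"] < 0.05
    n = len(list(seeds))
    return {"detection_fraction": hits / n, "n_seeds": n}


def de_null_calibration(seed: int = 1) -> dict:
    """Simplified NB Wald test under the null (5 vs 5, dispersion 0.1)."""
    cm = simulate.simulate_counts(
        simulate.CountSimSpec(n_genes=2000, dispersion=0.1, log2fc=0.0, seed=seed)
    )
    de = ex.nb_wald_de(ex.filter_low_counts(cm))
    p = de.table["pvalue"].dropna()
    return {
        "ks_p": float(stats.kstest(p, "uniform").pvalue),
        "bh_positive_fraction": float((de.table["padj"] < 0.05).mean()),
        "n_genes": int(len(p)),
    }


def de_effect_recovery(seeds=range(50), log2fc: float = 4.5) -> dict:
    """Mean estimated log2 fold change for one planted gene, 5 vs 5."""
    est = []
    for seed in seeds:
        lfc = np.zeros(400)
        lfc[0] = log2fc
        cm = simulate.simulate_counts(
            simulate.CountSimSpec(n_genes=400, dispersion=0.1, log2fc=lfc, seed=seed)
        )
        de = ex.nb_wald_de(ex.filter_low_counts(cm))
        if "g00001" in de.table.index:
            est.append(float(de.table.loc["g00001", "log2fc"]))
    return {
        "mean_log2fc": float(np.mean(est)),
        "planted_log2fc": log2fc,
        "n_reps": len(est),
    }


def pca_outlier_contrast(seeds=range(20)) -> dict:
    """Trait separation by outlier-SNP PC1 versus genome-wide PC1 when the
    trait is driven by a minority of SNPs shared across non-sister
    species (mutually correlated, weakly structured)."""
    wins = 0
    r2_out, r2_gw = [], []
    for seed in seeds:
        spec = simulate.SimPanelSpec(
            seed=seed, n_species=4, samples_per_species=13, n_sites=2000, fst=0.08
        )
        panel, _ = simulate.simulate_structured_panel(spec)
        X = panel.dosages().astype(float)
        rng = np.random.default_rng(seed)
        group_a = np.isin(panel.species, ["sp1", "sp3"])
        causal = rng.choice(panel.n_sites, 20, replace=False)
        for j in causal:
            X[group_a, j] = rng.binomial(2, 0.8, size=group_a.sum())
            X[~group_a, j] = rng.binomial(2, 0.1, size=(~group_a).sum())
        y = X[:, causal].mean(axis=1)
        y = (y - y.mean()) / y.std() + 0.4 * rng.standard_normal(len(y))
        trait = pd.Series(y, index=panel.samples)
        keep = gwas.maf_filter(X, 0.05)
        pruned = structure.ld_prune(X[:, keep])
        gw = structure.pc1_trait_regression(
            structure.pca(X[:, keep[pruned]], panel.samples), trait
        )
        out = structure.pc1_trait_regression(structure.pca(X[:, causal], panel.samples), trait)
        wins += out["r2"] > gw["r2"]
        r2_out.append(out["r2"])
        r2_gw.append(gw["r2"])
    n = len(list(seeds))
    return {
        "outlier_beats_genomewide_fraction": wins / n,
        "median_r2_outliers": float(np.median(r2_out)),
        "median_r2_genomewide": float(np.median(r2_gw)),
        "n_seeds": n,
    }
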