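"""Synthetic-data generation for every pipeline stage.

The generator emulates the statistical structure the analyses assume —
not sequence evolution.  Population structure follows the Balding-Nichols
model: per species, allele frequencies are Beta-distributed around an
ancestral frequency p with variance p(1-p)*FST, then haplotype alleles are
independent Bernoulli draws.  Linkage exists only where a selective sweep
is implanted: a donor haplotype is copied into a fraction of a target
population's haplotypes, truncated at geometrically distributed
breakpoints around the core, which is exactly the extended-homozygosity
footprint the haplotype scans detect.

Every operation is a pure function of its spec and seed; stage-local seeds
are derived from one bundle seed by fixed offsets so stages can be rerun
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import io as deio
from .expression import CountMatrix
from .panel import HaplotypePanel, SiteTable
from .qc import DepthMatrix
from .traits import shared_branch_covariance

__all__ = [
    "SimPanelSpec",
    "SweepSpec",
    "TraitSimSpec",
    "CountSimSpec",
    "simulate_structured_panel",
    "implant_sweep",
    "simulate_trait",
    "simulate_bm_trait",
    "random_tree",
    "simulate_gene_models_and_effects",
    "simulate_site_info",
    "simulate_depth_matrix",
    "simulate_counts",
    "emit_fixture_bundle",
]

#: fixed per-stage seed offsets, so one bundle seed reruns any stage alone
SEED_OFFSETS = {
    "panel": 0,
    "sweep": 101,
    "trait": 202,
    "genes": 303,
    "depth": 404,
    "counts": 505,
    "tree": 606,
    "site_info": 707,
}


@dataclass
class SimPanelSpec:
    """Structured multi-species panel under the Balding-Nichols model."""

    seed: int = 0
    n_species: int = 3
    samples_per_species: tuple[int, ...] | int = 20
    n_sites: int = 5000
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 5_000_000})
    fst: float = 0.1
    ancestral_af_range: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must lie in [0, 1)")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        lo, hi = self.ancestral_af_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_af_range must lie within (0, 1)")
        if isinstance(self.samples_per_species, int):
            self.samples_per_species = (self.samples_per_species,) * self.n_species
        if len(self.samples_per_species) != self.n_species:
            raise ValueError("one sample count per species required")


@dataclass
class SweepSpec:
    """Implanted selective sweep: donor-haplotype copying with geometric
    breakpoints (mean ``decay_length`` bp to the first breakpoint per side)."""

    target_population: str
    core_chrom: str
    core_position: int
    carrier_fraction: float = 0.8
    decay_length: float = 50_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction must lie in [0, 1]")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")


@dataclass
class TraitSimSpec:
    """Trait = sum of SNP effects + polygenic term + residual noise."""

    causal_sites: dict[int, float] = field(default_factory=dict)  # site index -> beta
    polygenic_var: float = 0.0
    residual_var: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.polygenic_var < 0 or self.residual_var < 0:
            raise ValueError("variances must be >= 0")


@dataclass
class CountSimSpec:
    """Negative-binomial count matrix with group fold changes and
    designated opsin genes (emulating a 5-vs-5 eye-transcriptome design)."""

    n_genes: int = 2000
    group_sizes: tuple[int, int] = (5, 5)
    dispersion: float | np.ndarray = 0.1
    log2fc: float | np.ndarray = 0.0
    mean_count: float = 100.0
    cds_lengths: np.ndarray | None = None
    opsin_ids: dict[str, str] | None = None
    opsin_tpm_shares: dict[str, dict[str, float]] | None = None  # group -> class -> weight
    noncoding_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.dispersion) <= 0):
            raise ValueError("dispersion must be > 0")
        if self.cds_lengths is not None and np.any(np.asarray(self.cds_lengths) <= 0):
            raise ValueError("cds_lengths must be > 0")


def simulate_structured_panel(spec: SimPanelSpec) -> tuple[HaplotypePanel, SiteTable]:
    """Phased multi-species panel with Balding-Nichols differentiation.

    Per site: ancestral frequency p ~ Uniform(ancestral_af_range); species
    frequency ~ Beta(p (1-F)/F, (1-p)(1-F)/F) (mean p, variance
    p(1-p)F); alleles Bernoulli.  Positions are unique, sorted, spread
    over the chromosomes proportionally to length."""
    rng = np.random.default_rng(spec.seed + SEED_OFFSETS["panel"])
    chroms = list(spec.chrom_lengths)
    lens = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    n_per = rng.multinomial(spec.n_sites, lens / lens.sum())
    chrom_arr, pos_arr = [], []
    for c, k in zip(chroms, n_per):
        L = spec.chrom_lengths[c]
        if k > L:
            raise ValueError(f"more sites than positions on {c}")
        pos = np.sort(rng.choice(np.arange(1, L + 1), size=k, replace=False))
        chrom_arr.append(np.repeat(c, k))
        pos_arr.append(pos)
    chrom_arr = np.concatenate(chrom_arr)
    pos_arr = np.concatenate(pos_arr)

    lo, hi = spec.ancestral_af_range
    p = rng.uniform(lo, hi, size=spec.n_sites)
    species_names = [f"sp{i + 1}" for i in range(spec.n_species)]
    hap_blocks = []
    species_per_sample = []
    samples = []
    for si, (name, n_samp) in enumerate(zip(species_names, spec.samples_per_species)):
        if spec.fst == 0.0:
            f = p
        else:
            a = p * (1.0 - spec.fst) / spec.fst
            b = (1.0 - p) * (1.0 - spec.fst) / spec.fst
            f = rng.beta(a, b)
        hap_blocks.append(
            (rng.random((2 * n_samp, spec.n_sites)) < f).astype(np.int8)
        )
        species_per_sample += [name] * n_samp
        samples += [f"{name}_s{k + 1}" for k in range(n_samp)]
    panel = HaplotypePanel(
        haplotypes=np.concatenate(hap_blocks, axis=0),
        samples=samples,
        species=np.array(species_per_sample),
        chrom=chrom_arr,
        pos=pos_arr,
        chrom_lengths=dict(spec.chrom_lengths),
    )
    sites = SiteTable(pd.DataFrame({"chrom": chrom_arr, "pos": pos_arr, "ancestral_af": p}))
    return panel, sites


def implant_sweep(panel: HaplotypePanel, spec: SweepSpec) -> HaplotypePanel:
    """Copy one derived-carrying donor haplotype into a fraction of the
    target population, truncated at geometric breakpoints around the core.

    Each carrier copy extends from the core until an independently drawn
    breakpoint on each side (distance ~ Exponential with mean
    ``decay_length`` bp, the continuous limit of the geometric); outside
    the copied segment the original haplotype is retained.  Other
    populations are untouched.  Core-site derived frequency in the target
    becomes >= carrier_fraction."""
    if spec.target_population not in panel.species_names:
        raise ValueError(f"target population '{spec.target_population}' not in panel")
    out = panel.copy()
    core = out.site_index(spec.core_chrom, spec.core_position)
    rows = out.haplotype_indices(spec.target_population)
    carriers_now = rows[out.haplotypes[rows, core] == 1]
    if carriers_now.size == 0:
        raise ValueError("core allele is monomorphic-ancestral in the target population")
    if spec.carrier_fraction == 0.0:
        return out
    rng = np.random.default_rng(spec.seed + SEED_OFFSETS["sweep"])
    donor = int(carriers_now[rng.integers(carriers_now.size)])
    k = int(np.ceil(spec.carrier_fraction * rows.size))
    chosen = rng.choice(rows, size=k, replace=False)
    if donor not in chosen:  # the donor itself always carries the sweep haplotype
        chosen = np.append(chosen[:-1], donor) if k == rows.size else np.append(chosen, donor)
    on_chrom = out.chrom == spec.core_chrom
    chrom_pos = out.pos[on_chrom]
    chrom_cols = np.flatnonzero(on_chrom)
    core_pos = spec.core_position
    donor_hap = out.haplotypes[donor, chrom_cols].copy()
    for h in chosen:
        left = core_pos - rng.exponential(spec.decay_length)
        right = core_pos + rng.exponential(spec.decay_length)
        seg = (chrom_pos >= left) & (chrom_pos <= right)
        out.haplotypes[h, chrom_cols[seg]] = donor_hap[seg]
    return out


def simulate_trait(
    panel: HaplotypePanel, spec: TraitSimSpec, kinship: np.ndarray | None = None
) -> pd.Series:
    """y = sum_j beta_j x_j + g + e with diploid dosages x, polygenic
    g ~ MVN(0, sigma_g^2 K) and iid residual e."""
    for s in spec.causal_sites:
        if not 0 <= s < panel.n_sites:
            raise ValueError(f"causal site index {s} outside the panel")
    rng = np.random.default_rng(spec.seed + SEED_OFFSETS["trait"])
    n = panel.n_samples
    X = panel.dosages().astype(float)
    y = np.zeros(n)
    for s, beta in spec.causal_sites.items():
        y += beta * X[:, s]
    if spec.polygenic_var > 0:
        if kinship is None:
            raise ValueError("kinship matrix required when polygenic_var > 0")
        K = np.asarray(kinship, dtype=float)
        jitter = 1e-10 * max(np.trace(K) / n, 1.0)
        L = np.linalg.cholesky(K + jitter * np.eye(n))
        y += np.sqrt(spec.polygenic_var) * (L @ rng.standard_normal(n))
    y += np.sqrt(spec.residual_var) * rng.standard_normal(n)
    return pd.Series(y, index=panel.samples, name="trait")


def random_tree(n_tips: int, seed: int = 0, min_bl: float = 0.1, max_bl: float = 2.0) -> TreeNode:
    """Random bifurcating rooted tree with uniform branch lengths, built by
    sequential random joins (tips named t1..tn)."""
    rng = np.random.default_rng(seed + SEED_OFFSETS["tree"])
    nodes = []
    for i in range(n_tips):
        t = TreeNode(name=f"t{i + 1}")
        t.length = float(rng.uniform(min_bl, max_bl))
        nodes.append(t)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode()
        parent.length = float(rng.uniform(min_bl, max_bl))
        parent.extend([nodes[i], nodes[j]])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = None
    return root


def simulate_bm_trait(
    tree: TreeNode, lambda_sim: float, sigma2: float = 1.0, seed: int = 0
) -> pd.Series:
    """Brownian trait on a tree with Pagel-lambda covariance scaling.

    Draws y ~ MVN(0, sigma^2 C_lambda) where C is the shared-branch-length
    matrix and C_lambda keeps the diagonal but multiplies off-diagonal
    entries by lambda."""
    if not 0.0 <= lambda_sim <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    C, tips = shared_branch_covariance(tree)
    V = lambda_sim * C
    np.fill_diagonal(V, np.diag(C))
    n = len(tips)
    rng = np.random.default_rng(seed + SEED_OFFSETS["tree"])
    jitter = 1e-12 * max(np.trace(V) / n, 1.0)
    L = np.linalg.cholesky(sigma2 * V + jitter * np.eye(n))
    return pd.Series(L @ rng.standard_normal(n), index=tips, name="trait")


def simulate_gene_models_and_effects(
    panel: HaplotypePanel,
    n_genes: int,
    seed: int = 0,
    gene_length: tuple[int, int] = (3000, 8000),
    n_cds_exons: int = 3,
    utr3_length: int = 500,
    flank: int = 5000,
    splice_region: int = 3,
    missense_ratio: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Place non-overlapping gene models and annotate every panel SNP.

    Returns (genes, features, annotation).  ``genes`` has gene_id, chrom,
    start, end, strand, tss; ``features`` has per-gene CDS /
    three_prime_UTR / intron intervals; ``annotation`` has one row per SNP:
    snp_id, chrom, pos, maf, effects (semicolon-joined labels), genes.

    Label rules by position: CDS -> missense or synonymous (Bernoulli with
    ``missense_ratio``); 3' UTR; intron (splice-region&intron within
    ``splice_region`` bp of a CDS edge); within ``flank`` bp outside the
    gene -> upstream/downstream by strand; otherwise intergenic.  A SNP can
    carry labels from several genes."""
    rng = np.random.default_rng(seed + SEED_OFFSETS["genes"])
    chroms = list(panel.chrom_lengths)
    lens = np.array([panel.chrom_lengths[c] for c in chroms], dtype=float)
    per_chrom = np.floor(n_genes * lens / lens.sum()).astype(int)
    while per_chrom.sum() < n_genes:
        per_chrom[int(np.argmax(lens / (per_chrom + 1)))] += 1

    gene_rows, feat_rows = [], []
    gid = 0
    for c, k in zip(chroms, per_chrom):
        if k == 0:
            continue
        L = panel.chrom_lengths[c]
        slot = L // k
        if slot < gene_length[1] + 2 * flank:
            raise ValueError(f"{k} genes do not fit on {c} (length {L})")
        for s in range(k):
            gid += 1
            glen = int(rng.integers(gene_length[0], gene_length[1] + 1))
            lo = s * slot + flank
            hi = (s + 1) * slot - flank - glen
            start = int(rng.integers(lo, max(hi, lo + 1)))
            end = start + glen - 1
            strand = "+" if rng.random() < 0.5 else "-"
            name = f"gene{gid:04d}"
            tss = start if strand == "+" else end
            gene_rows.append(
                {"gene_id": name, "chrom": c, "start": start, "end": end,
                 "strand": strand, "tss": tss}
            )
            # 3' UTR at the 3' end; the rest alternates CDS exons and introns
            if strand == "+":
                utr = (end - utr3_length + 1, end)
                body = (start, end - utr3_length)
            else:
                utr = (start, start + utr3_length - 1)
                body = (start + utr3_length, end)
            feat_rows.append({"gene_id": name, "type": "three_prime_UTR",
                              "start": utr[0], "end": utr[1]})
            b0, b1 = body
            edges = np.linspace(b0, b1 + 1, 2 * n_cds_exons).astype(int)
            for e in range(n_cds_exons):
                cs, ce = edges[2 * e], edges[2 * e + 1] - 1
                feat_rows.append({"gene_id": name, "type": "CDS", "start": int(cs), "end": int(ce)})
                if e < n_cds_exons - 1:
                    feat_rows.append(
                        {"gene_id": name, "type": "intron",
                         "start": int(edges[2 * e + 1]), "end": int(edges[2 * e + 2] - 1)}
                    )
    genes = pd.DataFrame(gene_rows)
    features = pd.DataFrame(feat_rows)

    freq = panel.derived_frequency()
    maf = np.minimum(freq, 1 - freq)
    ann_rows = []
    feats_by_gene = {g: f for g, f in features.groupby("gene_id")}
    for s in range(panel.n_sites):
        c, p = panel.chrom[s], int(panel.pos[s])
        labels: list[str] = []
        hit_genes: list[str] = []
        sub = genes[genes["chrom"] == c]
        for _, g in sub.iterrows():
            if g["start"] <= p <= g["end"]:
                hit_genes.append(g["gene_id"])
                f = feats_by_gene[g["gene_id"]]
                in_cds = ((f["type"] == "CDS") & (f["start"] <= p) & (p <= f["end"])).any()
                in_utr = (
                    (f["type"] == "three_prime_UTR") & (f["start"] <= p) & (p <= f["end"])
                ).any()
                if in_cds:
                    labels.append(
                        "missense_variant" if rng.random() < missense_ratio else "synonymous_variant"
                    )
                elif in_utr:
                    labels.append("3_prime_UTR_variant")
                else:
                    cds = f[f["type"] == "CDS"]
                    near_edge = (
                        (np.abs(cds["start"].to_numpy() - p) <= splice_region)
                        | (np.abs(cds["end"].to_numpy() - p) <= splice_region)
                    ).any()
                    labels.append(
                        "splice_region_variant&intron_variant" if near_edge else "intron_variant"
                    )
            elif g["start"] - flank <= p < g["start"]:
                hit_genes.append(g["gene_id"])
                labels.append(
                    "upstream_gene_variant" if g["strand"] == "+" else "downstream_gene_variant"
                )
            elif g["end"] < p <= g["end"] + flank:
                hit_genes.append(g["gene_id"])
                labels.append(
                    "downstream_gene_variant" if g["strand"] == "+" else "upstream_gene_variant"
                )
        if not labels:
            labels = ["intergenic_region"]
        ann_rows.append(
            {
                "snp_id": f"{c}:{p}",
                "chrom": c,
                "pos": p,
                "maf": float(maf[s]),
                "effects": ";".join(labels),
                "genes": ";".join(hit_genes),
            }
        )
    return genes, features, pd.DataFrame(ann_rows)


def simulate_site_info(panel: HaplotypePanel, seed: int = 0, fail_fraction: float = 0.0) -> pd.DataFrame:
    """Plausible per-site QC INFO fields; a ``fail_fraction`` of sites get a
    randomly chosen failing rule (for filter exercises)."""
    rng = np.random.default_rng(seed + SEED_OFFSETS["site_info"])
    n = panel.n_sites
    info = pd.DataFrame(
        {
            "chrom": panel.chrom,
            "pos": panel.pos,
            "n_alleles": 2,
            "mq": np.round(rng.uniform(52, 60, n), 4),
            "mq0f": np.round(rng.uniform(0.0, 0.05, n), 4),
            "missing_frac": np.round(rng.uniform(0.0, 0.1, n), 4),
            "exchet": np.round(rng.uniform(0.3, 1.0, n), 4),
            "strandbias_p": np.round(rng.uniform(0.05, 1.0, n), 4),
            "ab_ref": 0,
            "ab_alt": 0,
        }
    )
    het = (panel.haplotypes[0::2] != panel.haplotypes[1::2]).sum(axis=0)
    reads = rng.binomial(np.maximum(het, 1) * 20, 0.5)
    info["ab_ref"] = reads
    info["ab_alt"] = np.maximum(het, 1) * 20 - reads
    from .qc import allele_balance_test

    info["ab_p"] = [
        allele_balance_test([(r, a)]) for r, a in zip(info["ab_ref"], info["ab_alt"])
    ]
    if fail_fraction > 0:
        bad = rng.random(n) < fail_fraction
        which = rng.integers(0, 5, n)
        info.loc[bad & (which == 0), "mq"] = 40.0
        info.loc[bad & (which == 1), "mq0f"] = 0.3
        info.loc[bad & (which == 2), "missing_frac"] = 0.5
        info.loc[bad & (which == 3), "exchet"] = 0.01
        info.loc[bad & (which == 4), "strandbias_p"] = 1e-5
    return info


def simulate_depth_matrix(
    n_samples: int,
    n_sites: int,
    per_sample_mean: float | np.ndarray = 20.0,
    per_sample_sd: float | np.ndarray = 4.0,
    duplicated_sites: tuple[int, ...] = (),
    seed: int = 0,
    chrom: str = "chr1",
    positions: np.ndarray | None = None,
) -> DepthMatrix:
    """Per-sample x site read depths (Gaussian around each sample's mean,
    floored at 0); all samples' depths are doubled at ``duplicated_sites``
    to mimic a collapsed duplication.  The stated per-sample moments are
    attached as the genome-wide moments, so planted anomalies score
    exactly."""
    means = np.broadcast_to(np.asarray(per_sample_mean, dtype=float), (n_samples,)).copy()
    sds = np.broadcast_to(np.asarray(per_sample_sd, dtype=float), (n_samples,)).copy()
    if np.any(means <= 0):
        raise ValueError("per-sample means must be positive")
    rng = np.random.default_rng(seed + SEED_OFFSETS["depth"])
    # scale 0 is allowed: depths are then exactly the sample mean
    d = rng.normal(means[:, None], sds[:, None], size=(n_samples, n_sites))
    d = np.maximum(d, 0.0)
    for s in duplicated_sites:
        d[:, s] *= 2.0
    if positions is None:
        positions = np.arange(1, n_sites + 1, dtype=np.int64)
    return DepthMatrix(
        depths=d,
        samples=[f"s{i + 1}" for i in range(n_samples)],
        chrom=np.repeat(chrom, n_sites),
        pos=positions,
        sample_mean=means,
        sample_sd=np.maximum(sds, 1e-12),
    )


def simulate_counts(spec: CountSimSpec) -> CountMatrix:
    """Negative-binomial gene x sample counts with per-gene group fold
    changes; designated opsin genes get means proportional to the
    configured TPM shares."""
    rng = np.random.default_rng(spec.seed + SEED_OFFSETS["counts"])
    n1, n2 = spec.group_sizes
    n = n1 + n2
    genes = [f"g{i + 1:05d}" for i in range(spec.n_genes)]
    lengths = (
        np.asarray(spec.cds_lengths, dtype=float)
        if spec.cds_lengths is not None
        else rng.integers(300, 3000, size=spec.n_genes).astype(float)
    )
    disp = np.broadcast_to(np.asarray(spec.dispersion, dtype=float), (spec.n_genes,))
    lfc = np.broadcast_to(np.asarray(spec.log2fc, dtype=float), (spec.n_genes,))
    base = rng.lognormal(np.log(spec.mean_count), 1.0, size=spec.n_genes)

    gene_index = {g: i for i, g in enumerate(genes)}
    mu1 = base.copy()
    mu2 = base * 2.0**lfc
    if spec.opsin_ids:
        shares = spec.opsin_tpm_shares or {}
        for grp, mu in (("group1", mu1), ("group2", mu2)):
            w = shares.get(grp)
            if w is None:
                continue
            scale = 50.0 * spec.mean_count  # opsins dominate an eye library
            for cls, weight in w.items():
                g = spec.opsin_ids.get(cls)
                if g in gene_index:
                    i = gene_index[g]
                    mu[i] = max(weight * scale, 1e-3) * (lengths[i] / 1000.0)

    counts = np.empty((spec.n_genes, n), dtype=np.int64)
    for g in range(spec.n_genes):
        r = 1.0 / disp[g]
        counts[g, :n1] = rng.negative_binomial(r, r / (r + mu1[g]), size=n1)
        counts[g, n1:] = rng.negative_binomial(r, r / (r + mu2[g]), size=n2)
    cols = [f"g1_s{i + 1}" for i in range(n1)] + [f"g2_s{i + 1}" for i in range(n2)]
    biotype = np.where(
        rng.random(spec.n_genes) < spec.noncoding_fraction, "lncRNA", "protein_coding"
    )
    if spec.opsin_ids:  # opsins are always protein coding
        for g in spec.opsin_ids.values():
            if g in gene_index:
                biotype[gene_index[g]] = "protein_coding"
    groups = pd.Series(["group1"] * n1 + ["group2"] * n2, index=cols)
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=cols),
        lengths=pd.Series(lengths, index=genes),
        biotype=pd.Series(biotype, index=genes),
        groups=groups,
    )


def emit_fixture_bundle(
    out_dir,
    panel: HaplotypePanel,
    site_info: pd.DataFrame | None = None,
    genes: pd.DataFrame | None = None,
    features: pd.DataFrame | None = None,
    annotation: pd.DataFrame | None = None,
    traits: pd.DataFrame | None = None,
    depth: DepthMatrix | None = None,
    counts: CountMatrix | None = None,
    tree: TreeNode | None = None,
) -> dict[str, Path]:
    """Write all generated artifacts as plain-text files.

    Produces panel.vcf (+ samples.tsv with species), genes.gff3,
    annotation.tsv, traits.tsv, depths.tsv, counts.tsv and tree.nwk for
    whichever artifacts are given; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["vcf"] = out / "panel.vcf"
    deio.write_vcf(paths["vcf"], panel, site_info)
    paths["samples"] = out / "samples.tsv"
    pd.DataFrame({"sample_id": panel.samples, "species": panel.species}).to_csv(
        paths["samples"], sep="\t", index=False
    )
    if genes is not None and features is not None:
        paths["gff3"] = out / "genes.gff3"
        deio.write_gff3(paths["gff3"], genes, features)
    if annotation is not None:
        paths["annotation"] = out / "annotation.tsv"
        annotation.to_csv(paths["annotation"], sep="\t", index=False)
    if traits is not None:
        paths["traits"] = out / "traits.tsv"
        traits.to_csv(paths["traits"], sep="\t", index=False)
    if depth is not None:
        paths["depths"] = out / "depths.tsv"
        df = pd.DataFrame(depth.depths, index=depth.samples)
        df.columns = [f"{c}:{p}" for c, p in zip(depth.chrom, depth.pos)]
        df.to_csv(paths["depths"], sep="\t")
    if counts is not None:
        paths["counts"] = out / "counts.tsv"
        tab = counts.counts.copy()
        tab.insert(0, "length_bp", counts.lengths.astype(int))
        tab.insert(1, "biotype", counts.biotype)
        tab.index.name = "gene_id"
        tab.to_csv(paths["counts"], sep="\t")
    if tree is not None:
        paths["tree"] = out / "tree.nwk"
        deio.write_newick(paths["tree"], tree)
    return paths
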