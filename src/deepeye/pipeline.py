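"""In-process pipeline orchestration: one YAML config, deterministic reruns,
and a JSON manifest with checksums of every artifact written.

Stages run in the order listed; each consumes the in-memory artifacts of
earlier stages (or files named under ``inputs``) and writes plain-text
outputs under ``out_dir``.  Identical config + seed reproduces identical
checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import expression as expr
from . import gwas, io, phylo, qc, scan, simulate, structure, traits

log = logging.getLogger("deepeye")

__all__ = ["PipelineConfig", "parse_config", "run_pipeline", "STAGES"]

#: allowed parameter keys per stage (unknown keys are rejected at parse time)
STAGES: dict[str, set[str]] = {
    "simulate": {
        "n_species", "samples_per_species", "n_sites", "chrom_lengths", "fst",
        "ancestral_af_range", "sweep", "trait", "n_genes", "depth", "counts",
    },
    "qc": {"config"},
    "disttree": {"window_bp", "replicates", "outgroup"},
    "phylosig": {"column"},
    "gwas": {"column", "maf_min", "top_fraction"},
    "pcacmp": {"column", "n_components"},
    "enrich": {"bin_width", "n_perm"},
    "scan": {"pop_a", "pop_b", "null_windows", "window_bp"},
    "expr": {"min_count", "min_samples", "padj_max", "abs_lfc_min"},
}

_TOP_KEYS = {"seed", "out_dir", "inputs", "stages"}


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "deepeye_out"
    inputs: dict[str, str] = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "inputs": dict(self.inputs),
            "stages": [dict(s) for s in self.stages],
        }


def parse_config(path_or_dict) -> PipelineConfig:
    """Load and validate a pipeline config; unknown keys are an error
    naming the offending key path."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict)
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    stages = []
    for i, st in enumerate(raw.get("stages", []) or []):
        if isinstance(st, str):
            st = {"name": st}
        extra = set(st) - {"name", "params"}
        if extra:
            raise ValueError(f"stages[{i}]: unknown key(s) {sorted(extra)}")
        name = st.get("name")
        if name not in STAGES:
            raise ValueError(f"stages[{i}]: unknown stage '{name}'")
        params = st.get("params") or {}
        bad = set(params) - STAGES[name]
        if bad:
            raise ValueError(f"stages[{i}] ({name}): unknown parameter(s) {sorted(bad)}")
        stages.append({"name": name, "params": params})
    for key, p in (raw.get("inputs") or {}).items():
        if not Path(p).exists():
            raise FileNotFoundError(f"inputs.{key}: no such file '{p}'")
    cfg = PipelineConfig(
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "deepeye_out")),
        inputs=dict(raw.get("inputs") or {}),
        stages=stages,
    )
    log.info("config parsed: %s", json.dumps(cfg.to_dict()))
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Context:
    """Mutable bag of in-memory artifacts shared between stages."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.out = Path(cfg.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.obj: dict[str, object] = {}
        self.files: dict[str, Path] = {}

    def need_panel(self):
        if "panel" not in self.obj:
            vcf = self.cfg.inputs.get("vcf")
            if vcf is None:
                raise RuntimeError("stage needs a panel: run 'simulate' first or set inputs.vcf")
            species = None
            samples = self.cfg.inputs.get("samples")
            if samples:
                df = pd.read_csv(samples, sep="\t")
                species = dict(zip(df["sample_id"], df["species"]))
            panel, sites = io.read_vcf(vcf, species)
            self.obj["panel"] = panel
            self.obj["site_info"] = sites.df
        return self.obj["panel"]

    def write(self, key: str, path: Path):
        self.files[key] = path


def _stage_simulate(ctx: _Context, p: dict) -> None:
    spec = simulate.SimPanelSpec(
        seed=ctx.cfg.seed,
        n_species=p.get("n_species", 3),
        samples_per_species=tuple(np.atleast_1d(p.get("samples_per_species", 20)).tolist())
        if not isinstance(p.get("samples_per_species", 20), int)
        else p.get("samples_per_species", 20),
        n_sites=p.get("n_sites", 5000),
        chrom_lengths=p.get("chrom_lengths", {"chr1": 5_000_000}),
        fst=p.get("fst", 0.1),
        ancestral_af_range=tuple(p.get("ancestral_af_range", (0.05, 0.95))),
    )
    panel, sites = simulate.simulate_structured_panel(spec)
    if p.get("sweep"):
        sw = dict(p["sweep"])
        sw.setdefault("seed", ctx.cfg.seed)
        # snap the requested core to the nearest simulated site with a
        # derived allele in the target population
        idx = panel.nearest_site(sw["core_chrom"], sw["core_position"])
        rows = panel.haplotype_indices(sw["target_population"])
        if panel.haplotypes[rows, idx].sum() == 0:
            on_c = np.flatnonzero(panel.chrom == sw["core_chrom"])
            has_derived = on_c[panel.haplotypes[rows][:, on_c].sum(axis=0) > 0]
            idx = int(has_derived[np.argmin(np.abs(panel.pos[has_derived] - sw["core_position"]))])
        sw["core_position"] = int(panel.pos[idx])
        panel = simulate.implant_sweep(panel, simulate.SweepSpec(**sw))
    ctx.obj["panel"] = panel
    site_info = simulate.simulate_site_info(panel, seed=ctx.cfg.seed)
    ctx.obj["site_info"] = site_info

    K = gwas.centered_kinship(panel.dosages().astype(float)).K
    tr = dict(p.get("trait") or {})
    tr.setdefault("seed", ctx.cfg.seed)
    trait = simulate.simulate_trait(
        panel,
        simulate.TraitSimSpec(
            causal_sites={int(k): float(v) for k, v in (tr.get("causal_sites") or {}).items()},
            polygenic_var=tr.get("polygenic_var", 0.2),
            residual_var=tr.get("residual_var", 1.0),
            seed=tr["seed"],
        ),
        kinship=K,
    )
    sl = 10.0 + 2.0 * np.random.default_rng(ctx.cfg.seed).standard_normal(panel.n_samples)
    traits_df = pd.DataFrame(
        {
            "sample_id": panel.samples,
            "species": panel.species,
            "clade": "Diplotaxodon",
            "eye_diameter_cm": np.round(1.0 + 0.1 * trait.to_numpy(), 4),
            "standard_length_cm": np.round(np.abs(sl) + 1.0, 4),
        }
    )
    traits_df["trait"] = trait.to_numpy()
    ctx.obj["traits"] = traits_df

    genes, features, annotation = simulate.simulate_gene_models_and_effects(
        panel, n_genes=p.get("n_genes", 20), seed=ctx.cfg.seed
    )
    ctx.obj.update({"genes": genes, "features": features, "annotation": annotation})

    dp = dict(p.get("depth") or {})
    depth = simulate.simulate_depth_matrix(
        n_samples=panel.n_samples,
        n_sites=panel.n_sites,
        per_sample_mean=dp.get("per_sample_mean", 20.0),
        per_sample_sd=dp.get("per_sample_sd", 4.0),
        duplicated_sites=tuple(dp.get("duplicated_sites", ())),
        seed=ctx.cfg.seed,
        chrom=str(panel.chrom[0]),
        positions=panel.pos,
    )
    ctx.obj["depth"] = depth

    cs = dict(p.get("counts") or {})
    cs.setdefault("seed", ctx.cfg.seed)
    counts = simulate.simulate_counts(simulate.CountSimSpec(**cs))
    ctx.obj["counts"] = counts

    paths = simulate.emit_fixture_bundle(
        ctx.out,
        panel,
        site_info=site_info,
        genes=genes,
        features=features,
        annotation=annotation,
        traits=traits_df,
        depth=depth,
        counts=counts,
    )
    ctx.files.update(paths)


def _stage_qc(ctx: _Context, p: dict) -> None:
    panel = ctx.need_panel()
    cfg = qc.SiteFilterConfig(**(p.get("config") or {}))
    site_info = ctx.obj["site_info"].copy()
    if "ab_p" not in site_info.columns and {"ab_ref", "ab_alt"}.issubset(site_info.columns):
        site_info["ab_p"] = [
            qc.allele_balance_test([(r, a)]) if r + a > 0 else float("nan")
            for r, a in zip(site_info["ab_ref"], site_info["ab_alt"])
        ]
    retained, report = qc.apply_site_filters(site_info, ctx.obj.get("depth"), cfg)
    # filtered VCF: retained sites only, FILTER column annotating failed rules
    keep = np.flatnonzero(report.passed)
    filtered = panel.copy()
    filtered.haplotypes = filtered.haplotypes[:, keep]
    filtered.chrom = filtered.chrom[keep]
    filtered.pos = filtered.pos[keep]
    vpath = ctx.out / "panel.filtered.vcf"
    io.write_vcf(vpath, filtered, site_info.iloc[keep])
    ctx.write("filtered_vcf", vpath)
    out = ctx.out / "qc_report.tsv"
    pd.DataFrame(
        {
            "chrom": panel.chrom,
            "pos": panel.pos,
            "passed": report.passed,
            "failing_rules": [";".join(f) for f in report.failing_rules],
        }
    ).to_csv(out, sep="\t", index=False)
    ctx.obj["qc_passed"] = report.passed
    ctx.write("qc_report", out)


def _stage_disttree(ctx: _Context, p: dict) -> None:
    panel = ctx.need_panel()
    dos = panel.dosages().astype(float)
    D = phylo.pairwise_distance(dos, panel.samples)
    tree, support = phylo.window_bootstrap_support(
        dos, panel.samples, panel.chrom, panel.pos,
        window_bp=p.get("window_bp", 100_000),
        replicates=p.get("replicates", 100),
        seed=ctx.cfg.seed,
    )
    if p.get("outgroup"):
        tree = phylo.root_by_outgroup(tree, p["outgroup"])
    dpath = ctx.out / "distances.tsv"
    D.to_csv(dpath, sep="\t")
    tpath = ctx.out / "nj_tree.nwk"
    io.write_newick(tpath, tree)
    ctx.obj["tree"] = tree
    ctx.write("distances", dpath)
    ctx.write("tree", tpath)


def _stage_phylosig(ctx: _Context, p: dict) -> None:
    tree = ctx.obj.get("tree")
    if tree is None and ctx.cfg.inputs.get("tree"):
        tree = io.read_newick(ctx.cfg.inputs["tree"])
    if tree is None:
        raise RuntimeError("phylosig needs a tree: run 'disttree' or set inputs.tree")
    col = p.get("column", "trait")
    tdf = ctx.obj["traits"].set_index("sample_id")
    res = traits.pagel_lambda(tree, tdf[col])
    out = ctx.out / "phylosig.json"
    out.write_text(json.dumps({
        "lambda": res.lambda_hat, "sigma2": res.sigma2_hat, "mu": res.mu_hat,
        "loglik": res.loglik, "loglik_lambda0": res.loglik_lambda0,
        "loglik_lambda1": res.loglik_lambda1,
    }, indent=2) + "\n")
    ctx.write("phylosig", out)


def _stage_gwas(ctx: _Context, p: dict) -> None:
    panel = ctx.need_panel()
    col = p.get("column", "trait")
    y = ctx.obj["traits"].set_index("sample_id").loc[panel.samples, col].to_numpy(float)
    X = panel.dosages().astype(float)
    K = gwas.centered_kinship(X)
    assoc = gwas.lmm_scan(y, X, K, panel.chrom, panel.pos, maf_min=p.get("maf_min", 0.05))
    outliers, k = gwas.select_top_fraction(assoc, q=p.get("top_fraction", 0.01))
    apath = ctx.out / "assoc.tsv"
    assoc.to_csv(apath, sep="\t", index=False)
    opath = ctx.out / "outliers.tsv"
    outliers.to_csv(opath, sep="\t", index=False)
    ctx.obj["assoc"] = assoc
    ctx.obj["outliers"] = outliers
    ctx.write("assoc", apath)
    ctx.write("outliers", opath)


def _stage_pcacmp(ctx: _Context, p: dict) -> None:
    panel = ctx.need_panel()
    col = p.get("column", "trait")
    trait = ctx.obj["traits"].set_index("sample_id")[col]
    X = panel.dosages().astype(float)
    keep = gwas.maf_filter(X, 0.05)
    pruned = structure.ld_prune(X[:, keep])
    res_gw = structure.pca(X[:, keep[pruned]], panel.samples,
                           n_components=p.get("n_components", 10))
    summary = {"genomewide": structure.pc1_trait_regression(res_gw, trait)}
    if "outliers" in ctx.obj and len(ctx.obj["outliers"]):
        oidx = ctx.obj["outliers"]["site_index"].to_numpy()
        res_out = structure.pca(X[:, oidx], panel.samples,
                                n_components=min(p.get("n_components", 10), len(oidx)))
        summary["outliers"] = structure.pc1_trait_regression(res_out, trait)
        res_out.scores.to_csv(ctx.out / "pca_outliers.tsv", sep="\t")
    res_gw.scores.to_csv(ctx.out / "pca_genomewide.tsv", sep="\t")
    out = ctx.out / "pca_regression.json"
    out.write_text(json.dumps(summary, indent=2) + "\n")
    ctx.write("pca_regression", out)


def _stage_enrich(ctx: _Context, p: dict) -> None:
    ann = ctx.obj["annotation"]
    ann = ann[ann["maf"] > 0]
    outliers = ctx.obj.get("outliers")
    if outliers is None or not len(outliers):
        raise RuntimeError("enrich needs GWA outliers: run 'gwas' first")
    keys = set(zip(outliers["chrom"], outliers["pos"]))
    mask = [tuple(x) in keys for x in zip(ann["chrom"], ann["pos"])]
    test = ann[np.array(mask)]
    res = enr.maf_matched_permutation(
        test, ann, bin_width=p.get("bin_width", 0.05),
        n_perm=p.get("n_perm", 1000), seed=ctx.cfg.seed,
    )
    out = ctx.out / "enrichment.tsv"
    res.table.to_csv(out, sep="\t")
    ctx.write("enrichment", out)


def _stage_scan(ctx: _Context, p: dict) -> None:
    panel = ctx.need_panel()
    species = panel.species_names
    pop_a = p.get("pop_a", species[0])
    pop_b = p.get("pop_b", species[-1])
    pa = panel.subset_species([pop_a])
    pb = panel.subset_species([pop_b])
    xp = scan.xpehh_scan(pa, pb)
    null = scan.window_empirical_null(
        xp, panel.chrom_lengths, width=p.get("window_bp", 30_000),
        n_windows=p.get("null_windows", 10_000), seed=ctx.cfg.seed,
    )
    out = ctx.out / "xpehh.tsv"
    xp.to_csv(out, sep="\t", index=False)
    ctx.obj["xpehh"] = xp
    ctx.obj["window_null"] = null
    ctx.write("xpehh", out)
    if "outliers" in ctx.obj and len(ctx.obj["outliers"]):
        cand = scan.rank_candidate_windows(xp, ctx.obj["outliers"][["chrom", "pos"]], null)
        cpath = ctx.out / "candidates.tsv"
        cand.to_csv(cpath, sep="\t", index=False)
        ctx.write("candidates", cpath)


def _stage_expr(ctx: _Context, p: dict) -> None:
    cm = ctx.obj["counts"]
    filt = expr.filter_low_counts(cm, p.get("min_count", 5), p.get("min_samples", 3))
    de = expr.nb_wald_de(filt)
    top = expr.select_top_de(de, p.get("padj_max", 0.05), p.get("abs_lfc_min", 4.5))
    de.table.to_csv(ctx.out / "de.tsv", sep="\t")
    top.to_csv(ctx.out / "de_top.tsv", sep="\t")
    ctx.write("de", ctx.out / "de.tsv")
    ctx.write("de_top", ctx.out / "de_top.tsv")


_STAGE_FN = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "disttree": _stage_disttree,
    "phylosig": _stage_phylosig,
    "gwas": _stage_gwas,
    "pcacmp": _stage_pcacmp,
    "enrich": _stage_enrich,
    "scan": _stage_scan,
    "expr": _stage_expr,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages in order and write a manifest.

    A stage failure halts the run with the failing stage named; artifacts
    written so far are retained and listed in the manifest."""
    ctx = _Context(cfg)
    manifest = {"seed": cfg.seed, "stages": [], "artifacts": {}}
    try:
        for st in cfg.stages:
            log.info("running stage %s", st["name"])
            _STAGE_FN[st["name"]](ctx, st["params"])
            manifest["stages"].append({"name": st["name"], "params": st["params"]})
    except Exception as exc:
        manifest["failed_stage"] = st["name"]
        manifest["error"] = str(exc)
        raise RuntimeError(f"stage '{st['name']}' failed: {exc}") from exc
    finally:
        for key, path in ctx.files.items():
            if Path(path).exists():
                manifest["artifacts"][key] = {
                    "path": str(path),
                    "sha256": _sha256(Path(path)),
                }
        mpath = ctx.out / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
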