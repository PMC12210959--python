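# deepeye

Population-genomic and transcriptomic analysis of eye-size adaptation in
deepwater Lake Malawi cichlids (*Diplotaxodon*), packaged as a reusable,
fully tested Python library.

Deepwater *Diplotaxodon* species vary enormously in relative eye size
(7–13% of standard length), and the variation cuts across the species
phylogeny — a signature of parallel adaptation to depth. Linking that
phenotype to genotype takes a chain of analyses, each of which this
package implements from phased variant data down to eye-transcriptome
profiles:

- **Variant QC** — bcftools-style site filters (MQ < 50, MQ0F > 0.10,
  \>20% missing, excess-het < 0.2, strand-bias *P* < 0.001, heterozygote
  allele-balance *P* < 0.01) plus a *depth-deviation* score
  DD(s) = (1/N) Σᵢ (dᵢₛ − μᵢ)/σᵢ that removes collapsed duplications at
  DD > 1.5, and a median-coverage ratio check for suspected duplicated loci.
- **Genetic relationships** — allele-sharing distances
  d
  ᵢⱼ = mean |gᵢ − gⱼ|/2 over jointly called sites, Saitou–Nei
  neighbor joining, bootstrap support from resampling 100-kb genomic
  windows, and outgroup rooting.
- **Phylogenetic signal** — Pagel's λ by maximum likelihood under
  y ~ N(μ**1**, σ²C_λ), where C is the shared-branch-length matrix and λ
  scales its off-diagonal entries.
- **Association** — a GEMMA-style univariate linear mixed model
  y = Wα + xβ + u + ε with u ~ N(0, λᵥᵣτ⁻¹K) and centered kinship
  K = X_cX_cᵀ/p; per-SNP likelihood-ratio tests via one eigendecomposition
  of K; Bonferroni threshold α/M and top-fraction outlier selection
  (k = ⌊qM⌋, e.g. 190 SNPs at q = 10⁻⁴ for M = 1,900,366).
- **Structure contrast** — plink-style LD pruning (50-SNP windows, step
  10, r² > 0.1), variance-standardized PCA, and OLS of the trait on PC1
  for outlier-SNP versus genome-wide variation.
- **Annotation enrichment** — the MAF-matched permutation test: random
  SNP sets drawn from the callset matched to the outlier set's minor-allele
  frequency histogram (bins of 0.05) give an empirical null for per-effect
  counts; fold ratio = observed/mean(null), empirical *P* = fraction of
  draws strictly exceeding the observed count. Plus TSS ± 25 kb gene
  mapping and derived-allele segregation χ² tests.
- **Selection scans** — EHH, iHH, iHS (standardized in derived-frequency
  bins of 0.025), site-EHH/iES and XP-EHH, written from scratch, with the
  empirical null built from 10,000 random 30-kb windows and candidate-window
  ranking at the 0.95/0.05 quantiles.
- **Expression** — CDS-based TPM, a simplified negative-binomial Wald DE
  stage (median-of-ratios size factors, method-of-moments dispersion),
  the |log2FC| > 4.5 top-gene rule, and rod/cone opsin expression palettes
  with the two RH2A copies merged.
- **Synthetic data** — a first-class generator (Balding–Nichols structured
  panels, haplotype-copy selective sweeps, polygenic traits, Brownian
  traits with a set λ, gene models with annotation labels, depth matrices
  with planted duplications, NB count matrices) so every stage is testable
  without any external download.

## Worked example

`examples/` holds one short script per capability. For instance the
selection scan (`python examples/07_selection_scan.py`):

```
iHS in the swept population at the core (80% sweep): -3.41 (negative = long derived haplotypes)
standardized XP-EHH at the core: -4.42 (negative = selection in population B)
candidate window min score -7.84, null quantile 0.0079 -> flagged: True
```

A completed sweep implanted in population B produces long shared
haplotypes there: the within-population iHS at the core is strongly
negative, the cross-population XP-EHH (A vs B) is negative, and the 30-kb
candidate window falls below the 0.05 quantile of the 10,000-random-window
null — the criterion for calling recent divergent selection.

And the association stage (`python examples/04_gwas_outliers.py`):

```
tested 4727 SNPs after MAF >= 5% filtering
Bonferroni threshold (FWER 0.05): 1.06e-05
top association: chr1:276476 p = 3.38e-08 (planted causal site: chr1:276476)
significant at Bonferroni: 2 SNPs
top 0.1% outlier set: k = 4 SNPs; causal included: True
```

The planted causal variant (≈40% of trait variance) tops the scan and
clears the Bonferroni line; the top-fraction rule then fixes the outlier
set size deterministically.

The whole chain can also be run end to end from one YAML config:

```bash
deepeye run --config pipeline.yaml     # or: python -m deepeye.cli run ...
```

which executes simulate → qc → disttree → phylosig → gwas → pcacmp →
enrich → scan → expr and writes a manifest with SHA-256 checksums
(identical config + seed ⇒ identical checksums).

## Limitations

Read alignment, variant calling, phasing, snpEff annotation, GO-term
enrichment and the exact DESeq2 shrinkage estimators are out of scope:
their outputs are consumed as inputs (or replaced by a documented
simplified stage, for DE). See `docs/methods.md` for the models,
parameter choices, and what the synthetic data does and does not emulate.
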