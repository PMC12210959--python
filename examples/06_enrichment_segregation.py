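"""MAF-matched annotation enrichment and derived-allele segregation.

The enrichment test draws random SNP sets from the callset matched to the
outlier set's MAF histogram, giving a null for per-effect counts; the
fold ratio is observed / mean(null).  The segregation test asks whether
sites where the derived allele dominates big-eyed species cluster in one
gene class.
"""

import numpy as np
import pandas as pd

from deepeye import enrichment as enr
from deepeye import simulate

panel, _ = simulate.simulate_structured_panel(
    simulate.SimPanelSpec(seed=6, n_species=4, samples_per_species=8, n_sites=3000,
                          chrom_lengths={"chr1": 3_000_000}, fst=0.1)
)
genes, features, annotation = simulate.simulate_gene_models_and_effects(panel, 25, seed=6)
annotation = annotation[annotation["maf"] > 0]

# outlier set enriched for missense labels (mimicking trait-associated SNPs)
rng = np.random.default_rng(6)
is_mis = annotation["effects"].str.contains("missense")
test = pd.concat([
    annotation[is_mis].sample(30, random_state=1),
    annotation[~is_mis].sample(60, random_state=2),
])
res = enr.maf_matched_permutation(test, annotation, n_perm=1000, seed=6)
row = res.table.loc["missense_variant"]
print(f"missense: observed {row['observed']}, null mean {row['null_mean']:.1f}, "
      f"ratio {row['ratio']:.1f}x, empirical P {row['p_string']}")

gene_set = enr.map_outliers_to_genes(test, genes, tss_window=25_000)
print(f"genes with TSS within 25 kb of an outlier: {len(gene_set)}")

af = enr.derived_af_by_species(panel, list(range(10)))
groups = {"sp1": "big", "sp2": "big", "sp3": "small", "sp4": "small"}
classes = {site: ("vision" if i < 5 else "muscle") for i, site in enumerate(af.index)}
seg = enr.segregation_test(af, groups, classes)
print("\ndominance-group contingency (gene class x eye-size group):")
print(seg.contingency)
print(f"chi-square = {seg.chi2:.2f}, p = {seg.p:.3f}")
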