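"""Eye-transcriptome profiling: DE stage and opsin visual palettes.

Simulates a 5-vs-5 count matrix with a handful of strongly DE genes and a
designated opsin set whose expression shares differ between groups (the
small-eyed group expresses both green opsins, the big-eyed group almost
only rh2b), then runs the filter -> DE -> top-gene -> palette chain.
"""

import numpy as np

from deepeye import expression as ex
from deepeye import simulate

opsin_ids = {
    "rh1": "g00001", "sws1": "g00002", "sws2a": "g00003", "sws2b": "g00004",
    "rh2a_alpha": "g00005", "rh2a_beta": "g00006", "rh2b": "g00007", "lws": "g00008",
}
lfc = np.zeros(1200)
lfc[100:105] = 5.0   # overexpressed in group 2
lfc[105:110] = -5.0  # underexpressed in group 2
spec = simulate.CountSimSpec(
    n_genes=1200, group_sizes=(5, 5), dispersion=0.1, log2fc=lfc,
    opsin_ids=opsin_ids,
    opsin_tpm_shares={
        "group1": {"rh1": 200.0, "rh2a_alpha": 4.0, "rh2a_beta": 5.0, "rh2b": 1.0,
                   "sws1": 0.001, "sws2a": 0.001, "sws2b": 0.001, "lws": 0.001},
        "group2": {"rh1": 400.0, "rh2a_alpha": 0.01, "rh2a_beta": 0.01, "rh2b": 3.0,
                   "sws1": 0.001, "sws2a": 0.001, "sws2b": 0.001, "lws": 0.001},
    },
    seed=8,
)
cm = simulate.simulate_counts(spec)

filt = ex.filter_low_counts(cm)
print(f"{filt.n_genes} of {cm.n_genes} genes pass the low-count filter")

de = ex.nb_wald_de(filt)
n_de = (de.table["padj"] < 0.05).sum()
top = ex.select_top_de(de, padj_max=0.05, abs_lfc_min=4.5)
print(f"{n_de} genes DE at FDR < 0.05; {len(top)} with |log2FC| > 4.5 (> ~23-fold)")
print("strongest:", top.head(3)["log2fc"].round(2).to_dict())

tpm = ex.tpm_normalize(filt if all(g in filt.counts.index for g in opsin_ids.values()) else cm)
prof = ex.opsin_palette(tpm, opsin_ids, groups=cm.groups)
print("\nopsin expression shares, median [min-max] per group:")
for _, row in prof.group_summary.query("measure in ('rod_share','cone_share_rh2a','cone_share_rh2b')").iterrows():
    print(f"  {row['group']:>7} {row['measure']:<18} {row['formatted']}")
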