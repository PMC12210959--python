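"""MAF-matched permutation enrichment, TSS-window gene mapping, and the
derived-allele segregation chi-square."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from deepeye import enrichment as enr
from deepeye import simulate


class TestMafBins:
    def test_bin_edges_half_open(self):
        # bin b covers (b*w, (b+1)*w]: 0.05 falls in the first bin
        bins = enr.maf_bins(np.array([0.01, 0.05, 0.051, 0.5]))
        assert bins.tolist() == [0, 0, 1, 9]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            enr.maf_bins(np.array([0.0]))
        with pytest.raises(ValueError):
            enr.maf_bins(np.array([0.6]))


def snp_table(mafs, effects):
    return pd.DataFrame({"maf": mafs, "effects": effects})


class TestMatchedPermutation:
    def test_matched_histogram_invariant(self, rng):
        control = snp_table(rng.uniform(0.01, 0.5, 500), ["intron_variant"] * 500)
        test = control.iloc[rng.choice(500, 40, replace=False)]
        tb = enr.maf_bins(test["maf"].to_numpy())
        cb = enr.maf_bins(control["maf"].to_numpy())
        counts = pd.Series(tb).value_counts().to_dict()
        for _ in range(20):
            draw = enr.draw_matched_set(cb, counts, rng)
            db = pd.Series(cb[draw]).value_counts().to_dict()
            assert db == counts

    def test_degenerate_all_labelled_control(self):
        control = snp_table([0.1, 0.2, 0.3, 0.4], ["missense_variant"] * 4)
        test = control.iloc[:2]
        res = enr.maf_matched_permutation(test, control, n_perm=50, seed=1)
        row = res.table.loc["missense_variant"]
        assert row["observed"] == 2
        assert row["p_empirical"] == 0.0
        assert row["ratio"] == pytest.approx(1.0)
        assert row["p_string"].startswith("<")

    def test_exhaustive_enumeration_oracle(self):
        # 4 control SNPs in one MAF bin, 2 labelled; test set of 2 with 1
        # labelled: P(null count > 1) = P(both labelled) = C(2,2)/C(4,2) = 1/6
        control = snp_table(
            [0.21, 0.22, 0.23, 0.24],
            ["missense_variant", "missense_variant", "intron_variant", "intron_variant"],
        )
        test = snp_table([0.21, 0.22], ["missense_variant", "intron_variant"])
        res = enr.maf_matched_permutation(test, control, n_perm=6000, seed=3)
        exact = sum(
            1 for pair in combinations(range(4), 2) if pair == (0, 1)
        ) / len(list(combinations(range(4), 2)))
        got = res.table.loc["missense_variant", "p_empirical"]
        assert got == pytest.approx(exact, abs=0.02)

    def test_p_monotone_in_observed_count(self, rng):
        control = snp_table(
            rng.uniform(0.01, 0.5, 300), np.where(rng.random(300) < 0.4, "missense_variant", "intron_variant")
        )
        null = enr.maf_matched_permutation(
            control.iloc[:30], control, n_perm=300, seed=5
        ).null_counts["missense_variant"].to_numpy()
        ps = [(null > k).mean() for k in range(0, 30)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_underpopulated_bin_errors(self):
        control = snp_table([0.1], ["intron_variant"])
        test = snp_table([0.1, 0.12], ["intron_variant", "intron_variant"])
        with pytest.raises(ValueError, match="bin"):
            enr.maf_matched_permutation(test, control, n_perm=10, seed=0)


class TestMapOutliersToGenes:
    GENES = pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3"],
            "chrom": ["chr1", "chr1", "chr1"],
            "tss": [110_000, 125_000, 126_001],
        }
    )

    def test_inclusive_boundary_at_25kb(self):
        out = pd.DataFrame({"chrom": ["chr1"], "pos": [100_000]})
        got = enr.map_outliers_to_genes(out, self.GENES)
        assert got == ["g1", "g2"]  # 10 kb and exactly 25 kb in; 26,001 out

    def test_other_chromosome_excluded(self):
        out = pd.DataFrame({"chrom": ["chr2"], "pos": [110_000]})
        assert enr.map_outliers_to_genes(out, self.GENES) == []

    def test_deduplicated_across_outliers(self):
        out = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [109_000, 111_000]})
        # both outliers hit all three genes; each gene reported once
        assert enr.map_outliers_to_genes(out, self.GENES) == ["g1", "g2", "g3"]


class TestDerivedAf:
    def test_af_and_min_samples(self, tiny_panel):
        panel, _ = tiny_panel
        af = enr.derived_af_by_species(panel, [0, 1, 2])
        for sp in panel.species_names:
            rows = panel.haplotype_indices(sp)
            assert af.iloc[0][sp] == pytest.approx(panel.haplotypes[rows, 0].mean())

    def test_single_sample_species_missing(self, tiny_panel):
        panel, _ = tiny_panel
        sub = panel.copy()
        sub.species = np.array(["solo", "sp1", "sp1", "sp2", "sp2", "sp2"])
        af = enr.derived_af_by_species(sub, [0])
        assert np.isnan(af.iloc[0]["solo"])

    def test_polarization_flip_symmetry(self, tiny_panel):
        panel, _ = tiny_panel
        flipped = panel.copy()
        flipped.haplotypes[:, 0] = 1 - flipped.haplotypes[:, 0]
        a = enr.derived_af_by_species(panel, [0]).iloc[0]
        b = enr.derived_af_by_species(flipped, [0]).iloc[0]
        assert np.allclose(a.to_numpy(), 1 - b.to_numpy())


class TestSegregation:
    GROUPS = {"spA": "big", "spB": "big", "spC": "small", "spD": "small"}

    def test_balanced_counts_chi2_zero(self):
        af = pd.DataFrame(
            {
                "spA": [0.9, 0.1, 0.9, 0.1],
                "spB": [0.9, 0.1, 0.9, 0.1],
                "spC": [0.1, 0.9, 0.1, 0.9],
                "spD": [0.1, 0.9, 0.1, 0.9],
            },
            index=["s1", "s2", "s3", "s4"],
        )
        classes = {"s1": "vision", "s2": "vision", "s3": "muscle", "s4": "muscle"}
        res = enr.segregation_test(af, self.GROUPS, classes)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        # contingency [[11, 1], [7, 27]]: chi2 = sum (O-E)^2 / E from marginals
        obs = np.array([[11, 1], [7, 27]], dtype=float)
        row = obs.sum(1, keepdims=True)
        col = obs.sum(0, keepdims=True)
        E = row @ col / obs.sum()
        expected_chi2 = ((obs - E) ** 2 / E).sum()

        sites, classes, af_rows = [], {}, {}
        k = 0
        for cls, (n_big, n_small) in (("vision", (11, 1)), ("muscle", (7, 27))):
            for grp, n in (("big", n_big), ("small", n_small)):
                for _ in range(n):
                    sid = f"s{k}"
                    k += 1
                    classes[sid] = cls
                    if grp == "big":
                        af_rows[sid] = {"spA": 0.9, "spB": 0.9, "spC": 0.1, "spD": 0.1}
                    else:
                        af_rows[sid] = {"spA": 0.1, "spB": 0.1, "spC": 0.9, "spD": 0.9}
        af = pd.DataFrame(af_rows).T
        res = enr.segregation_test(af, self.GROUPS, classes)
        assert res.chi2 == pytest.approx(expected_chi2)
        assert res.contingency.loc["vision", "big"] == 11
        assert res.contingency.loc["muscle", "small"] == 27

    def test_tie_unassigned(self):
        af = pd.DataFrame(
            {"spA": [0.9, 0.9], "spB": [0.1, 0.9], "spC": [0.9, 0.1], "spD": [0.1, 0.1]},
            index=["s1", "s2"],
        )
        res = enr.segregation_test(af, self.GROUPS, {"s1": "vision", "s2": "vision"})
        # s1: one big-dominant, one small-dominant -> tie -> unassigned
        assert res.site_groups["s1"] == "unassigned"
        assert res.site_groups["s2"] == "big"
        assert res.goodness_of_fit.iloc[0]["n_sites"] == 1
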