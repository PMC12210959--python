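"""Generator statistics: differentiation level, sweep structure, trait
variance decomposition, Brownian-trait moments, annotations, depths, counts."""

import numpy as np
import pandas as pd
import pytest

from deepeye import qc, scan, simulate
from deepeye.traits import shared_branch_covariance


def hudson_fst(p1, p2, n1, n2):
    """Textbook Hudson FST estimator (ratio of averages) on allele freqs."""
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num.sum() / den.sum()


class TestStructuredPanel:
    def test_fst_zero_frequencies_match_ancestral(self):
        spec = simulate.SimPanelSpec(
            seed=3, n_species=2, samples_per_species=50, n_sites=1500, fst=0.0
        )
        panel, sites = simulate.simulate_structured_panel(spec)
        anc = sites.df["ancestral_af"].to_numpy()
        for sp in panel.species_names:
            f = panel.derived_frequency(sp)
            # binomial sampling error around the ancestral frequency
            se = np.sqrt(anc * (1 - anc) / 100)
            assert np.mean(np.abs(f - anc) < 4 * se) > 0.99
            assert abs((f - anc).mean()) < 0.01

    def test_same_seed_bit_identical(self):
        spec = simulate.SimPanelSpec(seed=5, n_sites=300)
        a, _ = simulate.simulate_structured_panel(spec)
        b, _ = simulate.simulate_structured_panel(simulate.SimPanelSpec(seed=5, n_sites=300))
        assert a == b

    def test_hudson_fst_matches_target(self):
        spec = simulate.SimPanelSpec(
            seed=2, n_species=3, samples_per_species=20, n_sites=5000, fst=0.1
        )
        panel, _ = simulate.simulate_structured_panel(spec)
        freqs = [panel.derived_frequency(sp) for sp in panel.species_names]
        ests = [
            hudson_fst(freqs[i], freqs[j], 40, 40)
            for i in range(3)
            for j in range(i + 1, 3)
        ]
        assert abs(np.mean(ests) - 0.1) < 0.02

    def test_balding_nichols_variance(self):
        # per-species frequency variance ~ p(1-p) * FST over many sites
        spec = simulate.SimPanelSpec(
            seed=9, n_species=8, samples_per_species=2, n_sites=10_000, fst=0.15,
            ancestral_af_range=(0.5, 0.5),
        )
        panel, sites = simulate.simulate_structured_panel(spec)
        # estimate the latent Beta variance from the spread of species freqs
        # using many species per site; sample noise (n=4 haplotypes) inflates
        # the raw variance by p(1-p)(1-F)/4 on average, subtract it out
        freqs = np.stack([panel.derived_frequency(sp) for sp in panel.species_names])
        raw_var = freqs.var(axis=0, ddof=1).mean()
        noise = (0.25 * (1 - 0.15)) / 4
        assert abs((raw_var - noise) - 0.25 * 0.15) < 0.005

    def test_positions_sorted_unique_within_bounds(self, small_panel):
        panel, _ = small_panel
        assert np.all(np.diff(panel.pos) > 0)
        assert panel.pos.max() <= panel.chrom_lengths["chr1"]

    def test_invalid_fst_rejected(self):
        with pytest.raises(ValueError, match="fst"):
            simulate.SimPanelSpec(fst=1.0)


class TestImplantSweep:
    @staticmethod
    def _core(panel):
        mid = panel.n_sites // 2
        rows = panel.haplotype_indices("sp1")
        # nearest site where sp1 carries the derived allele
        has = np.flatnonzero(panel.haplotypes[rows].sum(axis=0) > 0)
        j = has[np.argmin(np.abs(has - mid))]
        return int(j), int(panel.pos[j])

    def test_zero_carrier_fraction_noop(self, small_panel):
        panel, _ = small_panel
        _, pos = self._core(panel)
        out = simulate.implant_sweep(
            panel,
            simulate.SweepSpec("sp1", "chr1", pos, carrier_fraction=0.0, seed=1),
        )
        assert out == panel

    def test_full_sweep_identical_haplotypes(self, small_panel):
        panel, _ = small_panel
        j, pos = self._core(panel)
        out = simulate.implant_sweep(
            panel,
            simulate.SweepSpec(
                "sp1", "chr1", pos, carrier_fraction=1.0, decay_length=1e9, seed=1
            ),
        )
        rows = out.haplotype_indices("sp1")
        assert (out.haplotypes[rows] == out.haplotypes[rows[0]]).all()
        # EHH of the derived core allele is 1 across the whole region
        curves = scan.ehh_decay(out.haplotypes[rows], out.pos, j, 1)
        assert np.all(curves["left"][1] == 1.0)
        assert np.all(curves["right"][1] == 1.0)

    def test_frequency_conservation(self, small_panel):
        panel, _ = small_panel
        j, pos = self._core(panel)
        out = simulate.implant_sweep(
            panel,
            simulate.SweepSpec("sp1", "chr1", pos, carrier_fraction=0.8, seed=4),
        )
        rows = out.haplotype_indices("sp1")
        assert out.haplotypes[rows, j].mean() >= 0.8
        for sp in ("sp2", "sp3"):
            other = panel.haplotype_indices(sp)
            assert np.array_equal(out.haplotypes[other], panel.haplotypes[other])

    def test_monomorphic_ancestral_core_rejected(self, small_panel):
        panel, _ = small_panel
        p2 = panel.copy()
        rows = p2.haplotype_indices("sp1")
        p2.haplotypes[rows, 5] = 0
        with pytest.raises(ValueError, match="monomorphic"):
            simulate.implant_sweep(
                p2, simulate.SweepSpec("sp1", "chr1", int(p2.pos[5]), 0.5, seed=0)
            )


class TestSimulateTrait:
    def test_null_trait_uncorrelated_with_dosages(self, small_panel):
        panel, _ = small_panel
        y = simulate.simulate_trait(
            panel, simulate.TraitSimSpec(residual_var=1.0, seed=2)
        ).to_numpy()
        X = panel.dosages().astype(float)
        sd = X.std(axis=0)
        ok = sd > 0
        r = ((X[:, ok] - X[:, ok].mean(0)) * (y - y.mean())[:, None]).mean(0) / (
            sd[ok] * y.std()
        )
        assert np.mean(np.abs(r) < 0.5) >= 0.99

    def test_single_causal_variance_share(self):
        # expected 50% variance share: sample R^2 in [0.35, 0.65] at n=200
        spec = simulate.SimPanelSpec(seed=21, n_species=1, samples_per_species=200, n_sites=50)
        panel, _ = simulate.simulate_structured_panel(spec)
        X = panel.dosages().astype(float)
        j = int(np.argmin(np.abs(X.mean(0) / 2 - 0.5)))
        beta = np.sqrt(1.0 / X[:, j].var())  # beta^2 var(x) = residual var = 1
        y = simulate.simulate_trait(
            panel, simulate.TraitSimSpec(causal_sites={j: beta}, residual_var=1.0, seed=3)
        ).to_numpy()
        r2 = np.corrcoef(X[:, j], y)[0, 1] ** 2
        assert 0.35 < r2 < 0.65

    def test_seed_reproducibility(self, small_panel):
        panel, _ = small_panel
        a = simulate.simulate_trait(panel, simulate.TraitSimSpec(seed=9))
        b = simulate.simulate_trait(panel, simulate.TraitSimSpec(seed=9))
        assert a.equals(b)


class TestBrownianTrait:
    def test_lambda_zero_kills_cross_tip_covariance(self):
        tree = simulate.random_tree(6, seed=1)
        draws = np.stack(
            [simulate.simulate_bm_trait(tree, 0.0, seed=s).to_numpy() for s in range(2000)]
        )
        cov = np.cov(draws.T)
        off = cov[~np.eye(6, dtype=bool)]
        C, _ = shared_branch_covariance(tree)
        assert np.abs(off).max() < 0.15 * np.diag(C).max()

    def test_lambda_one_matches_tree_covariance(self):
        tree = simulate.random_tree(6, seed=2)
        C, tips = shared_branch_covariance(tree)
        draws = np.stack(
            [simulate.simulate_bm_trait(tree, 1.0, seed=s).to_numpy() for s in range(2000)]
        )
        cov = np.cov(draws.T)
        # MVN moment check: elementwise within Monte-Carlo error
        se = np.sqrt((np.outer(np.diag(C), np.diag(C)) + C**2) / 2000)
        assert np.all(np.abs(cov - C) < 5 * se)

    def test_seed_reproducibility(self):
        tree = simulate.random_tree(10, seed=3)
        a = simulate.simulate_bm_trait(tree, 0.7, seed=4)
        assert a.equals(simulate.simulate_bm_trait(tree, 0.7, seed=4))


@pytest.fixture(scope="module")
def annotated(small_panel):
    panel, _ = small_panel
    return panel, simulate.simulate_gene_models_and_effects(panel, n_genes=8, seed=13)


class TestGeneModels:

    def test_intergenic_far_from_genes(self, annotated):
        panel, (genes, features, ann) = annotated
        flank = 5000
        for _, row in ann.iterrows():
            near = genes[
                (genes["chrom"] == row["chrom"])
                & (genes["start"] - flank <= row["pos"])
                & (row["pos"] <= genes["end"] + flank)
            ]
            if near.empty:
                assert row["effects"] == "intergenic_region"
            else:
                assert "intergenic_region" not in row["effects"]

    def test_cds_snps_coding_effect(self, annotated):
        panel, (genes, features, ann) = annotated
        cds = features[features["type"] == "CDS"]
        hits = 0
        for _, row in ann.iterrows():
            in_cds = (
                (cds["start"] <= row["pos"]) & (row["pos"] <= cds["end"])
            ).any() and (
                genes.set_index("gene_id").loc[
                    cds[(cds["start"] <= row["pos"]) & (row["pos"] <= cds["end"])]["gene_id"],
                    "chrom",
                ]
                == row["chrom"]
            ).any()
            if in_cds:
                hits += 1
                labels = set(row["effects"].split(";"))
                assert labels & {"missense_variant", "synonymous_variant"}
        assert hits > 0

    def test_label_counts_at_least_n_snps(self, annotated):
        panel, (_, _, ann) = annotated
        total = sum(len(e.split(";")) for e in ann["effects"])
        assert total >= len(ann)
        assert len(ann) == panel.n_sites

    def test_gene_density_error(self, small_panel):
        panel, _ = small_panel
        with pytest.raises(ValueError, match="fit"):
            simulate.simulate_gene_models_and_effects(panel, n_genes=500, seed=0)


class TestDepthMatrix:
    def test_no_duplication_near_zero_scores(self):
        d = simulate.simulate_depth_matrix(10, 200, 30.0, 0.0, seed=1)
        assert np.abs(qc.depth_deviation(d)).max() < 1e-3

    def test_planted_duplication_scores_high(self):
        d = simulate.simulate_depth_matrix(10, 200, 20.0, 2.0, duplicated_sites=(50,), seed=2)
        dd = qc.depth_deviation(d)
        assert dd[50] > 1.5  # expected z ~ mean/sd = 10
        assert dd[50] > 5

    def test_seed_reproducibility(self):
        a = simulate.simulate_depth_matrix(5, 50, 20.0, 4.0, seed=3)
        b = simulate.simulate_depth_matrix(5, 50, 20.0, 4.0, seed=3)
        assert np.array_equal(a.depths, b.depths)


class TestSimulateCounts:
    def test_all_zero_gene_removed_by_filter(self):
        from deepeye import expression as ex

        cm = simulate.simulate_counts(simulate.CountSimSpec(n_genes=50, seed=4))
        cm.counts.iloc[0] = 0
        filt = ex.filter_low_counts(cm)
        assert cm.counts.index[0] not in filt.counts.index

    def test_group_sizes_and_determinism(self):
        cm = simulate.simulate_counts(simulate.CountSimSpec(n_genes=30, group_sizes=(4, 6), seed=5))
        assert cm.counts.shape == (30, 10)
        assert (cm.groups.value_counts()[["group1", "group2"]] == [4, 6]).all()
        cm2 = simulate.simulate_counts(simulate.CountSimSpec(n_genes=30, group_sizes=(4, 6), seed=5))
        assert cm.counts.equals(cm2.counts)


class TestFixtureBundle:
    def test_round_trip_idempotent(self, tiny_panel, tmp_path):
        from deepeye import io as dio

        panel, _ = tiny_panel
        info = simulate.simulate_site_info(panel, seed=1)
        tree = simulate.random_tree(5, seed=1)
        paths = simulate.emit_fixture_bundle(tmp_path, panel, site_info=info, tree=tree)
        text1 = paths["vcf"].read_text()
        assert all("|" in line.split("\t", 9)[-1] for line in text1.splitlines() if not line.startswith("#"))
        panel2, sites2 = dio.read_vcf(paths["vcf"], dict(zip(panel.samples, panel.species)))
        assert panel2 == panel
        out2 = tmp_path / "again"
        paths2 = simulate.emit_fixture_bundle(out2, panel2, site_info=sites2.df)
        assert paths2["vcf"].read_text() == text1
        t2 = dio.read_newick(paths["tree"])
        assert {t.name for t in t2.tips()} == {f"t{i}" for i in range(1, 6)}
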