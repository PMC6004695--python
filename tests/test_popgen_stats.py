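"""Per-site estimators against closed forms and brute-force oracles, site
filtering rules, and per-gene aggregation behaviour."""

import numpy as np
import pandas as pd
import pytest

from cavescan.popgen_stats import (
    compute_per_gene_stats,
    dxy_per_gene,
    filter_sites,
    fst_per_gene,
    per_site_dxy,
    per_site_pi,
    per_site_wc_components,
    pi_per_gene,
    read_vcf,
)
from cavescan.synthetic_data import SimulationConfig, simulate_genotypes, write_vcf

from conftest import make_annotation, make_dataset


# ---------------------------------------------------------------------------
# brute-force oracles: direct allele-pair counting
# ---------------------------------------------------------------------------

def brute_pi(n, ac):
    """Probability two distinct sampled alleles differ."""
    pairs = n * (n - 1) / 2
    diff = ac * (n - ac)
    return diff / pairs


def brute_dxy(n1, ac1, n2, ac2):
    """Probability one allele from each population differ."""
    return (ac1 * (n2 - ac2) + (n1 - ac1) * ac2) / (n1 * n2)


def wc_oracle(n1, ac1, n2, ac2):
    """Textbook two-population Weir-Cockerham ANOVA on allele counts,
    written independently of the package's vectorised components."""
    r = 2
    p1, p2 = ac1 / n1, ac2 / n2
    nt = n1 + n2
    pbar = (ac1 + ac2) / nt
    msp = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (r - 1)
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (nt - r)
    nc = (nt - (n1 ** 2 + n2 ** 2) / nt) / (r - 1)
    denom = msp + (nc - 1) * msg
    return (msp - msg), denom


class TestPerSiteEstimators:
    def test_pi_closed_form(self):
        # n = 10 alleles, alt count 5 -> 2 * 0.5 * 0.5 * 10/9
        pi = per_site_pi(np.array([10]), np.array([5]))
        assert pi[0] == pytest.approx(5.0 / 9.0, abs=1e-12)

    def test_pi_monomorphic_is_zero(self):
        assert per_site_pi(np.array([20]), np.array([0]))[0] == 0.0
        assert per_site_pi(np.array([20]), np.array([20]))[0] == 0.0

    def test_pi_skips_sites_with_fewer_than_two_alleles(self):
        assert np.isnan(per_site_pi(np.array([1]), np.array([1]))[0])

    @pytest.mark.parametrize("ac1,n1,ac2,n2,expected", [
        (10, 10, 0, 10, 1.0),       # fixed difference
        (5, 10, 5, 10, 0.5),        # p1 = p2 = 0.5
        (3, 10, 8, 10, 0.62),       # 0.3*0.2 + 0.8*0.7
    ])
    def test_dxy_closed_forms(self, ac1, n1, ac2, n2, expected):
        d = per_site_dxy(np.array([n1]), np.array([ac1]), np.array([n2]), np.array([ac2]))
        assert d[0] == pytest.approx(expected, abs=1e-12)

    def test_fst_fixed_difference_is_one(self):
        num, den = per_site_wc_components(
            np.array([20]), np.array([20]), np.array([20]), np.array([0]))
        assert num[0] / den[0] == pytest.approx(1.0, abs=1e-12)

    def test_fst_equal_frequencies_nonpositive(self):
        num, den = per_site_wc_components(
            np.array([20]), np.array([10]), np.array([20]), np.array([10]))
        assert num[0] / den[0] <= 0

    def test_per_site_values_match_bruteforce_oracles(self, rng):
        n1 = rng.integers(4, 60, 100) * 2
        n2 = rng.integers(4, 60, 100) * 2
        ac1 = rng.integers(0, n1 + 1)
        ac2 = rng.integers(0, n2 + 1)
        np.testing.assert_allclose(
            per_site_pi(n1, ac1), brute_pi(n1, ac1), atol=1e-10)
        np.testing.assert_allclose(
            per_site_dxy(n1, ac1, n2, ac2), brute_dxy(n1, ac1, n2, ac2), atol=1e-10)
        num, den = per_site_wc_components(n1, ac1, n2, ac2)
        onum, oden = wc_oracle(n1.astype(float), ac1.astype(float),
                               n2.astype(float), ac2.astype(float))
        np.testing.assert_allclose(num, onum, atol=1e-10)
        np.testing.assert_allclose(den, oden, atol=1e-10)


class TestPerGeneAggregation:
    def test_gene_mean_of_per_site_pi(self, one_gene_annotation):
        # one site with pi = 0.5 * (10/9 correction undone by using n large)
        # three monomorphic sites -> per-gene mean = pi_site / 4
        ds = make_dataset([
            ("chr1", 10, 10, 5, 10, 0),
            ("chr1", 20, 10, 0, 10, 0),
            ("chr1", 30, 10, 0, 10, 0),
            ("chr1", 40, 10, 0, 10, 0),
        ])
        pi = pi_per_gene(ds, one_gene_annotation, 0)
        assert pi["geneA"] == pytest.approx((5.0 / 9.0) / 4.0, abs=1e-12)

    def test_dxy_symmetric_under_population_swap(self, rng, one_gene_annotation):
        rows = [("chr1", int(p), 20, int(rng.integers(0, 21)),
                 30, int(rng.integers(0, 31))) for p in range(1, 50)]
        ds = make_dataset(rows)
        d1 = dxy_per_gene(ds, one_gene_annotation)
        d2 = dxy_per_gene(ds.swapped(), one_gene_annotation)
        assert d1["geneA"] == d2["geneA"]

    def test_fst_weighted_vs_mean_methods_differ_in_general(self, one_gene_annotation):
        ds = make_dataset([
            ("chr1", 10, 20, 20, 20, 0),
            ("chr1", 20, 20, 10, 20, 9),
        ])
        w = fst_per_gene(ds, one_gene_annotation, method="weighted")["geneA"]
        m = fst_per_gene(ds, one_gene_annotation, method="mean")["geneA"]
        assert w != m

    def test_gene_without_sites_is_missing_not_zero(self):
        ann = make_annotation([("chr1", 0, 100, "gA"), ("chr1", 200, 300, "gB")])
        ds = make_dataset([("chr1", 10, 10, 5, 10, 5)])
        stats = compute_per_gene_stats(ds, ann)
        row = stats.set_index("gene_id").loc["gB"]
        assert row["n_retained_sites"] == 0
        assert np.isnan(row["pi_pop1"]) and np.isnan(row["fst"]) and np.isnan(row["dxy"])

    def test_monomorphic_gene_fst_missing(self, one_gene_annotation):
        ds = make_dataset([("chr1", 10, 10, 0, 10, 0)])
        assert np.isnan(fst_per_gene(ds, one_gene_annotation)["geneA"])

    def test_bounds_invariants_on_random_data(self, rng):
        cfg = SimulationConfig(seed=9, n_genes=50, sites_per_gene=20,
                               geneset_size=10, planted_outlier_fraction=0.1)
        sim = simulate_genotypes(cfg)
        stats = compute_per_gene_stats(sim.dataset, sim.annotation)
        ok = stats.dropna()
        assert ((ok["pi_pop1"] >= 0) & (ok["pi_pop1"] <= 1)).all()
        assert ((ok["pi_pop2"] >= 0) & (ok["pi_pop2"] <= 1)).all()
        assert ((ok["dxy"] >= 0) & (ok["dxy"] <= 1)).all()
        assert (ok["fst"] <= 1).all()

    def test_population_label_permutation_gives_near_zero_fst(self, rng):
        # permute individuals across population labels: structure destroyed
        cfg = SimulationConfig(seed=21, n_genes=60, sites_per_gene=50,
                               background_F=0.2, planted_outlier_fraction=0.0,
                               missing_rate=0.0, geneset_size=10)
        sim = simulate_genotypes(cfg)
        g = np.hstack([sim.genotypes_pop1, sim.genotypes_pop2])
        perm = rng.permutation(g.shape[1])
        g = g[:, perm]
        h1, h2 = g[:, :25], g[:, 25:]
        sites = sim.dataset.sites.copy()
        for cols, mat in ((("n1", "ac1"), h1), (("n2", "ac2"), h2)):
            sites[cols[0]] = 2 * (mat >= 0).sum(axis=1)
            sites[cols[1]] = np.where(mat > 0, mat, 0).sum(axis=1)
        ds = make_dataset(sites[["chrom", "pos", "n1", "ac1", "n2", "ac2"]].to_numpy().tolist())
        fst = fst_per_gene(ds, sim.annotation)
        assert abs(fst.mean()) < 0.02


class TestSiteFiltering:
    def test_masked_sites_removed(self):
        ann = make_annotation([("chr1", 0, 1000, "geneA")], masks=[("chr1", 9, 20)])
        # 1-based positions 10..20 fall in mask [9, 20): positions 10..20 ->
        # pos-1 in 9..19 inside; pos 21 -> 20 outside
        ds = make_dataset([("chr1", p, 20, 5, 20, 5) for p in (5, 10, 20, 21)])
        kept, log = filter_sites(ds, ann, min_individuals=6)
        assert sorted(kept.sites["pos"]) == [5, 21]
        assert log.removed_masked == 2

    def test_indel_pad_boundary_exact(self):
        # indel affects 1-based position 100 (BED [99, 100)); the 10 bp pad
        # removes positions 90..110; 89 and 111 are retained
        ann = make_annotation([("chr1", 0, 1000, "geneA")], indels=[("chr1", 99, 100)])
        ds = make_dataset([("chr1", p, 20, 5, 20, 5) for p in (89, 90, 110, 111)])
        kept, log = filter_sites(ds, ann, min_individuals=6)
        assert sorted(kept.sites["pos"]) == [89, 111]
        assert log.removed_indel_adjacent == 2

    def test_minimum_individuals_per_population(self, one_gene_annotation):
        # 5 genotyped individuals = 10 alleles in pop2 -> removed; 6 kept
        ds = make_dataset([
            ("chr1", 10, 20, 5, 10, 2),
            ("chr1", 20, 20, 5, 12, 2),
        ])
        kept, log = filter_sites(ds, one_gene_annotation, min_individuals=6)
        assert list(kept.sites["pos"]) == [20]
        assert log.removed_low_coverage == 1

    def test_unknown_chromosome_warns_and_is_ignored(self, one_gene_annotation):
        ann = make_annotation([("chr1", 0, 1000, "geneA")], masks=[("chrZ", 0, 50)])
        ds = make_dataset([("chr1", 10, 20, 5, 20, 5)])
        with pytest.warns(UserWarning, match="chrZ"):
            kept, _ = filter_sites(ds, ann)
        assert kept.n_sites == 1

    def test_overlapping_masks_merged_silently(self):
        ann = make_annotation([("chr1", 0, 1000, "geneA")],
                              masks=[("chr1", 0, 50), ("chr1", 40, 80)])
        ds = make_dataset([("chr1", p, 20, 5, 20, 5) for p in (45, 75, 85)])
        kept, log = filter_sites(ds, ann)
        assert list(kept.sites["pos"]) == [85]
        assert log.removed_masked == 2


class TestVcfRoundTrip:
    def test_written_vcf_reproduces_allele_counts(self, tmp_path):
        cfg = SimulationConfig(seed=4, n_genes=10, sites_per_gene=10,
                               geneset_size=5, missing_rate=0.1)
        sim = simulate_genotypes(cfg)
        path = tmp_path / "sim.vcf"
        write_vcf(sim, path)
        pop1 = [f"surface{i:02d}" for i in range(cfg.n_diploids_pop1)]
        pop2 = [f"cave{i:02d}" for i in range(cfg.n_diploids_pop2)]
        ds = read_vcf(path, pop1, pop2)
        pd.testing.assert_frame_equal(
            ds.sites.astype("int64", errors="ignore").reset_index(drop=True)[["pos", "n1", "ac1", "n2", "ac2"]].astype("int64"),
            sim.dataset.sites[["pos", "n1", "ac1", "n2", "ac2"]].astype("int64"),
        )
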