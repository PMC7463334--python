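"""Genotype filtering, LD pruning, structure covariate, and WC84 FST."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from reefscape.genotypes import (
    GenotypeMatrix,
    filter_snps,
    fst_scan,
    ld_prune,
    multilocus_fst,
    pairwise_fst,
    structure_covariate,
    wc_fst_components,
)
from tests.conftest import toy_matrix


def wc84_single_locus_oracle(counts_a, counts_b):
    """Independent transcription of the WC84 a/b/c formulas for one locus,
    two populations.  counts_* = (n_homref, n_het, n_homalt)."""
    pops = []
    for c in (counts_a, counts_b):
        n = sum(c)
        p = (2 * c[2] + c[1]) / (2 * n)  # alt allele
        h = c[1] / n
        pops.append((n, p, h))
    r = 2
    nbar = sum(n for n, _, _ in pops) / r
    nc = (r * nbar - sum(n**2 for n, _, _ in pops) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p, _ in pops) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p, _ in pops) / ((r - 1) * nbar)
    hbar = sum(n * h for n, _, h in pops) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


class TestFilterSnps:
    def test_hand_constructed_matrix_counts(self):
        """6 individuals x 4 SNPs: SNP0 fine; SNP1 monomorphic (fails MAF);
        SNP2 major genotype 5/6 > 0.95? no -> passes; SNP3 high missing;
        ind5 missing 3/4 of genotypes -> dropped first."""
        codes = np.array([
            #  s0  s1  s2  s3
            [0, 0, 1, -1],
            [1, 0, 1, -1],
            [2, 0, 1, 0],
            [0, 0, 1, -1],
            [1, 0, 1, 1],
            [-1, 0, -1, -1],
        ], dtype=np.int8)
        m = toy_matrix(codes, sites=["A"] * 6)
        out = filter_snps(m, maf=0.05, major_geno=0.95, miss=0.5)
        assert out.n_individuals == 5  # ind5 dropped (missing 0.75 >= 0.5)
        # after ind filter: s1 monomorphic (MAF 0), s2 all-het (major genotype 1.0),
        # s3 missing 3/5 >= 0.5 -> only s0 survives
        assert out.n_snps == 1
        assert out.snps["pos"].tolist() == [100]

    def test_permissive_thresholds_keep_everything(self):
        codes = np.array([[0, 1], [1, 2], [2, 0], [1, 1]], dtype=np.int8)
        m = toy_matrix(codes)
        out = filter_snps(m, maf=0.0, major_geno=1.01, miss=1.01)
        assert out.n_snps == 2 and out.n_individuals == 4

    def test_monomorphic_snp_always_removed(self):
        codes = np.array([[0, 0], [0, 1], [0, 2], [0, 1]], dtype=np.int8)
        out = filter_snps(toy_matrix(codes), maf=0.05)
        assert out.n_snps == 1

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 3, (40, 30)).astype(np.int8)
        m = toy_matrix(codes)
        once = filter_snps(m)
        twice = filter_snps(once)
        assert np.array_equal(once.codes, twice.codes)


class TestLdPrune:
    def test_duplicated_column_removed(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, 30)
        codes = np.column_stack([col, col, rng.integers(0, 3, 30)]).astype(np.int8)
        out = ld_prune(toy_matrix(codes), r2=0.3)
        assert out.n_snps == 2

    def test_orthogonal_columns_kept(self):
        codes = np.array([[0, 0], [0, 2], [2, 0], [2, 2]] * 5, dtype=np.int8)
        out = ld_prune(toy_matrix(codes), r2=0.3)
        assert out.n_snps == 2

    def test_matches_greedy_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        base = rng.integers(0, 3, 40)
        codes = np.column_stack([
            base,
            np.clip(base + rng.integers(-1, 2, 40), 0, 2),  # correlated with 0
            rng.integers(0, 3, 40),
            base[::-1],
            np.clip(base + rng.integers(-1, 2, 40), 0, 2),  # correlated with 0
        ]).astype(np.int8)
        m = toy_matrix(codes)
        out = ld_prune(m, r2=0.3, window_snps=10)
        # brute-force first-kept-wins greedy rule
        d = codes.astype(float)
        kept = []
        for j in range(5):
            if all(np.corrcoef(d[:, k], d[:, j])[0, 1] ** 2 <= 0.3 for k in kept):
                kept.append(j)
        assert out.snps["pos"].tolist() == [(k + 1) * 100 for k in kept]

    def test_different_scaffolds_never_pruned_together(self):
        rng = np.random.default_rng(2)
        col = rng.integers(0, 3, 30)
        m = toy_matrix(np.column_stack([col, col]).astype(np.int8))
        m.snps.loc[1, "scaffold"] = "s2"
        assert ld_prune(m, r2=0.3).n_snps == 2


class TestStructureCovariate:
    def test_planted_clusters_separated_by_sign(self):
        rng = np.random.default_rng(3)
        n, L = 60, 200
        p1, p2 = rng.uniform(0.1, 0.9, L), None
        p2 = np.clip(p1 + rng.choice([-0.4, 0.4], L), 0.05, 0.95)
        g1 = rng.binomial(2, p1, (n // 2, L))
        g2 = rng.binomial(2, p2, (n // 2, L))
        m = toy_matrix(np.vstack([g1, g2]).astype(np.int8))
        axis = structure_covariate(m, k=1)[:, 0]
        signs = np.sign(axis)
        acc = max((signs[:30] > 0).mean() + (signs[30:] < 0).mean(),
                  (signs[:30] < 0).mean() + (signs[30:] > 0).mean()) / 2
        assert acc >= 0.99

    def test_k_too_large_rejected(self):
        m = toy_matrix(np.zeros((4, 5), dtype=np.int8))
        with pytest.raises(ValueError):
            structure_covariate(m, k=4)

    def test_csv_covariate_passed_through(self, tmp_path):
        m = toy_matrix(np.random.default_rng(0).integers(0, 3, (4, 5)).astype(np.int8))
        df = pd.DataFrame({"id": [f"ind{i}" for i in range(4)], "axis1": [0.1, 0.2, 0.3, 0.4]})
        path = tmp_path / "cov.csv"
        df.to_csv(path, index=False)
        out = structure_covariate(m, method="csv", k=1, csv_path=str(path))
        assert np.allclose(out[:, 0], [0.1, 0.2, 0.3, 0.4])


class TestWcFst:
    def test_single_locus_matches_formula_oracle(self):
        """Two sites with genotype counts (6,3,1) and (1,4,5)."""
        codes = np.array(
            [0] * 6 + [1] * 3 + [2] * 1 + [0] * 1 + [1] * 4 + [2] * 5, dtype=np.int8
        )[:, None]
        sites = ["A"] * 10 + ["B"] * 10
        m = toy_matrix(codes, sites=sites)
        a, b, c = wc_fst_components(m.codes, np.array(sites))
        ao, bo, co = wc84_single_locus_oracle((6, 3, 1), (1, 4, 5))
        assert abs(a[0] - ao) < 1e-12
        assert abs(b[0] - bo) < 1e-12
        assert abs(c[0] - co) < 1e-12
        assert abs(multilocus_fst(m.codes, np.array(sites)) - ao / (ao + bo + co)) < 1e-12

    def test_panmictic_pool_fst_near_zero(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.2, 0.8, 2000)
        codes = rng.binomial(2, p, (60, 2000)).astype(np.int8)
        sites = np.array(["A"] * 30 + ["B"] * 30)
        assert abs(multilocus_fst(codes, sites)) < 0.01

    def test_fixed_alternate_alleles_give_one(self):
        codes = np.array([[0]] * 10 + [[2]] * 10, dtype=np.int8)
        sites = np.array(["A"] * 10 + ["B"] * 10)
        assert multilocus_fst(codes, sites) == pytest.approx(1.0)

    def test_invariant_to_snp_order_and_allele_swap(self):
        rng = np.random.default_rng(9)
        codes = rng.integers(0, 3, (40, 100)).astype(np.int8)
        codes[rng.random(codes.shape) < 0.05] = -1
        sites = np.array(["A", "B", "C", "D"] * 10)
        base = multilocus_fst(codes, sites)
        perm = rng.permutation(100)
        assert abs(multilocus_fst(codes[:, perm], sites) - base) < 1e-12
        swapped = np.where(codes == -1, -1, 2 - codes).astype(np.int8)
        assert abs(multilocus_fst(swapped, sites) - base) < 1e-12

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_fst_bounded_above_by_one(self, seed):
        rng = np.random.default_rng(seed)
        codes = rng.integers(0, 3, (24, 50)).astype(np.int8)
        sites = np.array(["A"] * 12 + ["B"] * 12)
        try:
            theta = multilocus_fst(codes, sites)
        except ValueError:
            return  # no variable loci
        assert theta <= 1.0 + 1e-12


class TestPairwiseFst:
    def test_small_sites_excluded_by_strict_rule(self):
        rng = np.random.default_rng(10)
        codes = rng.integers(0, 3, (34, 50)).astype(np.int8)
        sites = ["A"] * 12 + ["B"] * 12 + ["C"] * 10  # C has exactly 10 -> excluded
        tab = pairwise_fst(toy_matrix(codes, sites=sites), min_n=10)
        assert set(tab["site1"]) | set(tab["site2"]) == {"A", "B"}

    def test_pairs_ordered_lexicographically(self):
        rng = np.random.default_rng(11)
        codes = rng.integers(0, 3, (36, 80)).astype(np.int8)
        sites = ["C"] * 12 + ["A"] * 12 + ["B"] * 12
        tab = pairwise_fst(toy_matrix(codes, sites=sites), min_n=10)
        assert tab["site1"].tolist() == ["A", "A", "B"]
        assert tab["site2"].tolist() == ["B", "C", "C"]

    def test_too_few_sites_raises(self):
        codes = np.random.default_rng(0).integers(0, 3, (12, 10)).astype(np.int8)
        with pytest.raises(ValueError, match="at least 2 sites"):
            pairwise_fst(toy_matrix(codes, sites=["A"] * 12), min_n=10)


class TestFstScan:
    def test_identical_frequencies_give_flat_near_zero_track(self):
        """Both sites drawn from one frequency vector: the per-window track
        is flat around zero (the WC estimator is null-centered, so single
        values scatter slightly on either side)."""
        rng = np.random.default_rng(12)
        p = rng.uniform(0.3, 0.7, 200)
        codes = rng.binomial(2, p, (100, 200)).astype(np.int8)
        tab = fst_scan(toy_matrix(codes, sites=["A"] * 50 + ["B"] * 50), window_kb=2.0)
        assert abs(tab["fst_window"].mean()) < 0.02
        assert tab["fst_window"].abs().max() < 0.1

    def test_planted_divergent_region_elevates_windows(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(0.3, 0.7, 100)
        a = rng.binomial(2, p, (25, 100))
        b = rng.binomial(2, p, (25, 100))
        b[:, 40:60] = rng.binomial(2, np.clip(p[40:60] + 0.45, 0, 1), (25, 20))
        m = toy_matrix(np.vstack([a, b]).astype(np.int8), sites=["A"] * 25 + ["B"] * 25)
        tab = fst_scan(m, window_kb=1.0)
        inside = tab["fst_window"][40:60].mean()
        outside = pd.concat([tab["fst_window"][:35], tab["fst_window"][65:]]).mean()
        assert inside > outside + 0.05

    def test_window_spanning_scaffold_equals_multilocus_fst(self):
        rng = np.random.default_rng(14)
        codes = rng.integers(0, 3, (40, 30)).astype(np.int8)
        sites = np.array(["A"] * 20 + ["B"] * 20)
        m = toy_matrix(codes, sites=list(sites))
        tab = fst_scan(m, window_kb=1e9)
        a, b, c = wc_fst_components(codes, sites)
        with np.errstate(invalid="ignore"):
            per_snp = np.where(a + b + c != 0, a / (a + b + c), np.nan)
        assert np.allclose(tab["fst_window"], np.nanmean(per_snp))


class TestVcfRoundTrip:
    def test_write_then_read_preserves_codes(self, tmp_path):
        rng = np.random.default_rng(15)
        codes = rng.integers(-1, 3, (10, 20)).astype(np.int8)
        m = toy_matrix(codes, sites=["A"] * 5 + ["B"] * 5)
        path = tmp_path / "g.vcf"
        m.to_vcf(str(path))
        sites = m.individuals[["id", "site", "lon", "lat"]]
        back = GenotypeMatrix.from_vcf(str(path), sites)
        assert np.array_equal(back.codes, m.codes)
        assert back.snps["pos"].tolist() == m.snps["pos"].tolist()
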