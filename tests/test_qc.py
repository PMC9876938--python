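"""QC battery: closed-form oracles, boundary rules, null behavior."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as npst
from scipy import stats

from haplomerge import qc
from haplomerge.types import MISSING

from conftest import make_cohort


def brute_force_bh(p):
    """Textbook step-up Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestBH:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for n in (1, 5, 100, 1000):
            p = rng.random(n)
            assert np.allclose(qc.bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_with_ties(self):
        p = np.array([0.01, 0.01, 0.5, 0.5, 1.0])
        assert np.allclose(qc.bh_adjust(p), brute_force_bh(p), atol=1e-12)


class TestSnpMissingness:
    def test_wave_specific_excess_is_excluded(self):
        geno = np.ones((40, 3), dtype=np.int8)
        waves = np.array([0] * 20 + [1] * 20)
        geno[:3, 0] = MISSING           # 15% missing in wave 0 only
        cohort = make_cohort(geno, waves=waves)
        res = qc.snp_missingness_filter(cohort, threshold=0.05)
        assert list(res.excluded) == [0]

    def test_exact_threshold_is_retained(self):
        geno = np.ones((40, 2), dtype=np.int8)
        geno[:2, 0] = MISSING           # exactly 5% everywhere
        cohort = make_cohort(geno, waves=np.zeros(40, dtype=int))
        res = qc.snp_missingness_filter(cohort, threshold=0.05)
        assert res.n_excluded == 0

    def test_clean_sites_retained_and_idempotent(self, small_cohort):
        res = qc.snp_missingness_filter(small_cohort, threshold=0.5)
        assert res.n_excluded == 0


class TestDifferentialMissingness:
    def test_equal_missingness_retained(self):
        geno = np.ones((40, 2), dtype=np.int8)
        geno[0, 0] = MISSING
        geno[20, 0] = MISSING
        cases = np.array([True] * 20 + [False] * 20)
        res = qc.differential_missingness_test(make_cohort(geno, cases=cases), 0.2)
        assert res.n_excluded == 0
        assert res.table["p"].iloc[1] == 1.0

    def test_matches_hand_computed_chi_square(self):
        # cases 10/90 missing/observed vs controls 0/100
        geno = np.ones((200, 1), dtype=np.int8)
        cases = np.array([True] * 100 + [False] * 100)
        geno[:10, 0] = MISSING
        res = qc.differential_missingness_test(make_cohort(geno, cases=cases), 0.2)
        a, b, c, d = 10, 90, 0, 100
        n = a + b + c + d
        chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.table["chi2"].iloc[0] == pytest.approx(chi2, rel=1e-12)
        assert res.table["p"].iloc[0] == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-9)

    def test_null_fdr_control(self):
        """Under equal rates, the BH screen excludes few sites."""
        rng = np.random.default_rng(5)
        fracs = []
        for seed in range(10):
            geno = np.ones((100, 500), dtype=np.int8)
            miss = rng.random(geno.shape) < 0.05
            geno[miss] = MISSING
            cases = np.array([True] * 50 + [False] * 50)
            res = qc.differential_missingness_test(make_cohort(geno, cases=cases), 0.2)
            fracs.append(res.n_excluded / 500)
        assert np.mean(fracs) <= 0.25

    def test_single_class_raises(self):
        geno = np.ones((10, 2), dtype=np.int8)
        with pytest.raises(ValueError):
            qc.differential_missingness_test(make_cohort(geno, cases=np.ones(10, bool)))


class TestHWE:
    def test_perfect_proportions_give_zero_statistic(self):
        geno = np.concatenate([np.zeros(25), np.ones(50), np.full(25, 2)]).astype(np.int8)
        res = qc.hwe_test(make_cohort(geno[:, None]), np.ones(100, bool))
        assert res.table["chi2"].iloc[0] == 0.0
        assert res.table["p"].iloc[0] == 1.0

    def test_all_het_gives_chi_square_100(self):
        geno = np.ones((100, 1), dtype=np.int8)
        res = qc.hwe_test(make_cohort(geno), np.ones(100, bool))
        assert res.table["chi2"].iloc[0] == pytest.approx(100.0)

    def test_monomorphic_never_excluded(self):
        geno = np.zeros((50, 1), dtype=np.int8)
        res = qc.hwe_test(make_cohort(geno), np.ones(50, bool))
        assert res.table["p"].iloc[0] == 1.0
        assert res.n_excluded == 0


class TestMinPNull:
    def test_identity_for_one_batch(self):
        y = np.linspace(0, 1, 11)
        assert np.allclose(qc.minp_null_cdf(y, 1), y)

    def test_two_batches_closed_form(self):
        assert qc.minp_null_cdf(0.5, 2) == pytest.approx(0.75)

    @pytest.mark.parametrize("m", [2, 6, 26])
    def test_matches_empirical_cdf_of_min_uniforms(self, m):
        rng = np.random.default_rng(m)
        n_rep = 100_000
        mins = rng.random((n_rep, m)).min(axis=1)
        for y in (0.01, 0.05, 0.2, 0.5):
            theo = qc.minp_null_cdf(y, m)
            emp = (mins <= y).mean()
            se = np.sqrt(theo * (1 - theo) / n_rep)
            assert abs(emp - theo) < 3 * max(se, 1e-5)

    def test_quantile_consistency_with_cdf(self):
        """Plugging the order-statistic quantiles into the CDF recovers i/n."""
        for m in (2, 6, 26):
            n = 500
            q = qc.minp_theoretical_quantiles(n, m)
            back = qc.minp_null_cdf(q, m)
            assert np.allclose(back, np.arange(1, n + 1) / n, atol=1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            qc.minp_null_cdf(1.5, 2)


class TestBatchArtifacts:
    @staticmethod
    def _null_cohort(seed, n=240, s=300, waves=6):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.1, 0.9, s)
        geno = rng.binomial(2, p, (n, s)).astype(np.int8)
        wave = np.repeat(np.arange(waves), n // waves)
        return make_cohort(geno, waves=wave)

    def test_null_exclusion_rate_is_low(self):
        fracs = []
        for seed in range(10):
            cohort = self._null_cohort(seed)
            res = qc.batch_artifact_scan(cohort, fdr_threshold=0.1)
            fracs.append(res.n_excluded / cohort.n_sites)
        assert np.mean(fracs) <= 0.05

    def test_strong_wave_shift_is_detected(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cohort = self._null_cohort(100 + seed, n=600)
            geno = cohort.genotypes.copy()
            wave = cohort.samples["wave"].to_numpy()
            # shift allele frequency by ~0.3 in wave 0 at site 0
            rows = np.flatnonzero(wave == 0)
            rng = np.random.default_rng(seed)
            geno[rows, 0] = rng.binomial(2, 0.9, rows.size)
            geno[np.flatnonzero(wave != 0), 0] = rng.binomial(
                2, 0.6, (wave != 0).sum())
            shifted = make_cohort(geno, waves=wave)
            res = qc.batch_artifact_scan(shifted, fdr_threshold=0.1)
            if shifted.site_indices[0] in res.excluded:
                hits += 1
        assert hits >= int(0.95 * n_seeds)

    def test_zero_p_gets_zero_fdr(self):
        cohort = self._null_cohort(7)
        res = qc.batch_artifact_scan(cohort)
        tbl = res.table
        assert np.all(tbl.loc[tbl["min_p"] == 0, "p_fdr"] == 0)

    def test_single_wave_raises(self):
        geno = np.ones((20, 5), dtype=np.int8)
        with pytest.raises(ValueError):
            qc.batch_artifact_scan(make_cohort(geno))

    def test_order_independence(self):
        cohort = self._null_cohort(11)
        res = qc.batch_artifact_scan(cohort)
        perm = np.random.default_rng(0).permutation(cohort.n_sites)
        permuted = make_cohort(cohort.genotypes[:, perm],
                               site_indices=np.arange(cohort.n_sites),
                               waves=cohort.samples["wave"].to_numpy())
        res_p = qc.batch_artifact_scan(permuted)
        # p_fdr of permuted site j must equal p_fdr of original site perm[j]
        orig = res.table.set_index("site")["p_fdr"]
        assert np.allclose(res_p.table["p_fdr"].to_numpy(),
                           orig.loc[perm].to_numpy())


class TestMafCensor:
    def test_boundaries(self):
        geno = np.zeros((1000, 3), dtype=np.int8)
        geno[0, 1] = 1                     # MAF 0.0005 < 0.001 -> censored
        geno[:600, 2] = 1                  # MAF 0.3 -> kept
        cohort = make_cohort(geno)
        res = qc.maf_censor(cohort, 0.001)
        assert set(res.excluded) == {0, 1}

    def test_exact_threshold_retained(self):
        geno = np.zeros((1000, 1), dtype=np.int8)
        geno[0, 0] = 2                     # MAF exactly 0.001
        res = qc.maf_censor(make_cohort(geno), 0.001)
        assert res.n_excluded == 0


class TestPCA:
    def test_separates_populations(self, small_panel):
        h = small_panel.haplotypes
        pop0 = np.flatnonzero(small_panel.pop_label == "pop0")[:200]
        pop1 = np.flatnonzero(small_panel.pop_label == "pop1")[:100]
        rows = np.concatenate([pop0, pop1])
        G = (h[rows[::2]] + h[rows[1::2]]).astype(np.int8)
        labels = np.array([0] * 100 + [1] * 50)
        scores, _ = qc.pca(G, 4)
        pc1 = scores[:, 0]
        thr = (pc1[labels == 0].mean() + pc1[labels == 1].mean()) / 2
        side = pc1 > thr
        acc = max((side == labels.astype(bool)).mean(),
                  (side == ~labels.astype(bool)).mean())
        assert acc >= 0.95

    def test_duplicated_rows_get_identical_scores(self):
        rng = np.random.default_rng(1)
        G = rng.integers(0, 3, (30, 50)).astype(np.int8)
        G[5] = G[3]
        scores, _ = qc.pca(G, 3)
        assert np.allclose(scores[5], scores[3], atol=1e-10)

    def test_orthogonal_components(self):
        rng = np.random.default_rng(2)
        G = rng.integers(0, 3, (40, 60)).astype(np.int8)
        scores, loadings = qc.pca(G, 5)
        gram = loadings @ loadings.T
        assert np.allclose(gram, np.eye(5), atol=1e-8)


class TestHeterozygosityFilter:
    @staticmethod
    def _structured_cohort(seed, n=200, s=300):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.2, 0.8, s)
        geno = rng.binomial(2, p, (n, s)).astype(np.int8)
        return make_cohort(geno), rng

    def test_injected_outlier_is_flagged(self):
        cohort, rng = self._structured_cohort(0)
        geno = cohort.genotypes.copy()
        geno[0] = 1                      # all-heterozygous sample
        cohort = make_cohort(geno)
        pcs = rng.standard_normal((200, 4)) * 0.01
        res = qc.ancestry_adjusted_heterozygosity(cohort, pcs, sd_threshold=4.0)
        assert "s000" in res.excluded

    def test_intercept_only_regression(self):
        cohort, _ = self._structured_cohort(1)
        pcs = np.zeros((200, 4))
        with pytest.raises(ValueError, match="PC"):
            qc.ancestry_adjusted_heterozygosity(cohort, pcs)

    def test_het_explained_by_pc1_leaves_zero_residuals(self):
        cohort, rng = self._structured_cohort(2)
        pcs = np.zeros((200, 4))
        pcs[:, 0] = np.linspace(-1, 1, 200)
        pcs[:, 1] = rng.standard_normal(200)
        pcs[:, 2] = rng.standard_normal(200)
        pcs[:, 3] = rng.standard_normal(200)
        het = qc.heterozygosity(cohort)
        # replace observed het with an exact linear function of PC1
        fake = 0.3 + 0.05 * pcs[:, 0]
        X = qc._het_design(pcs)
        resid = fake - X @ np.linalg.lstsq(X, fake, rcond=None)[0]
        assert np.allclose(resid, 0.0, atol=1e-10)
        assert het.shape == fake.shape


class TestHomogeneousSubset:
    def test_anchor_mean_is_kept(self):
        rng = np.random.default_rng(0)
        pcs = rng.standard_normal((500, 10))
        pcs[0] = pcs[1:100].mean(axis=0)
        kept = qc.homogeneous_subset(pcs, np.arange(1, 100))
        assert 0 in kept

    def test_exclusion_exactly_at_quantile_boundary(self):
        rng = np.random.default_rng(1)
        p_cut = 5.73e-7
        pcs = rng.standard_normal((5000, 10))
        mu = pcs.mean(axis=0)
        cov = np.cov(pcs, rowvar=False)
        # place one sample just beyond the chi-square(10) cutoff distance
        d2_cut = stats.chi2.isf(p_cut, df=10)
        evals, evecs = np.linalg.eigh(cov)
        direction = evecs[:, -1] * np.sqrt(evals[-1])
        probe_out = mu + direction * np.sqrt(d2_cut * 1.02)
        probe_in = mu + direction * np.sqrt(d2_cut * 0.98)
        pcs_all = np.vstack([pcs, probe_out, probe_in])
        kept = qc.homogeneous_subset(pcs_all, np.arange(5000), p_cut)
        assert 5000 not in kept
        assert 5001 in kept

    def test_standard_normal_anchors_rarely_excluded(self):
        rng = np.random.default_rng(2)
        pcs = rng.standard_normal((10_000, 10))
        kept = qc.homogeneous_subset(pcs, np.arange(10_000))
        assert len(kept) >= 10_000 - 2   # expected exclusions ~ 10000*5.73e-7

    def test_too_few_anchors_raise(self):
        pcs = np.random.default_rng(3).standard_normal((20, 10))
        with pytest.raises(ValueError):
            qc.homogeneous_subset(pcs, np.arange(5))


class TestKinship:
    def test_identical_samples_look_like_duplicates(self):
        rng = np.random.default_rng(0)
        G = rng.binomial(2, rng.uniform(0.2, 0.8, 800), (150, 800)).astype(np.int8)
        G[1] = G[0]
        K = qc.kinship_matrix(G)
        assert K[0, 1] == pytest.approx(0.5, abs=0.05)

    def test_unrelated_pair_near_zero(self):
        rng = np.random.default_rng(1)
        G = rng.binomial(2, rng.uniform(0.2, 0.8, 2000), (40, 2000)).astype(np.int8)
        K = qc.kinship_matrix(G)
        iu, ju = np.triu_indices(40, 1)
        assert abs(K[iu, ju].mean()) < 3 / np.sqrt(2 * 2000)

    def test_parent_offspring_quarter_and_pruned(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.2, 0.8, 3000)
        h = (rng.random((80, 3000)) < p).astype(np.int8)
        father, mother = h[0] + h[1], h[2] + h[3]
        # child inherits one full haplotype from each parent
        child = h[1] + h[2]
        others = h[4::2] + h[5::2]
        G = np.vstack([father + 0, child, others]).astype(np.int8)
        K = qc.kinship_matrix(G)
        assert K[0, 1] == pytest.approx(0.25, abs=0.05)
        cohort = make_cohort(G)
        _, unrelated = qc.duplicate_and_relatedness_filter(cohort)
        assert not ({"s000", "s001"} <= set(unrelated))

    def test_duplicate_resolution_prefers_case_and_low_missingness(self):
        rng = np.random.default_rng(3)
        G = rng.binomial(2, rng.uniform(0.3, 0.7, 600), (120, 600)).astype(np.int8)
        G[1] = G[0]
        G[1, :30] = MISSING               # duplicate with higher missingness
        cases = np.zeros(120, bool)
        cohort = make_cohort(G, cases=cases)
        res, _ = qc.duplicate_and_relatedness_filter(cohort)
        assert list(res.excluded) == ["s001"]
        # now make the higher-missingness copy a case: it is kept instead
        cases[1] = True
        cohort = make_cohort(G, cases=cases)
        res, _ = qc.duplicate_and_relatedness_filter(cohort)
        assert list(res.excluded) == ["s000"]


class TestSampleMissingness:
    def test_boundary_rules(self):
        geno = np.ones((3, 200), dtype=np.int8)
        geno[1, :12] = MISSING            # 6% -> removed
        geno[2, :10] = MISSING            # exactly 5% -> kept
        res = qc.sample_missingness_filter(make_cohort(geno), 0.05)
        assert list(res.excluded) == ["s001"]


class TestProperties:
    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(npst.arrays(np.float64, st.integers(1, 200),
                       elements=st.floats(0.0, 1.0)))
    def test_bh_matches_brute_force_on_arbitrary_vectors(self, p):
        assert np.allclose(qc.bh_adjust(p), brute_force_bh(p), atol=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(1, 50), st.integers(2, 500))
    def test_minp_quantiles_invert_the_cdf(self, m, n):
        q = qc.minp_theoretical_quantiles(n, m)
        assert np.allclose(qc.minp_null_cdf(q, m), np.arange(1, n + 1) / n,
                           atol=1e-9)
        assert np.all(np.diff(q) >= 0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.floats(0.0, 1.0), st.integers(1, 100))
    def test_minp_cdf_bounds_and_monotonicity_in_batches(self, y, m):
        v = qc.minp_null_cdf(y, m)
        assert 0.0 <= v <= 1.0
        assert v >= qc.minp_null_cdf(y, max(1, m - 1)) - 1e-12


class TestFilterIdempotence:
    def test_rerunning_on_survivors_excludes_nothing(self, small_cohort):
        for fn in (lambda c: qc.snp_missingness_filter(c, 0.05),
                   lambda c: qc.maf_censor(c, 0.001)):
            res = fn(small_cohort)
            survivors = small_cohort.subset_sites(
                np.setdiff1d(small_cohort.site_indices, res.excluded))
            res2 = fn(survivors)
            assert res2.n_excluded == 0
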