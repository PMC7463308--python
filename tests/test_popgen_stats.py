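"""Diversity, pairwise PhiST, and AMOVA against an independent brute-force
oracle built from explicit pairwise-distance tables."""

import itertools

import numpy as np
import pytest
from scipy import stats

from relictgen.genotype_io import MISSING
from relictgen.popgen_stats import (
    amova,
    diversity,
    diversity_gradient,
    pairwise_phist,
)

from conftest import make_matrix, make_popmap


# ---------------------------------------------------------------------------
# Independent oracle: AMOVA from explicit SSD tables, one locus at a time.


def _ssd(geno_col, idx):
    """(1/n) * sum_{i<j} |g_i - g_j| over non-missing members of idx."""
    vals = [geno_col[i] for i in idx if geno_col[i] != MISSING]
    n = len(vals)
    if n == 0:
        return 0.0, 0
    s = sum(abs(a - b) for a, b in itertools.combinations(vals, 2))
    return s / n, n


def brute_force_amova(geno, pops, groups=None):
    """Variance components by direct summation; missing dropped pairwise.

    ``pops``: list of index lists; ``groups``: list of lists of pop indices
    (None -> 2-level).  Returns dict of components.
    """
    L = geno.shape[1]
    if groups is None:
        ssd_w = ssd_a = df_w = df_a = coef = 0.0
        for l in range(L):
            col = geno[:, l]
            all_idx = [i for p in pops for i in p]
            ss_t, n_t = _ssd(col, all_idx)
            ss_w = 0.0
            sizes = []
            for p in pops:
                s, n = _ssd(col, p)
                ss_w += s
                sizes.append(n)
            P = sum(1 for n in sizes if n > 0)
            if n_t == 0 or P == 0:
                continue
            ssd_w += ss_w
            ssd_a += ss_t - ss_w
            df_w += n_t - P
            df_a += P - 1
            coef += n_t - sum(n**2 for n in sizes) / n_t
        sig_c = ssd_w / df_w
        sig_a = (ssd_a - df_a * sig_c) / coef
        return {"among": sig_a, "within": sig_c,
                "phi_st": sig_a / (sig_a + sig_c)}
    # 3-level
    tot = dict(ssd_w=0.0, ssd_b=0.0, ssd_a=0.0, df_w=0.0, df_b=0.0, df_a=0.0,
               coef_b=0.0, coef_ba=0.0, coef_a=0.0)
    for l in range(L):
        col = geno[:, l]
        all_idx = [i for p in pops for i in p]
        ss_t, n_t = _ssd(col, all_idx)
        ss_w, sizes = 0.0, []
        for p in pops:
            s, n = _ssd(col, p)
            ss_w += s
            sizes.append(n)
        ss_g, gn = 0.0, []
        for g in groups:
            gidx = [i for pi in g for i in pops[pi]]
            s, n = _ssd(col, gidx)
            ss_g += s
            gn.append(n)
        P = sum(1 for n in sizes if n > 0)
        G = sum(1 for n in gn if n > 0)
        if n_t == 0:
            continue
        tot["ssd_w"] += ss_w
        tot["ssd_b"] += ss_g - ss_w
        tot["ssd_a"] += ss_t - ss_g
        tot["df_w"] += n_t - P
        tot["df_b"] += P - G
        tot["df_a"] += G - 1
        B = sum(
            sum(sizes[pi] ** 2 for pi in g) / ng if ng > 0 else 0.0
            for g, ng in zip(groups, gn)
        )
        C = sum(n**2 for n in sizes) / n_t
        D = sum(n**2 for n in gn) / n_t
        tot["coef_b"] += n_t - B
        tot["coef_ba"] += B - C
        tot["coef_a"] += n_t - D
    sig_c = tot["ssd_w"] / tot["df_w"]
    sig_b = (tot["ssd_b"] - tot["df_b"] * sig_c) / tot["coef_b"]
    sig_a = (tot["ssd_a"] - tot["df_a"] * sig_c - tot["coef_ba"] * sig_b) / tot[
        "coef_a"
    ]
    t = sig_a + sig_b + sig_c
    return {
        "among_groups": sig_a, "among_pops": sig_b, "within": sig_c,
        "phi_st": (sig_a + sig_b) / t, "phi_ct": sig_a / t,
        "phi_sc": sig_b / (sig_b + sig_c),
    }


# ---------------------------------------------------------------------------


class TestDiversity:
    def test_monomorphic_population(self):
        m = make_matrix(np.zeros((5, 4), np.int8))
        res = diversity(m, make_popmap(5, [5]), min_n=5)
        assert res.table.loc["pop0", "pi"] == 0.0
        assert res.table.loc["pop0", "hexp"] == 0.0

    def test_unbiased_gene_diversity_two_diploids(self):
        # genotypes 0 and 2: p = 0.5 over n = 4 genes -> 2*0.25*(4/3) = 2/3
        m = make_matrix([[0], [2]])
        res = diversity(m, make_popmap(2, [2]), min_n=2)
        assert res.table.loc["pop0", "hexp"] == pytest.approx(2 / 3)

    def test_all_heterozygous_hobs_one(self):
        m = make_matrix(np.ones((6, 3), np.int8))
        res = diversity(m, make_popmap(6, [6]), min_n=5)
        assert res.table.loc["pop0", "hobs"] == 1.0

    def test_small_population_excluded_with_warning(self):
        m = make_matrix(np.ones((7, 2), np.int8))
        pmap = make_popmap(7, [5, 2])
        with pytest.warns(UserWarning, match="excluded"):
            res = diversity(m, pmap, min_n=5)
        assert res.excluded == ["pop1"]
        assert list(res.table.index) == ["pop0"]


class TestAmovaOracle:
    """Components must match brute-force SSD computation to 1e-10."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_two_level_components(self, seed):
        rng = np.random.default_rng(seed)
        geno = rng.integers(0, 3, size=(14, 20)).astype(np.int8)
        m = make_matrix(geno)
        pmap = make_popmap(14, [5, 4, 5])
        res = amova(m, pmap, levels=2, n_perm=0)
        oracle = brute_force_amova(geno, [list(range(5)), list(range(5, 9)),
                                          list(range(9, 14))])
        assert res.sigma2["among_populations"] == pytest.approx(
            oracle["among"], abs=1e-10
        )
        assert res.sigma2["within_populations"] == pytest.approx(
            oracle["within"], abs=1e-10
        )
        assert res.phi_st == pytest.approx(oracle["phi_st"], abs=1e-10)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_three_level_components_with_missing(self, seed):
        rng = np.random.default_rng(seed)
        geno = rng.integers(0, 3, size=(16, 15)).astype(np.int8)
        geno[rng.random(geno.shape) < 0.1] = MISSING
        geno[0] = np.abs(geno[0])
        m = make_matrix(geno)
        pmap = make_popmap(16, [4, 4, 4, 4],
                           {"pop0": "A", "pop1": "A", "pop2": "B", "pop3": "B"})
        res = amova(m, pmap, levels=3, n_perm=0)
        pops = [list(range(4 * k, 4 * k + 4)) for k in range(4)]
        oracle = brute_force_amova(geno, pops, groups=[[0, 1], [2, 3]])
        for key, ok in [("among_groups", "among_groups"),
                        ("among_populations_within_groups", "among_pops"),
                        ("within_populations", "within")]:
            assert res.sigma2[key] == pytest.approx(oracle[ok], abs=1e-10)
        assert res.phi_ct == pytest.approx(oracle["phi_ct"], abs=1e-10)
        assert res.phi_sc == pytest.approx(oracle["phi_sc"], abs=1e-10)

    def test_allele_label_swap_invariance(self, rng):
        geno = rng.integers(0, 3, size=(10, 12)).astype(np.int8)
        m1 = make_matrix(geno)
        m2 = make_matrix(2 - geno)
        pmap = make_popmap(10, [5, 5])
        r1 = amova(m1, pmap, levels=2, n_perm=0)
        r2 = amova(m2, pmap, levels=2, n_perm=0)
        assert r1.sigma2 == r2.sigma2


class TestPhiSt:
    def test_fixed_difference_gives_one(self):
        geno = np.zeros((8, 10), np.int8)
        geno[4:] = 2
        m = make_matrix(geno)
        pmap = make_popmap(8, [4, 4])
        assert pairwise_phist(m, pmap).iloc[0, 1] == pytest.approx(1.0)

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.2, 0.8, 50)
        geno = rng.binomial(2, p, size=(20, 50)).astype(np.int8)
        m = make_matrix(geno)
        pmap = make_popmap(20, [10, 10])
        assert abs(pairwise_phist(m, pmap).iloc[0, 1]) < 0.02

    def test_pairwise_equals_two_level_amova_on_pair(self, rng):
        geno = rng.integers(0, 3, size=(12, 25)).astype(np.int8)
        m = make_matrix(geno)
        pmap = make_popmap(12, [4, 4, 4])
        mat = pairwise_phist(m, pmap)
        sub = m.take_samples(np.arange(8))
        sub_map = make_popmap(8, [4, 4])
        res = amova(sub, sub_map, levels=2, n_perm=0)
        assert mat.loc["pop0", "pop1"] == pytest.approx(res.phi_st, abs=1e-12)

    def test_single_population_degenerate(self):
        m = make_matrix(np.ones((4, 3), np.int8))
        with pytest.raises(ValueError):
            amova(m, make_popmap(4, [4]), levels=2, n_perm=0)

    def test_one_population_per_group_phi_ct_one_under_fixation(self):
        geno = np.zeros((8, 6), np.int8)
        geno[4:] = 2
        m = make_matrix(geno)
        pmap = make_popmap(8, [4, 4], {"pop0": "A", "pop1": "B"})
        res = amova(m, pmap, levels=3, n_perm=0)
        assert res.phi_ct == pytest.approx(1.0)


class TestPermutations:
    def test_pvalue_detects_structure(self):
        geno = np.zeros((12, 20), np.int8)
        geno[6:] = 2
        m = make_matrix(geno)
        pmap = make_popmap(12, [6, 6])
        res = amova(m, pmap, levels=2, n_perm=199, seed=0)
        assert res.p_values["phi_st"] < 0.02

    def test_pvalue_uniform_under_exchangeable_null(self):
        # Kolmogorov-Smirnov over 200 panmictic replicates
        rng = np.random.default_rng(11)
        pmap = make_popmap(12, [6, 6])
        pvals = []
        for _ in range(200):
            geno = rng.binomial(2, 0.4, size=(12, 15)).astype(np.int8)
            res = amova(make_matrix(geno), pmap, levels=2, n_perm=49,
                        seed=int(rng.integers(2**31)))
            pvals.append(res.p_values["phi_st"])
        stat = stats.kstest(pvals, "uniform").statistic
        # discrete p-grid (k+1)/50 inflates KS slightly; allow that plus noise
        assert stat < 0.13


class TestDiversityGradient:
    def test_constant_values_degenerate(self):
        coords = {f"p{i}": (float(i), float(i)) for i in range(5)}
        r, p = diversity_gradient({f"p{i}": 1.0 for i in range(5)}, coords, "lat")
        assert r == 0.0 and p == 1.0

    def test_exact_linear_in_longitude(self):
        coords = {f"p{i}": (0.0, float(i)) for i in range(6)}
        vals = {f"p{i}": 2.0 - 0.3 * i for i in range(6)}
        r, p = diversity_gradient(vals, coords, "lon")
        assert r == pytest.approx(-1.0)
        assert p < 1e-6

    def test_matches_closed_form(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=22)
        y = 0.4 * x + rng.normal(scale=0.5, size=22)
        coords = {f"p{i}": (x[i], 0.0) for i in range(22)}
        vals = {f"p{i}": y[i] for i in range(22)}
        r, _ = diversity_gradient(vals, coords, "lat")
        r_closed = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(r_closed, abs=1e-12)

    def test_zero_variance_predictor_rejected(self):
        coords = {f"p{i}": (1.0, float(i)) for i in range(4)}
        with pytest.raises(ValueError, match="zero variance"):
            diversity_gradient({f"p{i}": float(i) for i in range(4)}, coords,
                               "lat")
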