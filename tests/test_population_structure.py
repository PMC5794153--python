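"""AMOVA, Wright F_ST with G-test, Mantel — oracles and calibration."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dominant_sgs import Amova, MarkerMatrix, amova, fst_g_test, mantel_test
from dominant_sgs.population_structure import phenotype_sq_distances
from dominant_sgs.synthetic_data import SimConfig, simulate_clustered


def brute_force_amova(x: np.ndarray, labels: np.ndarray):
    """Independent oracle: centroid-based sums of squares and EMS components.

    Uses the identity sum_{i<j in g} d2/n_g = sum_{i in g} ||x_i - xbar_g||^2,
    a different route from the implementation's pairwise-distance form.
    """
    n, _ = x.shape
    pops = sorted(set(labels))
    k = len(pops)
    grand = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    ss_within = 0.0
    sizes = []
    for pop in pops:
        sub = x[labels == pop]
        sizes.append(len(sub))
        ss_within += float(((sub - sub.mean(axis=0)) ** 2).sum())
    ss_between = ss_total - ss_within
    df_b, df_w = k - 1, n - k
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    sizes = np.asarray(sizes, dtype=float)
    n0 = (n - (sizes**2).sum() / n) / (k - 1)
    s2_w = ms_w
    s2_b = (ms_b - ms_w) / n0
    return ss_between, ss_within, s2_b, s2_w


def _mm(x):
    x = np.asarray(x, dtype=np.int8)
    return MarkerMatrix(
        [f"i{k}" for k in range(x.shape[0])], [f"L{j}" for j in range(x.shape[1])], x
    )


class TestAmova:
    def test_internally_identical_opposite_populations_phi_one(self):
        x = np.array([[1, 1, 1, 1]] * 4 + [[0, 0, 0, 0]] * 4)
        res = amova(_mm(x), ["A"] * 4 + ["B"] * 4, n_perm=99, seed=1)
        assert res.phi_st == pytest.approx(1.0)
        assert res.pct_between == pytest.approx(100.0)

    def test_components_match_centroid_oracle_unequal_sizes(self, rng):
        x = rng.integers(0, 2, size=(8, 12))
        labels = np.array(["A"] * 3 + ["B"] * 5)
        res = amova(_mm(x), labels, n_perm=9, seed=0)
        ss_b, ss_w, s2_b, s2_w = brute_force_amova(x.astype(float), labels)
        assert res.ss_between == pytest.approx(ss_b, rel=1e-10)
        assert res.ss_within == pytest.approx(ss_w, rel=1e-10)
        assert res.sigma2_between == pytest.approx(s2_b, rel=1e-10)
        assert res.sigma2_within == pytest.approx(s2_w, rel=1e-10)

    def test_exact_p_matches_independent_enumeration(self, rng):
        x = rng.integers(0, 2, size=(6, 10))
        labels = np.array(["A", "A", "A", "B", "B", "B"])
        res = amova(_mm(x), labels, method="exact")
        # independent enumeration via the centroid-based oracle
        phis = []
        xf = x.astype(float)
        for perm in itertools.permutations(range(6)):
            *_, s2b, s2w = brute_force_amova(xf, labels[list(perm)])
            tot = s2b + s2w
            phis.append(0.0 if tot <= 0 else s2b / tot)
        phis = np.asarray(phis)
        obs = phis[0]  # identity permutation is first
        expect = float(np.mean(phis >= obs - 1e-12))
        assert res.p_value == pytest.approx(expect, abs=1e-12)

    def test_random_labels_on_panmictic_data_phi_near_zero(self, rng):
        x = rng.integers(0, 2, size=(120, 150))
        labels = rng.permutation(["A"] * 60 + ["B"] * 60)
        res = amova(_mm(x), labels, n_perm=99, seed=5)
        assert abs(res.phi_st) < 0.02
        assert res.p_value > 0.05

    def test_singleton_population_excluded_with_warning(self, rng):
        x = rng.integers(0, 2, size=(7, 5))
        with pytest.warns(UserWarning, match="single individual"):
            res = amova(_mm(x), ["A", "A", "A", "B", "B", "B", "C"], n_perm=9, seed=0)
        assert res.df_between == 1  # C dropped -> 2 groups

    def test_identical_phenotypes_phi_reported_zero_with_note(self):
        x = np.ones((6, 4), dtype=np.int8)
        res = amova(_mm(x), ["A"] * 3 + ["B"] * 3, n_perm=9, seed=0)
        assert res.phi_st == 0.0
        assert "identical" in res.note

    @given(st.integers(0, 5000))
    def test_percent_variance_sums_to_100(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 16))
        x = rng.integers(0, 2, size=(n, 8))
        labels = rng.choice(["A", "B", "C"], size=n)
        if min((labels == p).sum() for p in "ABC") < 2:
            return
        res = amova(_mm(x), labels, n_perm=5, seed=0)
        assert res.pct_between + res.pct_within == pytest.approx(100.0)

    def test_permutation_p_reproducible_under_seed(self, rng):
        x = rng.integers(0, 2, size=(20, 30))
        labels = ["A"] * 10 + ["B"] * 10
        p1 = amova(_mm(x), labels, n_perm=199, seed=7).p_value
        p2 = amova(_mm(x), labels, n_perm=199, seed=7).p_value
        assert p1 == p2

    def test_missing_data_pairwise_rescaling(self):
        from dominant_sgs import MISSING

        x = np.array([[1, 0, MISSING, 1], [0, 1, 1, MISSING], [1, 1, 0, 0]])
        d2 = phenotype_sq_distances(_mm(x))
        # pair (0,1): shared loci L1,L2 -> raw 2, rescaled by 4/2
        assert d2[0, 1] == pytest.approx(4.0)
        assert d2[0, 2] == pytest.approx(2 * 4 / 3)
        np.testing.assert_allclose(d2, d2.T)


class TestFst:
    def test_identical_populations_near_zero(self, rng):
        x = np.vstack([rng.integers(0, 2, size=(60, 200))])
        labels = ["A"] * 30 + ["B"] * 30
        res = fst_g_test(_mm(x), labels, n_perm=99, seed=1)
        assert abs(res.fst) < 0.03

    def test_fixed_opposite_populations(self):
        x = np.array([[1] * 30] * 10 + [[0] * 30] * 10)
        res = fst_g_test(_mm(x), ["A"] * 10 + ["B"] * 10, n_perm=99, seed=1)
        assert res.fst > 0.8  # dominant-data attenuation keeps it below 1
        assert res.p_value == pytest.approx(1 / 100)

    def test_monomorphic_matrix_rejected(self):
        x = np.ones((8, 5), dtype=np.int8)
        with pytest.raises(ValueError, match="monomorphic"):
            fst_g_test(_mm(x), ["A"] * 4 + ["B"] * 4, n_perm=9, seed=0)

    def test_recovers_divergence_target(self):
        # Balding-Nichols theta=0.4, HWE within populations
        vals = []
        for seed in range(3):
            cfg = SimConfig(seed=seed, theta_div=0.4, selfing=0.0,
                            n_individuals=(30,) * 6, n_loci=400)
            mk, sm, _ = simulate_clustered(cfg)
            vals.append(fst_g_test(mk, sm.labels(), n_perm=1, seed=0).fst)
        assert np.mean(vals) == pytest.approx(0.4, abs=0.08)


class TestMantel:
    def test_proportional_matrices_r_one(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        res = mantel_test(d, 3.5 * d, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_hand_computed_three_populations(self):
        g = np.array([[0, 0.1, 0.4], [0.1, 0, 0.2], [0.4, 0.2, 0]])
        e = np.array([[0, 10.0, 30.0], [10.0, 0, 25.0], [30.0, 25.0, 0]])
        with pytest.warns(UserWarning, match="resolution"):
            res = mantel_test(g, e, n_perm=99, seed=0)
        v1, v2 = np.array([0.1, 0.4, 0.2]), np.array([10.0, 30.0, 25.0])
        expect = np.corrcoef(v1, v2)[0, 1]
        assert res.r == pytest.approx(expect, abs=1e-12)

    def test_cross_checks_scikit_bio(self, rng):
        from skbio.stats.distance import mantel as skbio_mantel

        a = rng.uniform(1, 10, size=(6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = rng.uniform(1, 10, size=(6, 6))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        res = mantel_test(a, b, n_perm=99, seed=0)
        r_ref = skbio_mantel(a, b, permutations=0)[0]
        assert res.r == pytest.approx(r_ref, abs=1e-10)

    def test_asymmetric_input_rejected(self):
        bad = np.arange(9, dtype=float).reshape(3, 3)
        with pytest.raises(ValueError, match="symmetric"):
            mantel_test(bad, bad, n_perm=9, seed=0)

    def test_null_p_roughly_uniform(self, rng):
        # independent random matrices, k=6: p should not pile up near 0 or 1
        ps = []
        for _ in range(120):
            def rand_d():
                m = rng.uniform(0, 1, size=(6, 6))
                m = (m + m.T) / 2
                np.fill_diagonal(m, 0)
                return m
            ps.append(mantel_test(rand_d(), rand_d(), n_perm=199, seed=int(rng.integers(2**31))).p_value)
        ps = np.asarray(ps)
        assert 0.35 < ps.mean() < 0.65
        assert (ps < 0.05).mean() < 0.15
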