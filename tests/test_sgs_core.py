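"""Kinship estimator, distance classes, correlogram regression and dispersal."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dominant_sgs import (
    MarkerMatrix,
    build_distance_classes,
    dispersal_estimates,
    fit_sgs,
    gene_dispersal_sigma,
    kinship_dominant,
    neighborhood_size,
    sp_statistic,
)
from dominant_sgs.dominant_freqs import UNIFORM_PRIOR, LocusFreqs
from dominant_sgs.sgs_core import KinshipMatrix
from dominant_sgs.synthetic_data import dominant_mask


def known_freqs(p, n=10**6):
    p = np.asarray(p, dtype=float)
    return LocusFreqs(
        locus_ids=[f"L{i}" for i in range(p.size)],
        n=np.full(p.size, n),
        m=np.zeros(p.size, dtype=int),
        q_hat=1.0 - p,
        p_hat=p,
        var_q=np.zeros(p.size),
        prior=UNIFORM_PRIOR,
    )


def _mm(x):
    x = np.asarray(x, dtype=np.int8)
    return MarkerMatrix(
        [f"i{k}" for k in range(x.shape[0])], [f"L{j}" for j in range(x.shape[1])], x
    )


class TestKinship:
    def test_hand_evaluated_formula_at_half_frequencies(self):
        # p=q=0.5, F_IS=0: B=0.75, per-locus denominator 4*0.5*0.5*0.25=0.25;
        # two all-band individuals over 100 loci -> 0.25^2*100 / 0.25*100 = 0.25
        x = np.ones((2, 100), dtype=np.int8)
        # a third individual with no bands keeps every locus polymorphic in-sample
        x = np.vstack([x, np.zeros((1, 100), dtype=np.int8)])
        k = kinship_dominant(_mm(x), known_freqs([0.5] * 100))
        assert k.values[0, 1] == pytest.approx(0.25, abs=1e-12)

    def test_unrelated_pairs_mean_near_zero(self, rng):
        p = rng.uniform(0.2, 0.8, 400)
        pheno = (rng.random((150, 400)) < 1 - (1 - p) ** 2).astype(np.int8)
        k = kinship_dominant(_mm(pheno), known_freqs(p))
        vals = k.condensed()
        assert abs(np.nanmean(vals)) < 0.005  # ~11k pairs x 400 loci

    def test_pedigree_calibration_slope_and_class_means(self, rng):
        # parent-offspring and half-sib are unbiased; full-sib inflates by the
        # four-gene identity term k2*E[p q^2(1+q)]/(4 E[p q^3]) - k2/2 ~ +0.05
        L, npairs = 600, 400
        p = rng.uniform(0.2, 0.8, L)

        def geno(n):
            return rng.binomial(2, p, size=(n, L)).astype(np.int8)

        def child(g1, g2):
            m = (rng.random(g1.shape) < g1 / 2).astype(np.int8)
            f = (rng.random(g2.shape) < g2 / 2).astype(np.int8)
            return m + f

        def mean_f(ga, gb):
            n = ga.shape[0]
            x = np.empty((2 * n, L), np.int8)
            x[0::2] = dominant_mask(ga)
            x[1::2] = dominant_mask(gb)
            k = kinship_dominant(_mm(x), known_freqs(p))
            return float(np.nanmean(k.values[np.arange(0, 2 * n, 2), np.arange(1, 2 * n, 2)]))

        pa, pb, pc = geno(npairs), geno(npairs), geno(npairs)
        f_un = mean_f(pa, pb)
        f_po = mean_f(pa, child(pa, pb))
        f_fs = mean_f(child(pa, pb), child(pa, pb))
        f_hs = mean_f(child(pa, pb), child(pa, pc))
        assert abs(f_un) < 0.02
        assert f_po == pytest.approx(0.25, rel=0.15)
        assert f_hs == pytest.approx(0.125, rel=0.15)
        assert 0.25 < f_fs < 0.33  # dominance inflation, upper bound from theory
        theta = np.array([0.0, 0.125, 0.25, 0.25])
        est = np.array([f_un, f_hs, f_po, f_fs])
        xc = theta - theta.mean()
        slope = float((xc * est).sum() / (xc * xc).sum())
        assert slope == pytest.approx(1.0, abs=0.15)

    def test_missing_loci_dropped_from_both_sums(self):
        from dominant_sgs import MISSING

        x = np.array([[1, 1, 0, 1], [1, MISSING, 0, 0], [0, 0, 1, 1]])
        k = kinship_dominant(_mm(x), known_freqs([0.5] * 4))
        assert k.loci_used[0, 1] == 3
        assert np.isfinite(k.values[0, 1])

    def test_f_is_one_rejected(self, toy_markers):
        with pytest.raises(ValueError, match="F_IS"):
            kinship_dominant(toy_markers, known_freqs([0.5] * 4), f_is=1.0)

    def test_symmetry_nan_diagonal(self, rng):
        pheno = rng.integers(0, 2, size=(12, 60))
        k = kinship_dominant(_mm(pheno), known_freqs(rng.uniform(0.3, 0.7, 60)))
        np.testing.assert_allclose(k.values, k.values.T)
        assert np.isnan(np.diag(k.values)).all()


class TestDistanceClasses:
    def test_200_pairs_give_5_classes_of_40(self, rng):
        d = rng.uniform(1, 1000, 200)
        c = build_distance_classes(d, min_pairs=40)
        assert c.n_classes == 5
        assert c.pair_counts.min() >= 40
        assert c.conforming

    def test_55_pairs_single_class_fallback_flagged(self, rng):
        xy = rng.uniform(0, 100, size=(11, 2))
        from scipy.spatial.distance import pdist, squareform

        with pytest.warns(UserWarning, match="single class"):
            c = build_distance_classes(squareform(pdist(xy)), min_pairs=40)
        assert c.n_classes == 1
        assert not c.conforming

    def test_too_few_pairs_errors_with_guidance(self):
        with pytest.raises(ValueError, match="min_pairs"):
            build_distance_classes(np.array([1.0, 2.0, 3.0]), min_pairs=40)

    @given(st.integers(0, 3000))
    def test_accepted_output_always_meets_min_pairs(self, seed):
        rng = np.random.default_rng(seed)
        n_pairs = int(rng.integers(200, 2000))
        d = rng.gamma(2.0, 200.0, n_pairs) + 0.1
        c = build_distance_classes(d, min_pairs=40)
        assert 1 <= c.n_classes <= 30
        assert c.pair_counts.min() >= 40
        assert c.pair_counts.sum() == n_pairs
        # classes contiguous over the observed range
        assert c.bounds[0] <= d.min() and c.bounds[-1] > d.max() - 1e-9

    def test_assignment_uses_half_open_intervals(self):
        d = np.concatenate([np.full(50, 1.0), np.full(50, 2.0), np.full(50, 3.0),
                            np.full(50, 4.0), np.full(50, 5.0)])
        c = build_distance_classes(d, min_pairs=40)
        idx = c.assign(np.array([1.0, 4.999, 5.0]))
        assert idx[0] == 0
        assert idx[-1] == c.n_classes - 1


class TestFitSgs:
    def _uniform_kinship(self, n, value=0.1):
        v = np.full((n, n), value, dtype=float)
        np.fill_diagonal(v, np.nan)
        return KinshipMatrix([f"i{k}" for k in range(n)], v, np.full((n, n), 100), 0.0)

    def test_constant_kinship_zero_slope_no_significance(self, rng):
        n = 40
        xy = rng.uniform(0, 500, size=(n, 2))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(xy))
        res = fit_sgs(self._uniform_kinship(n), d, n_perm=200, seed=0)
        assert res.b_f == pytest.approx(0.0, abs=1e-12)
        assert not res.slope_significant
        assert not res.classes["significant"].any()
        assert res.sp == pytest.approx(0.0, abs=1e-12)

    def test_zero_distance_pairs_kept_in_first_class_not_regression(self, rng):
        n = 30
        xy = rng.uniform(0, 100, size=(n, 2))
        xy[1] = xy[0]  # co-located pair
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(xy))
        k = self._uniform_kinship(n)
        res = fit_sgs(k, d, n_perm=50, seed=0, min_pairs=40)
        assert res.n_pairs_regression == n * (n - 1) // 2 - 1

    def test_sp_identity_holds_exactly(self, rng):
        n = 45
        xy = rng.uniform(0, 800, size=(n, 2))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(xy))
        v = rng.normal(0, 0.05, (n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, np.nan)
        k = KinshipMatrix([f"i{j}" for j in range(n)], v, np.full((n, n), 50), 0.0)
        res = fit_sgs(k, d, n_perm=100, seed=3)
        assert res.sp == sp_statistic(res.b_f, res.f1)

    def test_deterministic_under_seed(self, rng):
        n = 35
        xy = rng.uniform(0, 300, size=(n, 2))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(xy))
        v = rng.normal(0, 0.05, (n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, np.nan)
        k = KinshipMatrix([f"i{j}" for j in range(n)], v, np.full((n, n), 50), 0.0)
        r1 = fit_sgs(k, d, n_perm=100, seed=11)
        r2 = fit_sgs(k, d, n_perm=100, seed=11)
        assert r1.b_f_env == r2.b_f_env
        pd.testing.assert_frame_equal(r1.classes, r2.classes)


class TestSpAndDispersal:
    @pytest.mark.parametrize(
        "f1,bf,expected",
        [
            (0.15, -0.06, 0.07),   # whole patchy stand
            (0.14, -0.20, 0.23),   # pristine subgroup
            (0.06, -0.03, 0.03),   # disturbed subgroup
        ],
    )
    def test_sp_worked_examples_to_2dp(self, f1, bf, expected):
        assert round(sp_statistic(bf, f1), 2) == expected

    @pytest.mark.parametrize(
        "nb,de,expected",
        [
            (20.5, 8.19, 44.6),    # roadside stand, census density
            (15.2, 2.72, 66.7),
            (31.9, 3.40, 86.4),
            (64.3, 0.69, 272.3),   # printed 273.1; printed inputs are rounded
        ],
    )
    def test_sigma_g_from_printed_nb_and_density(self, nb, de, expected):
        assert gene_dispersal_sigma(nb, de) == pytest.approx(expected, rel=0.01)

    def test_tenth_density_scenario_reproduces_211m(self):
        assert gene_dispersal_sigma(15.2, 2.72, 0.1) == pytest.approx(210.8, rel=0.01)

    def test_halving_density_scales_sigma_by_sqrt2_exactly(self):
        base = gene_dispersal_sigma(20.0, 5.0, 1.0)
        assert gene_dispersal_sigma(20.0, 5.0, 0.5) == pytest.approx(base * np.sqrt(2.0), rel=1e-12)

    def test_dispersal_table_scenarios(self):
        est = dispersal_estimates(f_1=0.05, b_f=-0.05, census_density_per_ha=8.19)
        assert est.nb == pytest.approx((0.05 - 1) / -0.05)
        tab = est.table.set_index("fraction")["sigma_g_m"]
        assert tab[0.25] == pytest.approx(tab[1.0] * 2.0, rel=1e-12)
        assert tab[0.1] == pytest.approx(tab[1.0] * np.sqrt(10), rel=1e-12)

    def test_positive_slope_refused(self):
        with pytest.raises(ValueError, match="no positive SGS"):
            dispersal_estimates(f_1=0.1, b_f=0.02, census_density_per_ha=5.0)
        with pytest.raises(ValueError, match="negative"):
            neighborhood_size(0.1, 0.01)

    def test_nonsignificant_slope_suppressed(self):
        with pytest.raises(ValueError, match="suppressed"):
            dispersal_estimates(f_1=0.1, b_f=-0.02, census_density_per_ha=5.0,
                                significant=False)

    def test_invalid_density_rejected(self):
        with pytest.raises(ValueError, match="density"):
            dispersal_estimates(f_1=0.1, b_f=-0.02, census_density_per_ha=0.0)
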