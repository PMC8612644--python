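"""Peak harvesting, ANOSIM, rank tests, mixture AIC, and Dice overlap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from facemvpa import studies, topography
from facemvpa.topography import (
    PeakSet,
    anosim,
    bonferroni,
    compare_mixtures,
    dice,
    euclidean_dissimilarity,
    mixture_aic,
    peak_location_tests,
)


def brute_force_anosim_r(d, labels):
    """Exhaustive rank computation of the ANOSIM statistic."""
    n = d.shape[0]
    pairs, groups = [], []
    for i in range(n):
        for j in range(i + 1, n):
            pairs.append(d[i, j])
            groups.append(labels[i] == labels[j])
    ranks = stats.rankdata(pairs)
    within = np.array(groups)
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    return (rb - rw) / (len(pairs) / 2)


class TestAnosim:
    def test_two_separated_line_groups_give_r_one(self):
        """Hand-checkable example: ranked within {1.5, 1.5}, between
        {3, 4.5, 4.5, 6} -> R = (4.5 - 1.5) / 3 = 1."""
        pts = np.array([[0.0], [1.0], [10.0], [11.0]])
        d = np.abs(pts - pts.T)
        res = anosim(d, np.array(["a", "a", "b", "b"]), n_perm=99, seed=1)
        assert res.R == pytest.approx(1.0)

    def test_all_identical_points_give_r_zero(self):
        d = np.zeros((6, 6))
        res = anosim(d, np.array(["a"] * 3 + ["b"] * 3), n_perm=99, seed=2)
        assert res.R == pytest.approx(0.0)
        assert res.p == 1.0  # every permutation ties the observed statistic

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_r_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 9))
        pts = rng.normal(size=(n, 2))
        labels = rng.choice(["a", "b"], size=n)
        while min((labels == "a").sum(), (labels == "b").sum()) < 2:
            labels = rng.choice(["a", "b"], size=n)
        d = euclidean_dissimilarity(pts)
        res = anosim(d, labels, n_perm=9, seed=3)
        assert res.R == pytest.approx(brute_force_anosim_r(d, labels))

    def test_r_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(9, 3))
        labels = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        d = euclidean_dissimilarity(pts)
        r1 = anosim(d, labels, n_perm=9, seed=5).R
        r2 = anosim(np.expm1(2 * d), labels, n_perm=9, seed=5).R
        assert r1 == pytest.approx(r2)

    def test_matches_independent_reference_implementation(self):
        """Cross-check the R statistic against scikit-bio's ANOSIM."""
        from skbio import DistanceMatrix
        from skbio.stats.distance import anosim as skbio_anosim

        rng = np.random.default_rng(6)
        pts = np.vstack([rng.normal(0, 1, (8, 3)), rng.normal(1.5, 1, (8, 3))])
        labels = np.array(["a"] * 8 + ["b"] * 8)
        d = euclidean_dissimilarity(pts)
        ours = anosim(d, labels, n_perm=99, seed=7)
        ref = skbio_anosim(DistanceMatrix(d), labels.tolist(), permutations=99)
        assert ours.R == pytest.approx(float(ref["test statistic"]), abs=1e-12)

    def test_pvalue_uses_add_one_convention(self):
        rng = np.random.default_rng(8)
        pts = np.vstack([rng.normal(0, 1, (5, 3)), rng.normal(9, 1, (5, 3))])
        labels = np.array(["a"] * 5 + ["b"] * 5)
        res = anosim(euclidean_dissimilarity(pts), labels, n_perm=199, seed=9)
        assert res.p >= 1.0 / 200.0  # never exactly zero

    def test_singleton_group_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError, match="single member"):
            anosim(d, np.array(["a", "a", "b"]), n_perm=9, seed=10)

    def test_null_pvalues_approximately_uniform(self):
        """Random labels on i.i.d. points: p is uniform (KS at alpha=0.01)."""
        rng = np.random.default_rng(11)
        ps = []
        for i in range(200):
            pts = rng.normal(size=(18, 3))
            labels = np.repeat(["a", "b", "c"], 6)
            rng.shuffle(labels)
            ps.append(anosim(euclidean_dissimilarity(pts), labels,
                             n_perm=99, seed=1100 + i).p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestPeakLocationTests:
    def test_planted_shift_on_one_axis_detected_only_there(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 2, (200, 3))
        b = a + np.array([0.0, 10.0, 0.0])  # anterior shift only
        res = peak_location_tests([PeakSet("g1", a), PeakSet("g2", b)])
        assert res.kruskal_p_corrected["A"] < 0.05
        assert res.kruskal_p_corrected["R"] > 0.05
        assert res.kruskal_p_corrected["S"] > 0.05
        assert res.joint_significant

    def test_identical_distributions_rarely_rejected(self):
        rng = np.random.default_rng(13)
        hits = 0
        for _ in range(100):
            a = rng.normal(0, 2, (40, 3))
            b = rng.normal(0, 2, (40, 3))
            res = peak_location_tests([PeakSet("g1", a), PeakSet("g2", b)])
            hits += res.joint_significant
        assert hits <= 6  # >= 94 of 100 null replicates stay negative

    def test_bonferroni_multiplies_and_caps(self):
        assert bonferroni(0.01, 3) == pytest.approx(0.03)
        assert bonferroni(0.5, 3) == 1.0
        assert np.allclose(bonferroni(np.array([0.01, 0.4]), 3), [0.03, 1.0])

    def test_constant_axis_skipped_with_note(self):
        rng = np.random.default_rng(14)
        a = np.column_stack([rng.normal(size=10), np.zeros(10), rng.normal(size=10)])
        b = np.column_stack([rng.normal(size=10), np.zeros(10), rng.normal(size=10)])
        res = peak_location_tests([PeakSet("g1", a), PeakSet("g2", b)])
        assert res.skipped_axes == ["A"]
        assert "A" not in res.kruskal_p


class TestMixtureAic:
    def test_aic_formula(self):
        fit = topography.MixtureFit(k=1, log_likelihood=0.0, n_params=1, aic=2.0)
        assert fit.aic == 2 * fit.n_params - 2 * fit.log_likelihood

    def test_parameter_count(self):
        pts, labels = studies.sample_cluster_points(seed=15)
        f1 = mixture_aic(pts, labels, k=1)
        f3 = mixture_aic(pts, labels, k=3)
        assert f1.n_params == 9 and f3.n_params == 29  # 10k - 1

    def test_single_cluster_prefers_one_component(self):
        rng = np.random.default_rng(16)
        pts = rng.normal(0, 1, (60, 3))
        labels = np.repeat([0, 1, 2], 20)  # arbitrary split of one cloud
        f1 = mixture_aic(pts, labels, k=1)
        f3 = mixture_aic(pts, labels, k=3)
        assert f1.aic < f3.aic

    def test_three_separated_clusters_prefer_three_components(self):
        pts, labels = studies.sample_cluster_points(seed=17, separation=10.0)
        f1, f3 = compare_mixtures([mixture_aic(pts, labels, k=1),
                                   mixture_aic(pts, labels, k=3)])
        assert f3.aic < f1.aic
        assert f3.relative_likelihood == 1.0
        assert f1.relative_likelihood < 0.05

    def test_log_likelihood_matches_direct_evaluation(self):
        pts, labels = studies.sample_cluster_points(seed=18, n_per_group=10)
        fit = mixture_aic(pts, labels, k=3)
        ll = 0.0
        for x in pts:
            dens = 0.0
            for g in np.unique(labels):
                sub = pts[labels == g]
                dens += (len(sub) / len(pts)) * stats.multivariate_normal(
                    sub.mean(axis=0), np.cov(sub.T)
                ).pdf(x)
            ll += np.log(dens)
        assert fit.log_likelihood == pytest.approx(ll)

    def test_degenerate_cluster_regularized_not_crashed(self):
        pts = np.zeros((12, 3))  # identical points: singular covariance
        labels = np.repeat([0, 1, 2], 4)
        with pytest.warns(UserWarning, match="regularized"):
            fit = mixture_aic(pts, labels, k=3)
        assert np.isfinite(fit.aic)

    def test_mismatched_k_rejected(self):
        pts, labels = studies.sample_cluster_points(seed=19)
        with pytest.raises(ValueError, match="groups"):
            mixture_aic(pts, labels, k=2)


class TestDice:
    def test_identical_nonempty_masks(self):
        m = np.zeros(20, dtype=bool)
        m[3:9] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros(20, dtype=bool)
        b = np.zeros(20, dtype=bool)
        a[:5], b[10:] = True, True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros(10, dtype=bool)
        b = np.zeros(10, dtype=bool)
        a[[0, 1]] = True
        b[[1, 2]] = True
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty_defined_as_zero(self):
        assert dice(np.zeros(5, dtype=bool), np.zeros(5, dtype=bool)) == 0.0

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_and_identity_property(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random(30) < 0.4
        b = rng.random(30) < 0.4
        assert dice(a, b) == dice(b, a)
        if a.any():
            assert (dice(a, b) == 1.0) == np.array_equal(a, b)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros(4, dtype=bool), np.zeros(5, dtype=bool))


class TestHarvestPeaks:
    def test_peak_count_containment_and_determinism(self, design16):
        """n_perm controls the number of points per label; with a strong
        planted signal every univariate peak falls inside the familiarity
        region, and the harvest is seed-deterministic."""
        ds = studies.simulate_topography_dataset(
            seed=20, n_subjects=2, design=design16, amplitude_scale=30.0
        )
        ps = topography.harvest_peaks(ds, "univariate_contrast", n_perm=6, seed=21)
        assert ps.n_points == 6
        center = studies.planted_centers_mm()["familiarity"]
        assert np.linalg.norm(ps.points - center, axis=1).max() <= studies.TOPO_RADIUS_MM
        ps2 = topography.harvest_peaks(ds, "univariate_contrast", n_perm=6, seed=21)
        assert np.array_equal(ps.points, ps2.points)

    def test_subcategory_pair_restriction(self, design16):
        ds = studies.simulate_topography_dataset(
            seed=22, n_subjects=2, design=design16
        )
        ps = topography.harvest_peaks(
            ds, "subcategory_searchlight", n_perm=3, seed=23,
            subcategory_pair=("cinema", "music"),
        )
        assert ps.label == "subcategory_cinema+music"
        assert ps.n_points == 3
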