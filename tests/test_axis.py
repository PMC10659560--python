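"""Euclidean ImAge axes: fitting, projection, diagnostics."""

import numpy as np
import pandas as pd
import pytest

import chromage as c
from chromage import axis as ax


def _blobs(rng, n=60, d=4, sep=3.0, young_cov=None):
    young = rng.standard_normal((n, d))
    if young_cov is not None:
        young = young @ young_cov
    old = rng.standard_normal((n, d))
    old[:, 0] += sep
    x = np.vstack([young, old])
    labels = np.array(["young"] * n + ["old"] * n)
    return x, labels


class TestCentroidAxis:
    def test_two_point_geometry(self):
        x = np.array([[0.0, 0.0], [2.0, 0.0]])
        labels = np.array(["young", "old"])
        a = ax.fit_centroid_axis(x, labels)
        np.testing.assert_allclose(a.direction, [1.0, 0.0])
        np.testing.assert_allclose(a.origin, [0.0, 0.0])

    def test_label_swap_reorients(self):
        rng = np.random.default_rng(0)
        x, labels = _blobs(rng)
        a1 = ax.fit_centroid_axis(x, labels)
        swapped = np.where(labels == "young", "old", "young")
        a2 = ax.fit_centroid_axis(x, swapped)
        # orientation contract re-flips: old mean projection > young's in both
        for a, lab in [(a1, labels), (a2, swapped)]:
            p = ax.project(x, a)["p"].to_numpy()
            assert p[lab == "old"].mean() > p[lab == "young"].mean()

    def test_coincident_centroids_raise(self):
        x = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="coincide"):
            ax.fit_centroid_axis(x, np.array(["young", "old"]))

    def test_recovers_planted_drift(self, drift_table, small_pipeline_result):
        spec, _ = drift_table
        res = small_pipeline_result
        cos = abs(res.axis.direction @ spec.unit_drift())
        # at this noise level and 3 animals/group the z-scored direction is
        # noisy in the off-drift coordinates; the drift loading must still
        # dominate (the high-SNR recovery bound is exercised separately)
        assert np.argmax(np.abs(res.axis.direction)) == 0
        assert cos > 0.5


class TestSvmAxis:
    def test_separable_blobs_perfect_accuracy(self):
        rng = np.random.default_rng(1)
        x, labels = _blobs(rng, sep=8.0)
        a = ax.fit_svm_axis(x, labels)
        assert ax.separation_accuracy(x, labels, a) == 1.0

    def test_skewed_young_group_favors_svm(self):
        """Mixture-skewed young group: SVM separates held-out data better
        than the centroid axis (the centroid is dragged by the heavy tail)."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 80
            tail = rng.standard_normal((n // 4, 3)) + [-12, 0, 0]
            bulk = rng.standard_normal((3 * n // 4, 3))
            young = np.vstack([bulk, tail])
            old = rng.standard_normal((n, 3)) + [2.5, 0, 0]
            x = np.vstack([young, old])
            labels = np.array(["young"] * n + ["old"] * n)
            tr = rng.random(2 * n) < 0.7
            a_svm = ax.fit_svm_axis(x[tr], labels[tr])
            a_cen = ax.fit_centroid_axis(x[tr], labels[tr])
            acc_svm = ax.separation_accuracy(x[~tr], labels[~tr], a_svm)
            acc_cen = ax.separation_accuracy(x[~tr], labels[~tr], a_cen)
            wins += acc_svm >= acc_cen
        assert wins >= 15

    def test_anisotropic_directions_differ_but_both_oriented(self):
        rng = np.random.default_rng(2)
        cov = np.array([[1.0, 0.0, 0.0], [0.0, 5.0, 0.0], [0.0, 0.0, 1.0]])
        young = rng.standard_normal((200, 3)) @ cov
        old = rng.standard_normal((200, 3)) @ cov + [4, 8, 0]
        x = np.vstack([young, old])
        labels = np.array(["young"] * 200 + ["old"] * 200)
        a_svm = ax.fit_svm_axis(x, labels)
        a_cen = ax.fit_centroid_axis(x, labels)
        assert abs(a_svm.direction @ a_cen.direction) < 0.999
        for a in (a_svm, a_cen):
            p = ax.project(x, a)["p"].to_numpy()
            assert p[labels == "old"].mean() > p[labels == "young"].mean()


class TestProjection:
    def test_point_on_axis_and_origin(self):
        a = ax.ImAgeAxis(np.zeros(3), np.array([1.0, 0, 0]), "centroid")
        r = ax.project(np.array([[5.0, 0, 0], [0.0, 0, 0]]), a)
        assert r["d_o"].iloc[0] == 0.0
        assert r["p"].iloc[1] == 0.0

    def test_matches_least_squares_oracle(self):
        rng = np.random.default_rng(3)
        origin = rng.standard_normal(5)
        d = rng.standard_normal(5)
        d /= np.linalg.norm(d)
        a = ax.ImAgeAxis(origin, d, "centroid")
        pts = rng.standard_normal((50, 5))
        r = ax.project(pts, a)
        for i, x in enumerate(pts):
            # distance to the line via least-squares residual
            t, *_ = np.linalg.lstsq(d[:, None], x - origin, rcond=None)
            resid = np.linalg.norm((x - origin) - d * t)
            assert abs(r["d_o"].iloc[i] - resid) <= 1e-9

    def test_pythagoras_identity(self):
        rng = np.random.default_rng(4)
        d = rng.standard_normal(6)
        a = ax.ImAgeAxis(rng.standard_normal(6), d, "centroid")
        pts = rng.standard_normal((100, 6))
        r = ax.project(pts, a)
        rel = pts - a.origin
        np.testing.assert_allclose(r["p"] ** 2 + r["d_o"] ** 2,
                                   (rel**2).sum(axis=1), atol=1e-9)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(5)
        pts = rng.standard_normal((20, 4))
        d = rng.standard_normal(4)
        shift = rng.standard_normal(4)
        a1 = ax.ImAgeAxis(np.zeros(4), d, "centroid")
        a2 = ax.ImAgeAxis(shift, d, "centroid")
        r1 = ax.project(pts, a1)
        r2 = ax.project(pts + shift, a2)
        np.testing.assert_allclose(r1["p"], r2["p"], atol=1e-12)
        np.testing.assert_allclose(r1["d_o"], r2["d_o"], atol=1e-12)

    def test_dim_mismatch_raises(self):
        a = ax.ImAgeAxis(np.zeros(3), np.array([1.0, 0, 0]), "centroid")
        with pytest.raises(ValueError):
            ax.project(np.zeros((2, 4)), a)


class TestVarianceFraction:
    def test_all_variance_on_axis(self):
        t = np.linspace(0, 1, 30)[:, None]
        x = t * np.array([[1.0, 0, 0]])
        a = ax.ImAgeAxis(np.zeros(3), np.array([1.0, 0, 0]), "centroid")
        assert ax.axis_variance_fraction(x, a) == pytest.approx(1.0)

    def test_isotropic_noise_near_one_over_d(self):
        rng = np.random.default_rng(6)
        d = 8
        x = rng.standard_normal((4000, d))
        a = ax.ImAgeAxis(np.zeros(d), np.eye(d)[0], "centroid")
        frac = ax.axis_variance_fraction(x, a)
        assert abs(frac - 1 / d) < 0.02

    def test_drift_dominates(self, small_pipeline_result):
        # on the raw (unstandardized) bootstrap means the drift feature's
        # between-group variance dwarfs the per-feature sampling noise
        res = small_pipeline_result
        boot = res.bootstrap_table
        x = boot[c.feature_columns(boot)].to_numpy()
        raw_axis = ax.fit_centroid_axis(x[boot["group"] != "middle"],
                                        boot.loc[boot["group"] != "middle", "group"].to_numpy())
        assert ax.axis_variance_fraction(x, raw_axis) > 0.5

    def test_zero_variance_raises(self):
        a = ax.ImAgeAxis(np.zeros(2), np.array([1.0, 0]), "centroid")
        with pytest.raises(ValueError):
            ax.axis_variance_fraction(np.ones((5, 2)), a)


class TestSeparationAndCorrelation:
    def test_identical_distributions_chance_level(self):
        rng = np.random.default_rng(7)
        accs = []
        for _ in range(20):
            x = rng.standard_normal((200, 3))
            labels = np.array(["young"] * 100 + ["old"] * 100)
            a = ax.fit_centroid_axis(x, labels)
            accs.append(ax.separation_accuracy(x, labels, a))
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_monotone_fixture_rho_one(self, small_pipeline_result):
        """Per-age-group median readouts are perfectly rank-ordered by age.

        (Per-animal Spearman cannot reach 1 with tied ages, so the monotone
        contract is checked at the age-group level.)"""
        res = small_pipeline_result
        med = res.readouts.groupby("age")["p"].median()
        from scipy.stats import spearmanr
        assert spearmanr(med.index, med.to_numpy()).statistic == pytest.approx(1.0)

    def test_aggregation_flagged(self, small_pipeline_result):
        assert small_pipeline_result.age_correlation["aggregation"] == "median"

    def test_constant_input_raises(self):
        df = pd.DataFrame({"animal": list("abc"), "age": [1, 2, 3], "p": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError):
            ax.age_correlation(df)


class TestOrganPairSpearman:
    @staticmethod
    def _readouts(values_by_organ, ages=(2, 15, 27), n_per_age=3):
        rows = []
        for organ, fn in values_by_organ.items():
            aid = 0
            for age in ages:
                for _ in range(n_per_age):
                    aid += 1
                    rows.append({"animal": f"m{aid}", "age": age, "organ": organ,
                                 "channel": "DAPI", "value": fn(age, aid)})
        return pd.DataFrame(rows)

    def test_identical_readouts_robust(self):
        r = self._readouts({"liver": lambda a, i: a + 0.01 * i,
                            "heart": lambda a, i: a + 0.01 * i})
        rep = c.organ_pair_spearman(r)
        assert np.allclose(rep["rho"], 1.0)
        assert rep["robust"].all()

    def test_single_age_driven_correlation_not_robust(self):
        rng = np.random.default_rng(8)
        # correlation exists only because the oldest age is an outlier block
        def liver(a, i):
            return (100.0 + 0.001 * i) if a == 27 else rng.normal()
        def heart(a, i):
            return (100.0 + 0.001 * i) if a == 27 else rng.normal()
        rep = c.organ_pair_spearman(self._readouts({"liver": liver, "heart": heart},
                                                   n_per_age=4))
        assert not rep["robust"].any()

    def test_bonferroni_factor_documented(self):
        r = self._readouts({"liver": lambda a, i: a, "heart": lambda a, i: a,
                            "brain": lambda a, i: -a})
        rep = c.organ_pair_spearman(r)
        n_pairs, n_channels, n_subsets = 3, 1, 4
        factor = n_pairs * n_channels * n_subsets
        raw = rep["p"].to_numpy()
        adj = rep["p_bonferroni"].to_numpy()
        np.testing.assert_allclose(adj, np.minimum(1.0, raw * factor))
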