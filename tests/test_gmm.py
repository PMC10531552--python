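import json

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from suvadc.gmm import (
    GaussianComponent,
    MixtureModel,
    assign_clusters,
    correlate_within_clusters,
    demarcation_thresholds,
    fit_gmm,
    gaussian_intersections,
)
from suvadc.standardize import znormalize_table

from .conftest import make_table


def _weighted_density(c, x):
    return np.exp(c.log_density(np.asarray(x)[:, None]))


def _grid_scan_roots(c1, c2, lo, hi, n=2_000_001):
    """Brute-force sign-change scan of the weighted density difference."""
    x = np.linspace(lo, hi, n)
    diff = _weighted_density(c1, x) - _weighted_density(c2, x)
    sign = np.sign(diff)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    return [(x[i] + x[i + 1]) / 2 for i in idx]


def _match_components(model, true_means):
    fitted = np.stack([c.mean for c in model.components])
    cost = np.linalg.norm(fitted[:, None, :] - np.asarray(true_means)[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    return rows, cols


class TestGaussianComponent:
    def test_rejects_bad_weight(self):
        with pytest.raises(ValueError, match="weight"):
            GaussianComponent(0.0, [0.0], [[1.0]])

    def test_rejects_non_pd_covariance(self):
        with pytest.raises(ValueError, match="positive-definite"):
            GaussianComponent(0.5, [0.0, 0.0], [[1.0, 2.0], [2.0, 1.0]])

    def test_log_density_matches_scipy(self, rng):
        from scipy.stats import multivariate_normal

        c = GaussianComponent(0.4, [1.0, -1.0], [[2.0, 0.3], [0.3, 0.5]])
        x = rng.normal(size=(50, 2))
        expected = np.log(0.4) + multivariate_normal.logpdf(x, c.mean, c.cov)
        np.testing.assert_allclose(c.log_density(x), expected, rtol=1e-10)


class TestFitGmm:
    def test_recovers_well_separated_2d_mixture(self, rng):
        true_means = [(-4.0, 0.0), (0.0, 3.0), (4.0, -2.0)]
        true_weights = [0.3, 0.45, 0.25]
        n = 10_000
        comp = rng.choice(3, size=n, p=true_weights)
        x = np.stack([rng.multivariate_normal(true_means[c], 0.25 * np.eye(2)) for c in comp])
        model = fit_gmm(x, k=3, seed=0)
        rows, cols = _match_components(model, true_means)
        for r, c in zip(rows, cols):
            assert np.linalg.norm(model.components[r].mean - np.asarray(true_means[c])) < 0.1
            assert abs(model.components[r].weight - true_weights[c]) < 0.03

    def test_loglik_monotone(self, rng):
        x = np.concatenate([rng.normal(-3, 1, 500), rng.normal(3, 1, 500)])
        model = fit_gmm(x, k=3, seed=0)
        ll = np.asarray(model.log_likelihoods)
        assert (np.diff(ll) >= -1e-8).all()

    def test_k1_equals_sample_moments(self, rng):
        y = rng.normal(2.0, 1.5, size=400)
        model = fit_gmm(y, k=1, seed=0, n_init=1)
        assert float(model.components[0].mean[0]) == pytest.approx(y.mean(), rel=1e-9)
        assert float(model.components[0].cov[0, 0]) == pytest.approx(y.var(), rel=1e-9)

    def test_restart_reproducibility(self, rng):
        x = rng.normal(size=(500, 2))
        a = fit_gmm(x, k=3, seed=123)
        b = fit_gmm(x, k=3, seed=123)
        assert a.to_json() == b.to_json()

    def test_collapsed_mixture_does_not_crash(self, rng):
        # one true component: extra fitted components stay tiny or the
        # covariance floor engages, without an exception
        x = rng.normal(0.0, 1.0, size=(2000, 2))
        model = fit_gmm(x, k=3, seed=0)
        assert sum(c.weight for c in model.components) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points(self, rng):
        with pytest.raises(ValueError, match="at least"):
            fit_gmm(rng.normal(size=(20, 2)), k=3)

    def test_identical_points(self):
        with pytest.raises(ValueError, match="identical"):
            fit_gmm(np.ones((100, 2)), k=3)

    def test_non_finite(self, rng):
        x = rng.normal(size=(100, 2))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_gmm(x, k=3)

    def test_1d_components_sorted_with_thresholds(self, rng):
        x = np.concatenate([rng.normal(m, 0.5, 400) for m in (-4, 0, 4)])
        model = fit_gmm(x, k=3, seed=0)
        means = [float(c.mean[0]) for c in model.components]
        assert means == sorted(means)
        assert model.demarcation is not None and len(model.demarcation) == 2


class TestIntersections:
    def test_symmetric_single_root(self):
        c1 = GaussianComponent(0.5, [0.0], [[1.0]])
        c2 = GaussianComponent(0.5, [2.0], [[1.0]])
        assert gaussian_intersections(c1, c2) == pytest.approx([1.0])

    def test_equal_means_unequal_variances(self):
        c1 = GaussianComponent(0.5, [0.0], [[1.0]])
        c2 = GaussianComponent(0.5, [0.0], [[4.0]])
        roots = gaussian_intersections(c1, c2)
        assert len(roots) == 2
        assert roots[0] == pytest.approx(-roots[1], abs=1e-12)
        scanned = _grid_scan_roots(c1, c2, -6, 6)
        assert len(scanned) == 2
        np.testing.assert_allclose(roots, scanned, atol=1e-5)

    def test_unequal_weights_shift_root_toward_light_component(self):
        heavy = GaussianComponent(0.9, [0.0], [[1.0]])
        light = GaussianComponent(0.1, [2.0], [[1.0]])
        (root,) = gaussian_intersections(heavy, light)
        assert root > 1.0  # pushed toward the lighter component's mean
        d1 = _weighted_density(heavy, [root])[0]
        d2 = _weighted_density(light, [root])[0]
        assert abs(d1 - d2) < 1e-9

    def test_density_equality_at_all_roots(self, rng):
        for _ in range(20):
            c1 = GaussianComponent(float(rng.uniform(0.1, 0.9)), [float(rng.normal())],
                                   [[float(rng.uniform(0.2, 3.0))]])
            c2 = GaussianComponent(float(rng.uniform(0.1, 0.9)), [float(rng.normal())],
                                   [[float(rng.uniform(0.2, 3.0))]])
            for root in gaussian_intersections(c1, c2):
                d1 = _weighted_density(c1, [root])[0]
                d2 = _weighted_density(c2, [root])[0]
                assert abs(d1 - d2) < 1e-9

    def test_identical_components_rejected(self):
        c = GaussianComponent(0.5, [0.0], [[1.0]])
        with pytest.raises(ValueError, match="identical"):
            gaussian_intersections(c, GaussianComponent(0.5, [0.0], [[1.0]]))

    def test_requires_1d(self):
        c2d = GaussianComponent(0.5, [0.0, 0.0], np.eye(2))
        with pytest.raises(ValueError, match="1D"):
            gaussian_intersections(c2d, c2d)


class TestDemarcationThresholds:
    @staticmethod
    def _model(weights, means, variances):
        comps = [GaussianComponent(w, [m], [[v]]) for w, m, v in zip(weights, means, variances)]
        return MixtureModel(comps, ndim=1)

    def test_symmetric_three_components(self):
        model = self._model([1 / 3] * 3, [-2.0, 0.0, 2.0], [1.0, 1.0, 1.0])
        assert demarcation_thresholds(model) == pytest.approx([-1.0, 1.0])

    def test_unequal_variances_match_grid_scan(self):
        model = self._model([0.3, 0.5, 0.2], [-3.0, 0.0, 3.5], [0.5, 1.5, 0.8])
        thresholds = demarcation_thresholds(model)
        for thr, (c1, c2) in zip(thresholds, zip(model.components[:-1], model.components[1:])):
            lo, hi = float(c1.mean[0]), float(c2.mean[0])
            scanned = [r for r in _grid_scan_roots(c1, c2, lo, hi) if lo < r < hi]
            assert scanned, "grid scan found no root between the means"
            assert min(abs(thr - r) for r in scanned) < 1e-5

    def test_exactly_k_minus_1(self):
        model = self._model([0.2, 0.3, 0.5], [-1.0, 0.5, 4.0], [1.0, 0.7, 2.0])
        assert len(demarcation_thresholds(model)) == 2

    def test_midpoint_fallback_when_no_root_between_means(self, caplog):
        # w1/w2 = e^4 shifts the equal-variance intersection to mu_mid + 4,
        # outside (0, 1): the midpoint is used and a warning logged
        w2 = 1.0 / (1.0 + np.exp(4.0) + 1e6)
        w1 = w2 * np.exp(4.0)
        w3 = 1.0 - w1 - w2
        model = self._model([w1, w2, w3], [0.0, 1.0, 100.0], [1.0, 1.0, 1.0])
        with caplog.at_level("WARNING", logger="suvadc.gmm"):
            thresholds = demarcation_thresholds(model)
        assert thresholds[0] == pytest.approx(0.5)
        assert any("midpoint" in rec.message for rec in caplog.records)

    def test_requires_sorted_means(self):
        model = self._model([0.5, 0.3, 0.2], [2.0, 0.0, -2.0], [1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="sorted"):
            demarcation_thresholds(model)

    def test_requires_1d_model(self):
        comps = [GaussianComponent(1 / 3, [0.0, 0.0], np.eye(2)) for _ in range(3)]
        model = MixtureModel(comps, ndim=2)
        with pytest.raises(ValueError, match="1D"):
            demarcation_thresholds(model)


def _normalized_phantom_table(rng, n=6000, coupling=-0.4):
    """Three well-separated (ADC, SUV) compartments with known labels."""
    means = {"vital": (850.0, 4.0), "equivocal": (900.0, 1.0), "low_vital": (1700.0, 1.2)}
    sds = (120.0, 0.5)
    fractions = {"vital": 0.3, "equivocal": 0.4, "low_vital": 0.3}
    rows_adc, rows_suv, rows_truth = [], [], []
    for name, frac in fractions.items():
        m = means[name]
        k = int(frac * n)
        rho = coupling if name == "vital" else 0.0
        cov = np.array([[sds[0] ** 2, rho * sds[0] * sds[1]],
                        [rho * sds[0] * sds[1], sds[1] ** 2]])
        draws = rng.multivariate_normal(m, cov, size=k)
        rows_adc.append(draws[:, 0])
        rows_suv.append(np.abs(draws[:, 1]))
        rows_truth.extend([name] * k)
    table = make_table(np.concatenate(rows_adc), np.concatenate(rows_suv), truth=rows_truth)
    table, _ = znormalize_table(table)
    return table, fractions


class TestAssignClusters:
    def test_recovers_truth_proportions(self, rng):
        table, fractions = _normalized_phantom_table(rng)
        data = table.df[["adc_norm", "suv_norm"]].to_numpy()
        model = fit_gmm(data, k=3, seed=0)
        _, proportions = assign_clusters(model, table)
        for name, frac in fractions.items():
            assert proportions[name] == pytest.approx(frac, abs=0.05)

    def test_proportions_sum_to_one(self, rng):
        table, _ = _normalized_phantom_table(rng, n=1500)
        model = fit_gmm(table.df[["adc_norm", "suv_norm"]].to_numpy(), k=3, seed=0)
        _, proportions = assign_clusters(model, table)
        assert sum(proportions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_voxel_at_component_mean_assigned_to_it(self, rng):
        table, _ = _normalized_phantom_table(rng, n=1500)
        model = fit_gmm(table.df[["adc_norm", "suv_norm"]].to_numpy(), k=3, seed=0)
        for j, comp in enumerate(model.components):
            if comp.weight < 0.1:
                continue
            resp = model.log_responsibilities(comp.mean[None, :])[0]
            assert int(np.argmax(resp)) == j

    def test_semantic_relabeling_invariant_to_permutation(self, rng):
        table, _ = _normalized_phantom_table(rng, n=1500)
        model = fit_gmm(table.df[["adc_norm", "suv_norm"]].to_numpy(), k=3, seed=0)
        labeled_a, props_a = assign_clusters(model, table)
        permuted = MixtureModel(
            components=[model.components[i] for i in (2, 0, 1)],
            ndim=2,
            log_likelihoods=model.log_likelihoods,
        )
        labeled_b, props_b = assign_clusters(permuted, table)
        assert props_a == props_b
        assert labeled_a.df["cluster"].equals(labeled_b.df["cluster"])

    def test_1d_assignment_by_thresholds(self, rng):
        x = np.concatenate([rng.normal(m, 0.4, 400) for m in (-3, 0, 3)])
        model = fit_gmm(x, k=3, seed=0)
        table = make_table(np.full(x.size, 1000.0), np.abs(x) + 1.0)
        table.df["suv_norm"] = x
        labeled, proportions = assign_clusters(model, table, feature="suv")
        thr = model.demarcation
        below = table.df["suv_norm"] < thr[0]
        assert (labeled.df.loc[below, "cluster"] == "low_vital").all()
        above = table.df["suv_norm"] > thr[1]
        assert (labeled.df.loc[above, "cluster"] == "vital").all()

    def test_missing_normalized_columns(self, rng):
        model = fit_gmm(rng.normal(size=(200, 2)), k=3, seed=0)
        with pytest.raises(ValueError, match="normalized"):
            assign_clusters(model, make_table([1000.0] * 5, [1.0] * 5))


class TestCorrelateWithinClusters:
    def test_recovers_vital_coupling(self, rng):
        table, _ = _normalized_phantom_table(rng, n=10_000, coupling=-0.4)
        model = fit_gmm(table.df[["adc_norm", "suv_norm"]].to_numpy(), k=3, seed=0)
        labeled, _ = assign_clusters(model, table)
        corr = correlate_within_clusters(labeled)
        assert corr["vital"]["r"] is not None
        assert corr["vital"]["r"] < 0
        assert corr["vital"]["r"] == pytest.approx(-0.4, abs=0.1)

    def test_null_coupling_gives_small_r(self, rng):
        table, _ = _normalized_phantom_table(rng, n=10_000, coupling=-1e-9)
        model = fit_gmm(table.df[["adc_norm", "suv_norm"]].to_numpy(), k=3, seed=0)
        labeled, _ = assign_clusters(model, table)
        corr = correlate_within_clusters(labeled)
        for name in ("equivocal", "low_vital"):
            assert abs(corr[name]["r"]) < 0.05

    def test_tiny_cluster_reported_missing(self):
        table = make_table([800.0, 900.0], [4.0, 5.0], cluster=["vital", "vital"])
        with pytest.warns(UserWarning, match="undefined"):
            corr = correlate_within_clusters(table)
        assert corr["vital"]["r"] is None
        assert corr["vital"]["n"] == 2

    def test_requires_cluster_column(self):
        with pytest.raises(ValueError, match="cluster"):
            correlate_within_clusters(make_table([800.0], [4.0]))
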