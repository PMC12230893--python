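"""Mixed-effects fits, overdispersion diagnostics, paired comparison and
the spatial correlogram."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from urbancfd.models import (
    GAUSSIAN,
    NEGATIVE_BINOMIAL,
    ModelSpec,
    fit_mixed,
    overdispersion_test,
    paired_difference_test,
    spatial_correlogram,
)


def simulate_counts(
    n_cells: int,
    n_fuas: int,
    rng: np.random.Generator,
    income_slope: float = 0.0,
    fua_sd: float = 0.3,
    theta: float | None = None,
    baseline: float = 3.0,
) -> pd.DataFrame:
    """Direct NB/Poisson count simulator (independent of the package's
    community generator)."""
    fua = rng.integers(0, n_fuas, size=n_cells)
    b = rng.normal(0, fua_sd, size=n_fuas)
    z = rng.normal(size=n_cells)
    ctype = rng.choice(["invaded", "non-invaded"], size=n_cells)
    mu = np.exp(baseline + income_slope * z + b[fua])
    if theta is None:
        y = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=theta, scale=mu / theta)
        y = rng.poisson(lam)
    return pd.DataFrame(
        {
            "richness": y,
            "z_income": z,
            "type": ctype,
            "country": np.where(fua < n_fuas // 2, "ES", "PT"),
            "fua": [f"f{g}" for g in fua],
        }
    )


class TestNegativeBinomialMixed:
    def test_type_one_error_controlled(self):
        """No income effect simulated: income term non-significant in the
        vast majority of replicates."""
        hits = 0
        reps = 30
        for r in range(reps):
            data = simulate_counts(100, 10, np.random.default_rng(100 + r))
            res = fit_mixed(ModelSpec(response="richness", family=NEGATIVE_BINOMIAL), data)
            hits += res.tests.loc["z_income", "p"] > 0.05
        assert hits / reps >= 0.85

    def test_parameter_recovery(self):
        """Simulated log-scale slope 0.3 at n=500: recovered within 0.1."""
        est = []
        for r in range(15):
            data = simulate_counts(500, 20, np.random.default_rng(200 + r), income_slope=0.3)
            res = fit_mixed(ModelSpec(response="richness", family=NEGATIVE_BINOMIAL), data)
            est.append(res.coef("z_income"))
        assert abs(np.median(est) - 0.3) < 0.1

    def test_zero_group_variance_detected(self):
        data = simulate_counts(300, 10, np.random.default_rng(9), fua_sd=0.0)
        res = fit_mixed(ModelSpec(response="richness", family=NEGATIVE_BINOMIAL), data)
        assert res.random_variance < 0.01

    def test_group_variance_recovered(self):
        data = simulate_counts(800, 40, np.random.default_rng(10), fua_sd=0.5)
        res = fit_mixed(ModelSpec(response="richness", family=NEGATIVE_BINOMIAL), data)
        assert 0.05 < res.random_variance < 1.0

    def test_noncount_response_rejected(self):
        data = simulate_counts(50, 5, np.random.default_rng(1))
        data["richness"] = data["richness"] + 0.5
        with pytest.raises(ValueError, match="counts"):
            fit_mixed(ModelSpec(response="richness", family=NEGATIVE_BINOMIAL), data)

    def test_single_group_rejected(self):
        data = simulate_counts(50, 1, np.random.default_rng(2))
        with pytest.raises(ValueError, match="2 groups"):
            fit_mixed(ModelSpec(response="richness", family=NEGATIVE_BINOMIAL), data)


class TestGaussianMixed:
    def _sim(self, n_cells, n_fuas, rng, slope=0.0, fua_sd=0.5, resid_sd=1.0):
        fua = rng.integers(0, n_fuas, size=n_cells)
        b = rng.normal(0, fua_sd, size=n_fuas)
        z = rng.normal(size=n_cells)
        ctype = rng.choice(["invaded", "non-invaded"], size=n_cells)
        y = slope * z + b[fua] + rng.normal(0, resid_sd, size=n_cells)
        return pd.DataFrame(
            {
                "cfd": y,
                "z_income": z,
                "type": ctype,
                "country": np.where(fua % 2 == 0, "ES", "PT"),
                "fua": [f"f{g}" for g in fua],
            }
        )

    def test_slope_recovery_and_f_tests(self):
        data = self._sim(600, 20, np.random.default_rng(3), slope=-0.5)
        res = fit_mixed(ModelSpec(response="cfd", family=GAUSSIAN), data)
        assert res.coef("z_income") == pytest.approx(-0.5, abs=0.15)
        assert (res.tests["kind"] == "F").all()
        assert res.tests.loc["z_income", "p"] < 0.001

    def test_balanced_anova_closed_form(self):
        """On balanced one-way data, REML variance components equal the
        classical ANOVA estimators MSW and (MSB - MSW)/n."""
        rng = np.random.default_rng(6)
        g, n_per = 8, 10
        b = rng.normal(0, 0.7, size=g)
        y = np.concatenate([b[i] + rng.normal(0, 1.0, n_per) for i in range(g)])
        fua = np.repeat([f"f{i}" for i in range(g)], n_per)
        means = y.reshape(g, n_per).mean(axis=1)
        msw = y.reshape(g, n_per).var(axis=1, ddof=1).mean()
        msb = n_per * means.var(ddof=1)
        sigma_b2 = (msb - msw) / n_per
        diff = pd.Series(y, index=[f"c{i}" for i in range(len(y))])
        res = paired_difference_test(diff, diff * 0.0, pd.Series(fua, index=diff.index))
        assert res.random_variance == pytest.approx(sigma_b2, abs=1e-6)
        assert res.params["Intercept"] == pytest.approx(means.mean(), abs=1e-6)


class TestOverdispersion:
    def test_poisson_ratio_near_one(self):
        data = simulate_counts(1000, 10, np.random.default_rng(4), fua_sd=0.0)
        stat, ratio, p = overdispersion_test(data)
        assert ratio == pytest.approx(1.0, abs=0.15)

    def test_nb_power(self):
        """theta = 0.5 (strong overdispersion): detected essentially always."""
        detected = 0
        reps = 30
        for r in range(reps):
            data = simulate_counts(300, 10, np.random.default_rng(300 + r), fua_sd=0.0, theta=0.5)
            _, _, p = overdispersion_test(data)
            detected += p < 0.001
        assert detected / reps >= 0.95

    def test_constant_fitted_zero_statistic(self):
        # response identical to fitted mean -> statistic 0
        data = simulate_counts(100, 5, np.random.default_rng(5), fua_sd=0.0)
        data["richness"] = 7  # intercept-only perfect fit within groups
        data["z_income"] = 0.0
        stat, ratio, p = overdispersion_test(data)
        assert stat == pytest.approx(0.0, abs=1e-6)

    def test_noncount_rejected(self):
        data = simulate_counts(50, 5, np.random.default_rng(6))
        data["richness"] = data["richness"] + 0.3
        with pytest.raises(ValueError, match="count"):
            overdispersion_test(data)


class TestPairedDifference:
    def _fua(self, idx, n_fuas=5):
        return pd.Series([f"f{i % n_fuas}" for i in range(len(idx))], index=idx)

    def test_all_zero_differences(self):
        idx = [f"c{i}" for i in range(20)]
        z = pd.Series(np.linspace(-1, 1, 20), index=idx)
        res = paired_difference_test(z, z.copy(), self._fua(idx))
        assert res.params["Intercept"] == 0.0
        assert res.tests["p"].iloc[0] == 1.0

    def test_shifted_normal_detected(self):
        rng = np.random.default_rng(7)
        idx = [f"c{i}" for i in range(50)]
        inv = pd.Series(rng.normal(0.5, 0.1, 50), index=idx)
        na = pd.Series(0.0, index=idx)
        res = paired_difference_test(inv, na, self._fua(idx))
        assert 0.4 < res.params["Intercept"] < 0.6
        assert res.tests["p"].iloc[0] < 0.001

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(8)
        idx = [f"c{i}" for i in range(40)]
        inv = pd.Series(rng.normal(0.3, 0.2, 40), index=idx)
        na = pd.Series(0.0, index=idx)
        a = paired_difference_test(inv, na, self._fua(idx))
        b = paired_difference_test(na, inv, self._fua(idx))
        assert a.params["Intercept"] == pytest.approx(-b.params["Intercept"], abs=1e-8)
        assert a.tests["stat"].iloc[0] == pytest.approx(b.tests["stat"].iloc[0], rel=1e-6)

    def test_no_pairs_rejected(self):
        with pytest.raises(ValueError, match="pairs"):
            paired_difference_test(
                pd.Series({"a": 1.0}), pd.Series({"b": 2.0}), pd.Series({"a": "f0", "b": "f0"})
            )


class TestSpatialCorrelogram:
    def test_iid_residuals_pass(self):
        """Independent residuals: the CI-includes-zero verdict holds in
        nearly all replicates."""
        ok = 0
        reps = 15
        for r in range(reps):
            rng = np.random.default_rng(400 + r)
            xy = rng.uniform(0, 10, size=(80, 2))
            e = pd.Series(rng.normal(size=80))
            ok += spatial_correlogram(e, xy, n_boot=200, seed=r).no_autocorrelation
        assert ok / reps >= 0.85

    def test_smooth_gradient_detected(self):
        rng = np.random.default_rng(9)
        xy = rng.uniform(0, 10, size=(100, 2))
        e = pd.Series(np.sin(xy[:, 0] / 3.0) * 2 + rng.normal(size=100) * 0.3)
        res = spatial_correlogram(e, xy, n_boot=300, seed=1)
        assert not res.no_autocorrelation
        assert res.correlation[0] > 0  # short-distance positive correlation

    def test_permutation_destroys_structure(self):
        rng = np.random.default_rng(10)
        xy = rng.uniform(0, 10, size=(100, 2))
        e = np.sin(xy[:, 0] / 3.0) * 2 + rng.normal(size=100) * 0.3
        e_perm = pd.Series(rng.permutation(e))
        res = spatial_correlogram(e_perm, xy, n_boot=300, seed=2)
        assert res.no_autocorrelation

    def test_collocated_cells_rejected(self):
        e = pd.Series(np.random.default_rng(0).normal(size=40))
        xy = np.zeros((40, 2))
        with pytest.raises(ValueError, match="collocated"):
            spatial_correlogram(e, xy, n_boot=10, seed=0)

    def test_too_few_cells_rejected(self):
        e = pd.Series(np.arange(10.0))
        xy = np.random.default_rng(1).uniform(size=(10, 2))
        with pytest.raises(ValueError, match="30 cells"):
            spatial_correlogram(e, xy, n_boot=10, seed=0)
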