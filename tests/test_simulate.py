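import numpy as np
import pandas as pd
import pytest
from scipy import stats

from osteomap.cohort import default_schema
from osteomap.simulate import (
    BALANCE_LATENT,
    DependenceModel,
    GeneratorConfig,
    InfeasibleMarginalError,
    MarginalModel,
    OutcomeModel,
    default_dependence,
    fit_truncated_normal,
    fit_zero_inflated_counts,
    nearest_psd_correlation,
    plant_outcomes,
    sample_cohort,
    sample_latents,
)

from _oracles import truncated_normal_moments_by_quadrature


class TestTruncatedNormalFit:
    def test_negligible_truncation_recovers_parent(self):
        mu, sigma = fit_truncated_normal(0.0, 1.0, -10.0, 10.0)
        assert mu == pytest.approx(0.0, abs=1e-6)
        assert sigma == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_bounds_mean_at_midpoint(self):
        mu, _ = fit_truncated_normal(5.0, 2.0, 0.0, 10.0)
        assert mu == pytest.approx(5.0, abs=1e-8)

    def test_ctx_fit_verified_by_quadrature(self):
        # serum CTX: heavy right truncation asymmetry relative to its range
        mu, sigma = fit_truncated_normal(484.08, 323.24, 63.65, 2674.00, "CTX")
        m, s = truncated_normal_moments_by_quadrature(mu, sigma, 63.65, 2674.00)
        assert m == pytest.approx(484.08, rel=1e-3)
        assert s == pytest.approx(323.24, rel=1e-3)

    def test_infeasible_targets_name_variable(self):
        with pytest.raises(InfeasibleMarginalError, match="narrow"):
            fit_truncated_normal(0.5, 10.0, 0.0, 1.0, "narrow")

    def test_mean_outside_bounds_rejected(self):
        with pytest.raises(InfeasibleMarginalError):
            fit_truncated_normal(5.0, 1.0, 0.0, 1.0, "x")


class TestZeroInflatedCounts:
    def test_moments_match_published_sdi_summary(self):
        p_zero, theta = fit_zero_inflated_counts(2.03, 4.05, 19)
        m = MarginalModel(
            variable="SDI", family="zero-inflated-count",
            lower=0, upper=19, p_zero=p_zero, theta=theta,
        )
        mean, sd = m.moments()
        assert mean == pytest.approx(2.03, rel=1e-6)
        assert sd == pytest.approx(4.05, rel=1e-6)

    def test_zero_inflation_gives_median_zero(self):
        p_zero, _ = fit_zero_inflated_counts(2.03, 4.05, 19)
        assert p_zero > 0.5  # majority mass at 0 => median 0

    def test_all_default_marginals_match_targets_within_1pct(self, schema):
        for v in default_schema().continuous:
            m = MarginalModel.from_spec(v)
            mean, sd = m.moments()
            assert mean == pytest.approx(v.target_mean, rel=0.01), v.name
            assert sd == pytest.approx(v.target_sd, rel=0.01), v.name


class TestDependence:
    def test_default_correlation_is_psd_unit_diagonal(self):
        dep = default_dependence()
        w = np.linalg.eigvalsh(dep.correlation)
        assert w.min() >= -1e-10
        assert np.allclose(np.diag(dep.correlation), 1.0)

    def test_nearest_psd_projection_fixes_indefinite_matrix(self):
        c = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        fixed = nearest_psd_correlation(c)
        assert np.linalg.eigvalsh(fixed).min() >= -1e-10
        assert np.allclose(np.diag(fixed), 1.0)

    def test_unknown_latent_in_outcome_rejected(self):
        with pytest.raises(ValueError, match="nope"):
            DependenceModel(
                latent_names=("a", "b"),
                correlation=np.eye(2),
                outcomes=(OutcomeModel("y", {"nope": 1.0}, 0.5),),
            )


class TestSampling:
    def test_identical_seeds_bitwise_identical(self):
        a = sample_cohort(GeneratorConfig(n_records=50, seed=9)).data
        b = sample_cohort(GeneratorConfig(n_records=50, seed=9)).data
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = sample_cohort(GeneratorConfig(n_records=50, seed=1)).data
        b = sample_cohort(GeneratorConfig(n_records=50, seed=2)).data
        assert not a.equals(b)

    def test_values_respect_published_ranges(self):
        tab = sample_cohort(GeneratorConfig(n_records=2000, seed=4))
        for v in tab.schema.continuous:
            x = tab.values(v.name)
            assert x.min() >= v.min_allowed and x.max() <= v.max_allowed

    def test_identity_correlation_gives_independent_columns(self):
        schema = default_schema()
        names = tuple(v.name for v in schema.continuous) + (BALANCE_LATENT,)
        dep = DependenceModel(
            latent_names=names,
            correlation=np.eye(len(names)),
            outcomes=default_dependence().outcomes,
        )
        tab = sample_cohort(
            GeneratorConfig(n_records=10_000, seed=5, dependence=dep)
        )
        cont = [v.name for v in schema.continuous]
        corr = tab.data[cont].corr().to_numpy()
        off = corr[~np.eye(len(cont), dtype=bool)]
        assert np.abs(off).max() < 0.04

    def test_copula_kendall_tau_near_zero_under_independence(self):
        schema = default_schema()
        names = tuple(v.name for v in schema.continuous) + (BALANCE_LATENT,)
        dep = DependenceModel(
            latent_names=names, correlation=np.eye(len(names)),
            outcomes=default_dependence().outcomes,
        )
        tab = sample_cohort(GeneratorConfig(n_records=4000, seed=6, dependence=dep))
        tau = stats.kendalltau(tab.values("CTX"), tab.values("TBS")).statistic
        assert abs(tau) < 0.03

    def test_planted_correlation_appears_in_sample(self):
        tab = sample_cohort(GeneratorConfig(n_records=10_000, seed=7))
        r = np.corrcoef(tab.values("CTX"), tab.values("ALP"))[0, 1]
        assert r > 0.4  # latent 0.6 shrinks through the marginal transforms
        r2 = np.corrcoef(tab.values("TBS"), tab.values("BS_Lumbar"))[0, 1]
        assert r2 < -0.3


class TestPlantOutcomes:
    def _latents(self, n, seed=0):
        return sample_latents(GeneratorConfig(n_records=n, seed=seed))

    def test_zero_coefficients_give_half_prevalence(self):
        dep = default_dependence()
        dep = DependenceModel(
            latent_names=dep.latent_names,
            correlation=dep.correlation,
            outcomes=(OutcomeModel("Fracture", {}, 0.5),),
        )
        z = self._latents(20_000)
        out = plant_outcomes(z, dep, seed=0)
        assert out["Fracture"].mean() == pytest.approx(0.5, abs=0.02)

    def test_extreme_intercept_saturates(self):
        dep = default_dependence()
        dep = DependenceModel(
            latent_names=dep.latent_names,
            correlation=dep.correlation,
            outcomes=(OutcomeModel("Fracture", {}, 1e-9),),
        )
        out = plant_outcomes(self._latents(5000), dep, seed=0)
        assert out["Fracture"].sum() == 0

    def test_default_prevalences_recovered(self):
        tab = sample_cohort(GeneratorConfig(n_records=20_000, seed=8))
        assert tab.values("Fracture").mean() == pytest.approx(0.25, abs=0.02)
        assert tab.values("Romberg").mean() == pytest.approx(0.30, abs=0.02)

    def test_fracture_negatively_associated_with_lumbar_bmd(self):
        tab = sample_cohort(GeneratorConfig(n_records=10_000, seed=9))
        r = np.corrcoef(tab.values("Fracture"), tab.values("BMD_Lumbar"))[0, 1]
        assert r < -0.05

    def test_fracture_positively_associated_with_romberg(self):
        tab = sample_cohort(GeneratorConfig(n_records=10_000, seed=10))
        r = np.corrcoef(tab.values("Fracture"), tab.values("Romberg"))[0, 1]
        assert r > 0.05
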