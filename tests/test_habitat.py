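"""Habitat-model tests: design sampling, GLS/OLS reduction, variance
component and coefficient recovery on data simulated from the model,
cluster-robust sandwich behavior, the candidate-model enumeration and the
Akaike-averaging arithmetic."""

import numpy as np
import pandas as pd
import pytest

from pumaconnect import bbmm, habitat
from pumaconnect.covariates import CovariateStack
from pumaconnect.raster import RasterGrid
from tests.conftest import make_track


# ---------------------------------------------------------------------------
# simulators (independent of the fitting code)
# ---------------------------------------------------------------------------

def simulate_lmm(n_animals=8, n_per=60, beta=None, sigma2_u=0.5,
                 sigma2_s=0.0, rho=500.0, tau2=1.0, seed=0, extent=5000.0):
    """Draw design rows directly from the mixed-model data-generating
    process: random covariates, animal random intercepts, and (optionally)
    exponential spatially correlated residuals."""
    rng = np.random.default_rng(seed)
    all_terms = habitat.HABITAT_TERMS + (habitat.QUADRATIC_TERM,)
    if beta is None:
        beta = {}
    frames = []
    for a in range(n_animals):
        xy = rng.uniform(0, extent, size=(n_per, 2))
        df = pd.DataFrame({
            "animal_id": f"a{a:02d}", "x": xy[:, 0], "y": xy[:, 1]})
        for t in habitat.HABITAT_TERMS:
            df[t] = rng.standard_normal(n_per)
        df[habitat.QUADRATIC_TERM] = df["ruggedness"] ** 2
        df["young_adult"] = float(a % 2)
        df["male"] = float((a // 2) % 2)
        df["area_B"] = float(a % 3 == 1)
        df["area_C"] = float(a % 3 == 2)
        lin = np.full(n_per, beta.get(habitat.INTERCEPT, 0.0))
        for t in (*all_terms, *habitat.INDICATOR_TERMS):
            lin += beta.get(t, 0.0) * df[t].to_numpy()
        d = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1))
        cov = sigma2_s * np.exp(-d / rho) + tau2 * np.eye(n_per)
        resid = np.linalg.cholesky(cov) @ rng.standard_normal(n_per)
        b_a = rng.normal(0, np.sqrt(sigma2_u))
        df["response"] = lin + b_a + resid
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# design sampling
# ---------------------------------------------------------------------------

class TestSampleDesign:
    def _setup(self, small_stack):
        g = small_stack.grid
        mid = g.xll + g.n_cols / 2 * g.cell_size, \
            g.yll + g.n_rows / 2 * g.cell_size
        tr = make_track([(mid[0] - 2000, mid[1]), (mid[0] + 2000, mid[1])],
                        interval_h=7.0, sex="M", age_class="young_adult",
                        capture_area="B")
        surf = bbmm.occurrence_surface(tr, 300.0, 26.2, g)
        buf = bbmm.buffered_extent(surf, 4000.0)
        return tr, surf, buf

    def test_row_count_matches_location_count(self, small_stack):
        tr, surf, buf = self._setup(small_stack)
        rows = habitat.sample_design(surf, buf, small_stack, tr, 500, seed=0)
        assert len(rows) == 500

    def test_buffer_only_points_get_the_floor(self, small_stack):
        tr, surf, buf = self._setup(small_stack)
        rows = habitat.sample_design(surf, buf, small_stack, tr, 2000, seed=1)
        assert rows["response"].min() == pytest.approx(np.log(1e-5))
        assert (rows["response"] >= np.log(1e-5) - 1e-12).all()

    def test_same_seed_reproduces_points(self, small_stack):
        tr, surf, buf = self._setup(small_stack)
        r1 = habitat.sample_design(surf, buf, small_stack, tr, 100, seed=9)
        r2 = habitat.sample_design(surf, buf, small_stack, tr, 100, seed=9)
        pd.testing.assert_frame_equal(r1, r2)

    def test_indicators_follow_attributes(self, small_stack):
        tr, surf, buf = self._setup(small_stack)
        rows = habitat.sample_design(surf, buf, small_stack, tr, 10, seed=2)
        assert (rows["young_adult"] == 1.0).all()
        assert (rows["male"] == 1.0).all()
        assert (rows["area_B"] == 1.0).all()
        assert (rows["area_C"] == 0.0).all()

    def test_empty_buffer_rejected(self, small_stack):
        tr, surf, _ = self._setup(small_stack)
        with pytest.raises(ValueError, match="empty buffered extent"):
            habitat.sample_design(surf, np.zeros_like(surf.support),
                                  small_stack, tr, 10, seed=0)


# ---------------------------------------------------------------------------
# mixed-model machinery
# ---------------------------------------------------------------------------

class TestFitLmm:
    def test_reduces_to_ols_when_components_vanish(self):
        rows = simulate_lmm(sigma2_u=0.0, sigma2_s=0.0, tau2=1.0, seed=1,
                            beta={"ruggedness": 0.5, habitat.INTERCEPT: 2.0})
        terms = habitat.HABITAT_TERMS
        comp = habitat.VarianceComponents(0.0, 0.0, 1.0, 1.0)
        fit = habitat.fit_lmm(rows, terms, comp)
        X = habitat.design_matrix(rows, terms)
        y = rows["response"].to_numpy()
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-6)

    def test_variance_component_recovery(self):
        # moderate spatial structure: the ML estimates should land near
        # the generating values (range within a factor of two)
        rows = simulate_lmm(n_animals=8, n_per=80, sigma2_u=1.0,
                            sigma2_s=2.0, rho=800.0, tau2=0.5, seed=2)
        comp = habitat.estimate_variance_components(rows)
        # sigma2_u is estimated from only 8 cluster intercepts and is
        # partially confounded with the long-range spatial sill, so its
        # band is wide; the spatially identified components sit tighter
        assert 0.05 < comp.sigma2_u < 4.0
        assert 0.7 < comp.sigma2_s < 6.0
        assert 400.0 < comp.rho < 1600.0
        assert 0.15 < comp.tau2 < 1.5

    def test_coefficient_recovery_within_two_se(self):
        beta = {habitat.INTERCEPT: 1.0, "ruggedness": 0.8, "shrub": -0.4}
        rows = simulate_lmm(n_animals=10, n_per=60, sigma2_u=0.5,
                            sigma2_s=1.0, rho=600.0, tau2=0.8, seed=3,
                            beta=beta)
        comp = habitat.estimate_variance_components(rows, n_restarts=1)
        fit = habitat.fit_lmm(rows, habitat.HABITAT_TERMS, comp)
        for name, truth in [("ruggedness", 0.8), ("shrub", -0.4)]:
            est = fit.coef(name)
            se = fit.se(name, sandwich=False)
            assert abs(est - truth) < 3.0 * se

    def test_fewer_clusters_than_parameters_warns(self, caplog):
        # 6 animals but 13 fixed effects: the cluster-robust estimator is
        # rank-starved and says so
        rows = simulate_lmm(n_animals=6, n_per=50, sigma2_u=0.2, seed=4)
        comp = habitat.VarianceComponents(0.2, 1e-8, 500.0, 1.0)
        with caplog.at_level("WARNING"):
            habitat.fit_lmm(rows, habitat.HABITAT_TERMS, comp)
        assert "clusters" in caplog.text

    def test_fewer_than_two_animals_rejected_for_components(self):
        rows = simulate_lmm(n_animals=1, n_per=50, seed=5)
        with pytest.raises(ValueError, match="two individuals"):
            habitat.estimate_variance_components(rows)


class TestSandwich:
    def test_agrees_with_model_vcov_when_correctly_specified(self):
        ratios = []
        for seed in range(10):
            rows = simulate_lmm(n_animals=10, n_per=40, sigma2_u=0.4,
                                sigma2_s=0.0, tau2=1.0, seed=seed)
            comp = habitat.VarianceComponents(0.4, 1e-8, 500.0, 1.0)
            fit = habitat.fit_lmm(rows, ("ruggedness",), comp)
            i = fit.names.index("ruggedness")
            ratios.append(np.sqrt(fit.vcov_sandwich[i, i]
                                  / fit.vcov_model[i, i]))
        assert np.median(ratios) == pytest.approx(1.0, abs=0.35)

    def test_sandwich_covers_under_heteroscedasticity(self):
        # animal-specific error variances violate the model; the robust
        # SE should still cover the true (zero) coefficient
        hits_model, hits_sand = 0, 0
        n_reps = 25
        for seed in range(n_reps):
            rng = np.random.default_rng(1000 + seed)
            frames = []
            for a in range(10):
                n = 40
                df = pd.DataFrame({"animal_id": f"a{a}",
                                   "x": rng.uniform(0, 1000, n),
                                   "y": rng.uniform(0, 1000, n)})
                for t in habitat.HABITAT_TERMS:
                    df[t] = rng.standard_normal(n)
                df[habitat.QUADRATIC_TERM] = df["ruggedness"] ** 2
                df["young_adult"] = float(a % 2)
                df["male"] = float((a // 2) % 2)
                df["area_B"] = float(a % 3 == 1)
                df["area_C"] = float(a % 3 == 2)
                scale = 0.3 + 2.5 * (a % 4)
                df["response"] = rng.normal(0, scale, n)
                frames.append(df)
            rows = pd.concat(frames, ignore_index=True)
            comp = habitat.VarianceComponents(1e-8, 1e-8, 500.0, 1.0)
            fit = habitat.fit_lmm(rows, ("ruggedness",), comp)
            est = fit.coef("ruggedness")
            hits_model += abs(est) < 2 * fit.se("ruggedness", sandwich=False)
            hits_sand += abs(est) < 2 * fit.se("ruggedness", sandwich=True)
        assert hits_sand >= 0.85 * n_reps
        assert hits_sand >= hits_model


class TestEnumeration:
    def test_candidate_count_is_192(self):
        subsets = habitat.enumerate_subsets()
        assert len(subsets) == 192

    def test_quadratic_requires_its_parent(self):
        for terms in habitat.enumerate_subsets():
            if habitat.QUADRATIC_TERM in terms:
                assert "ruggedness" in terms

    def test_includes_empty_and_global(self):
        subsets = habitat.enumerate_subsets()
        assert () in subsets
        assert habitat.HABITAT_TERMS + (habitat.QUADRATIC_TERM,) in subsets

    def test_indicators_in_every_design(self):
        rows = simulate_lmm(n_animals=4, n_per=10, seed=0)
        for terms in ((), ("ruggedness",)):
            X = habitat.design_matrix(rows, terms)
            assert X.shape[1] == 1 + len(habitat.INDICATOR_TERMS) + len(terms)


class TestAveraging:
    def test_weights_closed_form(self):
        w = habitat.akaike_weights(np.array([100.0, 102.0]))
        np.testing.assert_allclose(w, [0.7311, 0.2689], atol=5e-5)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_weights_sum_to_one_large_set(self):
        rng = np.random.default_rng(0)
        w = habitat.akaike_weights(rng.uniform(500, 600, 192))
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def _fits(self, seed=0):
        rows = simulate_lmm(n_animals=6, n_per=30, sigma2_u=0.3,
                            sigma2_s=0.0, tau2=1.0, seed=seed,
                            beta={"ruggedness": 1.0})
        comp = habitat.VarianceComponents(0.3, 1e-8, 500.0, 1.0)
        return habitat.fit_all_subsets(rows, comp)

    def test_forced_terms_have_unit_weight(self):
        avg = habitat.model_average(self._fits())
        for t in habitat.INDICATOR_TERMS:
            assert avg.weight_of_evidence[t] == pytest.approx(1.0, abs=1e-12)
        for t in habitat.HABITAT_TERMS:
            assert avg.weight_of_evidence[t] <= 1.0 + 1e-12

    def test_single_model_identity(self):
        fits = self._fits()
        avg = habitat.model_average(fits[:1])
        f = fits[0]
        for t in f.names:
            if t == habitat.INTERCEPT:
                continue
            assert avg.coefficients[t] == pytest.approx(f.coef(t))
            assert avg.unconditional_se[t] == pytest.approx(f.se(t))
            assert avg.weight_of_evidence[t] == 1.0

    def test_mismatched_data_rejected(self):
        f1 = self._fits(seed=1)[0]
        f2 = self._fits(seed=2)[0]
        with pytest.raises(ValueError, match="identical data"):
            habitat.model_average([f1, f2])

    def test_table_ordered_by_weight(self):
        avg = habitat.model_average(self._fits())
        tab = avg.table()
        w = tab["w_plus"].dropna().to_numpy()
        assert (np.diff(w) <= 1e-12).all()
        assert tab.iloc[-1]["variable"] == habitat.INTERCEPT

    def test_global_null_comparison(self):
        rows = simulate_lmm(n_animals=8, n_per=40, sigma2_u=0.3,
                            sigma2_s=0.0, tau2=1.0, seed=7,
                            beta={"ruggedness": 1.5, "shrub": -1.0})
        comp = habitat.VarianceComponents(0.3, 1e-8, 500.0, 1.0)
        glob = habitat.fit_lmm(rows, habitat.HABITAT_TERMS, comp)
        null = habitat.fit_lmm(rows, (), comp)
        res = habitat.compare_global_null(glob, null)
        assert res["passes"] and res["delta_aic"] > 10.0
        # equal AICs fail the margin
        assert not habitat.compare_global_null(glob, glob)["passes"]


# ---------------------------------------------------------------------------
# prediction and conductance
# ---------------------------------------------------------------------------

def _standardized_stack(layer_values: dict[str, np.ndarray]) -> CovariateStack:
    layers = {n: RasterGrid(v) for n, v in layer_values.items()}
    params = {n: (0.0, 1.0) for n in layer_values}
    return CovariateStack(layers, standardization=params)


class TestPrediction:
    # the published averaged model for reference: intercept 6.833,
    # ruggedness +0.583 per SD
    AVG = habitat.AveragedHabitatModel(
        weight_of_evidence={"ruggedness": 0.999},
        coefficients={"ruggedness": 0.583},
        unconditional_se={"ruggedness": 0.156},
        intercept=6.833, intercept_se=1.033)

    def test_mean_landscape_predicts_the_intercept(self):
        stack = _standardized_stack({"ruggedness": np.zeros((8, 8))})
        out = habitat.predict_quality(self.AVG, stack)
        np.testing.assert_allclose(out.values, 6.833)

    def test_one_sd_of_ruggedness_adds_its_coefficient(self):
        stack = _standardized_stack({"ruggedness": np.ones((8, 8))})
        out = habitat.predict_quality(self.AVG, stack)
        np.testing.assert_allclose(out.values, 6.833 + 0.583)

    def test_zero_coefficients_give_constant_intercept_map(self):
        avg = habitat.AveragedHabitatModel({}, {}, {}, 2.5, 0.1)
        stack = _standardized_stack(
            {"ruggedness": np.random.default_rng(0).normal(size=(8, 8))})
        out = habitat.predict_quality(avg, stack)
        np.testing.assert_allclose(out.values, 2.5)

    def test_unstandardized_stack_rejected(self):
        stack = CovariateStack({"ruggedness": RasterGrid(np.zeros((8, 8)))})
        with pytest.raises(ValueError, match="standardized"):
            habitat.predict_quality(self.AVG, stack)

    def test_missing_layer_rejected(self):
        stack = _standardized_stack({"forest": np.zeros((8, 8))})
        with pytest.raises(KeyError, match="ruggedness"):
            habitat.predict_quality(self.AVG, stack)


class TestConductance:
    def test_rescale_override_and_range(self):
        rng = np.random.default_rng(0)
        q = RasterGrid(rng.normal(5, 2, (10, 10)))
        water = np.zeros((10, 10), dtype=bool)
        water[0, :3] = True
        cond = habitat.quality_to_conductance(q, water)
        v = cond.values
        assert v.max() == pytest.approx(1.0)
        assert (v > 0).all()
        np.testing.assert_allclose(v[water], 1e-3)
        # monotone among non-water cells
        land = ~water
        order_q = np.argsort(q.values[land])
        assert (np.diff(v[land][order_q]) >= -1e-15).all()

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            habitat.quality_to_conductance(RasterGrid(np.ones((5, 5))))
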