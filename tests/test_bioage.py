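"""Physiology-based comparators and effect-size statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

import methylpace as mp
from methylpace.errors import DataError, DegenerateDataError, NumericalError


def _reference_toy():
    return mp.BiomarkerReference(
        markers=["m1", "m2"],
        q=pd.Series({"m1": 0.0, "m2": 10.0}),
        k=pd.Series({"m1": 1.0, "m2": 2.0}),
        s=pd.Series({"m1": 1.0, "m2": 1.0}),
    )


@pytest.fixture(scope="module")
def synthetic_reference():
    rng = np.random.default_rng(0)
    n = 1200
    age = rng.uniform(25, 75, n)
    table = pd.DataFrame({"age": age})
    for j, (q, k, s) in enumerate([(10, 0.5, 2.0), (50, -0.8, 4.0), (3, 0.1, 0.5)]):
        table[f"m{j}"] = q + k * age + rng.normal(0, s, n)
    return table


class TestFitReference:
    def test_noise_free_regressions_exact(self):
        age = np.linspace(30, 60, 50)
        table = pd.DataFrame({"age": age, "m1": 5 + 0.4 * age, "m2": 80 - 1.1 * age})
        # markers fitted one at a time: exactly linear markers are mutually
        # collinear, so the joint healthy-covariance step rejects them
        ref1 = mp.fit_reference(table, markers=["m1"], healthy_rule="all")
        ref2 = mp.fit_reference(table, markers=["m2"], healthy_rule="all")
        assert ref1.q["m1"] == pytest.approx(5.0, abs=1e-8)
        assert ref1.k["m1"] == pytest.approx(0.4, abs=1e-10)
        assert ref2.k["m2"] == pytest.approx(-1.1, abs=1e-10)
        assert ref1.s["m1"] > 0  # floored, never exactly zero

    def test_single_marker_covariance_is_scalar_variance(self, synthetic_reference):
        ref = mp.fit_reference(synthetic_reference, markers=["m0"])
        assert ref.hd_cov.shape == (1, 1)

    def test_subject_order_irrelevant(self, synthetic_reference):
        rng = np.random.default_rng(1)
        shuffled = synthetic_reference.sample(frac=1.0, random_state=2)
        a = mp.fit_reference(synthetic_reference)
        b = mp.fit_reference(shuffled)
        pd.testing.assert_series_equal(a.q, b.q, atol=1e-10, rtol=0)
        pd.testing.assert_series_equal(a.k, b.k, atol=1e-12, rtol=0)

    def test_singular_covariance_rejected(self):
        age = np.linspace(30, 60, 40)
        rng = np.random.default_rng(3)
        m1 = 5 + 0.4 * age + rng.normal(0, 1, 40)
        table = pd.DataFrame({"age": age, "m1": m1, "m2": 2 * m1})
        with pytest.raises(NumericalError):
            mp.fit_reference(table, healthy_rule="all")


class TestKDM:
    def test_on_the_line_identity(self, synthetic_reference):
        """Subjects lying exactly on every reference regression line get
        biological age equal to chronological age."""
        ref = mp.fit_reference(synthetic_reference)
        ages = np.array([30.0, 45.0, 60.0])
        x = pd.DataFrame(
            {m: ref.q[m] + ref.k[m] * ages for m in ref.markers}
        )
        ba = mp.kdm_biological_age(x, ref)
        np.testing.assert_allclose(ba.to_numpy(), ages, atol=1e-8)

    def test_single_marker_inverse_regression(self):
        ref = mp.BiomarkerReference(
            markers=["m1"], q=pd.Series({"m1": 2.0}),
            k=pd.Series({"m1": 0.5}), s=pd.Series({"m1": 1.0}),
        )
        ba = mp.kdm_biological_age(pd.DataFrame({"m1": [22.0]}), ref)
        assert ba.iloc[0] == pytest.approx((22.0 - 2.0) / 0.5)

    def test_two_marker_hand_arithmetic(self):
        ba = mp.kdm_biological_age(
            pd.DataFrame({"m1": [30.0], "m2": [74.0]}), _reference_toy()
        )
        assert ba.iloc[0] == pytest.approx((30 * 1 + 64 * 2) / 5)  # 31.6

    def test_augmented_variant_pulls_toward_chronological_age(self):
        ref = _reference_toy()
        x = pd.DataFrame({"m1": [30.0], "m2": [74.0]})
        plain = mp.kdm_biological_age(x, ref).iloc[0]
        augmented = mp.kdm_biological_age(x, ref, age=[50.0], s_ba=1.0).iloc[0]
        assert plain < augmented < 50.0

    def test_regression_slope_near_one_in_reference_population(
        self, synthetic_reference
    ):
        ref = mp.fit_reference(synthetic_reference)
        ba = mp.kdm_biological_age(synthetic_reference, ref)
        slope = np.polyfit(synthetic_reference["age"], ba, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_all_zero_slopes_undefined(self):
        ref = mp.BiomarkerReference(
            markers=["m1"], q=pd.Series({"m1": 0.0}),
            k=pd.Series({"m1": 0.0}), s=pd.Series({"m1": 1.0}),
        )
        with pytest.raises(NumericalError):
            mp.kdm_biological_age(pd.DataFrame({"m1": [1.0]}), ref)


def _constants(gamma_m=0.09, gamma_a=0.09):
    return mp.GompertzConstants(
        coefficients={"m1": 0.02}, intercept=-9.5,
        gamma_markers=gamma_m, gamma_age=gamma_a,
        age_intercept=-10.0, age_slope=0.08, horizon=10.0,
    )


class TestPhenotypicAge:
    def test_calibration_fixed_point(self):
        """When the marker linear predictor equals the age model's value at
        age a (same Gompertz shape), Phenotypic Age is a."""
        c = _constants()
        for a in (30.0, 50.0, 70.0):
            xb = c.age_intercept + c.age_slope * a
            years, clamped = mp.phenotypic_age_from_xb([xb], c)
            assert not clamped.any()
            assert years[0] == pytest.approx(a, abs=1e-6)

    def test_strictly_increasing_in_linear_predictor(self):
        c = _constants(gamma_m=0.11, gamma_a=0.09)
        xb = np.linspace(-8, -2, 40)
        years, _ = mp.phenotypic_age_from_xb(xb, c)
        assert np.all(np.diff(years) > 0)

    def test_matches_brute_force_numerical_inversion(self):
        c = _constants(gamma_m=0.12, gamma_a=0.085)

        def risk_from_xb(xb, gamma):
            return 1 - np.exp(-np.exp(xb) * (np.exp(gamma * c.horizon) - 1) / gamma)

        for xb in (-7.0, -5.0, -3.5):
            target = risk_from_xb(xb, c.gamma_markers)
            brute = brentq(
                lambda a: risk_from_xb(
                    c.age_intercept + c.age_slope * a, c.gamma_age
                ) - target,
                -200, 400, xtol=1e-12,
            )
            years, _ = mp.phenotypic_age_from_xb([xb], c)
            assert years[0] == pytest.approx(brute, abs=1e-6)

    def test_marker_pathway_with_age_coefficient(self):
        c = mp.GompertzConstants(
            coefficients={"m1": 0.02, "age": 0.05}, intercept=-12.0,
            gamma_markers=0.09, gamma_age=0.09,
            age_intercept=-10.0, age_slope=0.08,
        )
        ref = mp.BiomarkerReference(
            markers=["m1"], q=pd.Series({"m1": 0.0}),
            k=pd.Series({"m1": 1.0}), s=pd.Series({"m1": 1.0}), pheno=c,
        )
        x = pd.DataFrame({"m1": [40.0, 80.0]})
        years = mp.phenotypic_age(x, ref, age=[50.0, 50.0])
        assert years.iloc[1] > years.iloc[0]
        with pytest.raises(DataError):
            mp.phenotypic_age(x, ref)  # age term configured but ages missing

    def test_missing_constants_rejected(self):
        ref = _reference_toy()
        with pytest.raises(DataError):
            mp.phenotypic_age(pd.DataFrame({"m1": [1.0], "m2": [1.0]}), ref)


class TestHomeostaticDysregulation:
    @pytest.fixture(scope="class")
    def ref(self, synthetic_reference):
        return mp.fit_reference(synthetic_reference)

    def test_zero_at_centroid(self, ref):
        x = ref.hd_mean.to_frame().T
        assert mp.homeostatic_dysregulation(x, ref).iloc[0] == pytest.approx(0.0)

    def test_identity_covariance_reduces_to_log1p_euclidean(self):
        probes = ["m1", "m2"]
        ref = mp.BiomarkerReference(
            markers=probes,
            q=pd.Series(0.0, index=probes), k=pd.Series(1.0, index=probes),
            s=pd.Series(1.0, index=probes),
            hd_mean=pd.Series([1.0, 2.0], index=probes),
            hd_cov=pd.DataFrame(np.eye(2), index=probes, columns=probes),
        )
        x = pd.DataFrame({"m1": [4.0], "m2": [6.0]})
        expected = np.log1p(np.sqrt(3**2 + 4**2))
        assert mp.homeostatic_dysregulation(x, ref).iloc[0] == pytest.approx(expected)

    def test_matches_explicit_quadratic_form(self, synthetic_reference, ref):
        x = synthetic_reference[ref.markers].iloc[:5]
        got = mp.homeostatic_dysregulation(x, ref)
        inv = np.linalg.inv(ref.hd_cov.to_numpy())
        diff = x.to_numpy() - ref.hd_mean.to_numpy()
        expected = np.log1p(np.sqrt(np.einsum("ij,jk,ik->i", diff, inv, diff)))
        np.testing.assert_allclose(got.to_numpy(), expected, atol=1e-8)

    def test_affine_rescaling_with_refit_is_invariant(self, synthetic_reference):
        ref_a = mp.fit_reference(synthetic_reference)
        rescaled = synthetic_reference.copy()
        rescaled["m1"] = 3.5 * rescaled["m1"] - 20.0
        ref_b = mp.fit_reference(rescaled)
        x_a = synthetic_reference.iloc[:8]
        x_b = rescaled.iloc[:8]
        np.testing.assert_allclose(
            mp.homeostatic_dysregulation(x_a, ref_a).to_numpy(),
            mp.homeostatic_dysregulation(x_b, ref_b).to_numpy(),
            atol=1e-8,
        )

    def test_dimension_mismatch_rejected(self, ref):
        with pytest.raises(DataError):
            mp.homeostatic_dysregulation(pd.DataFrame({"m0": [1.0]}), ref)


class TestAgeAcceleration:
    def test_exact_affine_measure_has_zero_residuals(self):
        age = np.linspace(30, 70, 20)
        out = mp.age_acceleration(2 * age + 5, age)
        np.testing.assert_allclose(out.to_numpy(), 0.0, atol=1e-10)

    def test_age_independent_measure_residuals_are_centered_measure(self):
        rng = np.random.default_rng(4)
        age = rng.uniform(30, 70, 500)
        measure = rng.normal(5, 1, 500)
        out = mp.age_acceleration(measure, age)
        assert abs(out.sum()) < 1e-8
        r = np.corrcoef(out, measure - measure.mean())[0, 1]
        assert r > 0.99

    def test_invariant_to_adding_affine_function_of_age(self):
        rng = np.random.default_rng(5)
        age = rng.uniform(30, 70, 100)
        measure = rng.normal(0, 1, 100)
        a = mp.age_acceleration(measure, age)
        b = mp.age_acceleration(measure + 0.7 * age - 3.0, age)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_zero_age_variance_rejected(self):
        with pytest.raises(DataError):
            mp.age_acceleration([1.0, 2.0, 3.0], [50.0, 50.0, 50.0])


class TestEffectSizes:
    def test_identical_groups_give_zero_d(self):
        g = np.arange(10.0)
        assert mp.cohens_d(g, g).estimate == pytest.approx(0.0)

    def test_planted_standardized_difference_recovered(self):
        ds = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            d = mp.cohens_d(rng.normal(0.74, 1, 500), rng.normal(0.0, 1, 500))
            ds.append(d.estimate)
        assert np.mean(ds) == pytest.approx(0.74, abs=0.15)

    def test_d_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        g1, g2 = rng.normal(1, 1, 80), rng.normal(0, 1.2, 90)
        ours = mp.cohens_d(g1, g2).estimate
        theirs = pingouin.compute_effsize(g1, g2, eftype="cohen")
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(DegenerateDataError):
            mp.cohens_d([1.0, 1.0], [1.0, 1.0])

    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r = mp.pearson_r(x, x)
        assert r.estimate == pytest.approx(1.0)

    def test_fisher_ci_brackets_estimate(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 200)
        y = 0.5 * x + rng.normal(0, 1, 200)
        r = mp.pearson_r(x, y)
        assert r.ci_low < r.estimate < r.ci_high
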