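"""Nine-model age-prediction family: catalog, OLS oracle, CV, refinement, validation."""

import numpy as np
import pandas as pd
import pytest

import periskin as ps
from periskin.age_models import (
    PeriorbitalAgeModel,
    cross_validate,
    expected_multiple_correlation,
    fit_model,
    model_catalog,
    refine_model,
    validate_model,
)
from periskin.synthetic import DEFAULT_FEATURE_AGE_CORR

from conftest import make_linear_cohort


def normal_equations(cohort, subset):
    """Independent brute-force OLS: solve X'X beta = X'y directly."""
    x = np.column_stack([np.ones(len(cohort)), cohort[list(subset)].to_numpy(float)])
    y = cohort["age"].to_numpy(float)
    return np.linalg.solve(x.T @ x, x.T @ y)


def test_catalog_matches_design():
    cat = model_catalog()
    assert cat[1] == ("Wb", "Wu", "Wa")
    assert cat[2] == ("Md", "Mw")
    assert cat[3] == ("Pb", "Pu")
    assert cat[4] == ("Wb", "Wu", "Wa", "Md", "Mw")
    assert cat[5] == ("Wb", "Wu", "Wa", "Pb", "Pu")
    assert cat[6] == ("Md", "Mw", "Pb", "Pu")
    assert len(cat[7]) == 7 and set(cat[7]) == set(ps.FEATURES)
    # models 8 and 9 drop Wa from models 1 and 5 (device-only variants)
    assert set(cat[8]) == set(cat[1]) - {"Wa"}
    assert set(cat[9]) == set(cat[5]) - {"Wa"}


def test_exact_linear_recovery_and_perfect_cv():
    df = make_linear_cohort({"Pu": 0.2}, intercept=30.0, n=300)
    res = fit_model(df, ("Pu",))
    assert abs(res.intercept - 30.0) < 1e-8
    assert abs(res.coefficients["Pu"] - 0.2) < 1e-8
    cv = cross_validate(df, ("Pu",), k=10, seed=0)
    assert abs(cv.mean_r - 1.0) < 1e-9


@pytest.mark.parametrize("number", sorted(model_catalog()))
def test_ols_matches_normal_equations(build_cohort, number):
    subset = model_catalog()[number]
    res = PeriorbitalAgeModel.from_catalog(build_cohort, number).fit()
    oracle = normal_equations(build_cohort, subset)
    assert np.allclose(res.params.to_numpy(), oracle, atol=1e-8)


def test_noisy_parameter_recovery_coverage():
    """True coefficients fall in their 95% CIs in >= 90% of 100 seeds."""
    true = {"Wb": 0.15, "Pu": 0.25}
    covered = {f: 0 for f in true}
    for seed in range(100):
        df = make_linear_cohort(true, intercept=25.0, n=300, noise_sd=5.0, seed=seed)
        res = fit_model(df, ("Wb", "Pu"))
        for f, b in true.items():
            covered[f] += abs(res.params[f] - b) <= 1.96 * res.bse[f]
    for f, count in covered.items():
        assert count >= 90, (f, count)


def test_cv_null_model_near_zero(build_cohort):
    shuffled = build_cohort.copy()
    shuffled["age"] = np.random.default_rng(0).permutation(shuffled["age"].to_numpy())
    cv = cross_validate(shuffled, model_catalog()[7], seed=1)
    assert abs(cv.mean_r) <= 0.1


def test_cv_matches_conditional_independence_closed_form(build_cohort):
    """Model-7 CV r ~= sqrt(S/(1+S)), S = sum r_i^2/(1-r_i^2)."""
    target = expected_multiple_correlation(DEFAULT_FEATURE_AGE_CORR.values())
    cv = cross_validate(build_cohort, model_catalog()[7], seed=0)
    assert abs(cv.mean_r - target) <= 0.02


def test_cv_invariant_to_subject_ordering(build_cohort):
    shuffled = build_cohort.sample(frac=1.0, random_state=5).reset_index(drop=True)
    a = cross_validate(build_cohort, ("Pb", "Pu"), seed=3)
    b = cross_validate(shuffled, ("Pb", "Pu"), seed=3)
    assert a.mean_r == b.mean_r


def test_cv_guards(build_cohort):
    with pytest.raises(ValueError, match="at least"):
        cross_validate(build_cohort.head(50), ("Pb",), k=10)


def test_refinement_fixed_point(build_cohort):
    res = PeriorbitalAgeModel.from_catalog(build_cohort, 3).fit()
    assert (res.coefficients >= 0).all()
    refined = refine_model(res)
    assert refined is res and not refined.refined


def test_refinement_removes_constructed_collinear_feature():
    """x2 = x1 + small noise while only x1 drives age: the redundant
    negative-coefficient copy is removed, one informative feature remains."""
    rng = np.random.default_rng(1)
    n = 400
    x1 = rng.uniform(0, 100, n)
    df = pd.DataFrame(
        {
            "id": [f"C{i}" for i in range(n)],
            "Wb": x1,
            "Wu": x1 + rng.normal(0, 0.5, n),
            "age": 20 + 0.3 * x1 + rng.normal(0, 2.0, n),
        }
    )
    res = fit_model(df, ("Wb", "Wu"))
    assert (res.coefficients < 0).any()  # collinearity artifact present
    refined = refine_model(res)
    assert refined.refined
    assert len(refined.subset) == 1
    assert (refined.coefficients >= 0).all()


def test_refined_models_never_carry_negative_coefficients(build_cohort, validation_cohort):
    for cohort in (build_cohort, validation_cohort):
        for number in model_catalog():
            refined = PeriorbitalAgeModel.from_catalog(cohort, number).fit().refine()
            assert (refined.coefficients >= 0).all(), (number, len(cohort))


def test_predict_intercept_and_arithmetic():
    df = make_linear_cohort({"Pu": 0.5}, intercept=20.0, n=100)
    res = fit_model(df, ("Pu",))
    assert abs(res.predict({"Pu": 0.0}) - 20.0) < 1e-8
    assert abs(res.predict({"Pu": 40.0}) - 40.0) < 1e-8
    with pytest.raises(KeyError, match="Pu"):
        res.predict({"Wb": 1.0})


def test_in_sample_correlation_equals_multiple_correlation(build_cohort):
    res = PeriorbitalAgeModel.from_catalog(build_cohort, 7).fit()
    yhat = res.predict(build_cohort)
    r = np.corrcoef(yhat, build_cohort["age"])[0, 1]
    beta = normal_equations(build_cohort, res.subset)
    x = np.column_stack([np.ones(len(build_cohort)), build_cohort[list(res.subset)].to_numpy(float)])
    r_brute = np.corrcoef(x @ beta, build_cohort["age"])[0, 1]
    assert abs(r - r_brute) < 1e-10
    assert abs(r - np.sqrt(res.rsquared)) < 1e-10


def test_monotone_nesting_in_sample(build_cohort):
    r2 = {
        n: PeriorbitalAgeModel.from_catalog(build_cohort, n).fit().rsquared
        for n in model_catalog()
    }
    assert r2[7] >= r2[5] and r2[7] >= r2[6] >= r2[3] and r2[1] >= r2[8]


def test_validation_close_to_cv_on_exchangeable_cohorts(build_cohort, validation_cohort):
    cv = cross_validate(build_cohort, model_catalog()[7], seed=0)
    final = PeriorbitalAgeModel.from_catalog(build_cohort, 7).fit()
    val_r = validate_model(final, validation_cohort)
    assert len(validation_cohort) == 515
    assert abs(val_r - cv.mean_r) <= 0.05


def test_noiseless_validation_perfect():
    train = make_linear_cohort({"Wb": 0.4}, intercept=22.0, n=200, seed=0)
    test = make_linear_cohort({"Wb": 0.4}, intercept=22.0, n=100, seed=1)
    res = fit_model(train, ("Wb",))
    assert abs(validate_model(res, test) - 1.0) < 1e-9
    with pytest.raises(ValueError, match="at least 10"):
        validate_model(res, test.head(5))


def test_rank_deficient_design_names_collinear_feature():
    df = make_linear_cohort({"Wb": 0.2}, intercept=30.0, n=100)
    df["Wu"] = df["Wb"]  # exact duplicate
    with pytest.raises(np.linalg.LinAlgError, match="Wu|Wb"):
        fit_model(df, ("Wb", "Wu"))


def test_summary_mentions_features_and_refinement(build_cohort):
    refined = PeriorbitalAgeModel.from_catalog(build_cohort, 7, training_id="build").fit().refine()
    text = refined.summary()
    assert "periorbital" in text.lower() and "build" in text
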