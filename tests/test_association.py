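"""Logistic disease associations, BH-FDR, disease PCA and PC1 correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import periskin as ps
from periskin.age_models import PeriorbitalAgeModel
from periskin.association import (
    DiseaseAssociationStudy,
    association_table,
    bh_fdr,
    disease_pca,
    logistic_association,
    pc1_correlation,
)


def brute_force_bh(p):
    """Step-up enumeration: q_(i) = min_{j>=i} p_(j) * m / j on sorted order."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = [
        min(p[order[j]] * m / (j + 1) for j in range(i, m))
        for i in range(m)
    ]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# -- logistic regression ----------------------------------------------------

def test_two_by_two_table_matches_hand_computed_log_odds_ratio():
    # exposed: 30/100 diseased; unexposed: 10/100
    rows = []
    for exposed, diseased, count in [(1, 1, 30), (1, 0, 70), (0, 1, 10), (0, 0, 90)]:
        rows += [{"exposed": exposed, "D": diseased}] * count
    df = pd.DataFrame(rows)
    res = logistic_association(df, "D", "exposed")
    log_or = np.log((30 * 90) / (70 * 10))
    se = np.sqrt(1 / 30 + 1 / 70 + 1 / 10 + 1 / 90)
    assert abs(res.beta - log_or) < 1e-6
    assert abs(res.se - se) < 1e-4


def test_known_logistic_slope_recovered_within_ci():
    """Slope 0.05 per year of skin age recovered in >= 90% of 100 seeds."""
    covered = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        skin = rng.uniform(20, 70, 600)
        p = 1 / (1 + np.exp(-(-3.0 + 0.05 * (skin - 45))))
        df = pd.DataFrame({"skin": skin - 45, "D": (rng.uniform(size=600) < p).astype(int)})
        res = logistic_association(df, "D", "skin")
        covered += abs(res.beta - 0.05) <= 1.96 * res.se
    assert covered >= 90


def test_single_class_and_separation_rejected():
    df = pd.DataFrame({"x": np.arange(50, dtype=float), "D": np.zeros(50, dtype=int)})
    with pytest.raises(ValueError, match="single observed class"):
        logistic_association(df, "D", "x")
    sep = pd.DataFrame({"x": np.arange(50, dtype=float), "D": (np.arange(50) >= 25).astype(int)})
    with pytest.raises(ValueError, match="separab"):
        logistic_association(sep, "D", "x")


def test_wald_and_lrt_pvalues_agree_at_moderate_significance():
    rng = np.random.default_rng(8)
    n = 800
    x = rng.uniform(-1, 1, n)
    p = 1 / (1 + np.exp(-(-1.5 + 0.45 * x)))
    df = pd.DataFrame({"x": x, "D": (rng.uniform(size=n) < p).astype(int)})
    wald = logistic_association(df, "D", "x")
    lrt = logistic_association(df, "D", "x", use_lrt=True)
    assert abs(wald.beta - lrt.beta) < 1e-8
    assert 0.5 <= lrt.pvalue / wald.pvalue <= 2.0


def test_age_adjustment_attenuates_age_mediated_association(build_cohort):
    """Disease depends on skin age only through chronological age, so
    adjusting for age pulls the skin-age coefficient toward zero."""
    skin = PeriorbitalAgeModel.from_catalog(build_cohort, 7).fit().predict(build_cohort)
    work = build_cohort.copy()
    work["skin"] = skin
    crude = logistic_association(work, "D0", "skin")
    adjusted = logistic_association(work, "D0", "skin", covariates=("age",))
    assert crude.beta > 0 and crude.pvalue < 1e-6
    assert abs(adjusted.beta) < abs(crude.beta)


# -- BH-FDR -----------------------------------------------------------------

def test_bh_known_family():
    q = bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
    assert bh_fdr([0.37])[0] == 0.37
    assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
def test_bh_matches_stepup_enumeration(pvals):
    assert np.allclose(bh_fdr(pvals), brute_force_bh(pvals), atol=1e-12)


def test_bh_order_preserving_and_bounded():
    rng = np.random.default_rng(0)
    p = rng.uniform(size=15)
    q = bh_fdr(p)
    assert np.all(q >= p) and np.all(q <= 1)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-15)
    with pytest.raises(ValueError):
        bh_fdr([])


# -- PCA --------------------------------------------------------------------

def one_factor_diseases(n=2000, seed=0, k=7):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    cols = {}
    for j in range(k):
        p = 1 / (1 + np.exp(-(-1.5 + 1.2 * z)))
        cols[f"D{j + 1}"] = (rng.uniform(size=n) < p).astype(int)
    return pd.DataFrame(cols), z


def test_one_factor_simulation_gives_same_sign_pc1_loadings():
    df, _ = one_factor_diseases()
    res = disease_pca(df)
    assert (res.pc1_loadings > 0).all()
    assert res.explained_variance_ratio[0] == max(res.explained_variance_ratio)


def test_pc1_explains_all_retained_variance_in_rank_one_case():
    rng = np.random.default_rng(1)
    d = (rng.uniform(size=200) < 0.4).astype(int)
    df = pd.DataFrame({"D1": d, "D2": d, "D3": 0, "D4": 0})
    with pytest.warns(UserWarning, match="zero-variance"):
        res = disease_pca(df)
    assert res.dropped == ("D3", "D4")
    assert abs(res.explained_variance_ratio[0] - 1.0) < 1e-12


def test_loadings_match_independent_eigendecomposition(build_cohort):
    cols = [f"D{i}" for i in range(1, 8)]
    res = disease_pca(build_cohort[cols])
    corr = np.corrcoef(build_cohort[cols].to_numpy(float), rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    v1 = evecs[:, np.argmax(evals)]
    if v1.sum() < 0:
        v1 = -v1
    assert np.allclose(res.pc1_loadings.to_numpy(), v1, atol=1e-8)


def test_pc1_correlation_trivia():
    df, z = one_factor_diseases(n=600, seed=3)
    res = disease_pca(df)
    r_self, _ = pc1_correlation(res, res.pc1)
    assert abs(r_self - 1.0) < 1e-12
    # brute-force covariance / sd formula
    r, _ = pc1_correlation(res, z)
    x, y = res.pc1, z
    brute = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
    assert abs(r - brute) < 1e-12
    with pytest.raises(ValueError, match="length mismatch"):
        pc1_correlation(res, z[:-5])


def test_pca_guards():
    with pytest.raises(ValueError):
        disease_pca(pd.DataFrame({"D1": np.zeros(100), "D2": np.zeros(100)}))
    with pytest.raises(ValueError):
        disease_pca(pd.DataFrame({"D1": [0, 1] * 5}))  # n < 30


# -- full table and study object -------------------------------------------

def test_association_table_has_eight_labeled_rows(build_cohort):
    skin = PeriorbitalAgeModel.from_catalog(build_cohort, 7).fit().predict(build_cohort)
    table = association_table(build_cohort, skin)
    assert list(table["code"]) == ["D0", "D1", "D2", "D3", "D4", "D5", "D6", "D7"]
    assert table["q_skin_age"].between(0, 1).all()
    assert (table["q_skin_age"] >= table["p_skin_age"] - 1e-15).all()


def test_individual_fdr_family_option(build_cohort):
    skin = PeriorbitalAgeModel.from_catalog(build_cohort, 7).fit().predict(build_cohort)
    table = association_table(build_cohort, skin, fdr_family="individual")
    d0 = table.set_index("code").loc["D0"]
    assert d0["q_skin_age"] == d0["p_skin_age"]  # D0 outside the 7-test family


def test_fully_null_family_rarely_significant():
    rng = np.random.default_rng(0)
    counts = []
    for seed in range(20):
        cohort = ps.generate_cohort(
            ps.CohortConfig(
                n_per_decade=120,
                disease_models={f"D{i}": (0.15, 0.0) for i in range(1, 8)},
                seed=seed,
            )
        )
        skin = rng.uniform(20, 70, len(cohort))  # unrelated score
        table = association_table(cohort, skin)
        counts.append(int((table["q_skin_age"] < 0.05).sum()))
    assert np.mean(counts) <= 0.5  # expected false discoveries ~ alpha


def test_study_object_summary_and_significance(build_cohort):
    skin = PeriorbitalAgeModel.from_catalog(build_cohort, 7).fit().predict(build_cohort)
    results = DiseaseAssociationStudy(build_cohort, skin).fit()
    assert {"D2", "D3", "D4", "D5"} <= set(results.significant)
    assert "PC1" in results.summary()
    assert results.pc1_r > 0.2
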