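"""Mixed-model engine: recovery, OLS oracle, VIF, AIC ranking, R^2."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from bmivol.cohort import GeneratorConfig, RoiEffect, generate_cohort
from bmivol.lmm import (
    DesignError,
    ModelSpec,
    RandomStructure,
    compare_random_structures,
    compute_vif,
    fit_lmm,
    r_squared,
    standard_spec,
)

NO_RANDOM = RandomStructure(site_intercept=False, subject_intercept=False,
                            hemisphere_within_subject=True)


def _effect(**over):
    base = dict(intercept=5000.0, beta_group=300.0, beta_bmi=40.0,
                beta_age=-5.0, beta_sex=-30.0, beta_icv=2e-3,
                beta_hemisphere=25.0, var_site=0.0, var_subject=0.0,
                var_residual=0.0)
    base.update(over)
    return RoiEffect(**base)


def _cohort(eff, *, n_sites=4, per_site=50, seed=0, roi="hippocampus", **cfg):
    return generate_cohort(GeneratorConfig(
        n_sites=n_sites, subjects_per_site=per_site, qc_missing_rate=0.0,
        roi_effects={roi: eff}, seed=seed, **cfg))


def test_noise_free_data_recovers_generator_coefficients_exactly():
    tab = _cohort(_effect())
    fit = fit_lmm(tab, standard_spec("hippocampus", "group", "bmi"))
    assert fit.method == "exact"
    expect = dict(group=300.0, bmi=40.0, age=-5.0, icv=2e-3,
                  sex=-30.0, hemisphere=25.0)
    for term, b in expect.items():
        assert fit.coef(term).b == pytest.approx(b, rel=1e-6)


def test_engine_without_random_terms_equals_closed_form_ols():
    tab = _cohort(_effect(var_residual=150.0**2), seed=5)
    spec = ModelSpec("hippocampus",
                     ("group", "bmi", "age", "sex", "hemisphere", "icv"),
                     random=NO_RANDOM)
    fit = fit_lmm(tab, spec)
    sub = tab.copy()
    X = np.column_stack([
        np.ones(len(sub)), (sub.group == "case").astype(float), sub.bmi,
        sub.age, (sub.sex == "F").astype(float),
        (sub.hemisphere == "right").astype(float), sub.icv,
    ])
    beta = np.linalg.solve(X.T @ X, X.T @ sub.volume.to_numpy())
    terms = ("group", "bmi", "age", "sex", "hemisphere", "icv")
    for j, term in enumerate(terms, start=1):
        assert fit.coef(term).b == pytest.approx(beta[j], rel=1e-8)


def test_mixed_fit_recovers_bmi_slope_within_two_se():
    eff = _effect(beta_bmi=60.0, var_site=100.0**2, var_subject=300.0**2,
                  var_residual=120.0**2)
    tab = _cohort(eff, n_sites=10, per_site=100, seed=9, roi="lateral_ventricles")
    fit = fit_lmm(tab, standard_spec("lateral_ventricles", "group", "bmi"))
    c = fit.coef("bmi")
    assert fit.converged
    assert abs(c.b - 60.0) < 3 * c.se
    assert c.t == pytest.approx(c.b / c.se)
    # and the estimate tracks the closed-form OLS oracle on the same design
    X = np.column_stack([
        np.ones(len(tab)), (tab.group == "case").astype(float), tab.bmi,
        tab.age, (tab.sex == "F").astype(float),
        (tab.hemisphere == "right").astype(float), tab.icv,
    ])
    beta = np.linalg.lstsq(X, tab.volume.to_numpy(), rcond=None)[0]
    assert c.b == pytest.approx(beta[2], abs=0.5 * c.se)


def test_centering_covariate_changes_intercept_only():
    eff = _effect(var_site=80.0**2, var_subject=200.0**2, var_residual=100.0**2)
    tab = _cohort(eff, seed=3)
    spec = standard_spec("hippocampus", "group", "bmi")
    fit0 = fit_lmm(tab, spec)
    shifted = tab.copy()
    shifted["bmi"] = shifted["bmi"] - shifted["bmi"].mean()
    fit1 = fit_lmm(shifted, spec)
    for term in ("group", "bmi", "age", "sex", "hemisphere", "icv"):
        assert fit1.coef(term).b == pytest.approx(fit0.coef(term).b, abs=1e-8 * max(1, abs(fit0.coef(term).b)))
        assert fit1.coef(term).se == pytest.approx(fit0.coef(term).se, rel=1e-6)
    assert fit1.coef("Intercept").b != pytest.approx(fit0.coef("Intercept").b)


def test_single_sex_cohort_with_sex_term_is_design_error():
    tab = _cohort(_effect(var_residual=100.0**2),
                  sex_model={"control": 1.0, "case": 1.0})
    with pytest.raises(DesignError):
        fit_lmm(tab, standard_spec("hippocampus", "group"))


def test_containment_df_counts_levels_consumed():
    tab = _cohort(_effect(var_residual=100.0**2), n_sites=4, per_site=50)
    fit = fit_lmm(tab, standard_spec("hippocampus", "group"))
    n_obs, p = 400, 6  # intercept + group + 4 covariates
    assert fit.coef("group").df == n_obs - p - (200 + 4)
    fit_res = fit_lmm(tab, standard_spec("hippocampus", "group"),
                      df_method="residual")
    assert fit_res.coef("group").df == n_obs - p


def test_vif_orthogonal_predictors_near_one(small_cohort):
    spec = standard_spec("hippocampus", "group", "bmi")
    vif = compute_vif(small_cohort, spec)
    assert vif["bmi"] == pytest.approx(1.0, abs=0.2)
    assert all(v >= 1.0 for v in vif.values())


def test_vif_duplicated_predictor_is_infinite(small_cohort):
    # medication_count duplicating bmi exactly
    tab = small_cohort.copy()
    tab["medication_count"] = tab["bmi"]
    spec = ModelSpec("hippocampus", ("bmi", "medication_count"))
    vif = compute_vif(tab, spec)
    assert np.isinf(vif["bmi"]) and np.isinf(vif["medication_count"])


def test_vif_independent_medication_and_bmi_near_one():
    cfg = GeneratorConfig(n_sites=5, subjects_per_site=100, qc_missing_rate=0.0,
                          include_medications=True, seed=17)
    tab = generate_cohort(cfg)
    cases = tab[tab.group == "case"]
    vif = compute_vif(cases, ModelSpec("hippocampus", ("bmi", "medication_count",
                                                       "age", "sex")))
    assert vif["bmi"] == pytest.approx(1.01, abs=0.05)
    assert vif["medication_count"] == pytest.approx(1.01, abs=0.05)


def test_aic_prefers_site_structure_when_site_variance_exists():
    wins = 0
    n_sims = 30
    eff = _effect(var_site=400.0**2, var_subject=200.0**2,
                  var_residual=150.0**2)
    specs = lambda: [  # noqa: E731
        standard_spec("hippocampus", "group",
                      random=RandomStructure(True, True, True)),
        standard_spec("hippocampus", "group",
                      random=RandomStructure(False, True, True)),
    ]
    for s in range(n_sims):
        tab = _cohort(eff, n_sites=8, per_site=30, seed=100 + s)
        ranked = compare_random_structures(tab, specs())
        if ranked.loc[0, "structure"] == "site+subject+hemi-resid":
            wins += 1
    assert wins >= 0.9 * n_sims


def test_aic_identical_specs_identical():
    tab = _cohort(_effect(var_site=100.0**2, var_subject=150.0**2,
                          var_residual=100.0**2), seed=4)
    spec = standard_spec("hippocampus", "group")
    ranked = compare_random_structures(tab, [spec, spec])
    assert ranked["aic"].iloc[0] == ranked["aic"].iloc[1]


def test_r_squared_null_and_deterministic_limits():
    flat = _effect(beta_group=0.0, beta_bmi=0.0, beta_age=0.0, beta_sex=0.0,
                   beta_icv=0.0, beta_hemisphere=0.0, var_residual=100.0**2)
    tab = _cohort(flat, seed=8)
    fit = fit_lmm(tab, standard_spec("hippocampus", "group"))
    assert r_squared(fit)["marginal"] == pytest.approx(0.0, abs=0.03)
    # deterministic outcome with the full generating model: marginal R^2 -> 1
    det = fit_lmm(_cohort(_effect()), standard_spec("hippocampus", "group", "bmi"))
    assert r_squared(det)["marginal"] == pytest.approx(1.0)
    # omitting a real subject-level predictor moves its share into the
    # subject variance: conditional stays ~1, marginal drops below it
    part = fit_lmm(_cohort(_effect()), standard_spec("hippocampus", "group"))
    rsq = r_squared(part)
    assert rsq["conditional"] == pytest.approx(1.0, abs=1e-6)
    assert rsq["marginal"] < rsq["conditional"]


def test_r_squared_matches_constructed_variance_shares():
    """fixed:random:residual = 1:1:2 -> marginal 0.25, conditional 0.5."""
    rng_sd = np.sqrt(1.0)
    eff = RoiEffect(intercept=0.0, beta_group=0.0, beta_bmi=2.0 / 4.12,
                    beta_age=0.0, beta_sex=0.0, beta_icv=0.0,
                    beta_hemisphere=0.0, var_site=0.25, var_subject=0.75,
                    var_residual=2.0)
    # var(bmi_slope * bmi) = (2/4.12)^2 * 4.12^2 ... choose slope so fixed var = 1
    eff = dataclasses.replace(eff, beta_bmi=1.0 / 4.12)
    cfg = GeneratorConfig(
        n_sites=30, subjects_per_site=120, qc_missing_rate=0.0,
        case_fraction=0.0, bmi_path_a=0.0,
        roi_effects={"caudate": eff}, seed=12,
    )
    tab = generate_cohort(cfg)
    fit = fit_lmm(tab, ModelSpec("caudate", ("bmi",)))
    rsq = r_squared(fit)
    assert rsq["marginal"] == pytest.approx(0.25, abs=0.05)
    assert rsq["conditional"] == pytest.approx(0.5, abs=0.05)


def test_orthogonal_covariate_does_not_inflate_residual_variance():
    eff = _effect(var_site=50.0**2, var_subject=100.0**2, var_residual=80.0**2)
    tab = _cohort(eff, seed=14)
    f0 = fit_lmm(tab, ModelSpec("hippocampus", ("group", "bmi")))
    f1 = fit_lmm(tab, ModelSpec("hippocampus", ("group", "bmi", "age")))
    assert f1.var_residual <= f0.var_residual * 1.01
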