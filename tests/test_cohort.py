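"""Generator contract: determinism, built-in effects, QC structure."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from bmivol.cohort import (
    ConfigError,
    GeneratorConfig,
    RoiEffect,
    default_roi_effects,
    generate_cohort,
    provenance,
)


def _flat_effect(**over):
    base = dict(intercept=1000.0, beta_group=0.0, beta_bmi=0.0, beta_age=0.0,
                beta_sex=0.0, beta_icv=0.0, beta_hemisphere=0.0,
                var_site=0.0, var_subject=0.0, var_residual=0.0)
    base.update(over)
    return RoiEffect(**base)


def test_identical_seed_and_config_reproduce_table_exactly():
    cfg = GeneratorConfig(n_sites=3, subjects_per_site=20, seed=5)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    pd.testing.assert_frame_equal(a, b)
    c = generate_cohort(cfg, seed=6)
    assert not a["volume"].equals(c["volume"])


def test_degenerate_noise_free_flat_model_gives_constant_volume():
    cfg = GeneratorConfig(
        n_sites=2, subjects_per_site=10, qc_missing_rate=0.0,
        roi_effects={"hippocampus": _flat_effect()}, seed=1,
    )
    tab = generate_cohort(cfg)
    assert np.allclose(tab["volume"], 1000.0)


def test_group_bmi_means_match_reference_distributions():
    """Realized group BMI means stay within 3 SEM of 24.43 and 26.80."""
    sizes = [161] * 16 + [159]  # 2735 subjects
    cfg = GeneratorConfig(n_sites=17, subjects_per_site=sizes, seed=11)
    tab = generate_cohort(cfg)
    subj = tab.drop_duplicates("subject_id")
    for grp, mean, sd in (("control", 24.43, 4.12), ("case", 26.80, 5.22)):
        vals = subj.loc[subj.group == grp, "bmi"]
        sem = sd / np.sqrt(len(vals))
        assert abs(vals.mean() - mean) < 3 * sem
    n_case = (subj.group == "case").sum()
    assert abs(n_case - 1134) <= 17  # per-site rounding only


def test_ols_on_generated_data_recovers_generator_coefficients():
    """Closed-form OLS on subject means recovers beta within 2 Monte-Carlo SE."""
    eff = _flat_effect(beta_group=600.0, beta_bmi=50.0, var_residual=200.0**2)
    cfg = GeneratorConfig(
        n_sites=4, subjects_per_site=500, qc_missing_rate=0.0,
        bmi_path_a=2.4, roi_effects={"lateral_ventricles": eff}, seed=21,
    )
    tab = generate_cohort(cfg)
    subj = tab.groupby("subject_id", as_index=False).agg(
        volume=("volume", "mean"), bmi=("bmi", "first"), group=("group", "first"))
    X = np.column_stack([
        np.ones(len(subj)), (subj.group == "case").astype(float), subj.bmi,
    ])
    y = subj.volume.to_numpy()
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    cov = (resid @ resid / (len(y) - 3)) * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    assert abs(beta[1] - 600.0) < 2 * se[1]
    assert abs(beta[2] - 50.0) < 2 * se[2]
    # path a recovered on BMI itself
    a_hat = subj.loc[subj.group == "case", "bmi"].mean() - subj.loc[
        subj.group == "control", "bmi"].mean()
    assert a_hat == pytest.approx(2.4, abs=0.5)


def test_site_variance_recovered_from_site_means():
    """With beta=0, between-site variance of site means approaches var_site."""
    eff = _flat_effect(var_site=300.0**2, var_residual=50.0**2)
    cfg = GeneratorConfig(
        n_sites=40, subjects_per_site=200, qc_missing_rate=0.0,
        roi_effects={"thalamus": eff}, seed=31,
    )
    tab = generate_cohort(cfg)
    site_means = tab.groupby("site_id")["volume"].mean()
    assert site_means.var(ddof=1) == pytest.approx(300.0**2, rel=0.35)


def test_provenance_records_true_indirect_effect():
    cfg = GeneratorConfig(
        n_sites=2, subjects_per_site=30, bmi_path_a=2.4,
        roi_effects={"lateral_ventricles": _flat_effect(beta_bmi=47.0)}, seed=3,
    )
    tab = generate_cohort(cfg)
    rec = provenance(cfg, tab)
    assert rec["true_indirect"]["lateral_ventricles"] == pytest.approx(2.4 * 47.0)
    assert rec["path_a"] == 2.4
    # default per-group means imply the additive shift
    assert GeneratorConfig().path_a == pytest.approx(26.80 - 24.43)


def test_qc_missingness_removes_both_hemispheres_jointly():
    cfg = GeneratorConfig(n_sites=3, subjects_per_site=40, qc_missing_rate=0.3,
                          seed=13)
    tab = generate_cohort(cfg)
    counts = tab.groupby(["subject_id", "roi"]).size()
    assert set(counts.unique()) == {2}
    # missingness actually happened
    n_expected = 3 * 40 * len(default_roi_effects())
    assert counts.shape[0] < n_expected


def test_covariates_constant_within_subject(small_cohort):
    nun = small_cohort.groupby("subject_id")[["group", "age", "sex", "bmi", "icv"]].nunique()
    assert (nun == 1).all().all()


@pytest.mark.parametrize(
    "field,value",
    [("n_sites", 0), ("subjects_per_site", 0), ("case_fraction", 1.5),
     ("qc_missing_rate", -0.1)],
)
def test_invalid_configuration_rejected(field, value):
    with pytest.raises(ConfigError):
        GeneratorConfig(**{field: value}).validate()


def test_negative_variance_rejected():
    with pytest.raises(ConfigError):
        GeneratorConfig(
            roi_effects={"amygdala": _flat_effect(var_site=-1.0)}
        ).validate()
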