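"""Per-ROI model families, FDR control, interaction screens and post-hocs.

For each subcortical ROI three mixed models are fitted: diagnosis alone
("group_only"), BMI alone ("bmi_only") and the joint diagnosis+BMI model,
all with age, sex, hemisphere and ICV covariates and the standard random
structure (site and subject intercepts, hemisphere-level residuals).
Benjamini-Hochberg FDR is applied within each model family x term across the
eight ROIs (not globally), matching the per-column adjustment pattern of the
primary results table.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import ROI_LABELS
from .effects import cohens_d, partial_r
from .lmm import (
    DesignError,
    ModelSpec,
    RandomStructure,
    compute_vif,
    fit_lmm,
    r_squared,
    standard_spec,
)

MODEL_FAMILIES = {
    "group_only": ("group",),
    "bmi_only": ("bmi",),
    "joint": ("group", "bmi"),
}


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def run_model_families(
    data: pd.DataFrame,
    *,
    alpha: float = 0.05,
    reml: bool = True,
    df_method: str = "containment",
    random: RandomStructure | None = None,
) -> pd.DataFrame:
    """Fit the three model families per ROI and FDR-adjust across ROIs.

    Returns one row per ROI x family x term of interest with coefficient,
    SE, DF, raw and FDR-adjusted p, and the effect size with its 95% CI
    (Cohen's d for the group contrast, partial r for BMI). ROIs missing from
    the table are skipped with a warning; per-ROI fit failures are recorded
    as NaN rows without aborting the remaining ROIs.
    """
    present = [r for r in ROI_LABELS if r in set(data["roi"])]
    missing = set(ROI_LABELS) - set(present)
    if missing:
        warnings.warn(f"ROIs absent from table, skipped: {sorted(missing)}")

    rows = []
    for family, lead in MODEL_FAMILIES.items():
        fits = {}
        for roi in present:
            spec = standard_spec(roi, *lead, random=random)
            try:
                fits[roi] = fit_lmm(data, spec, reml=reml, df_method=df_method)
            except DesignError as exc:
                warnings.warn(f"{roi}/{family}: {exc}")
                fits[roi] = None
        for term in lead:
            p_raw, recs = [], []
            for roi in present:
                fit = fits[roi]
                if fit is None:
                    recs.append(dict(roi=roi, model_family=family, term=term,
                                     b=np.nan, se_b=np.nan, df=np.nan,
                                     p_raw=np.nan, n1=None, n2=None,
                                     converged=False))
                    p_raw.append(np.nan)
                    continue
                c = fit.coef(term)
                recs.append(dict(roi=roi, model_family=family, term=term,
                                 b=c.b, se_b=c.se, df=c.df, p_raw=c.p,
                                 n1=fit.n1, n2=fit.n2, converged=fit.converged))
                p_raw.append(c.p)
            p_raw = np.asarray(p_raw)
            ok = np.isfinite(p_raw)
            p_fdr = np.full_like(p_raw, np.nan)
            if ok.any():
                p_fdr[ok] = bh_fdr(p_raw[ok])
            for rec, pf in zip(recs, p_fdr):
                rec["p_fdr"] = pf
                rec["significant"] = bool(np.isfinite(pf) and pf < alpha)
                if np.isfinite(rec["b"]) and rec["se_b"] > 0:
                    if term == "group":
                        es = cohens_d(rec["b"], rec["se_b"], rec["df"],
                                      rec["n1"], rec["n2"])
                        rec["effect_kind"] = "cohens_d"
                    else:
                        es = partial_r(rec["b"], rec["se_b"], rec["df"])
                        rec["effect_kind"] = "partial_r"
                    rec["effect"] = es.value
                    rec["effect_ci_low"] = es.ci_low
                    rec["effect_ci_high"] = es.ci_high
                else:
                    rec["effect_kind"] = None
                    rec["effect"] = rec["effect_ci_low"] = rec["effect_ci_high"] = np.nan
                rows.append(rec)
    out = pd.DataFrame(rows)
    return out.reset_index(drop=True)


def screen_interactions(
    data: pd.DataFrame,
    *,
    alpha: float = 0.05,
    df_method: str = "containment",
) -> pd.DataFrame:
    """Interaction screens per ROI.

    group x BMI: fixed interaction added to the joint model, FDR across
    ROIs; retained only when FDR-significant. BMI x site: likelihood-ratio
    test of a random BMI slope by site (ML fits); because the null pins a
    variance at the boundary, the p-value uses the 0.5*chi2_0 + 0.5*chi2_1
    mixture.
    """
    present = [r for r in ROI_LABELS if r in set(data["roi"])]
    rows = []
    for roi in present:
        rec = {"roi": roi}
        # fixed group x BMI interaction
        try:
            spec = ModelSpec(roi, ("group", "bmi", "group:bmi",
                                   "age", "sex", "hemisphere", "icv"))
            fit = fit_lmm(data, spec, reml=True, df_method=df_method)
            c = fit.coef("group:bmi")
            rec.update(gxb_b=c.b, gxb_se=c.se, gxb_p=c.p)
        except DesignError as exc:
            rec.update(gxb_b=np.nan, gxb_se=np.nan, gxb_p=np.nan,
                       note=str(exc))
        # random BMI slope by site (LRT, ML); the slope variable is centered
        # so the slope variance is not confounded with the site intercept
        try:
            centered = data.assign(bmi_c=data["bmi"] - data["bmi"].mean())
            spec0 = standard_spec(roi, "group", "bmi")
            fit0 = fit_lmm(centered, spec0, reml=False, df_method=df_method)
            fit1 = fit_lmm(centered, spec0, reml=False, df_method=df_method,
                           extra_vc={"bmi_site_slope": "0 + bmi_c"})
            diff = fit1.llf - fit0.llf
            # deterministic outcomes fit exactly under either structure
            lrt = max(0.0, 2.0 * diff) if np.isfinite(diff) else 0.0
            p_mix = 0.5 * stats.chi2.sf(lrt, 1) if lrt > 0 else 1.0
            rec.update(bmi_site_lrt=lrt, bmi_site_p=p_mix)
        except DesignError as exc:
            rec.update(bmi_site_lrt=np.nan, bmi_site_p=np.nan, note=str(exc))
        rows.append(rec)
    out = pd.DataFrame(rows)
    pg = out["gxb_p"].to_numpy()
    ok = np.isfinite(pg)
    fdr = np.full_like(pg, np.nan)
    if ok.any():
        fdr[ok] = bh_fdr(pg[ok])
    out["gxb_p_fdr"] = fdr
    out["gxb_retained"] = np.isfinite(fdr) & (fdr < alpha)
    ps = out["bmi_site_p"].to_numpy()
    oks = np.isfinite(ps)
    fdrs = np.full_like(ps, np.nan)
    if oks.any():
        fdrs[oks] = bh_fdr(ps[oks])
    out["bmi_site_p_fdr"] = fdrs
    out["bmi_site_significant"] = np.isfinite(fdrs) & (fdrs < alpha)
    return out


def variance_comparison(data: pd.DataFrame) -> pd.DataFrame:
    """Per-ROI percent difference in group variances of subject bilateral means.

    Reports ``100 * |var_case - var_control| / var_control``.
    """
    rows = []
    for roi in [r for r in ROI_LABELS if r in set(data["roi"])]:
        sub = data[(data["roi"] == roi) & data["volume"].notna()]
        means = sub.groupby(["subject_id"], as_index=False).agg(
            volume=("volume", "mean"), group=("group", "first"))
        v_ctrl = means.loc[means.group == "control", "volume"].var(ddof=1)
        v_case = means.loc[means.group == "case", "volume"].var(ddof=1)
        if not np.isfinite(v_ctrl) or not np.isfinite(v_case):
            raise ValueError(f"{roi}: both groups required for variance comparison")
        rows.append(dict(roi=roi, var_control=v_ctrl, var_case=v_case,
                         pct_difference=100.0 * abs(v_case - v_ctrl) / v_ctrl))
    return pd.DataFrame(rows)


def posthoc_medication_models(
    data: pd.DataFrame,
    *,
    roi: str = "lateral_ventricles",
    df_method: str = "containment",
) -> dict:
    """Medication post-hoc models on the case subset.

    Fits, among cases only: (1) BMI ~ medication count (subject-level, site
    random intercept); (2) ROI volume ~ medication count; (3) volume ~
    medication count + BMI with an interaction screen; (4) volume ~ lithium;
    plus volume ~ BMI alone for the R^2 comparison. Reports coefficients,
    the BMI/medication VIFs and marginal R^2 of the volume models. Returns a
    skip notice when medication fields are absent.
    """
    if "medication_count" not in data.columns or "lithium" not in data.columns:
        return {"skipped": "medication_count/lithium fields not present"}
    cases = data[data["group"] == "case"].copy()
    if cases.empty:
        return {"skipped": "no case subjects in table"}
    # BMI outcome fits reuse the engine by temporarily treating BMI as the
    # volume of the target ROI on subject-collapsed rows.
    bmi_as_outcome = cases[cases["roi"] == roi].copy()
    bmi_as_outcome["volume"] = bmi_as_outcome["bmi"]
    med_rand = RandomStructure(site_intercept=True, subject_intercept=False,
                               hemisphere_within_subject=False)
    out: dict = {}

    f_bmi_med = fit_lmm(
        bmi_as_outcome,
        ModelSpec(roi, ("medication_count", "age", "sex"), random=med_rand),
        df_method=df_method,
    )
    out["bmi_on_medications"] = _coef_dict(f_bmi_med, "medication_count")

    f_vol_med = fit_lmm(cases, standard_spec(roi, "medication_count"),
                        df_method=df_method)
    out["volume_on_medications"] = _coef_dict(f_vol_med, "medication_count")
    out["volume_on_medications"]["marginal_r2"] = r_squared(f_vol_med)["marginal"]

    f_vol_bmi = fit_lmm(cases, standard_spec(roi, "bmi"), df_method=df_method)
    out["volume_on_bmi"] = _coef_dict(f_vol_bmi, "bmi")
    out["volume_on_bmi"]["marginal_r2"] = r_squared(f_vol_bmi)["marginal"]

    spec_joint = standard_spec(roi, "medication_count", "bmi")
    f_joint = fit_lmm(cases, spec_joint, df_method=df_method)
    out["volume_joint"] = {
        "medication_count": _coef_dict(f_joint, "medication_count"),
        "bmi": _coef_dict(f_joint, "bmi"),
        "marginal_r2": r_squared(f_joint)["marginal"],
        "vif": compute_vif(cases, spec_joint),
    }
    f_inter = fit_lmm(
        cases,
        ModelSpec(roi, ("medication_count", "bmi", "medication_count:bmi",
                        "age", "sex", "hemisphere", "icv")),
        df_method=df_method,
    )
    out["volume_joint"]["interaction"] = _coef_dict(f_inter, "medication_count:bmi")

    f_li = fit_lmm(cases, standard_spec(roi, "lithium"), df_method=df_method)
    out["volume_on_lithium"] = _coef_dict(f_li, "lithium")
    return out


def _coef_dict(fit, term: str) -> dict:
    c = fit.coef(term)
    return {"term": term, "b": c.b, "se_b": c.se, "df": c.df, "t": c.t,
            "p": c.p, "converged": fit.converged}
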