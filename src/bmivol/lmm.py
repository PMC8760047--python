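"""Linear mixed-model engine for the per-ROI volume analyses.

One outcome ROI at a time, the model is

    volume ~ fixed terms (group, bmi, age, sex, hemisphere, icv, ...)
             + (1 | site) + (1 | subject)

with an independent hemisphere-level residual, i.e. the hemisphere
measurements nest within subjects, and subjects nest within data-collection
sites. Estimation is delegated to :class:`statsmodels` ``MixedLM`` (site as
the grouping factor, subject intercepts as a variance component); this
module's job is the contract around it: design construction, the
denominator-DF convention, the degenerate-data paths, and uniform summaries
consumed by the effect-size, FDR and mediation stages.

Denominator DF uses a containment-style convention:

    DF = n_obs - n_fixed_coefficients - n_grouping_levels_consumed

where the consumed levels are the subjects (when a subject intercept is
estimated) and the sites (when a site intercept is estimated). This
reproduces the magnitude pattern of published mega-analysis DFs; a plain
residual convention (``n_obs - n_fixed``) is available via ``df_method``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ROI_LABELS

#: Continuous fixed-term names (everything else is treated as 0/1).
_CONTINUOUS = {"bmi", "age", "icv"}

#: Fixed terms understood by the design builder.
KNOWN_TERMS = (
    "group",
    "bmi",
    "age",
    "sex",
    "hemisphere",
    "icv",
    "group:bmi",
    "medication_count",
    "lithium",
    "medication_count:bmi",
)

STANDARD_COVARIATES = ("age", "sex", "hemisphere", "icv")


class DesignError(ValueError):
    """The requested design cannot be built/estimated on this table."""


@dataclass(frozen=True)
class RandomStructure:
    site_intercept: bool = True
    subject_intercept: bool = True
    #: keep both hemisphere rows with independent hemisphere-level residuals;
    #: when False the table is collapsed to subject-level bilateral means.
    hemisphere_within_subject: bool = True

    def label(self) -> str:
        parts = []
        if self.site_intercept:
            parts.append("site")
        if self.subject_intercept:
            parts.append("subject")
        if self.hemisphere_within_subject:
            parts.append("hemi-resid")
        return "+".join(parts) if parts else "none"


@dataclass(frozen=True)
class ModelSpec:
    """Outcome ROI, ordered fixed terms, and the random-effect structure."""

    outcome_roi: str
    fixed_terms: tuple[str, ...]
    random: RandomStructure = field(default_factory=RandomStructure)

    def __post_init__(self):
        if self.outcome_roi not in ROI_LABELS:
            raise DesignError(f"unknown ROI: {self.outcome_roi!r}")
        if len(set(self.fixed_terms)) != len(self.fixed_terms):
            raise DesignError("duplicate fixed terms")
        unknown = set(self.fixed_terms) - set(KNOWN_TERMS)
        if unknown:
            raise DesignError(f"unknown fixed terms: {sorted(unknown)}")


@dataclass(frozen=True)
class Coef:
    term: str
    b: float
    se: float
    df: float
    t: float
    p: float


@dataclass
class LmmFit:
    """Uniform fitted-model summary.

    ``coefs`` maps fixed-term name -> :class:`Coef` (intercept under
    ``"Intercept"``). Variance components are on the outcome scale;
    ``var_fixed`` is the variance of the fixed-effect predictions over the
    estimation sample (used for marginal/conditional R^2).
    """

    spec: ModelSpec
    coefs: dict[str, Coef]
    var_site: float
    var_subject: float
    var_residual: float
    var_fixed: float
    llf: float
    aic: float
    reml: bool
    n_obs: int
    n_subjects: int
    n_sites: int
    n1: int | None
    n2: int | None
    converged: bool
    method: str  # "mixedlm" | "ols" | "exact"
    notes: list[str] = field(default_factory=list)

    def coef(self, term: str) -> Coef:
        return self.coefs[term]


def _numeric_frame(data: pd.DataFrame, roi: str, terms: tuple[str, ...],
                   collapse: bool) -> pd.DataFrame:
    sub = data.loc[(data["roi"] == roi) & data["volume"].notna()].copy()
    if sub.empty:
        raise DesignError(f"no observations for ROI {roi!r}")
    sub["group_n"] = (sub["group"] == "case").astype(float)
    sub["sex_n"] = (sub["sex"] == "F").astype(float)
    sub["hemi_n"] = (sub["hemisphere"] == "right").astype(float)
    if collapse:
        keys = {"site_id": "first", "group_n": "first", "sex_n": "first",
                "age": "first", "bmi": "first", "icv": "first", "volume": "mean"}
        for extra in ("medication_count", "lithium"):
            if extra in sub.columns:
                keys[extra] = "first"
        sub = sub.groupby("subject_id", as_index=False).agg(keys)
        sub["hemi_n"] = 0.5
    cols = {"group": "group_n", "sex": "sex_n", "hemisphere": "hemi_n"}
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            sub[t] = sub[cols.get(a, a)] * sub[cols.get(b, b)]
    return sub


def _design(sub: pd.DataFrame, terms: tuple[str, ...]) -> tuple[np.ndarray, list[str], np.ndarray]:
    cols = {"group": "group_n", "sex": "sex_n", "hemisphere": "hemi_n"}
    names = ["Intercept"] + list(terms)
    X = [np.ones(len(sub))]
    scales = [1.0]
    for t in terms:
        x = sub[cols.get(t, t)].to_numpy(dtype=float)
        s = float(np.std(x))
        if t in _CONTINUOUS or ":" in t:
            s = s if s > 0 else 1.0
        else:
            s = 1.0
        X.append(x / s)
        scales.append(s)
    X = np.column_stack(X)
    # singularity check on the standardized design
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError(
            "singular fixed-effect design (collinear or constant terms): "
            + ", ".join(names)
        )
    return X, names, np.asarray(scales)


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    p = X.shape[1]
    dof = max(len(y) - p, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    return beta, cov, sigma2


def fit_lmm(
    data: pd.DataFrame,
    spec: ModelSpec,
    *,
    reml: bool = True,
    df_method: str = "containment",
    extra_vc: dict[str, str] | None = None,
) -> LmmFit:
    """Fit the mixed model described by ``spec`` on a cohort table.

    Degenerate inputs are handled explicitly rather than passed to the
    optimizer: a perfectly deterministic outcome (zero residual after the
    fixed effects) returns the exact interpolating solution, and a spec with
    no random terms reduces to ordinary least squares. Non-convergence is
    reported on the result, never silently absorbed.

    ``extra_vc`` adds variance-component formulas evaluated within site
    groups (used for the random BMI-by-site slope screen).
    """
    collapse = not spec.random.hemisphere_within_subject
    terms = spec.fixed_terms
    if collapse and "hemisphere" in terms:
        terms = tuple(t for t in terms if t != "hemisphere")
    sub = _numeric_frame(data, spec.outcome_roi, terms, collapse)
    n_subjects = sub["subject_id"].nunique() if "subject_id" in sub.columns else len(sub)
    n_sites = sub["site_id"].nunique()
    if n_sites < 2 and spec.random.site_intercept:
        raise DesignError("need >= 2 sites for a site random intercept")

    y = sub["volume"].to_numpy(dtype=float)
    X, names, scales = _design(sub, terms)
    notes: list[str] = []

    n1 = n2 = None
    if "group" in terms:
        grp = sub.drop_duplicates("subject_id")["group_n"] if "subject_id" in sub.columns else sub["group_n"]
        n1 = int((grp == 0).sum())
        n2 = int((grp == 1).sum())

    if spec.random.hemisphere_within_subject and "subject_id" in sub.columns:
        counts = sub.groupby(["subject_id"]).size()
        n_single = int((counts % 2).sum())
        if n_single:
            notes.append(f"{n_single} subject(s) contribute a single hemisphere")

    use_site = spec.random.site_intercept
    use_subject = spec.random.subject_intercept and spec.random.hemisphere_within_subject

    # --- degenerate path: deterministic outcome (exact interpolation) ---
    beta0, cov0, sigma2_0 = _ols(y, X)
    sst = float(np.var(y)) * len(y)
    if sigma2_0 * len(y) <= max(1e-10 * max(sst, 1.0), 1e-12):
        coefs = _package_coefs(beta0, np.zeros_like(cov0), names, scales,
                               dfree=max(len(y) - len(names), 1), exact=True)
        return LmmFit(
            spec=spec, coefs=coefs, var_site=0.0, var_subject=0.0,
            var_residual=0.0, var_fixed=float(np.var(X @ beta0)),
            llf=np.inf, aic=-np.inf, reml=reml, n_obs=len(y),
            n_subjects=n_subjects, n_sites=n_sites, n1=n1, n2=n2,
            converged=True, method="exact",
            notes=notes + ["deterministic outcome: exact interpolation"],
        )

    # --- no random terms: plain OLS ---
    if not use_site and not use_subject and not extra_vc:
        beta, cov, sigma2 = _ols(y, X)
        dfree = _dof(df_method, len(y), len(names), 0)
        coefs = _package_coefs(beta, cov, names, scales, dfree)
        llf = -0.5 * len(y) * (np.log(2 * np.pi * sigma2) + 1)
        k = len(names) + 1
        return LmmFit(
            spec=spec, coefs=coefs, var_site=0.0, var_subject=0.0,
            var_residual=sigma2, var_fixed=float(np.var(X @ beta)),
            llf=llf, aic=-2 * llf + 2 * k, reml=reml, n_obs=len(y),
            n_subjects=n_subjects, n_sites=n_sites, n1=n1, n2=n2,
            converged=True, method="ols", notes=notes,
        )

    # --- mixed model via statsmodels ---
    from statsmodels.regression.mixed_linear_model import MixedLM

    if use_site:
        groups = sub["site_id"].to_numpy()
        exog_re = np.ones((len(y), 1))
        vc_formulas = {}
        if use_subject:
            vc_formulas["subject"] = "0 + C(subject_id)"
    else:
        groups = sub["subject_id"].to_numpy()
        exog_re = np.ones((len(y), 1))
        vc_formulas = {}
    if extra_vc:
        vc_formulas.update(extra_vc)

    frame = sub.copy()
    for j, nm in enumerate(names):
        frame[f"__x{j}"] = X[:, j]

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if vc_formulas:
            model = MixedLM.from_formula(
                "volume ~ 0 + " + " + ".join(f"__x{j}" for j in range(len(names))),
                data=frame, groups=groups, re_formula="1" if use_site or not use_site else None,
                vc_formula=vc_formulas,
            )
        else:
            model = MixedLM(y, X, groups=groups, exog_re=exog_re)
        try:
            res = model.fit(reml=reml, method="lbfgs", maxiter=500)
            converged = bool(res.converged)
        except Exception as exc:  # noqa: BLE001 - surfaced on the result
            notes.append(f"fit failed: {exc}")
            beta, cov, sigma2 = _ols(y, X)
            dfree = _dof(df_method, len(y), len(names),
                         (n_subjects if use_subject else 0) + (n_sites if use_site else 0))
            coefs = _package_coefs(beta, cov, names, scales, dfree)
            return LmmFit(
                spec=spec, coefs=coefs, var_site=np.nan, var_subject=np.nan,
                var_residual=sigma2, var_fixed=float(np.var(X @ beta)),
                llf=np.nan, aic=np.nan, reml=reml, n_obs=len(y),
                n_subjects=n_subjects, n_sites=n_sites, n1=n1, n2=n2,
                converged=False, method="mixedlm", notes=notes,
            )
    # Boundary/singular-covariance warnings are legitimate REML outcomes
    # (a variance component estimated at zero), recorded but not treated as
    # failures; res.converged reports true optimizer failure.
    for w in caught:
        msg = str(w.message)
        if "retry" in msg.lower() or "failed" in msg.lower():
            converged = False
        if msg not in notes and w.category.__name__ != "FutureWarning":
            notes.append(msg)

    fe = np.asarray(res.fe_params)
    cov_fe = np.asarray(res.cov_params())[: len(fe), : len(fe)]

    cov_re = np.asarray(res.cov_re)
    var_site = float(cov_re[0, 0]) if use_site else 0.0
    var_subject = 0.0
    if use_subject and vc_formulas:
        var_subject = float(res.vcomp[list(vc_formulas).index("subject")])
    elif not use_site:
        var_subject = float(cov_re[0, 0])
    var_resid = float(res.scale)

    levels = (n_subjects if use_subject else 0) + (n_sites if use_site else 0)
    dfree = _dof(df_method, len(y), len(names), levels)
    coefs = _package_coefs(fe, cov_fe, names, scales, dfree)

    k = len(names) + 1 + int(use_site) + len(vc_formulas) + (1 if not use_site else 0)
    llf = float(res.llf)
    aic = -2 * llf + 2 * k
    if reml:
        notes.append("AIC from REML likelihood; use ML fits for structure comparison")

    return LmmFit(
        spec=spec, coefs=coefs, var_site=var_site, var_subject=var_subject,
        var_residual=var_resid, var_fixed=float(np.var(X @ fe)),
        llf=llf, aic=aic, reml=reml, n_obs=len(y), n_subjects=n_subjects,
        n_sites=n_sites, n1=n1, n2=n2, converged=converged,
        method="mixedlm", notes=notes,
    )


def _dof(df_method: str, n_obs: int, n_fixed: int, levels: int) -> float:
    if df_method == "containment":
        return float(max(n_obs - n_fixed - levels, 1))
    if df_method == "residual":
        return float(max(n_obs - n_fixed, 1))
    raise ValueError(f"unknown df_method: {df_method!r}")


def _package_coefs(beta, cov, names, scales, dfree, exact=False) -> dict[str, Coef]:
    out = {}
    for j, nm in enumerate(names):
        b = float(beta[j] / scales[j])
        se = float(np.sqrt(max(cov[j, j], 0.0)) / scales[j])
        if exact or se == 0.0:
            t = np.inf if b != 0 else 0.0
            p = 0.0 if b != 0 else 1.0
            se_rep = se
        else:
            t = b / se
            p = 2.0 * stats.t.sf(abs(t), dfree)
            se_rep = se
        out[nm] = Coef(term=nm, b=b, se=se_rep, df=float(dfree), t=float(t), p=float(p))
    return out


def compute_vif(data: pd.DataFrame, spec: ModelSpec) -> dict[str, float]:
    """Variance inflation factors over the subject-level design.

    ``VIF_j = 1 / (1 - R^2_j)`` from regressing predictor j on the remaining
    predictors (plus intercept). Perfect collinearity yields ``inf``.
    """
    terms = tuple(t for t in spec.fixed_terms if t != "hemisphere")
    if len(terms) < 2:
        raise DesignError("VIF needs >= 2 fixed terms")
    sub = _numeric_frame(data, spec.outcome_roi, terms, collapse=True)
    cols = {"group": "group_n", "sex": "sex_n", "hemisphere": "hemi_n"}
    M = np.column_stack([sub[cols.get(t, t)].to_numpy(dtype=float) for t in terms])
    out = {}
    n = M.shape[0]
    for j, t in enumerate(terms):
        yj = M[:, j]
        Xj = np.column_stack([np.ones(n), np.delete(M, j, axis=1)])
        beta, _, _, _ = np.linalg.lstsq(Xj, yj, rcond=None)
        resid = yj - Xj @ beta
        sst = float(np.sum((yj - yj.mean()) ** 2))
        if sst == 0:
            out[t] = np.inf
            continue
        r2 = 1.0 - float(resid @ resid) / sst
        out[t] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def compare_random_structures(
    data: pd.DataFrame, specs: list[ModelSpec], *, df_method: str = "containment"
) -> pd.DataFrame:
    """AIC-rank candidate random structures sharing the same fixed terms.

    Fits use ML (not REML) so likelihoods are comparable across random
    structures. Returns a table sorted by AIC with the difference to the
    best structure (``delta_aic``).
    """
    fixed = {s.fixed_terms for s in specs}
    if len(fixed) != 1:
        raise DesignError("structure comparison requires identical fixed terms")
    rows = []
    for s in specs:
        fit = fit_lmm(data, s, reml=False, df_method=df_method)
        rows.append(
            {
                "structure": s.random.label(),
                "aic": fit.aic,
                "llf": fit.llf,
                "converged": fit.converged,
                "n_obs": fit.n_obs,
            }
        )
    out = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    out["delta_aic"] = out["aic"] - out["aic"].iloc[0]
    return out


def r_squared(fit: LmmFit) -> dict[str, float]:
    """Marginal and conditional R^2 (variance-partition definition).

    marginal = var(fixed) / (var(fixed) + site + subject + residual);
    conditional additionally credits the random-effect variances to the
    numerator. Undefined (NaN) when the total variance is zero.
    """
    total = fit.var_fixed + fit.var_site + fit.var_subject + fit.var_residual
    if not np.isfinite(total) or total <= 0:
        return {"marginal": np.nan, "conditional": np.nan}
    return {
        "marginal": fit.var_fixed / total,
        "conditional": (fit.var_fixed + fit.var_site + fit.var_subject) / total,
    }


def standard_spec(roi: str, *leading_terms: str,
                  random: RandomStructure | None = None) -> ModelSpec:
    """Convenience: leading terms plus the standard covariate set."""
    terms = tuple(leading_terms) + STANDARD_COVARIATES
    return ModelSpec(outcome_roi=roi, fixed_terms=terms,
                     random=random or RandomStructure())
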