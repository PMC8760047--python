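"""Sample-description statistics.

Welch two-sample t tests with the Welch-Satterthwaite degrees-of-freedom
adjustment, Pearson chi-square tests of independence (no continuity
correction), and WHO BMI categorization (normal < 25 <= overweight < 30 <=
obese; underweight is folded into "normal" for the three-category table).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    test: str  # "welch_t" | "chi2"
    statistic: float
    df: float
    p: float
    detail: dict


def welch_t_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    *, variable: str = "",
) -> GroupComparison:
    """Welch t from group summary statistics (group2 minus group1)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("group SDs must be > 0")
    v1, v2 = sd1 * sd1 / n1, sd2 * sd2 / n2
    t = (mean2 - mean1) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return GroupComparison(
        variable=variable, test="welch_t", statistic=float(t), df=float(df),
        p=float(p),
        detail={"mean1": mean1, "sd1": sd1, "n1": n1,
                "mean2": mean2, "sd2": sd2, "n2": n2,
                "df_int": int(round(df))},
    )


def welch_t(x1, x2, *, variable: str = "") -> GroupComparison:
    """Welch t from raw samples."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return welch_t_summary(
        float(x1.mean()), float(x1.std(ddof=1)), len(x1),
        float(x2.mean()), float(x2.std(ddof=1)), len(x2),
        variable=variable,
    )


def pearson_chi2(table, *, variable: str = "") -> GroupComparison:
    """Pearson chi-square test of independence on a contingency table.

    No continuity correction (matching the conventional reporting for
    r x c tables); df = (r - 1)(c - 1). All expected counts must be > 0.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, df, expected = stats.chi2_contingency(obs, correction=False)
    if (expected <= 0).any():
        raise ValueError("expected counts must be > 0")
    return GroupComparison(
        variable=variable, test="chi2", statistic=float(chi2), df=float(df),
        p=float(p), detail={"observed": obs.tolist(), "expected": expected.tolist()},
    )


BMI_CATEGORIES = ("normal", "overweight", "obese")


def bmi_categorize(values) -> dict[str, int]:
    """WHO cut-points: normal < 25, 25 <= overweight < 30, obese >= 30."""
    v = np.asarray(values, dtype=float)
    if (v <= 0).any() or np.isnan(v).any():
        raise ValueError("BMI values must be positive and non-missing")
    return {
        "normal": int((v < 25.0).sum()),
        "overweight": int(((v >= 25.0) & (v < 30.0)).sum()),
        "obese": int((v >= 30.0).sum()),
    }


def category_percentages(counts: dict[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    return {k: 100.0 * c / total for k, c in counts.items()}


def table_one(cohort: pd.DataFrame) -> pd.DataFrame:
    """Group comparisons of age, BMI, sex and BMI category on a cohort table.

    Operates on one row per subject (covariates are subject-constant).
    """
    subj = cohort.drop_duplicates("subject_id")
    ctrl = subj[subj["group"] == "control"]
    case = subj[subj["group"] == "case"]
    if ctrl.empty or case.empty:
        raise ValueError("both groups must be present")
    rows = []

    for var in ("age", "bmi"):
        cmpn = welch_t(ctrl[var], case[var], variable=var)
        rows.append(
            dict(variable=var, test="welch_t", statistic=cmpn.statistic,
                 df=cmpn.df, p=cmpn.p,
                 control=f"{ctrl[var].mean():.2f} ({ctrl[var].std(ddof=1):.2f})",
                 case=f"{case[var].mean():.2f} ({case[var].std(ddof=1):.2f})")
        )

    cat_ctrl = bmi_categorize(ctrl["bmi"])
    cat_case = bmi_categorize(case["bmi"])
    chi_w = pearson_chi2(
        [[cat_ctrl[c] for c in BMI_CATEGORIES], [cat_case[c] for c in BMI_CATEGORIES]],
        variable="bmi_category",
    )
    rows.append(dict(variable="bmi_category", test="chi2",
                     statistic=chi_w.statistic, df=chi_w.df, p=chi_w.p,
                     control="/".join(str(cat_ctrl[c]) for c in BMI_CATEGORIES),
                     case="/".join(str(cat_case[c]) for c in BMI_CATEGORIES)))

    sex_tab = [
        [int((ctrl["sex"] == "F").sum()), int((ctrl["sex"] == "M").sum())],
        [int((case["sex"] == "F").sum()), int((case["sex"] == "M").sum())],
    ]
    chi_s = pearson_chi2(sex_tab, variable="sex")
    rows.append(dict(variable="sex", test="chi2", statistic=chi_s.statistic,
                     df=chi_s.df, p=chi_s.p,
                     control=f"{sex_tab[0][0]} F / {sex_tab[0][1]} M",
                     case=f"{sex_tab[1][0]} F / {sex_tab[1][1]} M"))
    return pd.DataFrame(rows)
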