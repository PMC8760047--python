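"""Cohort CSV reading/validation and report assembly."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import COHORT_COLUMNS, HEMISPHERES, ROI_LABELS


class ValidationError(ValueError):
    """Input table violates the cohort schema; message lists offenders."""


_HEMI_ALIASES = {"l": "left", "lh": "left", "left": "left",
                 "r": "right", "rh": "right", "right": "right"}

_ROI_ALIASES = {
    "lateral ventricles": "lateral_ventricles",
    "lat. ventricles": "lateral_ventricles",
    "lat_ventricles": "lateral_ventricles",
    "nucleus accumbens": "accumbens",
    "caudate nucleus": "caudate",
}


def _norm_roi(label: str) -> str:
    key = str(label).strip().lower().replace("-", " ")
    key = _ROI_ALIASES.get(key, key).replace(" ", "_")
    return key


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Hemisphere and ROI labels are normalized to the canonical vocabulary.
    Unknown ROI labels, duplicated subject x hemisphere x ROI keys,
    non-positive volumes, and missing values in the mandatory covariates are
    reported with row numbers.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"missing columns: {missing_cols}")
    problems: list[str] = []

    df["hemisphere"] = df["hemisphere"].astype(str).str.strip().str.lower()
    bad_h = ~df["hemisphere"].isin(_HEMI_ALIASES)
    if bad_h.any():
        problems.append(f"unknown hemisphere labels at rows {df.index[bad_h].tolist()[:10]}")
    else:
        df["hemisphere"] = df["hemisphere"].map(_HEMI_ALIASES)

    df["roi"] = df["roi"].map(_norm_roi)
    bad_r = ~df["roi"].isin(ROI_LABELS)
    if bad_r.any():
        offenders = sorted(df.loc[bad_r, "roi"].unique())
        problems.append(
            f"unknown ROI labels {offenders} at rows {df.index[bad_r].tolist()[:10]}"
        )

    df["group"] = df["group"].astype(str).str.strip().str.lower()
    bad_g = ~df["group"].isin(("control", "case"))
    if bad_g.any():
        problems.append(f"group must be control/case; rows {df.index[bad_g].tolist()[:10]}")

    dup = df.duplicated(subset=["subject_id", "hemisphere", "roi"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["subject_id", "hemisphere", "roi"]].head(5)
        problems.append(
            "duplicate subject x hemisphere x ROI rows, e.g. "
            + "; ".join("/".join(map(str, r)) for r in keys.itertuples(index=False))
        )

    neg = df["volume"].notna() & (df["volume"] <= 0)
    if neg.any():
        problems.append(f"non-positive volumes at rows {df.index[neg].tolist()[:10]}")

    for col in ("group", "bmi", "age", "sex", "icv"):
        na = df[col].isna()
        if na.any():
            problems.append(f"missing {col} at rows {df.index[na].tolist()[:10]}")

    const = df.groupby("subject_id")[["group", "age", "sex", "bmi", "icv"]].nunique()
    varying = const[(const > 1).any(axis=1)]
    if not varying.empty:
        problems.append(
            f"covariates vary within subject(s): {varying.index.tolist()[:5]}"
        )

    if problems:
        raise ValidationError("cohort validation failed:\n- " + "\n- ".join(problems))
    return df


def _round2(x) -> float:
    return float(np.round(x, 2))


def coefficient_table(results: pd.DataFrame, *, legacy_sign: bool = False) -> pd.DataFrame:
    """Report-ready coefficient table (one row per ROI x family x term).

    ``legacy_sign`` flips group coefficients and their effect sizes to the
    control-as-positive coding used in some published tables; the underlying
    results are untouched.
    """
    out = results.copy()
    if legacy_sign:
        flip = out["term"] == "group"
        for col in ("b",):
            out.loc[flip, col] = -out.loc[flip, col]
        lo = -out.loc[flip, "effect_ci_high"].to_numpy()
        hi = -out.loc[flip, "effect_ci_low"].to_numpy()
        out.loc[flip, "effect"] = -out.loc[flip, "effect"]
        out.loc[flip, "effect_ci_low"] = lo
        out.loc[flip, "effect_ci_high"] = hi
    return out


def delta_effect_table(results: pd.DataFrame) -> pd.DataFrame:
    """Change in the group effect size after controlling for BMI, per ROI."""
    g0 = results[(results.model_family == "group_only") & (results.term == "group")]
    g1 = results[(results.model_family == "joint") & (results.term == "group")]
    merged = g0.merge(g1, on="roi", suffixes=("_unadjusted", "_bmi_adjusted"))
    merged["delta_d"] = merged["effect_bmi_adjusted"] - merged["effect_unadjusted"]
    cols = ["roi", "effect_unadjusted", "effect_bmi_adjusted", "delta_d",
            "significant_unadjusted", "significant_bmi_adjusted"]
    return merged[cols]


def write_report(
    out_dir,
    *,
    descriptives: pd.DataFrame | None = None,
    results: pd.DataFrame | None = None,
    interactions: pd.DataFrame | None = None,
    mediation=None,
    gate=None,
    manifest: dict | None = None,
    legacy_sign: bool = False,
) -> Path:
    """Assemble the Markdown + CSV/JSON report bundle.

    Partial reports are allowed: only the provided stages are rendered.
    Returns the path of the Markdown summary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["# Cohort analysis report", ""]

    if descriptives is not None:
        descriptives.to_csv(out / "descriptives.csv", index=False)
        lines += ["## Sample description", "", descriptives.to_markdown(index=False), ""]

    if results is not None:
        t2 = coefficient_table(results, legacy_sign=legacy_sign)
        t2.to_csv(out / "model_coefficients.csv", index=False)
        show = t2.copy()
        for col in ("b", "se_b", "effect", "effect_ci_low", "effect_ci_high"):
            show[col] = show[col].map(lambda v: _round2(v) if np.isfinite(v) else v)
        show["p_fdr"] = show["p_fdr"].map(
            lambda v: f"{v:.3f}{'*' if v < 0.05 else ''}" if np.isfinite(v) else "NA")
        lines += ["## Model families (per-ROI mixed models)",
                  f"(group coefficients shown in {'legacy' if legacy_sign else 'case=1'} coding)",
                  "", show[["roi", "model_family", "term", "b", "se_b", "df",
                            "p_fdr", "effect_kind", "effect",
                            "effect_ci_low", "effect_ci_high"]].to_markdown(index=False), ""]
        delta = delta_effect_table(results)
        delta.to_csv(out / "delta_effect_sizes.csv", index=False)
        lines += ["## Group effect size with vs without BMI adjustment", "",
                  delta.to_markdown(index=False), ""]

    if interactions is not None:
        interactions.to_csv(out / "interaction_screens.csv", index=False)
        lines += ["## Interaction screens", "", interactions.to_markdown(index=False), ""]

    if gate is not None and mediation is None:
        lines += ["## Mediation gate", "",
                  f"ROI {gate.roi}: gate {'passed' if gate.passed else 'FAILED'}"]
        if not gate.passed:
            lines += ["Failed criteria:"] + [f"- {c}" for c in gate.failed_criteria()]
        lines += [""]

    if mediation is not None:
        md = mediation.to_dict()
        with open(out / "mediation.json", "w", encoding="utf-8") as fh:
            json.dump(md, fh, indent=2, default=float)
        pd.DataFrame(
            [
                {"path": "a (group->BMI)", "estimate": mediation.a, "se": mediation.se_a},
                {"path": "b (BMI->volume)", "estimate": mediation.b_path, "se": mediation.se_b},
                {"path": "c (total)", "estimate": mediation.c, "se": np.nan},
                {"path": "c' (direct)", "estimate": mediation.c_prime, "se": np.nan},
                {"path": "a*b (indirect)", "estimate": mediation.indirect, "se": np.nan},
            ]
        ).to_csv(out / "mediation_paths.csv", index=False)
        lines += [
            "## Mediation of the group difference through BMI",
            "",
            f"ROI: {mediation.roi} ({mediation.mode} bootstrap, "
            f"{mediation.n_boot} replicates, {mediation.n_dropped} dropped)",
            f"- indirect effect a*b = {mediation.indirect:.2f} mm^3 "
            f"(95% CI {mediation.ci_low:.2f}; {mediation.ci_high:.2f})"
            f"{' *' if mediation.significant else ''}",
            f"- proportion mediated = {mediation.prop_mediated_pct:.2f}% "
            f"(95% CI {mediation.prop_ci_low:.2f}; {mediation.prop_ci_high:.2f})",
            f"- Sobel Z = {mediation.sobel_z:.2f}, p = {mediation.sobel_p:.3f}",
            "",
        ]

    manifest = dict(manifest or {})
    manifest.setdefault("software", {"bmivol": __version__})
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)

    md_path = out / "report.md"
    md_path.write_text("\n".join(lines), encoding="utf-8")
    return md_path
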