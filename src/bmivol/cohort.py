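"""Synthetic multi-site cohort generator.

Emulates the statistical structure of a case-control neuroimaging
mega-analysis of bipolar disorder (BD) and body mass index (BMI): two
diagnostic groups with a BMI shift, site-level random intercepts, subject-
level random intercepts with hemisphere-level residuals, and eight bilateral
subcortical region-of-interest (ROI) volumes driven by group, BMI, age, sex
and intracranial volume (ICV) fixed effects. A configurable group->BMI path
(``bmi_path_a``) together with each ROI's BMI slope builds a known mediated
(indirect) effect into the data, so mediation machinery can be validated
against ground truth.

The generator is the test substrate for the whole pipeline: identical
configuration and seed give a byte-identical table.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ROI_LABELS: tuple[str, ...] = (
    "lateral_ventricles",
    "accumbens",
    "amygdala",
    "hippocampus",
    "pallidum",
    "putamen",
    "caudate",
    "thalamus",
)

HEMISPHERES: tuple[str, str] = ("left", "right")

#: Columns of the long-format cohort table (one row per subject x hemisphere x ROI).
COHORT_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "site_id",
    "group",
    "age",
    "sex",
    "bmi",
    "icv",
    "hemisphere",
    "roi",
    "volume",
)


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class RoiEffect:
    """Fixed-effect coefficients and variance components for one ROI.

    Volumes are per-hemisphere, in mm^3. ``beta_group`` is the *direct*
    case-vs-control effect under case=1 coding (positive = larger in cases);
    the total group effect additionally includes the mediated share
    ``a * beta_bmi`` whenever the BMI model carries a group shift.
    Variance components are variances (sigma^2): site intercept, subject
    intercept, and the independent hemisphere-level residual.
    """

    intercept: float
    beta_group: float
    beta_bmi: float
    beta_age: float
    beta_sex: float
    beta_icv: float
    beta_hemisphere: float
    var_site: float
    var_subject: float
    var_residual: float

    def validate(self, roi: str) -> None:
        for name in ("var_site", "var_subject", "var_residual"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{roi}: {name} must be >= 0")


def _intercept_for(mean: float, e: dict) -> float:
    # Anchor the ROI mean at reference covariates: age 38, 58% female,
    # BMI 25.4, ICV 1.5e6 mm^3, control group, hemisphere-averaged.
    return (
        mean
        - 38.0 * e["beta_age"]
        - 0.58 * e["beta_sex"]
        - 25.4 * e["beta_bmi"]
        - 1.5e6 * e["beta_icv"]
        - 0.5 * e["beta_hemisphere"]
    )


# Field-realistic per-hemisphere means (mm^3) and the group/BMI coefficients
# of the joint diagnosis+BMI model under case=1 coding. Remaining slopes and
# variance components are realistic round values; see docs/methods.md.
_ROI_DEFAULTS: dict[str, dict] = {
    "lateral_ventricles": dict(
        mean=8000.0, beta_group=500.84, beta_bmi=51.54, beta_age=120.0,
        beta_sex=-100.0, beta_icv=4.3e-3, beta_hemisphere=-150.0,
        sd_site=500.0, sd_subject=3500.0, sd_resid=400.0,
    ),
    "accumbens": dict(
        mean=600.0, beta_group=-5.38, beta_bmi=0.33, beta_age=-2.0,
        beta_sex=-5.0, beta_icv=3.2e-4, beta_hemisphere=-10.0,
        sd_site=25.0, sd_subject=80.0, sd_resid=30.0,
    ),
    "amygdala": dict(
        mean=1600.0, beta_group=-29.70, beta_bmi=3.55, beta_age=-3.0,
        beta_sex=-20.0, beta_icv=8.5e-4, beta_hemisphere=15.0,
        sd_site=60.0, sd_subject=180.0, sd_resid=60.0,
    ),
    "hippocampus": dict(
        mean=3800.0, beta_group=-46.59, beta_bmi=0.95, beta_age=-8.0,
        beta_sex=-40.0, beta_icv=2.0e-3, beta_hemisphere=30.0,
        sd_site=120.0, sd_subject=380.0, sd_resid=120.0,
    ),
    "pallidum": dict(
        mean=1700.0, beta_group=-29.76, beta_bmi=-2.02, beta_age=-4.0,
        beta_sex=-15.0, beta_icv=9.1e-4, beta_hemisphere=-10.0,
        sd_site=60.0, sd_subject=170.0, sd_resid=60.0,
    ),
    "putamen": dict(
        mean=5000.0, beta_group=2.26, beta_bmi=3.43, beta_age=-15.0,
        beta_sex=-50.0, beta_icv=2.7e-3, beta_hemisphere=-40.0,
        sd_site=180.0, sd_subject=500.0, sd_resid=160.0,
    ),
    "caudate": dict(
        mean=3600.0, beta_group=-53.62, beta_bmi=-1.71, beta_age=-8.0,
        beta_sex=-30.0, beta_icv=1.9e-3, beta_hemisphere=20.0,
        sd_site=130.0, sd_subject=360.0, sd_resid=120.0,
    ),
    "thalamus": dict(
        mean=7500.0, beta_group=-94.66, beta_bmi=5.35, beta_age=-20.0,
        beta_sex=-70.0, beta_icv=4.0e-3, beta_hemisphere=-30.0,
        sd_site=260.0, sd_subject=700.0, sd_resid=230.0,
    ),
}


def default_roi_effects() -> dict[str, RoiEffect]:
    """Default effect table for the eight canonical ROIs."""
    out = {}
    for roi, e in _ROI_DEFAULTS.items():
        out[roi] = RoiEffect(
            intercept=_intercept_for(e["mean"], e),
            beta_group=e["beta_group"],
            beta_bmi=e["beta_bmi"],
            beta_age=e["beta_age"],
            beta_sex=e["beta_sex"],
            beta_icv=e["beta_icv"],
            beta_hemisphere=e["beta_hemisphere"],
            var_site=e["sd_site"] ** 2,
            var_subject=e["sd_subject"] ** 2,
            var_residual=e["sd_resid"] ** 2,
        )
    return out


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of a synthetic cohort.

    Defaults mirror the reference cohort: 17 sites, ~41% cases, group age
    distributions 35.47 (12.63) vs 41.72 (12.66) years, female fractions
    0.5721 / 0.6032, BMI 24.43 (4.12) vs 26.80 (5.22) kg/m^2.

    ``bmi_path_a``: if None, BMI is drawn from the per-group normal models
    (the implied additive group shift is the difference of group means);
    if a float, BMI is drawn from the control model (per-group SDs kept) and
    shifted by ``bmi_path_a`` for cases, so the group->BMI path is exactly
    known. Either way the built-in indirect effect on each ROI is
    ``path_a * beta_bmi``, recorded in the provenance output.
    """

    n_sites: int = 17
    subjects_per_site: int | Sequence[int] = 161
    case_fraction: float = 1134.0 / 2735.0
    age_model: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"control": (35.47, 12.63), "case": (41.72, 12.66)}
    )
    sex_model: Mapping[str, float] = field(
        default_factory=lambda: {"control": 0.5721, "case": 0.6032}
    )
    bmi_model: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"control": (24.43, 4.12), "case": (26.80, 5.22)}
    )
    bmi_path_a: float | None = None
    icv_model: tuple[float, float] = (1.5e6, 1.5e5)
    roi_effects: Mapping[str, RoiEffect] = field(default_factory=default_roi_effects)
    qc_missing_rate: float = 0.05
    age_bounds: tuple[float, float] = (18.0, 90.0)
    bmi_floor: float = 14.0
    include_medications: bool = False
    medication_probs: tuple[float, float, float, float] = (0.07, 0.35, 0.38, 0.20)
    lithium_rate: float = 0.455
    # Loadings of a shared latent driver onto medication count, BMI and
    # ventricular volume (cases only); all zero = independence.
    med_latent_loading: float = 0.0
    bmi_latent_loading: float = 0.0
    volume_latent_loading: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ConfigError("n_sites must be >= 1")
        for n in self.site_sizes():
            if n < 1:
                raise ConfigError("subjects_per_site entries must be >= 1")
        for name in ("case_fraction", "qc_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        for grp, (_, sd) in self.age_model.items():
            if sd < 0:
                raise ConfigError(f"age SD for {grp} must be >= 0")
        for grp, (_, sd) in self.bmi_model.items():
            if sd < 0:
                raise ConfigError(f"BMI SD for {grp} must be >= 0")
        if self.icv_model[1] < 0:
            raise ConfigError("ICV SD must be >= 0")
        unknown = set(self.roi_effects) - set(ROI_LABELS)
        if unknown:
            raise ConfigError(f"unknown ROI labels: {sorted(unknown)}")
        if not self.roi_effects:
            raise ConfigError("roi_effects must contain at least one ROI")
        for roi, eff in self.roi_effects.items():
            eff.validate(roi)
        if abs(sum(self.medication_probs) - 1.0) > 1e-9:
            raise ConfigError("medication_probs must sum to 1")

    def site_sizes(self) -> list[int]:
        if isinstance(self.subjects_per_site, int):
            return [self.subjects_per_site] * self.n_sites
        sizes = list(self.subjects_per_site)
        if len(sizes) != self.n_sites:
            raise ConfigError("subjects_per_site list must have n_sites entries")
        return sizes

    @property
    def path_a(self) -> float:
        """The additive group shift in BMI actually applied."""
        if self.bmi_path_a is not None:
            return float(self.bmi_path_a)
        return float(self.bmi_model["case"][0] - self.bmi_model["control"][0])

    def true_indirect(self) -> dict[str, float]:
        """Built-in indirect (group -> BMI -> volume) effect per ROI."""
        return {roi: self.path_a * eff.beta_bmi for roi, eff in self.roi_effects.items()}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["roi_effects"] = {k: dataclasses.asdict(v) for k, v in self.roi_effects.items()}
        d["age_model"] = {k: list(v) for k, v in self.age_model.items()}
        d["bmi_model"] = {k: list(v) for k, v in self.bmi_model.items()}
        d["sex_model"] = dict(self.sex_model)
        return d


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate a long-format cohort table from ``config``.

    Returns one row per subject x hemisphere x ROI with the
    :data:`COHORT_COLUMNS` schema. QC-style missingness withholds both
    hemispheres of a subject x ROI jointly (the rows are absent, mirroring
    quality-failed segmentations being withheld from analysis). Deterministic
    under (config, seed); ``seed`` defaults to ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sizes = config.site_sizes()
    n = int(sum(sizes))

    site = np.repeat(np.arange(1, config.n_sites + 1), sizes)
    # Deterministic per-site case counts (shuffled within site) so the
    # realized case fraction tracks the configured one closely.
    case = np.zeros(n, dtype=bool)
    start = 0
    for sz in sizes:
        k = int(round(config.case_fraction * sz))
        idx = start + rng.permutation(sz)[:k]
        case[idx] = True
        start += sz

    def group_draw(model, transform):
        out = np.empty(n)
        for is_case, label in ((False, "control"), (True, "case")):
            mask = case == is_case
            out[mask] = transform(model[label], mask.sum())
        return out

    age = group_draw(config.age_model, lambda m, k: rng.normal(m[0], m[1], k))
    age = np.clip(age, *config.age_bounds)
    sex_female = group_draw(config.sex_model, lambda p, k: rng.random(k) < p).astype(bool)

    if config.bmi_path_a is None:
        bmi = group_draw(config.bmi_model, lambda m, k: rng.normal(m[0], m[1], k))
    else:
        mu0 = config.bmi_model["control"][0]
        sd = np.where(case, config.bmi_model["case"][1], config.bmi_model["control"][1])
        bmi = mu0 + rng.standard_normal(n) * sd + config.bmi_path_a * case
    bmi = np.maximum(bmi, config.bmi_floor)

    icv = rng.normal(config.icv_model[0], config.icv_model[1], n)
    icv = np.maximum(icv, 1.0)

    latent = rng.standard_normal(n)
    if config.bmi_latent_loading:
        bmi = np.maximum(bmi + config.bmi_latent_loading * latent * case, config.bmi_floor)

    med_count = lith = None
    if config.include_medications:
        med = np.zeros(n, dtype=int)
        probs = np.asarray(config.medication_probs)
        cum = np.cumsum(probs)
        base = np.searchsorted(cum, rng.random(n), side="right")
        if config.med_latent_loading:
            base = np.clip(np.round(base + config.med_latent_loading * latent), 0, 3).astype(int)
        med[case] = base[case]
        med_count = np.where(case, med, 0)
        lith = np.where(case, rng.random(n) < config.lithium_rate, False).astype(bool)

    rois = list(config.roi_effects)
    frames = []
    subj_ids = np.array([f"sub{site[i]:02d}_{i + 1:05d}" for i in range(n)])
    site_ids = np.array([f"site{s:02d}" for s in site])
    for roi in rois:
        eff = config.roi_effects[roi]
        u_site_by_site = rng.normal(0.0, np.sqrt(eff.var_site), config.n_sites)
        u_site = u_site_by_site[site - 1]
        u_subj = rng.normal(0.0, np.sqrt(eff.var_subject), n)
        fixed = (
            eff.intercept
            + eff.beta_group * case
            + eff.beta_bmi * bmi
            + eff.beta_age * age
            + eff.beta_sex * sex_female
            + eff.beta_icv * icv
        )
        if roi == "lateral_ventricles" and config.volume_latent_loading:
            fixed = fixed + config.volume_latent_loading * latent * case
        keep = rng.random(n) >= config.qc_missing_rate
        for h, hemi in enumerate(HEMISPHERES):
            eps = rng.normal(0.0, np.sqrt(eff.var_residual), n)
            vol = fixed + eff.beta_hemisphere * h + u_site + u_subj + eps
            # volumes are physically positive; the floor binds only deep in
            # the ventricular tail
            vol = np.maximum(vol, 1.0)
            df = pd.DataFrame(
                {
                    "subject_id": subj_ids,
                    "site_id": site_ids,
                    "group": np.where(case, "case", "control"),
                    "age": age,
                    "sex": np.where(sex_female, "F", "M"),
                    "bmi": bmi,
                    "icv": icv,
                    "hemisphere": hemi,
                    "roi": roi,
                    "volume": vol,
                }
            )
            if med_count is not None:
                df["medication_count"] = med_count
                df["lithium"] = lith.astype(int)
            frames.append(df[keep])

    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values(["subject_id", "roi", "hemisphere"], kind="stable")
    return table.reset_index(drop=True)


def provenance(config: GeneratorConfig, table: pd.DataFrame | None = None) -> dict:
    """Reproducibility record: config, seed, built-in effects, realized sizes."""
    rec = {
        "config": config.to_dict(),
        "seed": config.seed,
        "path_a": config.path_a,
        "true_indirect": config.true_indirect(),
    }
    if table is not None:
        subj = table.drop_duplicates("subject_id")
        rec["realized"] = {
            "n_subjects": int(subj.shape[0]),
            "n_control": int((subj["group"] == "control").sum()),
            "n_case": int((subj["group"] == "case").sum()),
            "n_rows": int(table.shape[0]),
            "bmi_mean_control": float(subj.loc[subj.group == "control", "bmi"].mean()),
            "bmi_mean_case": float(subj.loc[subj.group == "case", "bmi"].mean()),
        }
    return rec


def write_cohort(table: pd.DataFrame, path, config: GeneratorConfig | None = None) -> None:
    """Write the cohort CSV (UTF-8, '.' decimal) plus a provenance JSON sidecar."""
    table.to_csv(path, index=False)
    if config is not None:
        side = str(path) + ".provenance.json"
        with open(side, "w", encoding="utf-8") as fh:
            json.dump(provenance(config, table), fh, indent=2, default=float)
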