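"""Simulation studies validating the pipeline against known ground truth.

Three studies, each run at a scale tractable on one CPU (sizes stated in
docs/methods.md):

* **mediation recovery** -- cohorts generated with a known indirect effect
  (group -> BMI path a = 2.4 kg/m^2, BMI -> ventricle slope +47 mm^3 per
  unit, direct group effect +501 mm^3, so the true indirect effect is
  ~112.8 mm^3, the total ~614 mm^3 and the proportion mediated ~18.4%);
  measures bias of the recovered indirect effect and the coverage of the
  95% bootstrap CI.
* **bootstrap size control** -- the same conditions with the group -> BMI
  path switched off (a = 0); measures how often the bootstrap CI falsely
  excludes zero.
* **FDR null** -- eight-ROI cohorts with every group and BMI effect set to
  zero; measures the fraction of ROI tests flagged significant after
  Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .cohort import GeneratorConfig, RoiEffect, default_roi_effects, generate_cohort
from .lmm import RandomStructure
from .mediation import bootstrap_mediation
from .pipeline import run_model_families

#: Calibrated single-ROI generator for the mediation studies. Variance
#: components are kept modest so the Monte-Carlo error of a 200-simulation
#: study sits well inside the quantities being estimated; the mediation
#: structure (paths, covariate effects) is what is under test.
MEDIATION_ROI = "lateral_ventricles"
MEDIATION_PATH_A = 2.4
MEDIATION_B_PATH = 47.0
MEDIATION_DIRECT = 501.2


def mediation_config(
    *,
    n_sites: int = 10,
    subjects_per_site: int = 60,
    path_a: float = MEDIATION_PATH_A,
    seed: int = 0,
) -> GeneratorConfig:
    base = default_roi_effects()[MEDIATION_ROI]
    eff = dataclasses.replace(
        base,
        beta_group=MEDIATION_DIRECT,
        beta_bmi=MEDIATION_B_PATH,
        var_site=300.0**2,
        var_subject=1500.0**2,
        var_residual=400.0**2,
    )
    return GeneratorConfig(
        n_sites=n_sites,
        subjects_per_site=subjects_per_site,
        bmi_path_a=path_a,
        roi_effects={MEDIATION_ROI: eff},
        qc_missing_rate=0.0,
        seed=seed,
    )


def mediation_recovery_study(
    *,
    n_sims: int = 200,
    n_sites: int = 10,
    subjects_per_site: int = 60,
    n_boot: int = 500,
    seed: int = 0,
) -> dict:
    """Recover a known indirect effect across simulated cohorts.

    Returns the truth, the mean recovered indirect effect and its bias (in
    % of truth), the 95% bootstrap CI coverage (%), and the mean recovered
    proportion mediated (%).
    """
    cfg0 = mediation_config(n_sites=n_sites, subjects_per_site=subjects_per_site)
    truth = cfg0.true_indirect()[MEDIATION_ROI]
    ss = np.random.SeedSequence([seed, 101])
    seeds = ss.generate_state(2 * n_sims).astype(np.int64) % (2**31)
    est, covered, props = [], [], []
    for i in range(n_sims):
        cfg = dataclasses.replace(cfg0, seed=int(seeds[2 * i]))
        table = generate_cohort(cfg)
        res = bootstrap_mediation(
            table, MEDIATION_ROI, n_boot=n_boot, seed=int(seeds[2 * i + 1]),
            mode="collapsed", force=True, min_subjects=50,
        )
        est.append(res.indirect)
        covered.append(res.ci_low <= truth <= res.ci_high)
        props.append(res.prop_mediated_pct)
    est = np.asarray(est)
    return {
        "true_indirect": truth,
        "true_prop_mediated_pct": 100.0 * truth / (truth + MEDIATION_DIRECT),
        "mean_indirect": float(est.mean()),
        "bias_pct": float(100.0 * (est.mean() - truth) / truth),
        "coverage_pct": float(100.0 * np.mean(covered)),
        "mean_prop_mediated_pct": float(np.mean(props)),
        "n_sims": n_sims,
        "n_boot": n_boot,
        "n_subjects": n_sites * subjects_per_site,
    }


def bootstrap_null_study(
    *,
    n_sims: int = 500,
    n_sites: int = 10,
    subjects_per_site: int = 60,
    n_boot: int = 500,
    seed: int = 0,
) -> dict:
    """False-positive rate of the bootstrap CI when the indirect path is off."""
    cfg0 = mediation_config(n_sites=n_sites, subjects_per_site=subjects_per_site,
                            path_a=0.0)
    ss = np.random.SeedSequence([seed, 202])
    seeds = ss.generate_state(2 * n_sims).astype(np.int64) % (2**31)
    excl = []
    for i in range(n_sims):
        cfg = dataclasses.replace(cfg0, seed=int(seeds[2 * i]))
        table = generate_cohort(cfg)
        res = bootstrap_mediation(
            table, MEDIATION_ROI, n_boot=n_boot, seed=int(seeds[2 * i + 1]),
            mode="collapsed", force=True, min_subjects=50,
        )
        excl.append(res.significant)
    return {
        "exclusion_rate": float(np.mean(excl)),
        "n_sims": n_sims,
        "n_boot": n_boot,
    }


def null_roi_effects() -> dict[str, RoiEffect]:
    """Default ROI effects with every group and BMI coefficient zeroed."""
    return {
        roi: dataclasses.replace(eff, beta_group=0.0, beta_bmi=0.0)
        for roi, eff in default_roi_effects().items()
    }


def fdr_null_study(
    *,
    n_sims: int = 60,
    n_sites: int = 8,
    subjects_per_site: int = 40,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Fraction of FDR-flagged ROI tests under a global null.

    Cohorts carry no group or BMI effects anywhere; every flag is a false
    discovery. Model fits use the subject-collapsed structure so the study
    stays tractable; the FDR step under test is identical to the
    hemisphere-level path.
    """
    ss = np.random.SeedSequence([seed, 303])
    seeds = ss.generate_state(n_sims).astype(np.int64) % (2**31)
    collapsed = RandomStructure(site_intercept=True, subject_intercept=False,
                                hemisphere_within_subject=False)
    flagged = total = 0
    for i in range(n_sims):
        cfg = GeneratorConfig(
            n_sites=n_sites, subjects_per_site=subjects_per_site,
            roi_effects=null_roi_effects(), qc_missing_rate=0.0,
            seed=int(seeds[i]),
        )
        table = generate_cohort(cfg)
        res = run_model_families(table, alpha=alpha, random=collapsed)
        flagged += int(res["significant"].sum())
        total += len(res)
    return {
        "flag_rate": flagged / total,
        "n_tests": total,
        "n_sims": n_sims,
    }
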