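#!/usr/bin/env python
"""Gated bootstrap mediation of the group difference through BMI.

Checks the four mediation criteria per ROI against the model-family
results, then bootstraps the ventricular indirect effect (5000 participant
resamples, stratified by site). Writes results/mediation/.
"""

from pathlib import Path

from bmivol.io import read_cohort, write_report
from bmivol.mediation import bootstrap_mediation, check_mediation_criteria
from bmivol.pipeline import run_model_families

OUT = Path(__file__).resolve().parents[1] / "results"
DATA = Path(__file__).resolve().parents[1] / "scratch"
ROI = "lateral_ventricles"


def main(seed: int = 7) -> None:
    cohort = read_cohort(DATA / "cohort.csv")
    results = run_model_families(cohort)
    for roi in results.roi.unique():
        gate = check_mediation_criteria(results, cohort, roi)
        status = "passes" if gate.passed else "fails: " + "; ".join(
            gate.failed_criteria())
        print(f"gate {roi}: {status}")
    gate = check_mediation_criteria(results, cohort, ROI)
    if not gate.passed:
        print("ventricular gate failed; stopping")
        return
    med = bootstrap_mediation(cohort, ROI, n_boot=5000, seed=seed,
                              mode="collapsed", gate=gate)
    write_report(OUT / "mediation", mediation=med, gate=gate,
                 manifest={"step": "04_mediation", "seed": seed})
    print(f"\nindirect effect a*b = {med.indirect:.2f} mm^3 "
          f"(95% CI {med.ci_low:.2f}; {med.ci_high:.2f})")
    print(f"proportion mediated = {med.prop_mediated_pct:.2f}% "
          f"(95% CI {med.prop_ci_low:.2f}; {med.prop_ci_high:.2f})")
    print(f"Sobel Z = {med.sobel_z:.2f}, p = {med.sobel_p:.4f}")


if __name__ == "__main__":
    main()
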