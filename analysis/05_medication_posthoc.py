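#!/usr/bin/env python
"""Medication post-hoc models on the case subset.

Number of medication classes vs BMI and vs ventricular volume, the joint
medication + BMI model with VIFs and marginal R^2, and the lithium model.
Writes results/medication_posthoc.json.
"""

import json
from pathlib import Path

from bmivol.io import read_cohort
from bmivol.pipeline import posthoc_medication_models

OUT = Path(__file__).resolve().parents[1] / "results"
DATA = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    cohort = read_cohort(DATA / "cohort.csv")
    rep = posthoc_medication_models(cohort)
    with open(OUT / "medication_posthoc.json", "w", encoding="utf-8") as fh:
        json.dump(rep, fh, indent=2, default=float)
    if "skipped" in rep:
        print(f"skipped: {rep['skipped']}")
        return
    bm = rep["bmi_on_medications"]
    print(f"BMI ~ medication classes: b = {bm['b']:.3f} "
          f"(t = {bm['t']:.2f}, p = {bm['p']:.3f})")
    joint = rep["volume_joint"]
    print(f"ventricles ~ medications + BMI: R^2 = {joint['marginal_r2']:.4f} "
          f"(medications only {rep['volume_on_medications']['marginal_r2']:.4f}, "
          f"BMI only {rep['volume_on_bmi']['marginal_r2']:.4f})")
    print(f"VIFs: BMI {joint['vif']['bmi']:.2f}, "
          f"medications {joint['vif']['medication_count']:.2f}")
    li = rep["volume_on_lithium"]
    print(f"lithium: b = {li['b']:.2f} (p = {li['p']:.3f})")


if __name__ == "__main__":
    main()
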