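#!/usr/bin/env python
"""Simulate the three condition registries (AMI, stroke, hip fracture).

Writes admissions/vitals/truth/hospitals CSVs per condition under
``results/registry/<condition>/`` and prints the realized margins against
their configured targets (30-day mortality, transfer rate, female share).
"""

from pathlib import Path

from hospmort.synthetic_registry import (
    default_config,
    generate_cohort,
    generate_hospitals,
    write_cohort,
)

SEED = 20260919
OUT = Path(__file__).resolve().parents[1] / "results" / "registry"

for i, cond in enumerate(("AMI", "stroke", "hip_fracture")):
    cfg = default_config(cond, seed=SEED + i)
    hospitals = generate_hospitals(cfg)
    admissions, vitals, truth = generate_cohort(cfg, hospitals)
    write_cohort(OUT / cond, admissions, vitals, truth, hospitals)
    first = admissions.drop_duplicates("patient_id")
    print(
        f"{cond}: {len(hospitals)} hospitals, {len(truth)} patients, "
        f"{len(admissions)} stays | 30d mortality "
        f"{100 * truth['death_30d'].mean():.1f}% (target "
        f"{100 * cfg.baseline_30d_mortality:.1f}%), transfers "
        f"{100 * (truth['n_stays'] >= 2).mean():.1f}% (target "
        f"{100 * cfg.transfer_probability:.1f}%), female "
        f"{100 * (first['sex'] == 'F').mean():.1f}% (target "
        f"{100 * cfg.female_fraction:.1f}%)"
    )
print(f"registries written under {OUT}")
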