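"""Simulate an HRS-like cohort and check its stated statistical structure.

Draws the default synthetic cohort (6,969 participants, the EA sample
size), which has a standard-normal polygenic score, five binary adverse
early-psychosocial exposures at prevalences back-calculated from the
published cell totals, a logistic ever-smoking outcome, and per-exposure
missing-completely-at-random survey fields.
"""

import smokegxe as sg

params = sg.SimulationParams(seed=1)
cohort = sg.simulate_cohort(params)

print(f"cohort: {len(cohort)} records, group {params.group}")
print(f"ever-smoking prevalence: {cohort.df['ever_smoked'].mean():.3f} (target ~0.55)")
print(f"female fraction:         {(cohort.df['gender'] == 'female').mean():.3f} "
      f"(target {params.prop_female})")
print(f"high-genetic-risk flag:  {cohort.truth['G'].mean():.3f} (top quartile of PGS)")
print("adverse-exposure prevalence (generating truth):")
for epf in sg.EPFS:
    obs = cohort.truth[sg.exposure_column(epf)].mean()
    print(f"  {epf:18s} {obs:.3f} (target {params.prev_E[epf]:.3f})")
print("missing fraction of raw fields (MCAR):")
for epf, cols in sg.EPF_RAW_FIELDS.items():
    frac = cohort.df[cols[0]].isna().mean()
    print(f"  {epf:18s} {frac:.3f} (target {params.missing_rates.get(epf, 0.0):.3f})")
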