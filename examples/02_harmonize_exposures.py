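"""Derive the analysis variables and show per-exposure complete-case sizes.

Harmonization turns raw survey fields into binary analysis variables:
ever smoking (any-wave endorsement of the 100-cigarette item), the
high-genetic-risk flag (polygenic score above the within-group 75th
percentile), and five adverse exposures.  Because missingness differs by
exposure, listwise deletion gives each interaction model its own N —
exactly why the published blocks report different sample sizes.
"""

import smokegxe as sg

cohort = sg.simulate_cohort(sg.SimulationParams(seed=1))
derived = sg.harmonize_cohort(cohort)

print(f"harmonized {len(derived)} records; columns: {', '.join(derived.columns)}")
print(f"ever smoking (Y):  mean {derived['Y'].mean():.3f}")
print(f"high genetic risk: mean {derived['G'].mean():.3f}")
print("per-exposure complete-case N (Y, G, exposure + age/gender/PC covariates):")
for epf in sg.EPFS:
    cc = sg.complete_cases(
        derived, ["Y", "G", sg.exposure_column(epf), *sg.DEFAULT_COVARIATES]
    )
    print(f"  {epf:18s} N = {len(cc)}")
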