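"""10-year ASCVD risk (2013 pooled cohort equations) and statin eligibility.

Evaluates the guideline's reference profile across sex/race strata and
then screens a simulated cohort through the pooled inclusion rules.
"""

import cogload as cl

print("reference profile: 55y, TC 213, HDL 50, SBP 120 untreated, nonsmoker")
for sex in ("female", "male"):
    for race in ("White", "Black"):
        rec = cl.PatientRecord(
            age=55, sex=sex, race_ethnicity=race,
            systolic_bp=120, total_cholesterol=213, hdl=50, ldl=130,
            smoking_flag=False,
        )
        print(f"  {race:6s} {sex:6s}: {100 * cl.ascvd_risk_2013(rec):.1f}%")

patients = cl.simulate_patients(cl.SimulationConfig(n_patients=500, seed=7))
table = cl.eligibility_frame(patients)
print(f"\nscreened {len(table)} simulated patients:")
print(table["indication"].value_counts().to_string())
print(f"eligible: {table['eligible'].sum()} "
      f"({100 * table['eligible'].mean():.1f}%)")
print("\nexclusion reasons among ineligible:")
print(table["exclusion_reason"].value_counts(dropna=True).to_string())
print()
print("Risk >= 7.5% at age 40-75 is the dominant indication; exclusions")
print("(pregnancy, statin allergy, hepatic/renal disease) and stale risk")
print("inputs (outside the 3-year lookback) remove patients before any")
print("inclusion rule is considered.")
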