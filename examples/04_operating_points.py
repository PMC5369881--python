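"""Three-level operating-point analysis (high sensitivity / balanced /
high specificity).

With 54 cases in the lower stratum, the least achievable sensitivity at
or above the 90% target is 49/54 = 90.7% - exactly the integer arithmetic
behind the reference study's printed operating sensitivities.  The table
reports, per marker and level, the midpoint cut-off and the achieved
sensitivity/specificity in percent.
"""

import pcpscore as pcp

cohort = pcp.generate_cohort(pcp.calibrated_config(seed=42))
df = pcp.marker_frame(cohort)

for lo, hi in cohort.strata:
    sub = df[(df.tpsa >= lo) & (df.tpsa < hi)]
    labels = (sub.diagnosis == "PCa").to_numpy().astype(int)
    markers = {
        m: (sub[m].to_numpy(), low) for m, low in pcp.MARKER_ORIENTATIONS.items()
    }
    table = pcp.three_level_table(markers, labels, sens_target=0.90, spec_target=0.90)
    print(f"\nstratum [{lo:g},{hi:g}): {labels.sum()} cases / "
          f"{len(labels) - labels.sum()} controls")
    print(table.to_string(index=False))

print("\nAt the high-sensitivity level every marker is pinned to the same")
print("achieved sensitivity (49/54 = 90.7% resp. 44/48 = 91.7%); the markers")
print("differ in how much specificity they retain there - the combined PCP")
print("score typically retains the most.")
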