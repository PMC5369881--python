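"""Generate a calibrated synthetic PSA cohort and inspect its structure.

Calibrates the generator so each diagnosis group's medians of tPSA, fPSA,
cPSA and %fPSA match the reference clinical cohort, then draws the
reference-sized cohort (54/579 PCa/BPH subjects with tPSA in [2,10) ng/mL
and 48/147 in [10,20)) and prints the group medians.  The PCP median is
never calibrated - it emerges from the marker structure.
"""

import pcpscore as pcp

config = pcp.calibrated_config(seed=42)
cohort = pcp.generate_cohort(config)
df = pcp.marker_frame(cohort)

print(f"cohort size: {len(cohort)}  "
      f"(PCa {int(cohort.labels().sum())}, BPH {int((1 - cohort.labels()).sum())})")
print(f"lower stratum [2,10): {len(pcp.stratify(cohort, (2, 10)))} subjects")
print(f"upper stratum [10,20): {len(pcp.stratify(cohort, (10, 20)))} subjects")
print("\ngroup medians (tPSA/fPSA/cPSA in ng/mL; %fPSA and PCP dimensionless):")
print(df.groupby("diagnosis")[["tpsa", "fpsa", "cpsa", "pct_fpsa", "pcp"]]
        .median().round(2))
print("\nPCa medians should sit near 9.2 / 1.0 / 8.0 / 0.13 with PCP near 22,")
print("BPH near 5.5 / 1.0 / 4.4 / 0.19 with PCP near 11.")
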