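"""Compare the diagnostic accuracy of PCP with the individual PSA markers.

Evaluates every marker univariately in the lower tPSA stratum [2,10) of a
calibrated synthetic cohort: logistic odds ratio with Wald CI, AUC with a
stratified-bootstrap percentile CI, and the Hosmer-Lemeshow calibration
test on the fitted probabilities.  %fPSA is oriented lower-is-positive
(low free fraction indicates cancer).
"""

import pcpscore as pcp

cohort = pcp.generate_cohort(pcp.calibrated_config(seed=42))
df = pcp.marker_frame(cohort)
sub = df[df.tpsa < 10]
labels = (sub.diagnosis == "PCa").to_numpy().astype(int)

print(f"stratum [2,10): n={len(sub)} ({labels.sum()} PCa)\n")
print(f"{'marker':>9} {'OR':>7} {'p':>7} {'AUC':>6} {'95% CI':>15} {'HL p':>6}")
for marker, lower in pcp.MARKER_ORIENTATIONS.items():
    x = sub[marker].to_numpy()
    fit = pcp.univariate_logistic(x, labels)
    est = pcp.bootstrap_auc(x, labels, lower_is_positive=lower, B=1000, seed=3)
    hl = pcp.hosmer_lemeshow(fit.fitted, labels)
    print(f"{marker:>9} {fit.odds_ratio:7.3f} {fit.p_display():>7} "
          f"{est.point:6.3f} [{est.ci_low:.3f}, {est.ci_high:.3f}] "
          f"{hl.p_value:6.3f}")

print("\nThe combined PCP score should show the highest AUC, with %fPSA")
print("close behind and tPSA/fPSA weakest, mirroring the reference study's")
print("ordering in this stratum (PCP 0.680 > %fPSA 0.675 > ... > fPSA 0.571).")
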