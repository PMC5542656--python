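"""Plant a dominance effect on severe disease and watch the pipeline find it.

Mimics the heterozygote-risk pattern behind the TiHo12/TiHo18 findings:
a pure dominance effect (log-OR 1.5 for heterozygotes) on class-5
membership, no additive effect.  Stepwise selection against the severe
outcome should retain the marker's dominance term, and the heterozygote
relative risk should be well above 1.
"""

from caninegbv import default_config, run_validation, simulate_cohort

config = default_config(
    seed=9, n_animals=2000, effects={"TiHo12": (0.0, 1.5)}, effect_target="severe"
)
cohort = simulate_cohort(config)
report = run_validation(cohort)

sw = report.sections["stepwise_severe"]
print(f"severe-CHD stepwise final terms: {sw['trace']['final_terms']}")
print(f"severe-CHD model AUC: {sw['auc']:.3f}")
for marker, entry in report.sections["dominance_risks"].items():
    rr = entry["relative_risk"]
    print(
        f"{marker}: heterozygote RR {rr['point']:.2f} "
        f"(95% CI {rr['ci_low']:.2f}-{rr['ci_high']:.2f}); "
        f"events {entry['heterozygous']['events']}/{entry['heterozygous']['n']} het "
        f"vs {entry['homozygous']['events']}/{entry['homozygous']['n']} hom"
    )
print(
    "\nThe planted dominance term is recovered and the heterozygote excess "
    "risk is estimated directly from the 2x2 genotype-by-outcome counts."
)
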