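"""Sensitivity of the step estimate to the period definitions.

Refits one condition's simulated series under the seven period-definition
scenarios: the main design (pre-lockdown to March 7, three excluded weeks,
with-restrictions from March 29), two longer exclusions, and four variants
with the pre-lockdown period ending March 21.
"""

from carecontacts import RunConfig, run_sensitivity

config = RunConfig(seed=5, conditions=["stroke"])
results = run_sensitivity(config)

print(f"condition: stroke (generating step OR "
      f"{__import__('carecontacts').get_condition('stroke').step_or})")
print(f"{'scenario':>12s} {'step OR':>8s} {'95% CI':>16s} {'weeks':>6s}")
for _, r in results.iterrows():
    print(
        f"{r['scenario']:>12s} {r['step_or']:8.3f} "
        f"{r['step_lo']:7.3f}-{r['step_hi']:.3f} {r['n_weeks']:6d}"
    )
print(
    "\nScenarios with longer exclusion windows estimate the step further"
    "\ninto the with-restrictions period, so under a recovering series the"
    "\nstep OR drifts toward 1; agreement across scenarios indicates the"
    "\nfinding is not an artefact of the chosen adjustment window."
)
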