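"""Small Monte-Carlo comparison of the recurrent-event models.

Runs 200 replicates of scenario 1a (constant hazards, both hazard
ratios 0.5) and prints the mean estimated hazard ratio, its empirical
SD and the empirical power of the robust Wald test for each model.
A desk-scale version of the full comparison table; use
``recurtrial table2`` for all 27 scenarios.
"""

from recurtrial import StudyConfig, run_scenario

summary = run_scenario(
    "1a", StudyConfig(seed=42), n_reps=200,
    models=("cox_first_event", "ag", "pwp_tt", "pwp_gt", "wlw"),
)

print(f"scenario {summary.scenario_id}: {summary.n_reps} replicates")
print(f"  mean max events/subject (strata): {summary.mean_max_events:.2f}"
      f" ({summary.sd_max_events:.2f})")
print(f"{'model':<16}{'mean HR':>9}{'emp SD':>8}{'power':>8}")
for name, ms in summary.models.items():
    print(f"{name:<16}{ms.mean_hr:>9.3f}{ms.emp_sd_hr:>8.3f}{ms.power_robust:>8.3f}")

# All models recover a hazard ratio near the generating 0.5; the
# first-event Cox analysis loses power relative to AG/PWP because it
# discards repeat events, and WLW sits below 0.5 (carry-over).
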