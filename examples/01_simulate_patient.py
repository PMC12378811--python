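"""Simulate one perioperative trajectory and inspect the planted structure.

A synthetic patient walks ~4,000 steps/day at baseline, declines in the
two months before surgery, bottoms out 10 days after, and recovers to
twice the baseline by day 120.  The printed values are the noise-free
planted curve at key days; the simulator adds daily noise, a weekday
rhythm, and missing days on top.
"""
from periostep import SimScenario, simulate_patient

scenario = SimScenario(
    baseline_mean=4000.0,
    preop_decline_start=-60,
    nadir_offset=10,
    recovery_end_offset=120,
    recovery_plateau=2.0,
    seed=42,
)
series, truth = simulate_patient(scenario)

print(f"observed days: {series.n_observed} of {len(series.data)}")
for day in (-200, -30, 0, 10, 120, 300):
    print(f"planted mean at day {day:+4d}: {scenario.mean_curve(day):7.0f} steps")
print(f"planted decline label: {truth.declined}")
# ~4,000 at baseline, ~3,400 mid-decline, 1,600 at the nadir, 8,000 on the
# plateau: the five-phase shape every later analysis step is scored against.
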