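"""Monte Carlo dosing simulation for typical infants (five scenarios).

For each scenario, 5000 virtual patients are drawn from the between-subject
distribution and their steady-state profiles summarised: median trough/peak
and the fraction attaining the conventional 5-10 mg/L trough and 20-50 mg/L
peak windows.
"""

from vancopk import FINAL_MODEL_PARAMS, builtin_scenarios, scenario, simulate_scenario, target_attainment
from vancopk.dosing import compare_regimens

print(f"{'scenario':<28}{'median trough':>14}{'median peak':>13}{'P(trough 5-10)':>16}{'P(peak 20-50)':>15}")
for sc in builtin_scenarios() + [scenario("a-alt")]:
    s = simulate_scenario(sc, FINAL_MODEL_PARAMS)
    att = target_attainment(s)
    label = f"{sc.label}: {sc.weight} kg, {sc.amount:g} mg q{sc.interval:g}h"
    print(f"{label:<28}{s.median_trough:>14.2f}{s.median_peak:>13.1f}{att['trough']:>16.2f}{att['peak']:>15.2f}")

print("\nregimen comparison for the 0.95-kg premature neonate (equal daily dose):")
rows = compare_regimens(scenario("a"), FINAL_MODEL_PARAMS,
                        [(19.0, 24.0), (9.5, 12.0), (4.75, 6.0)], trough_window=(5.0, 10.0))
for r in rows:
    print(f"  rank {r['rank']}: {r['amount']:5.2f} mg q{r['interval']:g}h  "
          f"trough {r['median_trough']:.2f} mg/L  attainment {r['trough_attainment']:.2f}")
# The 24-h regimen leaves the median trough near 3.3 mg/L — under the 5 mg/L
# floor — while splitting the same daily dose over shorter intervals raises
# the trough: dosing intervals, not just dose size, drive attainment here.
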