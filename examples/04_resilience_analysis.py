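"""Resistance vs recovery: tertile classes, shock years, mechanism verdict.

Scores a preset world, splits pixels into most/medium/least degraded
tertiles from the final three years, detects the four sharpest
landscape-median increases as shock years, and compares the classes' shock
responses and recoveries to name the degradation mechanism.
"""

from rangeres import experiments

for scenario in ("loss_of_resistance", "loss_of_recovery"):
    trial = experiments.discrimination_trial(scenario, seed=0)
    print(f"planted mechanism: {scenario}")
    print(f"  detected shock years: {trial['shock_years']} (planted {trial['planted_shock_years']})")
    for d in trial["detail"]["detail"]:
        sig = "significant" if d["significant"] else "n.s."
        print(f"  {d['year']} {d['metric']:>17}: most-least = {d['most_minus_least']:+.4f} ({sig})")
    print(f"  verdict: {trial['verdict']}")
    print()
# A positive most-least shock contrast means the eventually most-degraded
# pixels decline harder in drought years (lost resistance); a negative
# recovery contrast means they rebound less the year after (lost recovery).
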