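"""Simulate a synthetic savanna landscape with planted drought years.

Builds the reference world for the "loss of resistance" preset and prints
the rainfall record and how the true bare-ground fraction responds — the
ground truth every later stage is tested against.
"""

import numpy as np

from rangeres import synthetic

config = synthetic.WorldConfig(seed=0)
world = synthetic.generate_world(config, "loss_of_resistance")
rain = world["rainfall"]
cover = world["cover"]

totals = rain.annual_totals().mean(axis=(1, 2))
print("year  rain_mm  mean_bare_ground")
for i, year in enumerate(config.years):
    mark = "  <- drought" if year in config.shock_years else ""
    print(f"{year}  {totals[rain.year_index(year)]:7.0f}  {cover.cover[i].mean():.3f}{mark}")

print()
print(f"baseline bare ground: mean {world['truth'].baseline.mean():.3f}")
print(f"susceptibility delta: {world['truth'].susceptibility.min():.3f}-{world['truth'].susceptibility.max():.3f}")
print(f"recovery rate rho: constant {world['truth'].recovery_rate.mean():.2f}")
# Drought years (~50% rainfall deficit) push bare ground up in proportion to
# each pixel's susceptibility; wet years pull it back toward baseline.
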