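"""Build a coupled NDVI/climate scene and inspect its ground truth.

The generator produces a 20x20 grid of 15-day NDVI composites over 25 years,
a 4x4 monthly climate grid (5x coarser), and the exact event dates each
pixel-year was built with.
"""

import numpy as np

from phenodrivers import SimulationConfig, generate_climate_cube, generate_ndvi_cube

cfg = SimulationConfig(seed=42)
cube, truth = generate_ndvi_cube(cfg)
climate = generate_climate_cube(cfg)

print(f"NDVI cube: {dict(cube.sizes)}")
print(f"climate cube: {dict(climate.sizes)}")
print(f"NDVI range: [{float(cube.ndvi.min()):.3f}, {float(cube.ndvi.max()):.3f}]")

d = truth.dates
print("\nmean true event day-of-year over all pixel-years:")
for ev in ("sog", "bgs", "mat", "sos", "egs"):
    print(f"  {ev:>3}: {float(d[f'true_{ev}'].mean()):6.1f}")

apr = climate["temperature"].sel(month=4)
print(f"\nApril temperature: mean {float(apr.mean()):.2f} degC, "
      f"trend injected {cfg.temp_trend} K/decade")
print("Negative winter NDVI composites emulate snow; the true dates above are "
      "what the detector should recover.")
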