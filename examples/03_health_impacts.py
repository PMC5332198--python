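"""From a sensitivity surface to premature deaths.

Applies the impact equation dy = sum y0 * beta * dx * Pop with the PM2.5
concentration-response function (1% mortality per ug/m3), then the
half-year convention: each modeled month stands for six months, and the
annual impact is the sum of the two half-year values.
"""

from airburden import (
    annual_impact,
    annualized_mortality,
    crf_for,
    default_config,
    generate_scenario,
    half_year_impact,
    intersect_to_grid,
    within_state_fraction,
)

scenario = generate_scenario(default_config(seed=0))
exposure = intersect_to_grid(scenario.counties, scenario.grid)
crf = crf_for("PM25")

rates = {}
for month in ("JAN", "JUL"):
    field = scenario.ground_truth[("S1", "RC", month, "POC->PM25")]
    rates[month] = annualized_mortality(field, exposure, crf)
    print(f"{month}: {rates[month]:8.1f} annual-rate deaths "
          f"(if this month's delta-x held all year)")

jan_half = half_year_impact(rates["JAN"])
jul_half = half_year_impact(rates["JUL"])
annual = annual_impact(jan_half, jul_half)
print(f"\nhalf-year impacts: JAN {jan_half:.1f} + JUL {jul_half:.1f} "
      f"= annual {annual:.1f} deaths from S1 RC POC emissions")
print(f"seasonal ratio (annual rates): {rates['JAN'] / rates['JUL']:.1f} "
      ": winter-dominant residential combustion")

# Receptor accounting: how much of the burden falls inside the source state?
field = scenario.ground_truth[("S1", "RC", "JAN", "POC->PM25")]
frac = within_state_fraction(field, exposure, crf, scenario.state_mask("S1"))
print(f"\n{frac:.0f}% of S1's January POC-PM2.5 deaths occur inside S1 "
      "(the rest are exported downwind)")
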