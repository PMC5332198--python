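"""Health damage functions: deaths per 1,000 tons of emitted precursor.

A monthly damage function treats that month's conditions as if they held
all year (annual-rate deaths over 12x monthly tons); the annual value is
the mean of January and July. Signs are kept: a negative January NOx->O3
damage function is winter titration, not an error. States with very low
emissions produce inflated values and are flagged out of summaries.
"""

from airburden import (
    annual_hdf,
    annualized_mortality,
    crf_for,
    default_config,
    flag_low_emission,
    generate_scenario,
    intersect_to_grid,
    monthly_hdf,
)

scenario = generate_scenario(default_config(seed=0))
exposure = intersect_to_grid(scenario.counties, scenario.grid)

src = scenario.sources[("S1", "RC")]
for pair_key, crf_poll in (("POC->PM25", "PM25"), ("NOX->O3", "O3")):
    precursor = pair_key.split("->")[0]
    monthly = {}
    for month in ("JAN", "JUL"):
        deaths = annualized_mortality(
            scenario.ground_truth[("S1", "RC", month, pair_key)], exposure,
            crf_for(crf_poll))
        monthly[month] = monthly_hdf(deaths, src.emissions_tons[month][precursor],
                                     source_state="S1", sector="RC",
                                     precursor=precursor, pollutant=crf_poll,
                                     period=month)
    annual = annual_hdf(monthly["JAN"], monthly["JUL"])
    print(f"S1 RC {pair_key:11s} HDF: JAN {monthly['JAN'].value:8.3f}  "
          f"JUL {monthly['JUL'].value:8.3f}  ANNUAL {annual.value:8.3f} "
          "deaths per 1,000 tons")

# The low-emission pathology: tiny emissions inflate the ratio.
outlier = monthly_hdf(0.05, 0.02 / 12.0, source_state="XX", sector="EGU",
                      precursor="PEC", pollutant="PM25", period="JAN")
flagged = flag_low_emission([outlier], rank_count=0, floor_tons=1.0)[0]
print(f"\n0.05 deaths/yr over 0.02 tons/yr -> {outlier.value:,.0f} deaths per "
      f"1,000 tons (low-emission flag: {flagged.low_emission_flag})")
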