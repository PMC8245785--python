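"""Convert a light/dark scintillation pair into cellular carbon uptake.

Twenty picked ciliate cells were incubated 3 h with NaH14CO3 in a 2 mL
vial; a 100 uL subsample measured the medium's specific activity and the
remaining 1.9 mL was acidified and counted.  A foil-wrapped dark vial
controls for non-photosynthetic label uptake.
"""

from kleptocarbon import (
    ScintillationPair,
    Treatment,
    chl_per_cell,
    chl_specific_uptake,
    uptake_daily,
    uptake_hourly,
    FluorometrySample,
)

pair = ScintillationPair(
    culture_id="bottle-1", day=3.0,
    dpm_light=520.0, dpm_dark=29.0,   # raw counter readings, DPM
    n_cells=20, incubation_h=3.0,
    sa_dpm=222000.0, sa_volume=0.1,   # specific-activity subsample
    counted_volume=1.9, vial_volume=2.0,
    dic=26.0,                          # ug C/mL in the medium
)
treatment = Treatment("I40", irradiance=40.0, prey_target=1e4)

p_hourly, flags = uptake_hourly(pair)
p_daily = uptake_daily(p_hourly, treatment)  # x 14 h light

chl = chl_per_cell(FluorometrySample("bottle-1", 3.0, reading=1300.0, n_cells=20))
p_chl = chl_specific_uptake(p_daily, chl)

print(f"hourly uptake  p = {p_hourly:.1f} pg C/cell/h (flags: {flags or 'none'})")
print(f"daily uptake   P = {p_daily:.0f} pg C/cell/d")
print(f"chl-a content    = {chl:.1f} pg/cell")
print(f"chl-specific P   = {p_chl:.2f} pg C/(pg chl-a)/d")

# Interpretation: the light-minus-dark DPM excess, scaled by the medium's
# inorganic carbon and tracer activity, shows each cell fixing tens of
# pg C per hour in the light -- hundreds per photoperiod day.
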