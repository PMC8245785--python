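"""Estimate growth, clearance and ingestion from one day of count data.

A mixed culture starts a dilution cycle at 15 ciliates/mL over 4x10^4
prey/mL; by the next day the ciliates have grown and the prey have been
drawn down.  A prey monoculture run alongside provides the ungrazed
control growth rate.
"""

from kleptocarbon import Interval, clearance_ingestion, growth_rate

# control monoculture: prey alone grew from 4.0e4 to 6.6e4 in one day
k_control = growth_rate(4.0e4, 6.6e4, t=1.0)

iv = Interval(
    culture_id="bottle-1", t0=2.0, t1=3.0,
    N0=15.0, N1=27.0,          # ciliates, cells/mL
    C0=4.0e4, C1=4.6e4,        # prey, cells/mL
    k_control=k_control,
)
res = clearance_ingestion(iv)

print(f"prey control growth k = {k_control:.3f} /d")
print(f"ciliate growth mu_y   = {res.mu_y:.3f} /d")
print(f"grazing coefficient g = {res.g:.3f} /d")
print(f"clearance F           = {res.F * 1e3:.3f} uL/grazer/d")
print(f"ingestion I           = {res.I:.0f} prey/grazer/d")

# Interpretation: the prey grew slower than its control, and the gap --
# scaled by the log-mean grazer density -- says each ciliate swept a few
# microlitres of medium per day, ingesting a few hundred prey cells.
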