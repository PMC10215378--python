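"""Does a companion response's breakpoint coincide with Rmin?

Builds a paired study: a growth response following the linear-logistic
curve, and a companion physiological response (think milk yield or
immune titre) whose broken-line plateau starts exactly at the growth
curve's true Rmin.  The comparison should recover that construction.
"""

from linlogfit import SyntheticDesign, compare_rmin_to_breakpoint, make_pair

pair = make_pair(SyntheticDesign(seed=7, noise_sd=0.01), anchor="rmin")
report = compare_rmin_to_breakpoint(
    pair.primary, pair.companion, treatments=[77, 87, 97, 107, 117, 127]
)

print(f"fitted Rmax = {report.rmax:.2f}, Rmin = {report.rmin:.2f}")
print(f"companion breakpoint = {report.breakpoint:.2f}")
print(f"|breakpoint - Rmin| = {report.distance_to_rmin:.2f}, "
      f"|breakpoint - Rmax| = {report.distance_to_rmax:.2f}")
print(f"nearest inflection: {report.nearest_inflection}")
print(f"Rmin maps to treatment level {report.nearest_treatment_of_rmin:.0f}%")
# The breakpoint sits a fraction of a dose unit from Rmin and far from
# Rmax, so the companion response is classified as peaking at Rmin, and
# Rmin maps onto the 117% treatment of the 77-127 grid.
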