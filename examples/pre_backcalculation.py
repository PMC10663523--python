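"""Back-calculate a membrane-PRE profile for one conformer.

Builds the toy G domain (41 methyl reporters on a 12-A shell, centred 23 A
above the phosphate plane, plus 3 helix reporters buried at -6.5 A), then
computes each reporter's Gamma_2 from the plane-integrated
Solomon-Bloembergen model and the resulting intensity ratio I/I0.
"""

import memstates as ms

reference = ms.make_toy_domain()
prediction = ms.predict_profile(reference)

frame = prediction.to_frame().sort_values("z_height_A")
print(frame.to_string(index=False, float_format=lambda v: f"{v:10.4g}"))
print()
print(
    "Reporters high above the membrane keep I/I0 near 1; the helix "
    "reporters below the phosphate plane sit ~1.5 A from the spin-label "
    "plane and are fully bleached (ratio ~ 0). Between the two, the "
    "ratio falls off with the inverse fourth power of the distance to "
    "the label plane."
)
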