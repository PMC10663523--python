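"""Rotational correlation times: TRACT, hydrodynamics, rescaling.

Simulates a TROSY/anti-TROSY decay pair for a 34-ns rotor, refits the
rates, inverts the cross-correlated rate difference back to tau_c, then
compares with the Stokes-Einstein-Debye estimate for a free 21-kDa
protein and rescales a 45 C nanodisc value to 25 C.
"""

import memstates as ms
from memstates.rotation import rescale_tauc, sed_tauc

pair = ms.simulate_tract(34.0, noise=0.01, seed=3)
r_alpha, r_beta = ms.fit_tract_rates(pair)
tc = ms.rates_to_tauc(r_beta - r_alpha)
print(f"TRACT: R_alpha = {r_alpha:.1f} s-1, R_beta = {r_beta:.1f} s-1 "
      f"-> tau_c = {tc.tau_c_ns:.1f} ns (truth 34 ns)")

free = sed_tauc(21.0)
print(f"SED estimate for a free 21-kDa globule at 25 C: {free.tau_c_ns:.1f} ns")

nanodisc = ms.CorrelationTime(34.0, temperature_k=318.15)
for solvent in ("water", "heavy_water"):
    out = rescale_tauc(nanodisc, 318.15, 298.15, solvent)
    print(f"34 ns at 45 C -> {out.tau_c_ns:.1f} ns at 25 C ({solvent})")
print()
print(
    "A 34-ns G domain tumbles far slower than a free 21-kDa protein "
    "(~9 ns) but much faster than the ~55-ns assembly it is tethered to "
    "- the signature of a mobile domain anchored by its N-terminal helix."
)
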