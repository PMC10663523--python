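"""2H chain order: splittings -> smoothed profile -> chain extension.

Simulates quadrupolar splittings for a myristoyl-like chain (14 carbons)
with a plateau-then-decay order profile, masks three positions to mimic
unresolved Pake doublets, rebuilds the smoothed profile, and converts it
to a mean-torque chain-extension profile (terminal CH3 at 0).
"""

import numpy as np

import memstates as ms

carbons = np.arange(2, 15)
truth = ms.OrderProfile(
    carbons=carbons, s_cd=0.21 * np.minimum(1.0, np.exp(-(carbons - 8) / 4.0))
)

table = ms.simulate_splittings(truth, noise_khz=0.3, seed=2, mask=[5, 9, 11])
print(f"simulated {len(table.carbons)} resolved splittings "
      f"(3 positions masked as unresolved)")

profile = ms.smooth_profile(table, chain_length=14)
extension = ms.chain_extension(profile)

print("carbon  |S_CD|   segment travel (A)   distance from CH3 (A)")
for ci, s, tr, cum in zip(
    profile.carbons, profile.s_cd, extension.travel_A, extension.cumulative_A
):
    print(f"{ci:4d}    {s:.3f}        {tr:.3f}              {cum:6.3f}")
print()
print(
    "The smoothed profile is non-increasing toward the terminal methyl. "
    "Each |S_CD| maps to a mean segment projection on the bilayer normal "
    "(1.27 A at the all-trans limit); the cumulative sum is the chain "
    "extension whose slope distinguishes ordered from compressed chains."
)
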