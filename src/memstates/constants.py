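"""Physical constants (CODATA 2018) used across the package.

All NMR-facing quantities work in the unit system stated on each symbol;
lengths elsewhere in the package are in angstroms.
"""

MU0_OVER_4PI = 1e-7           # T m / A
GAMMA_H = 2.6752218744e8      # 1H gyromagnetic ratio, rad s^-1 T^-1
GAMMA_N = -2.7116e7           # 15N gyromagnetic ratio, rad s^-1 T^-1
G_E = 2.00231930436           # free-electron g factor
MU_B = 9.2740100783e-24       # Bohr magneton, J T^-1
HBAR = 1.054571817e-34        # J s
KB_SI = 1.380649e-23          # J K^-1
KB_KCAL_MOL = 1.987204259e-3  # kcal mol^-1 K^-1
N_AVOGADRO = 6.02214076e23    # mol^-1

M_PER_ANGSTROM = 1e-10
ANGSTROM6_PER_M6 = 1e60
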