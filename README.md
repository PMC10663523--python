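# memstates

Orientational-state analysis of a lipid-anchored GTPase G domain above a
planar membrane.

Peripheral membrane proteins such as myristoylated Arf-family GTPases are
tethered to the bilayer by an inserted N-terminal helix while their G
domain remains mobile, distributing over a small number of orientational
states that expose or occlude the functional switch regions.  This
package implements, as a reusable and tested library, the quantitative
machinery for characterizing that distribution from NMR observables:

* **Membrane PRE back-calculation** — for a conformer at height *z* above
  the phosphate plane, the transverse PRE from a laterally averaged plane
  of nitroxide-labelled lipids at depth *d* is the integrated
  Solomon–Bloembergen interaction
  Γ₂ = K_SB σ π / (2Δ⁴), Δ = z + d, and the observable is
  I/I₀ = R₂ e^(−Γ₂t)/(R₂+Γ₂).  A brute-force lattice-sum oracle validates
  the closed form; ratio errors follow
  (I_para/I_dia)·√(SN_para⁻² + SN_dia⁻²).
* **Sparse ensemble selection** — assuming fast exchange (Γ₂, not
  intensities, average over conformers), a fixed-size multiset of library
  conformers (N = 16) is selected to fit a measured I/I₀ profile by
  weighted least squares; 100 repeats against 15%-noise-perturbed data
  yield state populations with uncertainties, ensemble center-of-mass
  heights, and Welch *t*-tests between conditions.
* **Orientational states and PMFs** — tilt/spin angles (β, γ) from Kabsch
  superposition against a reference, rectangular state bins with circular
  γ arithmetic (defaults S1: β 57–73°, γ 115–187°; S2: 8–20°, 64–118°;
  S3: 20–30°, 0–50°), and free-energy surfaces F = −k_BT ln(n/n_max).
* **²H chain order** — Pake splittings to |S_CD| (Δν = ¾·χ_Q·|S|, methyl
  ⅓), plateau-assigned smoothed profiles, first-order mean-torque chain
  extension (⟨cos β⟩ = ½(1+√((8|S|−1)/3)), 1.27 Å all-trans travel),
  inversion-recovery R₁Z fits, and R₁Z-vs-S² square-law tables.
* **Rotational correlation times** — TRACT rate differences inverted for
  τ_c through the ¹H–¹⁵N dipole/CSA cross-correlated rate,
  Stokes–Einstein–Debye estimates, and η(T)/T rescaling with embedded
  light-/heavy-water viscosity tables.
* **Synthetic ground truth** — seeded generators for every input: a toy
  reporter geometry (41 G-domain + 3 buried helix methyls), three-state
  conformer libraries with known populations, noisy PRE tables, order
  profiles, and relaxation decays.

## Worked example

`examples/ensemble_fit.py` generates a 2000-conformer library from a known
20/30/50% S1/S2/S3 mixture (COM heights 18/22/26 Å), simulates its
fast-exchange PRE profile, and reruns 16-member selection on 100
noise-perturbed copies:

```
state   truth   recovered (mean +/- SD over 100 repeats)
S1       20%     34.3% +/- 21.9
S2       30%     36.1% +/- 19.1
S3       50%     29.6% +/- 22.7
unassigned: 0.0%
mean G-domain COM height: 21.2 A (truth mixture mean 23.2 A)
```

Each repeat's populations move in steps of 1/16 = 6.25%; at 15% noise the
three states are only weakly identifiable (the PRE profile is a smooth
r⁻⁴ function of height), so the spreads are wide but bracket the truth,
and the ensemble COM lands within ~2 Å of the mixture mean.

`examples/correlation_times.py` runs the relaxation side:

```
TRACT: R_alpha = 10.4 s-1, R_beta = 114.5 s-1 -> tau_c = 35.8 ns (truth 34 ns)
SED estimate for a free 21-kDa globule at 25 C: 8.9 ns
34 ns at 45 C -> 54.2 ns at 25 C (water)
34 ns at 45 C -> 56.1 ns at 25 C (heavy_water)
```

A ~34 ns G domain tumbles far slower than a free 21-kDa protein yet much
faster than the ~55 ns assembly carrying it — the signature of a mobile
domain on a membrane tether.  The other examples cover PRE
back-calculation (`pre_backcalculation.py`), state assignment and PMFs
(`orientation_pmf.py`), and chain order/extension (`chain_order.py`).

A thin CLI exposes the same stages for shell use
(`memstates simulate | predict-pre | fit-ensemble | states | pmf | order |
extension | tauc`), driven by a YAML config whose resolved values are
embedded in every results file.

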