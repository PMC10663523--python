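# Methods

`memstates` quantifies how the G domain of a lipid-anchored small GTPase
distributes over orientational states above a planar membrane, combining
four largely independent pieces of machinery: membrane-PRE
back-calculation, fixed-size conformer-ensemble selection, ²H acyl-chain
order analytics, and rotational-correlation-time utilities.  Everything is
exercisable on synthetic data with known ground truth; this note records
the models, the defaults, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Coordinate frame and orientations

All geometry lives in a fixed membrane frame: +z is the outward normal of
the protein-side leaflet and the phosphate plane of that leaflet is z = 0,
so every height is "Å above the phosphorous plane" and may be negative for
inserted groups.  A conformer is a rigid set of point reporters (methyl
carbons) tagged `g_domain` or `n_helix`.

The orientation of a conformer is read off the least-squares (Kabsch)
rotation R mapping a reference conformer onto it (common G-domain
reporters, translations removed): β is the polar angle of R·ẑ against the
membrane normal and γ the azimuth of R·x̂ about the normal, measured from
the membrane x̂, in [0, 360).  The reference's stored pose therefore
defines (β, γ) = (0, 0); `canonicalize_reference` rotates a reference into
its principal-axes pose (largest-variance axis → ẑ, ties broken by
descending eigenvalue then lexicographic axis preference, signs toward the
positive membrane axes) when a shape-anchored zero is wanted.  Because the
collective-variable convention of any particular upstream study may use a
different azimuth origin, `compute_orientation` exposes
`beta_offset_deg` / `gamma_offset_deg` calibration offsets; the default
state bins (S1: β 57–73°, γ 115–187°; S2: 8–20°, 64–118°; S3: 20–30°,
0–50°) are configuration, not constants.  γ intervals are circular: a bin
ending past 360° or printed beyond 180° is honoured on the circle, never
clipped.  State sets are validated pairwise disjoint (positive-area
overlap of the β interval and the γ arc); bins may share a boundary.

PMF surfaces are plain orientation histograms converted by
F = −k_B T ln(n/n_max), so the minimum over occupied bins is exactly 0 and
the surface is invariant to the total count.  Empty bins carry an explicit
"unvisited" marker (NaN in memory, the string `unvisited` on disk) rather
than an infinite energy, so files round-trip losslessly.

## Membrane PRE model

The nitroxide labels (5-doxyl PC at 5 mol%) diffuse laterally, so the PRE
observable is modelled as distance-to-plane, not per-snapshot label
positions: a reporter at height z sees a uniform plane of electron spins
at depth d below the phosphate plane.  Integrating the
Solomon–Bloembergen r⁻⁶ dipolar interaction over that plane gives

    Γ₂(z) = K_SB · σ · π / (2 Δ⁴),    Δ = z + d,

with K_SB = (1/15)(μ₀/4π)² γ_H² g_e² μ_B² S(S+1) · [4J(0) + 3J(ω_H)] and
J(ω) = τ/(1+ω²τ²).  The trans leaflet adds the same term at
Δ′ = z + s − d.  Defaults: σ = 0.05/65 Å⁻² (5 mol% at 65 Å² per lipid),
d = 8 Å (5-doxyl position), phosphate-plane separation s = 38 Å,
τ_PRE = 5 ns, 850 MHz, R₂,dia = 20 s⁻¹, transfer delay 8 ms.  These are
conventional methyl-TROSY-era values and are all configuration; nothing
downstream assumes them.

`gamma2_discrete` is an independent brute-force oracle: point labels on a
half-offset square lattice summed as K·σh²Σr⁻⁶.  At 0.5 Å spacing and a
cutoff of 100·Δ it agrees with the closed form to ≪0.5% for Δ between 10
and 30 Å (the truncated tail scales as (Δ/R_cut)⁴ ≈ 10⁻⁸).

Intensity ratios use the standard two-time-scale observable
I/I₀ = R₂ e^(−Γ₂ t) / (R₂ + Γ₂): line broadening during acquisition plus
magnetization loss over the transfer period.  This function is strictly
decreasing in Γ₂ and bounded in [0, 1] — both facts are load-bearing (the
ensemble selector inverts it; see below).  Reporters at or below the label
plane (the inserted helix methyls) are treated as fully bleached: ratio 0,
Γ₂ capped at 10⁹ s⁻¹ (a finite cap keeps fast-exchange averages finite),
with a warning rather than an error.

Measured tables store raw intensities and signal-to-noise; the ratio and
its uncertainty, ratio·sqrt(SN_para⁻² + SN_dia⁻²), are always recomputed
on load and never read from disk.

## Ensemble selection and the population protocol

Conformations interconvert faster than relaxation, so ensemble PREs
average rates, not intensities: Γ̄₂ per reporter is the weighted mean over
members and one ratio is computed from Γ̄₂ (`fast_exchange`; intensity
averaging is retained as a sensitivity option, and Jensen's inequality
makes the fast-exchange ratio the smaller of the two).

The fit selects an N-member multiset (N = 16 by default, uniform weights
1/N, repetition allowed) minimizing

    χ² = Σ_j ((ratio_calc,j − ratio_meas,j)/σ_j)²

over the reporters present in the measurement.  σ_j is the total
per-reporter uncertainty sqrt(err_eq1,j² + (ν·ratio_j)²), floored at 0.01,
where ν is the declared relative random error of the data
(`FitConfig.noise_fraction`, default 0.15).  Two properties of this
objective matter:

* With ν = 0 it is plain error-weighted least squares and the optimizer
  refines χ² all the way down — required for the planted-ensemble
  certificate below.
* With ν > 0 the search stops at the expected misfit
  χ²_target = Σ_j min(1, ν·ratio_j/σ_j)² (discrepancy principle).
  Without this stop, fitting data that carries 15% noise against ~3%
  intensity errors overfits the noise five-fold; worse, the [0, 1] clip
  of perturbed ratios makes the chase asymmetric (upward excursions
  saturate at 1 and cannot be fitted, downward ones can always be chased
  by adding membrane-proximal members), which systematically buries the
  ensemble and inflates the most membrane-proximal state.  The
  discrepancy stop removes that failure mode.

The optimizer is deterministic given the seed and has two parts.  First,
an exact-fit probe: the intensity ratio is strictly monotone in Γ₂, so a
measured profile pins down a unique target mean-response vector (inverted
per reporter by bracketed root-finding); a bounded-time integer
feasibility program (HiGHS, via `scipy.optimize.milp`) then asks whether
any N-multiset reproduces that target within tolerance.  On noise-free
data generated from the library this recovers the generating multiset —
plain local search provably cannot: the response matrix is effectively
low-rank, near-optimal alternates are dense, and the exact multiset is a
measure-zero basin (single-swap hill climbing stalls at χ² ~ 10⁻³).  On
noisy data the program is infeasible, detected in milliseconds, and
skipped.  Second, a stochastic hill climb: random starting multiset,
random single-member replacement proposals accepted on χ² decrease
(optionally simulated-annealing acceptance), then a steepest-descent
single-swap polish to a local optimum; 20 restarts × 2000 proposals by
default.

The population protocol mirrors the study design: each of `repeats`
(default 100) iterations perturbs every measured ratio with independent
Gaussian noise of SD = ν·ratio (clipped to [0, 1]; the perturb-the-start
variant is also available), reruns the selection with a repeat-derived
child seed, and records state fractions (multiples of 1/N), ensemble COM
(multiplicity-weighted mean of member G-domain COM heights), and χ².
Populations are reported as mean ± SD over repeats; two summaries are
compared per state with a two-sided Welch t-test on the per-repeat
fractions (degenerate zero-variance pairs return t = 0, p = 1 when
identical).

## Synthetic ground truth

The generators produce every pipeline input as a pure function of
(spec, seed):

* **Toy domain** — 41 G-domain reporters as seeded low-discrepancy
  (Fibonacci) points on a 12 Å shell, re-centred so the centroid sits
  exactly at the configured height (23 Å); 3 helix reporters on a line
  6.5 Å below the phosphate plane, matching the measured insertion depth
  of the anchoring helix.
* **Library** — each conformer draws a state from the truth fractions, an
  orientation uniform inside that state's (β, γ) bin, and a COM height
  from the state's normal distribution (means 18/22/26 Å for S1/S2/S3,
  SD 2 Å; resampled, capped at 100 attempts, so all G-domain reporters
  stay ≥1 Å above the label plane).  The G domain is rigidly rotated
  about its centroid while the helix reporters stay anchored — so
  different states bury different reporter subsets, the way the occluded
  state buries the switch-I face.  States are therefore separable but
  overlapping in their PRE signatures.
* **Measurements** — fast-exchange profile of a truth multiset, optional
  multiplicative Gaussian noise (default fraction 0.15), I_dia = 1000,
  S/N = 50 for both samples so the error formula is well defined.
* **Splittings / decays** — exact forward models (quadrupolar conversion;
  I(t) = I∞(1−2f e^(−Rt)); TROSY/anti-TROSY exponentials at R̄ ∓ η_xy)
  plus Gaussian noise; the inversion-recovery schedule defaults to the
  11-point experimental list (0.001 … 1.8 s).

What passing the recovery benchmark shows — and does not.  The headline
test (2000-member library, truth 20/30/50%, 15% noise, N = 16, 100
repeats) recovers each population within ±2 reported SD with <5%
unassigned.  The reported SDs are large (≈20 points): with r⁻⁴ distance
profiles, a 4 Å height ladder and 16-member granularity, the states are
only weakly identifiable at 15% noise, and a small membrane-proximal bias
(≈2 Å in COM) survives from the ratio clipping.  Real data differ in ways
the generator does not emulate: reporter-specific dynamics (S² effects on
PREs are not modelled), rotamer averaging, imperfect diamagnetic
references, correlated noise across reporters, and a conformer library
whose members are not drawn from the same generative process as the data.
Recovery here validates the machinery (objective, optimizer, bookkeeping),
not the field identifiability of any particular experimental system.

## ²H chain order

Pake 90°-edge splittings convert as |S_CD| = Δν/(¾·χ_Q) for methylenes,
with an additional factor 3 for the methyl (C₃ rotation pre-averages the
coupling); χ_Q defaults to 167 kHz.  Values above 0.5 are rejected as
unphysical.  Smoothed profiles follow the plateau-assignment convention:
resolved |S| values sorted descending are assigned to the resolved carbon
positions from the upper chain toward the terminal methyl, unresolved
positions are filled by monotone shape-preserving (PCHIP) interpolation
with flat end-extension, and the result is forced non-increasing toward
the methyl.  No de-Pake-ing: inputs are peak-picked splitting tables.

Chain extension uses the first-order mean-torque closed form
⟨cos β_i⟩ = ½(1 + sqrt((8|S_i| − 1)/3)), whose domain ends at |S| = 1/8;
below that the boundary value ½ is used and the position flagged rather
than extrapolated.  Per-carbon travel is 1.27 Å·⟨cos β⟩ (the all-trans
per-carbon projection) and the cumulative profile runs from the terminal
CH₃, arbitrarily placed at 0 — only slopes are comparable between chains.

Inversion-recovery series fit I(t) = I∞(1 − 2f e^(−R₁Z t)) by
Levenberg–Marquardt with analytic starting values (plateau from the last
point, rate from the mid-schedule delay); the 95% CI comes from the
covariance with a t-quantile at n−3 degrees of freedom.  Square-law
tables pair (S², R₁Z) sorted by S² with no fit — the curvature itself is
the readout.  Trajectory-derived order parameters are
⟨(3cos²θ−1)/2⟩ over frames of unit C–H vectors (tolerance 10⁻⁶), reported
as |S| with the signed value kept in metadata.

## Rotational correlation times

TRACT: TROSY and anti-TROSY decays are fitted independently as single
exponentials; the rate difference equals twice the ¹H–¹⁵N dipole/¹⁵N-CSA
transverse cross-correlated rate η_xy, built from conventional constants
(r_NH = 1.02 Å, Δσ_N = 160 ppm, 17° between the tensors) with
J(ω) = (2/5)τ_c/(1+ω²τ_c²) for a rigid isotropic rotor.  η_xy is strictly
increasing in τ_c, so the inversion is a bracketed Brent root-find on
[10⁻⁴ ps, 10 μs]; the forward–inverse round trip is exact to ≪0.1% over
5–100 ns.  The constants are conventional rather than fitted; only
self-consistency of forward and inverse is claimed.

Stokes–Einstein–Debye: r = (3Mv̄/4πN_A)^⅓ + hydration shell (v̄ = 0.73
cm³/g, shell 3.2 Å), τ_c = 4πηr³/(3k_BT).  For a 21 kDa globule at 25 °C
in water this gives ≈ 8.9 ns; empirical tabulations for real proteins of
this size run somewhat higher (~13 ns), and the package reports the SED
number without forcing agreement.

Temperature rescaling uses τ_c(T₂) = τ_c(T₁)·(η₂/η₁)·(T₁/T₂) with
embedded 1 °C-resolution viscosity tables over 0–100 °C: H₂O from the
standard Kestin-type correlation anchored at η(20 °C) = 1.0016 mPa·s,
D₂O as H₂O times a smooth literature-anchored isotope ratio (1.23 at
25 °C, decreasing with temperature) — NMR samples are routinely in D₂O
buffer and the rescaling result depends on the solvent table.  A 34 ns
value at 45 °C maps to 54.2 ns (H₂O) / 56.1 ns (D₂O) at 25 °C.
Rescaling is an exact group action (compositions and round trips are
identities to machine precision).

## Problem sizes, tolerances, determinism

The shipped benchmarks use a 200-member library for planted-recovery
certificates (20 seeds) and a 2000-member library with 100 repeats for
population recovery, with the hill climb at 3 restarts × 800 proposals
for the repeat protocol — sizes chosen as comfortable desk-scale runs
that leave the conclusions unchanged when enlarged.  All randomness flows
through `numpy` `SeedSequence`s keyed by (seed, stream, repeat), so
identical inputs give bit-identical outputs, including across the
repeat protocol's noise and search streams.  Numerical tie-breaks that
matter: polish swaps require a relative χ² improvement >10⁻¹⁴ (float
drift is shed by a final from-scratch recomputation); principal-axis
signs and orderings are fixed as described above; γ arithmetic is
everywhere modulo 360.

## Known limitations

* The PRE model has no order-parameter scaling, no rotamer averaging,
  and a sharp label plane (no label-depth distribution); absolute Γ₂
  values inherit the uncertainty of τ_PRE and the doxyl depth, which are
  configuration, not fitted.
* Continuous-weight ensemble reweighting (maximum-entropy/Bayesian) is
  deliberately out of scope; only fixed-size multisets are searched, and
  ensemble-size selection beyond a χ²-vs-N curve is not attempted.
* The orientation convention is self-consistent but arbitrary up to the
  calibration offsets; comparing bins against an external study requires
  calibrating γ's origin first.
* The mean-torque model is first-order; sub-1/8 order parameters carry a
  flagged boundary value rather than a model prediction.
* The integer exact-fit probe is worst-case exponential; it runs under a
  time limit and the search falls back to the stochastic climb, so
  optimality certificates on noise-free data are found in practice
  (seconds at library size 200) but not guaranteed in bounded time.
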