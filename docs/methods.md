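# Methods

`ectspec` analyses current–distance (I-z) ensembles from electrochemical
tunneling spectroscopy (ECTS) between redox partner proteins, and ships a
forward model of the measurement plus a 1D diffuse-double-layer module. This
note records the models, the defaults and why, the numerical choices, and
the limits of what the synthetic tests demonstrate.

## Measurement model

An ECTS I-z record is the probe current after the feedback loop is opened at
a set-point current `I_set` (default 0.4 nA) while the piezo retracts at
constant speed (12 nm/s) and constant electrode potentials `U_P`, `U_S`
(V vs SSC; bias `U_bias = U_P − U_S`). The idealized current is

    I*(z) = I_leak + (I_set − I_leak) · exp(−β z),

with `β` (nm⁻¹) the distance decay factor and `I_leak` a
distance-independent faradaic leakage through the probe insulation (default
2 pA; the instrument spec is only "below a few pA"). The recorded value at
each piezo position is the mean of `samples_per_point` analog samples
(20 for 15 nm/1024-point retractions, 35 for 100 nm/4096-point approaches),
clipped to the 10 nA amplifier ceiling.

Noise enters each sample as a lognormal multiplicative factor
(σ = 0.15) times the ideal current plus additive Gaussian current noise
(σ = 0.5 pA). These two sigmas are artifact choices — chosen once so that
the leakage floor is visible in a semilog plot without dominating fits —
and are the main respect in which the generator is idealized (no 1/f drift,
no piezo creep, no telegraph switching).

β disperses **curve to curve**, not point to point: each curve draws
`β ~ Normal(beta_mean, beta_sd)` truncated at 0.05 nm⁻¹ (a non-decaying
"curve" is unphysical and unfittable). The published histograms reflect
exactly this curve-level spread. Shipped presets:

| preset         | β mean ± sd (nm⁻¹) | notes                                 |
|----------------|--------------------|---------------------------------------|
| `bare_gold`    | 9 ± 2              | metallic junction, 50 mM buffer       |
| `pCc1_hCc`     | 1.5 ± 0.8          | specific partner pair                 |
| `inhibited`    | 3 ± 1              | WT hCc saturates the sample protein   |
| `self_ET`      | 3 ± 1              | non-specific hCc–hCc transfer         |
| `pure_water`   | 1.5 ± 1.5          | gold in pure water; sd is an artifact choice for "more broadly distributed" |
| `gold_layering`| oscillatory barrier | see below                             |
| `gated`        | gate-dependent     | see below                             |
| `approach`     | 1.5 ± 0.8          | 100 nm/4096 pts/35 samples, approach  |

Approach sweeps are generated with the amplitude pinned to the saturation
current at z = 0 (the sweep is recorded until the amplifier saturates) and
serialized ascending in z like every curve, with a `mode` flag.

## Decay-factor estimation

Per curve: (1) leakage = median |I| over the final 10% of points — this
assumes the sweep reaches its asymptote, which holds for β ≳ 1 nm⁻¹ over
15 nm and is why very slow decays get flagged rather than trusted;
(2) fit window = largest contiguous run with `3·I_leak < I < 0.9·I_sat`,
starting at the first unsaturated point (both thresholds are artifact
choices; the source experiments state none); (3) OLS of `ln(I − I_leak)`
vs z; `β = −slope`. A 3-parameter nonlinear refit (`method="nonlinear"`)
is available and agrees with the log-linear route to within 5% on default
synthetic data.

Quality flags (`too_few_points`, `saturated_start`, `leakage_dominated`,
`nonpositive_dropped`, `unfittable`) travel with each fit; flagged fits are
excluded from ensemble statistics and the per-gate counts are reported so N
stays auditable. `saturated_start` is only raised for retraction curves —
an approach sweep is *supposed* to end pinned at the ceiling. Ensemble
summaries read "distributed around X ± Y" as the arithmetic mean ± SD of
per-curve fits (default); a Gaussian fit to the histogram is available as
`method="gaussian"`. Default histogram bins: 0.25 nm⁻¹ below β = 5,
1 nm⁻¹ above.

Note one deliberate consequence of the flagging rules: at the gating
resonance (generative β = 0.5 ± 0.3 nm⁻¹) the slowest-decaying curves are
`leakage_dominated` over a 15 nm sweep and drop out, so the recovered
per-gate mean sits a few hundredths of nm⁻¹ above the generative center.
This mirrors what any tail-anchored analysis of such curves must do and is
well inside the quoted spread.

## Local barrier profiles and water layering

For a square barrier, `Φ_local = (ħ²/8mₑ)·(d ln I/dz)² ≈ 0.00952 eV·nm² ×
(slope in nm⁻¹)²`. This standard vacuum form is the only physics constant
in the module; if the original analysis applied a different prefactor or
smoothing, absolute Φ values shift by a constant factor while periodicities
are unaffected. Profiles use a sliding 0.15 nm window (≈10 points of a
1024-point/15 nm sweep): short enough to resolve 0.35 nm oscillations at
Nyquist, long enough to average point noise.

The `gold_layering` preset drives the generator with an oscillatory barrier
`Φ(z)` cycling between 0.5 and 1.2 eV with a 0.35 nm period (one water
diameter per expelled hydration layer). The ideal current uses the
path-attenuation form `exp(−∫₀ᶻ β_eff(s) ds)` with
`β_eff = slope_from_barrier(Φ)`, so the local log-slope equals `β_eff(z)`
exactly and the profile estimator recovers `Φ(z)` up to window smoothing
(which compresses the extremes by ~15% at the default window). The preset
models a well-insulated probe (leakage 0.05 pA, low noise): with a mean
slope near 9 nm⁻¹ and a 0.4 nA set point, the profile spans
`ln(0.4 nA / 0.15 pA)/9.2 ≈ 0.85 nm ≈ 2.4` oscillation periods before the
current reaches the leakage floor; at the default 2 pA leakage fewer than
1.5 periods survive and no periodicity is detectable by any method.

Periodicity detection: linear detrend, bias-corrected autocorrelation,
first local maximum at a lag in [0.1 nm, min(1 nm, span/2)] with
correlation ≥ 0.2, refined by 3-point parabolic interpolation. The span/2
lag cap means at least two full periods of data are required for a
candidate period; flat or trend-only profiles return "aperiodic" (None)
rather than a number.

## Electrochemical gating

The EC gate is the common shift of both electrode potentials at constant
bias, tuning the electrode Fermi levels relative to the proteins' redox
levels (midpoints: pCc₁ 0.28 V, hCc 0.35 V vs SSC). Its quantitative
definition is instrument-specific, so the mapping `(U_P, U_S) → Vg` is an
injectable function; the default convention is `Vg = −U_S`, which places
the resonance at −0.25 V when `U_S = 0.25 V`. The generative gate response
is a Gaussian well

    β(Vg) = β_off − (β_off − β_min) · exp(−(Vg − V0)² / 2w²)

with defaults β_off = 3.5 nm⁻¹, β_min = 0.5 nm⁻¹, V0 = −0.25 V,
w = 0.03 V. The narrow width puts the first off-resonance gate (−0.15 V)
essentially at β_off, giving an off/on ratio near 7; `active=False`
reproduces far-from-resonance operation (e.g. 500 mV bias), where β stays
flat at β_off. Per-gate spread is 0.3 nm⁻¹, matching the quoted dispersion
at the minimum.

Analysis side: fits are grouped by (U_P, U_S) after rounding to 1 mV, a
constant-bias check runs across groups, and the series minimum is located
by a 3-point parabola through the argmin (gate grids are 50–100 mV coarse;
an edge argmin is returned flagged). A series whose total range is below
the typical per-gate SD reports "no minimum", the metallic-junction
behaviour. On/off ratios divide the mean β at the two requested gates and
propagate the standard errors of the means. Potentials convert to the
absolute scale as `E(eV) = −U(V vs SSC) − 4.6`.

## Diffuse-double-layer module

The screening argument: at 100 mM the Debye length
`κ⁻¹ = sqrt(ε₀ε_r k_B T / 2 N_A e² c₀)` is ≈1 nm, so a field cannot
ordinarily survive several nm of electrolyte — unless ions are depleted
from the confined gap. The module provides the closed forms (Debye length;
exact Gouy–Chapman single-wall profile `ψ = 4 atanh(tanh(ψ₀/4) e^{−κz})`)
and a nonlinear 1D Poisson–Boltzmann solver for the gap,
`ψ'' = κ² sinh ψ` with Dirichlet walls, as damped Newton (backtracking
line search) on a second-order finite-difference grid with continuation
from the linearized solution for walls above 2 kT/e (validated to
20 kT/e). The default electrolyte (50 mM, 298 K, ε_r 78.5) treats the
phosphate buffer as an effective 1:1 salt; speciation and multivalency are
deliberately ignored. Potential boundary conditions were chosen over fixed
charge because the reference quantities are potential contours (±1.1 kT/e);
all internal potentials are in kT/e (25.7 mV at 298 K).

Numerical notes: the Newton residual tolerance is 1e-8 in reduced units; a
stall below the rounding floor of the 1/h² stencil is accepted as
converged. Ion profiles follow `c± = c₀ e^{∓ψ}` exactly by construction.
Verified properties: superposition of well-separated walls to 1e-4 kT/e,
the linearized cosh profile to 1% at small walls, second-order grid
convergence, and electroneutrality (integrated net ionic charge vs wall
`dψ/dx`) to 0.1%. The module reproduces only the qualitative confinement
physics — a mid-gap field and cation depletion across a 3 nm, 50 mM gap —
not the 3D protein electrostatics of the source study.

## Problem sizes and determinism

Default study sizes follow the reference acquisition: 150 retraction curves
per condition, 80 curves per gate over 9 gates at 200 mV bias, 30 approach
curves, 20 low-noise curves for periodicity. All generators consume numpy
`Generator` streams spawned per curve from a single `SeedSequence`, so a
fixed seed reproduces any ensemble bit-for-bit, and the pipeline's JSON
report is byte-identical across reruns of the same config.

## Known limitations

* The generator's noise model is stationary and uncorrelated in z; real
  sweeps show drift and occasional contact artifacts, so real-data means
  may need robust estimators the synthetic tests never exercise.
* Leakage estimation assumes the sweep tail is asymptotic; β ≲ 0.3 nm⁻¹
  curves over 15 nm violate this and are flagged rather than corrected.
* The square-barrier prefactor ignores image-potential and trapezoidal
  corrections; Φ values are "apparent" barriers.
* The gate mapping `Vg = −U_S` is a convention, not a measured calibration.
* No mechanistic rate theory (Marcus/hopping) is fitted anywhere; the
  gating well is phenomenological.
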