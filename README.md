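# ectspec

Analysis and forward simulation of **electrochemical tunneling spectroscopy
(ECTS) current–distance curves** — the measurement that probes how far
electrons travel through aqueous solution between redox partner proteins
(e.g. cytochrome c and cytochrome c₁) held on the probe and sample
electrodes of an electrochemical STM under bipotentiostatic control.

It is written for single-molecule bioelectrochemists who need to turn raw
I-z ensembles into the field's standard observables, and for anyone who
wants a tested, seedable forward model of the measurement itself.

## What it computes

For each I-z curve `I(z) ≈ I_leak + I₀ e^{−βz}`:

* **Distance decay factor β (nm⁻¹)** — leakage-subtracted log-linear fit
  over an automatically selected window clear of the faradaic leakage floor
  and amplifier saturation; ensemble histograms and mean ± SD
  (`ectspec.decay`).
* **Local barrier height** `Φ_local = (ħ²/8mₑ)(d ln I/dz)² ≈
  0.00952 eV·nm²·β²` as a profile along the gap, plus detection of the
  ~0.35 nm spatial periodicity left by successive water layers
  (`ectspec.barrier`).
* **Electrochemical gating** — β vs EC gate potential at constant bias,
  resonance-minimum localization, on/off ratios, and conversion to the
  absolute energy scale `E(eV) = −U(V vs SSC) − 4.6`
  (`ectspec.gating`).
* **Diffuse-double-layer electrostatics** — Debye length, the exact
  Gouy–Chapman single-wall profile, and a nonlinear 1D Poisson–Boltzmann
  solver `ψ'' = κ² sinh ψ` for the ion-depleted gap between two proteins
  (`ectspec.electrostatics`).
* **A forward model** of the acquisition (0.4 nA set point, 15 nm/1024-point
  retraction at 20 samples per point, 10 nA saturation, pA leakage,
  curve-to-curve β dispersion, optional oscillatory barrier and gate
  response) with shipped presets for every experimental condition
  (`ectspec.synthetic`).

Curves are stored in **ectsv**, a plain-text format with `# key = value`
headers, tab-separated `z_nm  I_A` rows and `# ---` separators
(`ectspec.curve_io`).

## Worked example

Simulate 150 protein-pair curves, fit every one, and summarize:

```bash
$ ectspec simulate --preset pCc1_hCc --n 150 --seed 7 --out pcc1.ectsv
wrote pcc1.ectsv
$ ectspec fit --in pcc1.ectsv --out pcc1_fits.tsv
{
  "beta_mean_nm": 1.4921245393850873,
  "beta_sd_nm": 0.6810574123793265,
  "n": 147
}
$ ectspec debye --conc-mm 100
0.9617
```

The summary says the ensemble decay factor is β = 1.49 ± 0.68 nm⁻¹ over
147 usable curves (3 of 150 were quality-flagged and excluded) — the
slow, several-nanometre decay characteristic of the specific partner pair,
an order of magnitude below the ~9 nm⁻¹ of a bare-gold junction. The last
command reports the Debye screening length at 100 mM: 0.96 nm, the scale
against which any longer-ranged field must be explained. Per-curve results
land in `pcc1_fits.tsv` (curve_id, condition, potentials, β, I₀, leakage,
r², flags).

The same works from Python:

```python
from ectspec import (get_preset, make_curve_set, fit_curve_set,
                     summarize_beta)

cs = make_curve_set(get_preset("pCc1_hCc"), 150, seed=7)
print(summarize_beta(fit_curve_set(cs)))
# beta = 1.49 +/- 0.68 nm^-1 (n = 147)
```

A full run (four conditions + gating + periodicity + Debye length, with a
validated JSON report) is `ectspec run --out-dir out/ --seed 1`, or
`run_pipeline(RunConfig(...))` from Python.

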