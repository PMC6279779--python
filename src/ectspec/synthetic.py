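"""Forward model of the I-z measurement for every experimental condition.

The raw tunneling-spectroscopy ensembles this package analyses are not
publicly deposited, so the downstream estimators are exercised against a
generative model of the acquisition:

* ideal current ``I*(z) = I_leak + (I_set - I_leak) * exp(-beta * z)``
  on a uniform piezo grid (15 nm / 1024 points retraction, 100 nm / 4096
  points approach, matching the reference acquisition settings);
* per-curve decay constants drawn from a truncated Normal(beta_mean,
  beta_sd) - the histograms of real experiments reflect curve-to-curve
  spread, not point noise;
* each reported point is the mean of ``samples_per_point`` noisy draws
  (lognormal multiplicative x additive Gaussian), clipped to the 10 nA
  amplifier ceiling;
* an optional oscillatory barrier Phi(z) (water layering) replaces the
  constant decay by ``exp(-integral of beta_eff(s) ds)`` with
  ``beta_eff = slope_from_barrier(Phi)``, so the local log-slope equals
  beta_eff(z) exactly;
* an optional :class:`GatingModel` makes the generative beta depend on the
  EC gate potential through a Gaussian resonance well.

All randomness flows through numpy Generators; curve sets spawn one child
stream per curve from a single seed, so a fixed seed reproduces a set
bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace
from typing import Mapping, Sequence, Union

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .barrier import slope_from_barrier
from .curve_io import APPROACH, MODES, RETRACTION, CurveSet, IZCurve
from .gating import neg_Us

#: curve-level decay constants are truncated here to avoid non-decaying curves
BETA_FLOOR = 0.05  # nm^-1

RngLike = Union[int, np.random.SeedSequence, np.random.Generator]


class PresetError(ValueError):
    """Invalid simulation preset."""


@dataclass(frozen=True)
class OscillationSpec:
    """Oscillatory local barrier: water layering in the gap.

    The barrier profile is ``Phi(z) = mid + amp * cos(2 pi z / period)``
    between ``phi_low`` and ``phi_high`` (eV), with the 0.35 nm default
    period of successive water layers.
    """

    period: float = 0.35  # nm
    phi_low: float = 0.5  # eV
    phi_high: float = 1.2  # eV

    def __post_init__(self) -> None:
        if not self.period > 0:
            raise PresetError("oscillation period must be positive")
        if not (0 <= self.phi_low < self.phi_high):
            raise PresetError("need 0 <= phi_low < phi_high")

    def phi(self, z: np.ndarray) -> np.ndarray:
        mid = 0.5 * (self.phi_high + self.phi_low)
        amp = 0.5 * (self.phi_high - self.phi_low)
        return mid + amp * np.cos(2.0 * np.pi * z / self.period)


@dataclass(frozen=True)
class GatingModel:
    """Gaussian resonance well of beta vs the EC gate potential.

    beta(Vg) = beta_off - (beta_off - beta_min) * exp(-(Vg - V0)^2 / 2 width^2)

    ``active=False`` represents gating far from resonance (e.g. 500 mV
    bias), where beta stays at ``beta_off`` for every gate.  The midpoint
    redox potentials of the partner proteins are carried as constants for
    reporting.
    """

    beta_off: float = 3.5  # nm^-1
    beta_min: float = 0.5  # nm^-1
    V0: float = -0.25  # V, resonance gate potential
    width: float = 0.03  # V
    E0_pCc1: float = 0.28  # V vs SSC
    E0_hCc: float = 0.35  # V vs SSC
    active: bool = True

    def __post_init__(self) -> None:
        if not (self.beta_off > self.beta_min > 0):
            raise PresetError("need beta_off > beta_min > 0")
        if not self.width > 0:
            raise PresetError("gating width must be positive")


def beta_at_gate(model: GatingModel, Vg: float) -> float:
    """Generative decay constant at EC gate potential ``Vg`` (V)."""
    if not model.active:
        return model.beta_off
    well = math.exp(-0.5 * ((Vg - model.V0) / model.width) ** 2)
    return model.beta_off - (model.beta_off - model.beta_min) * well


@dataclass(frozen=True)
class SimPreset:
    """Complete generative description of one experimental condition."""

    beta_mean: float  # nm^-1, generative decay constant
    beta_sd: float  # nm^-1, curve-to-curve spread
    leakage: float = 2e-12  # A, faradaic floor ("below a few pA")
    set_point: float = 0.4e-9  # A
    saturation: float = 10e-9  # A, amplifier ceiling
    z_span: float = 15.0  # nm
    n_points: int = 1024
    samples_per_point: int = 20
    noise_mult_sigma: float = 0.15  # lognormal sigma on each draw
    noise_add_sigma: float = 0.5e-12  # A, additive noise on each draw
    oscillation: OscillationSpec | None = None
    gating: GatingModel | None = None
    mode: str = RETRACTION
    condition: str = "unknown"
    U_P: float = 0.6  # V vs SSC
    U_S: float = -0.2  # V vs SSC
    speed: float = 12.0  # nm/s

    def __post_init__(self) -> None:
        if not self.beta_mean > 0:
            raise PresetError("beta_mean must be positive")
        if self.beta_sd < 0:
            raise PresetError("beta_sd must be non-negative")
        if not (0 < self.leakage < self.set_point < self.saturation):
            raise PresetError("need 0 < leakage < set_point < saturation")
        if self.n_points < 16:
            raise PresetError("n_points must be >= 16")
        if not self.z_span > 0:
            raise PresetError("z_span must be positive")
        if self.samples_per_point < 1:
            raise PresetError("samples_per_point must be >= 1")
        if self.noise_mult_sigma < 0 or self.noise_add_sigma < 0:
            raise PresetError("noise sigmas must be non-negative")
        if self.mode not in MODES:
            raise PresetError(f"unknown mode {self.mode!r}")


#: Shipped presets for the conditions of the reference experiments.
PRESETS: dict[str, SimPreset] = {
    # bare gold electrodes in 50 mM buffer: beta = 9 +/- 2 nm^-1
    "bare_gold": SimPreset(beta_mean=9.0, beta_sd=2.0, condition="bare_gold"),
    # specific pCc1-hCc partner pair: beta = 1.5 +/- 0.8 nm^-1
    "pCc1_hCc": SimPreset(beta_mean=1.5, beta_sd=0.8, condition="pCc1-hCc"),
    # interaction blocked by saturating WT hCc: beta doubles to 3 +/- 1 nm^-1
    "inhibited": SimPreset(beta_mean=3.0, beta_sd=1.0, condition="pCc1-hCc+WT_hCc"),
    # non-specific hCc-hCc self transfer, roughly double the specific beta
    "self_ET": SimPreset(beta_mean=3.0, beta_sd=1.0, condition="hCc-hCc"),
    # bare gold in pure water: beta like the protein pair, more broadly spread
    "pure_water": SimPreset(beta_mean=1.5, beta_sd=1.5, condition="bare_gold_pure_water"),
    # well-insulated probe, low noise: resolves the 0.35 nm barrier oscillation
    "gold_layering": SimPreset(beta_mean=9.0, beta_sd=0.0, leakage=0.05e-12,
                               noise_mult_sigma=0.02, noise_add_sigma=0.02e-12,
                               oscillation=OscillationSpec(),
                               condition="bare_gold_layering"),
    # EC-gated protein junction at 200 mV bias, red (resonance) condition
    "gated": SimPreset(beta_mean=3.5, beta_sd=0.3, gating=GatingModel(),
                       U_P=0.45, U_S=0.25, condition="pCc1-hCc"),
    # approach sweeps: 100 nm / 4096 points / 35 samples per point
    "approach": SimPreset(beta_mean=1.5, beta_sd=0.8, mode=APPROACH,
                          z_span=100.0, n_points=4096, samples_per_point=35,
                          condition="pCc1-hCc"),
}


def get_preset(name: str, **overrides) -> SimPreset:
    """Look up a shipped preset, optionally overriding fields."""
    try:
        preset = PRESETS[name]
    except KeyError:
        raise PresetError(f"unknown preset {name!r}; "
                          f"choose from {sorted(PRESETS)}") from None
    return replace(preset, **overrides) if overrides else preset


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _draw_beta(preset: SimPreset, rng: np.random.Generator) -> float:
    center = preset.beta_mean
    if preset.gating is not None:
        center = beta_at_gate(preset.gating, neg_Us(preset.U_P, preset.U_S))
    if preset.beta_sd == 0:
        return max(center, BETA_FLOOR)
    for _ in range(1000):
        beta = rng.normal(center, preset.beta_sd)
        if beta >= BETA_FLOOR:
            return float(beta)
    return BETA_FLOOR  # pragma: no cover - sd >> mean pathologies


def make_retraction_curve(preset: SimPreset, seed: RngLike) -> IZCurve:
    """Generate one curve from a preset (retraction or approach mode).

    Retraction curves start at the set-point current at z = 0; approach
    curves start at the amplifier ceiling (the sweep is recorded until
    saturation) and are serialized ascending in z like all curves.
    """
    rng = _as_rng(seed)
    z = np.linspace(0.0, preset.z_span, preset.n_points)
    amp0 = preset.saturation if preset.mode == APPROACH else preset.set_point

    if preset.oscillation is not None:
        beta_eff = slope_from_barrier(preset.oscillation.phi(z))
        attenuation = cumulative_trapezoid(beta_eff, z, initial=0.0)
    else:
        attenuation = _draw_beta(preset, rng) * z
    ideal = preset.leakage + (amp0 - preset.leakage) * np.exp(-attenuation)

    shape = (preset.n_points, preset.samples_per_point)
    draws = ideal[:, None] * rng.lognormal(0.0, preset.noise_mult_sigma, shape)
    draws += rng.normal(0.0, preset.noise_add_sigma, shape)
    I = np.clip(draws.mean(axis=1), 0.0, preset.saturation)

    return IZCurve(z=z, I=I, U_P=preset.U_P, U_S=preset.U_S, mode=preset.mode,
                   condition=preset.condition, speed=preset.speed,
                   set_point=preset.set_point)


make_curve = make_retraction_curve  # mode-agnostic alias


def make_curve_set(preset: SimPreset, n: int, seed: RngLike) -> CurveSet:
    """Generate ``n`` independent curves with child streams spawned from ``seed``."""
    if n < 1:
        raise PresetError(f"need n >= 1 curves, got {n}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    curves = [make_retraction_curve(preset, np.random.default_rng(child))
              for child in ss.spawn(n)]
    provenance = {
        "generator": "ectspec.synthetic.make_curve_set",
        "preset": asdict(preset),
        "n": n,
        "seed": ss.entropy if isinstance(ss.entropy, int) else str(ss.entropy),
    }
    return CurveSet(curves=curves, provenance=provenance)


def make_gating_dataset(model: GatingModel, gates: Sequence[float],
                        n_per_gate: int, preset: SimPreset,
                        seed: RngLike) -> Mapping[float, CurveSet]:
    """One CurveSet per EC gate potential, at the preset's constant bias.

    Per gate the electrode potentials are set to ``U_S = -Vg`` (the default
    gate mapping, inverted) and ``U_P = U_S + bias``; the generative beta
    is centred on :func:`beta_at_gate` with the preset's curve-to-curve
    spread.
    """
    if len(gates) == 0:
        raise PresetError("gates must be non-empty")
    if n_per_gate < 2:
        raise PresetError("need n_per_gate >= 2")
    bias = preset.U_P - preset.U_S
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    out: dict[float, CurveSet] = {}
    for Vg, child in zip(gates, ss.spawn(len(gates))):
        U_S = -float(Vg)
        preset_g = replace(preset, gating=model, U_S=U_S, U_P=U_S + bias)
        out[float(Vg)] = make_curve_set(preset_g, n_per_gate, child)
    return out
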