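"""Electrochemical gating analysis of the distance decay factor.

In bipotentiostatic tunneling spectroscopy the probe and sample potentials
can be swept together at constant bias; this common shift - the
electrochemical (EC) gate - tunes the electrode Fermi levels relative to
the redox levels of the proteins in the junction.  When they align,
electron transfer proceeds in quasi-isoenergetic conditions and the
distance decay factor beta collapses; off resonance beta recovers its
off-state value.  This module aggregates per-curve decay fits by electrode
condition, builds beta-vs-gate series, locates the resonance minimum,
computes on/off ratios and converts SSC potentials to the absolute
(vacuum) energy scale E = -e*U - 4.6 eV.

The quantitative definition of the EC gate axis is an injectable mapping
from (U_P, U_S); the default is Vg = -U_S.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .decay import COL_BETA

#: Work-function offset of the SSC reference on the absolute scale, eV.
ABSOLUTE_SCALE_OFFSET_EV = 4.6

#: Midpoint redox potentials of the partner proteins, V vs SSC.
E0_PCC1 = 0.28
E0_HCC = 0.35

GateMap = Callable[[float, float], float]


def neg_Us(U_P: float, U_S: float) -> float:
    """Default EC gate mapping: Vg = -U_S."""
    return -U_S


class GatingError(ValueError):
    """Inconsistent or insufficient gating data."""


def group_by_condition(fits: pd.DataFrame) -> dict[tuple[float, float], pd.DataFrame]:
    """Group a fits table by electrode condition (U_P, U_S).

    Potentials are rounded to 1 mV before exact-value grouping, so readings
    differing by fractions of a millivolt land in the same group.  Rows with
    a missing potential raise.
    """
    for col in ("U_P_V", "U_S_V", COL_BETA):
        if col not in fits.columns:
            raise GatingError(f"fits table lacks required column {col!r}")
    if fits[["U_P_V", "U_S_V"]].isna().any().any():
        bad = fits.index[fits[["U_P_V", "U_S_V"]].isna().any(axis=1)].tolist()
        raise GatingError(f"rows {bad} are missing an electrode potential")
    groups: dict[tuple[float, float], pd.DataFrame] = {}
    for key, sub in fits.groupby([fits["U_P_V"].round(3), fits["U_S_V"].round(3)]):
        groups[(float(key[0]), float(key[1]))] = sub
    return groups


@dataclass(frozen=True)
class GatingSeries:
    """Ensemble beta statistics indexed by EC gate potential at fixed bias."""

    gate: np.ndarray  # V, sorted ascending
    beta_mean: np.ndarray  # nm^-1
    beta_sd: np.ndarray  # nm^-1
    n: np.ndarray  # unflagged curves per gate
    bias: float  # V, common to every point

    def __len__(self) -> int:
        return int(self.gate.size)


def _unflagged(sub: pd.DataFrame) -> pd.Series:
    if "flags" in sub.columns:
        mask = sub["flags"].fillna("").astype(str) == ""
        sub = sub[mask]
    return sub[COL_BETA]


def gating_series(groups: Mapping[tuple[float, float], pd.DataFrame],
                  gate_map: GateMap = neg_Us) -> GatingSeries:
    """Per-gate mean +/- SD of unflagged beta, sorted by gate potential.

    All groups must share the probe-sample bias to 1e-9 V; a mixed-bias
    collection raises, listing the offending conditions.
    """
    if len(groups) < 2:
        raise GatingError(f"need >= 2 electrode conditions, got {len(groups)}")
    biases = {key: key[0] - key[1] for key in groups}
    ref = next(iter(biases.values()))
    offenders = [key for key, b in biases.items() if abs(b - ref) > 1e-9 + 5e-4]
    # 1 mV rounding of each potential allows ~1 mV bias scatter between groups
    if offenders:
        raise GatingError(f"mixed bias across conditions: {sorted(offenders)}")

    rows = []
    for (U_P, U_S), sub in groups.items():
        betas = _unflagged(sub).to_numpy(dtype=float)
        if betas.size < 2:
            raise GatingError(
                f"condition (U_P={U_P}, U_S={U_S}) has {betas.size} usable fits, need >= 2")
        rows.append((gate_map(U_P, U_S), betas.mean(), betas.std(ddof=1), betas.size))
    rows.sort(key=lambda r: r[0])
    gate, mean, sd, n = (np.array(col) for col in zip(*rows))
    return GatingSeries(gate=gate, beta_mean=mean, beta_sd=sd,
                        n=n.astype(int), bias=float(np.mean(list(biases.values()))))


class GateMinimum(NamedTuple):
    gate_V: float
    beta_min: float  # nm^-1
    at_edge: bool  # True when the argmin sits on the grid boundary


def find_gate_minimum(series: GatingSeries) -> GateMinimum | None:
    """Locate the resonance minimum of a beta-vs-gate series.

    The minimum grid point and its two neighbours are interpolated with a
    parabola; at a grid edge the raw argmin is returned with ``at_edge``
    set.  A flat series - total beta range smaller than the typical per-gate
    SD - yields None ("no minimum"), as for metallic junctions without
    accessible redox levels.
    """
    if len(series) < 3:
        raise GatingError(f"need >= 3 gates, got {len(series)}")
    b = series.beta_mean
    if float(b.max() - b.min()) < float(np.mean(series.beta_sd)):
        return None
    k = int(np.argmin(b))
    if k == 0 or k == len(series) - 1:
        return GateMinimum(float(series.gate[k]), float(b[k]), at_edge=True)
    x = series.gate[k - 1:k + 2]
    y = b[k - 1:k + 2]
    c2, c1, c0 = np.polyfit(x, y, 2)
    if c2 <= 0:  # degenerate neighbourhood; fall back to the grid point
        return GateMinimum(float(series.gate[k]), float(b[k]), at_edge=False)
    xv = -c1 / (2.0 * c2)
    yv = np.polyval([c2, c1, c0], xv)
    return GateMinimum(float(xv), float(yv), at_edge=False)


class OnOffRatio(NamedTuple):
    ratio: float
    sd: float  # propagated from the standard errors of the two gate means


def on_off_ratio(series: GatingSeries, Vg_on: float, Vg_off: float,
                 atol: float = 5e-4) -> OnOffRatio:
    """beta(off gate) / beta(on gate), with propagated uncertainty."""

    def locate(Vg: float) -> int:
        hits = np.flatnonzero(np.isclose(series.gate, Vg, atol=atol))
        if hits.size == 0:
            raise GatingError(f"gate {Vg} V not present in series")
        return int(hits[0])

    i_on, i_off = locate(Vg_on), locate(Vg_off)
    m_on, m_off = series.beta_mean[i_on], series.beta_mean[i_off]
    se_on = series.beta_sd[i_on] / np.sqrt(series.n[i_on])
    se_off = series.beta_sd[i_off] / np.sqrt(series.n[i_off])
    ratio = float(m_off / m_on)
    sd = abs(ratio) * float(np.hypot(se_off / m_off, se_on / m_on))
    return OnOffRatio(ratio=ratio, sd=sd)


def absolute_energy(U):
    """Absolute-scale energy (eV) of a potential U (V vs SSC): E = -U - 4.6."""
    return -1.0 * np.asarray(U, dtype=float) - ABSOLUTE_SCALE_OFFSET_EV if np.ndim(U) \
        else -float(U) - ABSOLUTE_SCALE_OFFSET_EV


def current_ratio_at(z: float, beta_on: float, beta_off: float,
                     set_point: float = 0.4e-9) -> float:
    """Current ratio of on- vs off-resonance exponentials, z nm past the set point.

    Both ideal curves share the set-point current at z = 0, so the set point
    cancels and the ratio is exp((beta_off - beta_on) * z); the parameter is
    kept for interface symmetry with the acquisition constants.
    """
    if z < 0:
        raise ValueError("z must be >= 0 (distance past the set-point position)")
    return float(np.exp((beta_off - beta_on) * z))
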