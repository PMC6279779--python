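"""Diffuse-double-layer electrostatics of the aqueous tunneling gap.

Long-distance current between redox partners requires an electric field
that survives across several nanometres of electrolyte.  In a bulk 1:1
electrolyte the field is screened over the Debye length
``kappa^-1 = sqrt(eps0 eps_r kB T / 2 NA e^2 c0)`` (~1 nm at 100 mM); near
a charged plane the potential follows the exact Gouy-Chapman solution
``psi(z) = 4 atanh(gamma exp(-z kappa))`` with ``gamma = tanh(psi0/4)``.
Between two walls confining an ion-depleted gap the full nonlinear
Poisson-Boltzmann problem

    d^2 psi / dx^2 = kappa^2 sinh(psi),   psi in units of kT/e,

is solved with Dirichlet (fixed-potential) walls by a damped Newton
iteration on a finite-difference grid, with continuation from the
linearized (Debye-Hueckel) solution.  Ion concentrations follow the
Boltzmann relation ``c+- = c0 exp(-+ psi)``, which exhibits the cation
depletion that sustains an extended field across the gap.

Potentials are handled in reduced units of kT/e throughout (25.7 mV per
kT/e at 298 K); :func:`kTe_to_mV` converts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants
from scipy.linalg import solve_banded


class ConvergenceError(RuntimeError):
    """Newton iteration failed; carries the last residual max-norm."""

    def __init__(self, message: str, residual: float):
        self.residual = residual
        super().__init__(f"{message} (last residual {residual:.3e})")


@dataclass(frozen=True)
class ElectrolyteSpec:
    """Bulk 1:1 electrolyte: concentration (mol/L), temperature, permittivity."""

    c0: float = 0.05  # mol/L; 50 mM phosphate buffer as effective 1:1 salt
    T: float = 298.0  # K
    eps_r: float = 78.5

    def __post_init__(self) -> None:
        if not self.c0 > 0:
            raise ValueError("c0 must be positive")
        if not self.T > 0:
            raise ValueError("T must be positive")
        if not self.eps_r > 1:
            raise ValueError("eps_r must exceed 1")


def debye_length(spec: ElectrolyteSpec) -> float:
    """Debye-Hueckel screening length kappa^-1 in nm.

    ~0.304 nm / sqrt(c0[M]) in water at 298 K; about 1 nm at 100 mM.
    """
    num = constants.epsilon_0 * spec.eps_r * constants.k * spec.T
    den = 2.0 * constants.N_A * constants.e ** 2 * 1000.0 * spec.c0
    return float(np.sqrt(num / den) * 1e9)


def kTe_to_mV(T: float = 298.0) -> float:
    """Thermal voltage kB*T/e in mV (25.7 mV at 298 K)."""
    return constants.k * T / constants.e * 1e3


def gouy_chapman_potential(psi0: float, spec: ElectrolyteSpec, z) -> np.ndarray:
    """Exact diffuse-layer potential (kT/e) at distances ``z`` (nm) from one wall.

    psi(z) = 4 atanh(tanh(psi0/4) exp(-z/kappa^-1)); reduces to the
    linearized ``psi0 exp(-z kappa)`` for small psi0.
    """
    z = np.asarray(z, dtype=float)
    gamma = np.tanh(psi0 / 4.0)
    return 4.0 * np.arctanh(gamma * np.exp(-z / debye_length(spec)))


@dataclass
class PBGapSolution:
    """Potential and ion-concentration profiles across a 1D confined gap."""

    z: np.ndarray  # nm across the gap
    psi: np.ndarray  # kT/e
    c_plus: np.ndarray  # mol/L
    c_minus: np.ndarray  # mol/L
    gap_width: float  # nm
    surface_potentials: tuple[float, float]  # kT/e at the (left, right) wall
    residual: float  # max-norm of the discrete PB residual


MAX_WALL_POTENTIAL = 20.0  # kT/e, validated range of the solver


def _linearized_profile(x: np.ndarray, L: float, psiL: float, psiR: float) -> np.ndarray:
    """Debye-Hueckel solution psi'' = psi with Dirichlet walls (x in kappa units)."""
    if L > 30.0:  # sinh overflows; walls decoupled to double precision anyway
        return psiL * np.exp(-x) + psiR * np.exp(-(L - x))
    return (psiL * np.sinh(L - x) + psiR * np.sinh(x)) / np.sinh(L)


def _newton_pb(psi: np.ndarray, h: float, tol: float, max_iter: int) -> tuple[np.ndarray, float]:
    """Damped Newton for the interior unknowns of psi'' = sinh(psi)."""
    n = psi.size
    # rounding floor of the residual: the 1/h^2 difference stencil amplifies
    # last-bit noise of psi, so demanding less than this would never converge
    floor = 64.0 * np.finfo(float).eps * max(1.0, float(np.max(np.abs(psi)))) / h ** 2

    def residual(p: np.ndarray) -> np.ndarray:
        return (p[:-2] - 2.0 * p[1:-1] + p[2:]) / h ** 2 - np.sinh(p[1:-1])

    F = residual(psi)
    norm = float(np.max(np.abs(F))) if F.size else 0.0
    for _ in range(max_iter):
        if norm <= tol:
            return psi, norm
        # tridiagonal Jacobian in solve_banded layout
        m = n - 2
        ab = np.zeros((3, m))
        ab[0, 1:] = 1.0 / h ** 2
        ab[1, :] = -2.0 / h ** 2 - np.cosh(psi[1:-1])
        ab[2, :-1] = 1.0 / h ** 2
        delta = solve_banded((1, 1), ab, -F)
        lam = 1.0
        while lam >= 1.0 / 64.0:
            trial = psi.copy()
            trial[1:-1] += lam * delta
            Ft = residual(trial)
            nt = float(np.max(np.abs(Ft)))
            if nt < norm:
                psi, F, norm = trial, Ft, nt
                break
            lam *= 0.5
        else:
            if norm <= max(tol, floor):
                return psi, norm
            raise ConvergenceError("Newton step stalled", norm)
    if norm <= tol:
        return psi, norm
    raise ConvergenceError(f"no convergence in {max_iter} iterations", norm)


def solve_pb_gap(spec: ElectrolyteSpec, gap_width: float,
                 wall_potentials: tuple[float, float], n_grid: int = 2001,
                 tol: float = 1e-8, max_iter: int = 100) -> PBGapSolution:
    """Solve the nonlinear 1D Poisson-Boltzmann equation between two walls.

    Parameters
    ----------
    gap_width
        Wall separation in nm.
    wall_potentials
        Dirichlet potentials (kT/e) at the left and right wall; the solver
        is validated for magnitudes up to 20 kT/e.
    n_grid
        Number of grid points (>= 50); the scheme is second-order accurate.
    """
    psiL, psiR = (float(v) for v in wall_potentials)
    if not gap_width > 0:
        raise ValueError("gap_width must be positive")
    if n_grid < 50:
        raise ValueError("n_grid must be >= 50")
    if max(abs(psiL), abs(psiR)) > MAX_WALL_POTENTIAL:
        raise ValueError(f"wall potentials beyond +/-{MAX_WALL_POTENTIAL} kT/e "
                         "are outside the validated range")

    kappa_inv = debye_length(spec)  # nm
    L = gap_width / kappa_inv  # reduced gap width
    x = np.linspace(0.0, L, n_grid)
    h = x[1] - x[0]

    # continuation: ramp the boundary values for strongly charged walls,
    # starting each stage from the previous converged interior profile
    scales = [1.0] if max(abs(psiL), abs(psiR)) <= 2.0 else [0.25, 0.5, 0.75, 1.0]
    psi = _linearized_profile(x, L, scales[0] * psiL, scales[0] * psiR)
    res = 0.0
    for s in scales:
        psi[0], psi[-1] = s * psiL, s * psiR
        psi, res = _newton_pb(psi, h, tol, max_iter)

    z = x * kappa_inv
    c_plus = spec.c0 * np.exp(-psi)
    c_minus = spec.c0 * np.exp(psi)
    return PBGapSolution(z=z, psi=psi, c_plus=c_plus, c_minus=c_minus,
                         gap_width=gap_width, surface_potentials=(psiL, psiR),
                         residual=res)


def depletion_summary(sol: PBGapSolution) -> tuple[float, float]:
    """Minimum cation concentration (mol/L) in the gap and its location (nm).

    The grid minimum is refined by parabolic interpolation when interior.
    """
    c = sol.c_plus
    k = int(np.argmin(c))
    if 0 < k < c.size - 1:
        y0, y1, y2 = c[k - 1], c[k], c[k + 1]
        denom = y0 - 2.0 * y1 + y2
        delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
        h = sol.z[1] - sol.z[0]
        return float(y1), float(sol.z[k] + delta * h)
    return float(c[k]), float(sol.z[k])
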