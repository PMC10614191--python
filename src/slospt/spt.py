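"""Scaled particle theory (SPT) for fluids of hard and charged spherocylinders.

A spherocylinder (cylinder of length ``L``, hemispherical caps of diameter
``D``) has core volume ``v_r = pi D^2 L / 4 + pi D^3 / 6`` and shape
parameter ``gamma = 1 + L/D``.  For the isotropic fluid at hard-core volume
fraction ``phi`` with ``y = phi / (1 - phi)``, SPT gives the reduced osmotic
pressure

    Pi~ = Pi v_r / k_B T = y + a(gamma) y^2 + b(gamma) y^3,
    a = 3 gamma (gamma + 1) / (3 gamma - 1),
    b = 12 gamma (2 gamma - 1) / (3 gamma - 1)^2.

The y^2 coefficient makes the second virial coefficient exact for convex
bodies; the cubic coefficient vanishes relative to a^2 in the long-rod limit,
as the Onsager limit requires.  The free volume fraction available to a rod
in its own fluid follows from the SPT insertion work plus the pressure term,

    alpha = (1 - phi) exp( -2a y - (3/2) b y^2 - Pi~ ),

and substituting the SPT pressure makes this fully explicit,

    -ln alpha = -ln(1 - phi) + (1 + 2a) y + (a + 3b/2) y^2 + b y^3.

The two forms are identical by construction (thermodynamic consistency: the
Gibbs–Duhem relation links alpha and the pressure exactly through

    Pi~(phi) = phi (1 - ln alpha) + integral_0^phi ln alpha dphi',

which this module also applies to *measured* alpha(phi) data to extract an
equation of state from simulation).  Charged rods enter through the SLO
effective diameter: the same expressions evaluated at gamma* = 1 + L/D_eff
and the effective volume fraction phi_eff = rho v_r(L, D_eff).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RodGeometry",
    "ThermoCurve",
    "spt_coefficients",
    "spt_pressure",
    "spt_alpha",
    "spt_alpha_from_pressure",
    "charged_pressure",
    "effective_volume_fraction",
    "pressure_from_alpha",
    "isotropic_excluded_volume",
]


@dataclass(frozen=True)
class RodGeometry:
    """Hard-core spherocylinder: length L, diameter D."""

    L: float
    D: float

    def __post_init__(self) -> None:
        if self.L < 0 or self.D <= 0:
            raise ValueError("require L >= 0 and D > 0")

    @property
    def gamma(self) -> float:
        return 1.0 + self.L / self.D

    @property
    def v_r(self) -> float:
        return math.pi * self.D**2 * self.L / 4.0 + math.pi * self.D**3 / 6.0


def isotropic_excluded_volume(L: float, D: float) -> float:
    """Orientation-averaged excluded volume of two identical spherocylinders.

    v_excl = (4 pi / 3) D^3 + 2 pi D^2 L + (pi / 2) L^2 D  (the L^2 term
    carries the isotropic average <sin theta> = pi/4).
    """
    return (4.0 * math.pi / 3.0) * D**3 + 2.0 * math.pi * D**2 * L \
        + (math.pi / 2.0) * L**2 * D


def _check_phi(phi) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0) or np.any(phi >= 1):
        raise ValueError("volume fraction must lie in [0, 1)")
    return phi


def spt_coefficients(gamma: float) -> tuple[float, float]:
    """(a, b) coefficients of the SPT pressure polynomial in y."""
    if gamma < 1:
        raise ValueError("gamma = 1 + L/D must be >= 1")
    a = 3.0 * gamma * (gamma + 1.0) / (3.0 * gamma - 1.0)
    b = 12.0 * gamma * (2.0 * gamma - 1.0) / (3.0 * gamma - 1.0) ** 2
    return a, b


def spt_pressure(phi_r, gamma: float):
    """Reduced osmotic pressure Pi v_r / k_B T of hard spherocylinders."""
    phi = _check_phi(phi_r)
    a, b = spt_coefficients(gamma)
    y = phi / (1.0 - phi)
    return y + a * y**2 + b * y**3


def spt_alpha(phi_r, gamma: float):
    """Free volume fraction for a spherocylinder in its own hard-rod fluid.

    Fully explicit form (SPT pressure substituted into the insertion work).
    """
    phi = _check_phi(phi_r)
    a, b = spt_coefficients(gamma)
    y = phi / (1.0 - phi)
    minus_ln = (-np.log1p(-phi) + (1.0 + 2.0 * a) * y
                + (a + 1.5 * b) * y**2 + b * y**3)
    return np.exp(-minus_ln)


def spt_alpha_from_pressure(phi_r, gamma: float, pi_tilde):
    """Free volume fraction with the reduced pressure supplied explicitly.

    alpha = (1 - phi) exp(-2a y - 1.5 b y^2 - Pi~).  Feeding the SPT pressure
    reproduces :func:`spt_alpha` to machine precision; feeding a measured
    pressure gives the corresponding thermodynamically consistent alpha.
    """
    phi = _check_phi(phi_r)
    a, b = spt_coefficients(gamma)
    y = phi / (1.0 - phi)
    return (1.0 - phi) * np.exp(-2.0 * a * y - 1.5 * b * y**2
                                - np.asarray(pi_tilde, dtype=float))


def effective_volume_fraction(number_density, L: float, D_eff: float):
    """phi_eff = rho * v_r(L, D_eff): volume fraction at the effective diameter."""
    rho = np.asarray(number_density, dtype=float)
    if np.any(rho < 0) or L < 0 or D_eff <= 0:
        raise ValueError("inputs must be non-negative (D_eff strictly positive)")
    return rho * RodGeometry(L, D_eff).v_r


def charged_pressure(phi_eff, gamma_star: float):
    """Reduced pressure of charged rods: SPT with the effective diameter.

    Identical functional form to :func:`spt_pressure`, evaluated at
    gamma* = 1 + L/D_eff and y_eff = phi_eff/(1 - phi_eff).  The returned
    pressure is reduced by the *effective* rod volume v_r(L, D_eff).
    """
    return spt_pressure(phi_eff, gamma_star)


@dataclass
class ThermoCurve:
    """Tabulated thermodynamics: volume fraction, free volume fraction, pressure.

    ``phi`` must be strictly increasing; ``alpha`` in (0, 1]; ``pi_tilde``
    may be absent until filled by :func:`pressure_from_alpha`.
    """

    phi: np.ndarray
    alpha: np.ndarray
    pi_tilde: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.phi.ndim != 1 or self.phi.shape != self.alpha.shape:
            raise ValueError("phi and alpha must be matching 1-d arrays")
        if np.any(np.diff(self.phi) <= 0):
            raise ValueError("phi grid must be strictly increasing")
        if np.any(self.phi < 0) or np.any(self.phi >= 1):
            raise ValueError("phi must lie in [0, 1)")
        if np.any(self.alpha <= 0) or np.any(self.alpha > 1):
            raise ValueError("alpha must lie in (0, 1]")
        if self.pi_tilde is not None:
            self.pi_tilde = np.asarray(self.pi_tilde, dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.phi / (1.0 - self.phi)


def pressure_from_alpha(curve: ThermoCurve, grid_warning_tol: float = 0.05
                        ) -> ThermoCurve:
    """Equation of state from free-volume data by thermodynamic integration.

    Widom's theorem plus Gibbs–Duhem give the exact relation

        Pi~(phi) = phi (1 - ln alpha(phi)) + integral_0^phi ln alpha dphi'.

    The integral is evaluated by the trapezoidal rule on the tabulated grid;
    below the first tabulated point ln alpha is extended linearly from
    (0, 0), which is exact to leading order in density.  Returns a new curve
    with ``pi_tilde`` filled; Pi~(0) = 0 by construction.
    """
    phi, alpha = curve.phi, curve.alpha
    ln_alpha = np.log(alpha)
    if phi[0] > 0:
        phi_ext = np.concatenate([[0.0], phi])
        ln_ext = np.concatenate([[0.0], ln_alpha])
    else:
        phi_ext, ln_ext = phi, ln_alpha
    if np.max(np.diff(phi_ext)) > grid_warning_tol:
        warnings.warn("phi grid is coarse; the trapezoidal integral of "
                      "ln alpha may be inaccurate", UserWarning, stacklevel=2)
    cumulative = np.concatenate([[0.0], np.cumsum(
        0.5 * (ln_ext[1:] + ln_ext[:-1]) * np.diff(phi_ext))])
    integral = cumulative[-len(phi):]
    pi_tilde = phi * (1.0 - ln_alpha) + integral
    return ThermoCurve(phi=phi.copy(), alpha=alpha.copy(), pi_tilde=pi_tilde)
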