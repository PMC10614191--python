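"""Effective hard diameter of charged rods (SLO mapping).

A charged rod behaves, at the second-virial level, like a hard rod with an
enlarged diameter ``D_eff``.  For two rods crossing at angle ``theta`` the
electrostatic repulsion adds, on top of the hard core, a distance

    Delta(theta; d_c) = integral_D^{d_c} [1 - exp(-beta U_c(x, theta))] dx

to the contact diameter, where ``U_c`` is the screened pair repulsion
truncated at ``d_c`` and shifted to vanish there.  Substituting
``t = (A'/sin theta) e^{-kappa (x - D)}`` expresses ``Delta`` through
exponential integrals; with ``a = A'/sin theta`` and ``s = e^{-kappa (d_c - D)}``

    kappa * Delta = kappa (d_c - D) - e^{a s} [ E1(a s) - E1(a) ]

and for an untruncated interaction (d_c -> infinity)

    kappa * Delta = ln a + gamma_E + E1(a).

The orientation-averaged effective diameter weights ``D + Delta(theta)`` by
the excluded-volume factor ``sin theta`` over isotropically distributed axes:

    D_eff = < sin theta (D + Delta) > / < sin theta >.

For strong repulsion (A' >~ 2) and infinite range the average has the closed
form (Euler's constant k_E ~= 0.5772156649)

    D_eff = D + kappa^{-1} [ ln A' + k_E + ln 2 - 1/2 ],

accurate to better than 2.2% relative to the exact integral.  For a finite
cutoff, the threshold cutoff ``d_c^t`` is the smallest ``d_c`` at which the
finite-range effective diameter lies within a stated relative tolerance
(default 2.2%) of the infinite-range value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import exp1, roots_legendre

EULER_GAMMA = 0.5772156649015329

__all__ = [
    "InteractionParams",
    "EffectiveDiameterResult",
    "slo_closed_form",
    "scaled_excluded_volume",
    "exact_effective_diameter",
    "threshold_cutoff",
    "threshold_table",
]


@dataclass(frozen=True)
class InteractionParams:
    """Screened rod–rod interaction: amplitude, screening, hard core, cutoff."""

    A: float
    kappa: float
    D: float
    d_c: float = math.inf

    def __post_init__(self) -> None:
        if self.A <= 0 or self.kappa <= 0 or self.D <= 0:
            raise ValueError("A, kappa and D must be strictly positive")
        if not self.d_c > self.D:
            raise ValueError(f"cutoff d_c={self.d_c} must exceed the diameter D={self.D}")

    @property
    def A_prime(self) -> float:
        return self.A * math.exp(-self.kappa * self.D)


@dataclass(frozen=True)
class EffectiveDiameterResult:
    """Effective diameter plus provenance of how it was computed."""

    D_eff: float
    method: str                      # "slo_closed_form" | "exact_integral"
    d_c_used: float
    rel_diff_vs_infinite: float = float("nan")


def _exp_e1(x: np.ndarray) -> np.ndarray:
    """e^x E1(x), stable for large x (asymptotic series beyond x = 50)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x < 50.0
    out[small] = np.exp(x[small]) * exp1(x[small])
    inv = 1.0 / x[~small]
    out[~small] = inv * (1 - inv * (1 - inv * (2 - inv * (6 - 24 * inv))))
    return out


def _growth_integral(a: np.ndarray) -> np.ndarray:
    """E(a) = int_0^a (1 - e^-t)/t dt = ln a + gamma_E + E1(a), with E(0) = 0."""
    a = np.asarray(a, dtype=float)
    out = np.zeros_like(a)
    pos = a > 0
    out[pos] = np.log(a[pos]) + EULER_GAMMA + exp1(a[pos])
    return out


def scaled_excluded_volume(A_prime: float, kappa: float, D: float,
                           theta, d_c: float = math.inf):
    """kappa * Delta(theta; d_c): scaled electrostatic excluded-volume kernel.

    ``Delta`` is the electrostatic thickening of the contact distance for two
    rods crossing at ``theta`` under the truncated-and-shifted screened
    repulsion with cutoff ``d_c`` (infinite cutoff for the bare interaction).
    Dimensionless, finite and non-negative for all crossing angles;
    ``theta`` must lie strictly inside (0, pi).
    """
    if A_prime <= 0:
        raise ValueError("A_prime must be strictly positive")
    if kappa <= 0 or D <= 0:
        raise ValueError("kappa and D must be strictly positive")
    if not d_c > D:
        raise ValueError("d_c must exceed D")
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0) or np.any(theta >= np.pi):
        raise ValueError("theta must lie strictly in (0, pi): parallel rods "
                         "have a divergent crossing geometry")
    a = A_prime / np.sin(theta)
    if math.isinf(d_c):
        return _growth_integral(a)
    dbar = kappa * (d_c - D)
    b = a * math.exp(-dbar)
    out = np.empty_like(a)
    # Small shifted argument: use the identity
    #   kappa Delta = E(a) - E(b) - (e^b - 1)(E1(b) - E1(a))
    # which is regular as b -> 0 (E(0) = 0, expm1(0) = 0).
    small = b < 1.0
    bs, as_ = b[small], a[small]
    safe = np.where(bs > 0, bs, 1.0)
    corr = np.where(bs > 0, np.expm1(bs) * (exp1(safe) - exp1(as_)), 0.0)
    out[small] = _growth_integral(as_) - _growth_integral(bs) - corr
    # Large shifted argument: exponentially scaled form avoids overflow.
    bl, al = b[~small], a[~small]
    out[~small] = dbar - (_exp_e1(bl) - np.exp(bl - al) * _exp_e1(al))
    return out


# Gauss–Legendre nodes for the orientation average, cached per point count.
_quad_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _theta_quadrature(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _quad_cache:
        nodes, weights = roots_legendre(n)
        # map to (0, pi/2); the integrand is symmetric about pi/2
        _quad_cache[n] = (0.25 * np.pi * (nodes + 1.0), 0.25 * np.pi * weights)
    return _quad_cache[n]


def exact_effective_diameter(A_prime: float, kappa: float, D: float,
                             d_c: float = math.inf, n_theta: int = 400,
                             ) -> EffectiveDiameterResult:
    """Orientation-averaged effective diameter by numerical quadrature.

    Averages ``sin(theta) * (D + Delta(theta; d_c))`` over isotropic axes
    (relative-angle density sin(theta)/2) and divides by ``<sin theta>``:

        D_eff = D + (2/pi) * integral_0^pi sin^2(theta) Delta(theta) dtheta.

    Gauss–Legendre quadrature with ``n_theta`` nodes on (0, pi/2), doubled by
    symmetry; 400 nodes give ~1e-12 relative accuracy for the parameters of
    interest (the sin^2 Jacobian tames the logarithmic theta -> 0 growth).
    """
    th, w = _theta_quadrature(n_theta)
    kernel = scaled_excluded_volume(A_prime, kappa, D, th, d_c)
    integral = 2.0 * np.sum(w * np.sin(th) ** 2 * kernel)
    d_eff = D + (2.0 / np.pi) * integral / kappa
    # quadrature self-check: halving the node count must not move the result
    th2, w2 = _theta_quadrature(n_theta // 2)
    kernel2 = scaled_excluded_volume(A_prime, kappa, D, th2, d_c)
    d_eff2 = D + (2.0 / np.pi) * 2.0 * np.sum(w2 * np.sin(th2) ** 2 * kernel2) / kappa
    if abs(d_eff - d_eff2) > 1e-8 * d_eff:
        raise ArithmeticError(
            f"theta quadrature not converged: n={n_theta} gives {d_eff!r}, "
            f"n={n_theta // 2} gives {d_eff2!r}; increase n_theta")
    return EffectiveDiameterResult(D_eff=float(d_eff), method="exact_integral",
                                   d_c_used=d_c)


def slo_closed_form(A_prime: float, kappa: float, D: float) -> EffectiveDiameterResult:
    """Closed-form effective diameter for an untruncated screened repulsion.

    D_eff = D + kappa^{-1} (ln A' + k_E + ln 2 - 1/2).  Valid for A' >~ 2;
    below that the dropped exponential-integral correction matters and a
    warning is issued (use the exact integral instead).
    """
    if A_prime <= 0:
        raise ValueError("A_prime must be strictly positive")
    if kappa <= 0 or D <= 0:
        raise ValueError("kappa and D must be strictly positive")
    if A_prime < 2.0:
        warnings.warn(
            f"closed-form effective diameter is only accurate for A' >~ 2 "
            f"(got A'={A_prime:.3g}); prefer exact_effective_diameter",
            UserWarning, stacklevel=2)
    d_eff = D + (math.log(A_prime) + EULER_GAMMA + math.log(2.0) - 0.5) / kappa
    return EffectiveDiameterResult(D_eff=float(d_eff), method="slo_closed_form",
                                   d_c_used=math.inf)


def threshold_cutoff(A: float, kappa_d: float, tol: float = 0.022,
                     d_c_max_over_D: float = 1e3) -> float:
    """Smallest cutoff (in units of D) within ``tol`` of the infinite-range limit.

    Finds the smallest ``d_c/D`` for which

        (D_eff(inf) - D_eff(d_c)) / D_eff(d_c) <= tol

    by bisection (the difference decreases monotonically with the cutoff).
    The finite-cutoff exact integral is the reference in the denominator.
    """
    if A <= 0 or kappa_d <= 0:
        raise ValueError("A and kappa_d must be strictly positive")
    if tol <= 0:
        raise ValueError("tol must be strictly positive")
    a_prime = A * math.exp(-kappa_d)
    d_inf = exact_effective_diameter(a_prime, kappa_d, 1.0).D_eff

    def excess(dc: float) -> float:
        d = exact_effective_diameter(a_prime, kappa_d, 1.0, dc).D_eff
        return (d_inf - d) / d - tol

    hi = d_c_max_over_D
    if excess(hi) > 0:
        raise ArithmeticError(
            f"threshold cutoff not bracketed below d_c/D = {d_c_max_over_D}")
    lo = 1.0 + 1e-9
    if excess(lo) <= 0:
        return lo
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if excess(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def threshold_table(A_values, kappa_d_values, tol: float = 0.022) -> pd.DataFrame:
    """Grid of threshold cutoffs and their effective diameters.

    One row per (A, kappa D) pair with columns ``A, kappaD, dct_over_D,
    Deff_over_D`` where ``Deff_over_D`` is the exact finite-cutoff effective
    diameter evaluated at the threshold cutoff.
    """
    A_values = np.atleast_1d(np.asarray(A_values, dtype=float))
    kappa_d_values = np.atleast_1d(np.asarray(kappa_d_values, dtype=float))
    if A_values.size == 0 or kappa_d_values.size == 0:
        raise ValueError("parameter lists must be non-empty")
    rows = []
    for kd in kappa_d_values:
        for A in A_values:
            dct = threshold_cutoff(A, kd, tol=tol)
            a_prime = A * math.exp(-kd)
            deff = exact_effective_diameter(a_prime, kd, 1.0, dct).D_eff
            rows.append({"A": A, "kappaD": kd, "dct_over_D": dct,
                         "Deff_over_D": deff})
    return pd.DataFrame(rows)
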