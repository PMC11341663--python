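"""Axisymmetric equilibrium of the intact (uncracked) aortic ring.

With plane strain and incompressibility the deformation of the annulus is a
one-parameter family: a material circle at reference radius ``rho`` maps to

    r(rho) = sqrt(a^2 - R_in^2 + rho^2),

where ``a`` is the deformed inner radius, and the circumferential stretch is
``lam(rho) = r/rho``.  Radial equilibrium with traction ``-P`` on the inner
wall and zero on the outer wall fixes ``a`` through

    integral_{R_in}^{R_out}  lam * W'(lam) * rho / r^2  d rho  =  P,

since the hoop–radial stress difference of an incompressible plane-strain
material is ``sigma_tt - sigma_rr = lam * W'(lam)``.  The total potential
energy per unit axial length is

    U_I = integral_A W dA  -  P * DeltaA_in,   DeltaA_in = pi (a^2 - R_in^2),

with the strain energy integrated over the reference cross-section (equal to
the deformed one by incompressibility).  Equilibrium is exactly stationarity
of ``U_I(a)`` on this kinematic family, which the oracle module exploits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from scipy.integrate import quad
from scipy.optimize import brentq

from .constitutive import MaterialSpec, StrainLimitError, reduced_energy, reduced_energy_derivative
from .errors import NoEquilibriumError, SolverError
from .geometry import AortaGeometry

__all__ = ["RingState", "solve_normal_ring", "potential_energy_normal"]

_QUAD_OPTS = dict(epsabs=1e-12, epsrel=1e-12, limit=200)


@dataclass(frozen=True)
class RingState:
    """Converged thick-wall solution of the intact ring."""

    geom: AortaGeometry
    mat: MaterialSpec
    p: float
    a: float                       # deformed inner radius
    W_SE: float                    # strain energy per unit axial length
    dA_in: float                   # lumen area change
    U: float                       # total potential energy per unit length
    residual: float                # boundary-condition defect (stress units)

    def lam(self, rho: float) -> float:
        """Circumferential stretch at reference radius rho."""
        return math.sqrt(1.0 + (self.a ** 2 - self.geom.R_in ** 2) / rho ** 2)

    def r(self, rho: float) -> float:
        """Deformed radius of the material circle at reference radius rho."""
        return math.sqrt(self.a ** 2 - self.geom.R_in ** 2 + rho ** 2)

    def radial_stress(self, rho: float) -> float:
        """sigma_rr at reference radius rho (equals -p at R_in, 0 at R_out)."""
        val, _ = quad(
            lambda s: _stress_diff_integrand(s, self.a, self.geom.R_in, self.mat),
            self.geom.R_in,
            rho,
            **_QUAD_OPTS,
        )
        return -self.p + val

    def hoop_stress(self, rho: float) -> float:
        """sigma_tt at reference radius rho."""
        lam = self.lam(rho)
        return self.radial_stress(rho) + lam * reduced_energy_derivative(self.mat, lam)


def _stress_diff_integrand(rho: float, a: float, R_in: float, mat: MaterialSpec) -> float:
    r2 = a * a - R_in * R_in + rho * rho
    lam = math.sqrt(r2) / rho
    return lam * reduced_energy_derivative(mat, lam) * rho / r2


def _pressure_of_a(a: float, geom: AortaGeometry, mat: MaterialSpec) -> float:
    """Inner pressure that equilibrates the ring whose deformed inner radius is a."""
    val, _ = quad(
        lambda s: _stress_diff_integrand(s, a, geom.R_in, mat),
        geom.R_in,
        geom.R_out,
        **_QUAD_OPTS,
    )
    return val


def strain_energy_per_length(a: float, geom: AortaGeometry, mat: MaterialSpec) -> float:
    """W_SE(a): strain energy per unit axial length on the kinematic family."""

    def integrand(rho: float) -> float:
        lam = math.sqrt(1.0 + (a * a - geom.R_in ** 2) / rho ** 2)
        return reduced_energy(mat, lam) * 2.0 * math.pi * rho

    val, _ = quad(integrand, geom.R_in, geom.R_out, **_QUAD_OPTS)
    return val


def ring_energy_at(a: float, geom: AortaGeometry, mat: MaterialSpec, p: float) -> float:
    """U_I evaluated at an arbitrary (not necessarily equilibrium) inner radius a.

    Used by the Ritz stationarity oracle; does not invoke any root finding.
    """
    return strain_energy_per_length(a, geom, mat) - p * math.pi * (a * a - geom.R_in ** 2)


def solve_normal_ring(geom: AortaGeometry, mat: MaterialSpec, p: float) -> RingState:
    """Solve the intact-ring equilibrium at inner pressure ``p`` (units of mu).

    Raises
    ------
    NoEquilibriumError
        If the pressure exceeds the ring's limit point (e.g. neo-Hookean at
        ``P > mu * ln(R_out/R_in)``).
    StrainLimitError
        If the Gent strain limit is violated inside the wall while bracketing.
    """
    if p < 0:
        raise ValueError("pressure must be non-negative")
    R_in = geom.R_in
    if p == 0.0:
        return RingState(geom, mat, 0.0, R_in, 0.0, 0.0, 0.0, 0.0)

    def f(a: float) -> float:
        return _pressure_of_a(a, geom, mat) - p

    # bracket: residual is -p at a = R_in and monotone increasing in a
    cap = None
    if mat.kind == "gent":
        # the largest stretch is at the inner wall: lam(R_in) = a / R_in
        cap = mat.lam_max * R_in
    lo = R_in
    step = R_in * 1e-6
    hi = None
    prev = lo
    for _ in range(200):
        cand = prev + step
        if cap is not None and cand >= cap:
            cand = 0.5 * (prev + cap)  # creep toward the strain-limit radius
        try:
            val = f(cand)
        except StrainLimitError:
            raise
        if val > 0.0:
            hi = cand
            break
        lo = prev = cand
        step *= 2.0
        if cap is None and cand > 1e4 * R_in:
            raise NoEquilibriumError(
                f"no equilibrium: pressure P/mu={p / mat.mu:g} above the ring limit point"
            )
    if hi is None:
        raise NoEquilibriumError(
            f"no equilibrium: pressure P/mu={p / mat.mu:g} above the ring limit point"
        )

    try:
        a = brentq(f, lo, hi, xtol=1e-14 * geom.R)
    except Exception as exc:  # pragma: no cover
        raise SolverError(f"ring root finding failed on bracket [{lo:g}, {hi:g}]") from exc

    residual = f(a)
    W_SE = strain_energy_per_length(a, geom, mat)
    dA_in = math.pi * (a * a - R_in * R_in)
    U = W_SE - p * dA_in
    return RingState(geom, mat, p, a, W_SE, dA_in, U, residual)


def potential_energy_normal(state: RingState, p: float | None = None) -> float:
    """Total potential energy per unit length U_I of a converged ring state."""
    if p is not None and p != state.p:
        return state.W_SE - p * state.dA_in
    return state.U
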