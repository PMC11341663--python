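"""Membrane equilibrium of the dissected aortic cross-section.

The dissected section is modeled as a closed two-segment membrane: the
intact wall of thickness ``H2`` over the angle ``2*pi - 2*alpha_lim`` and the
false-lumen wall remnant of thickness ``H1`` over the crack angle
``2*alpha_lim``.  Both surfaces carry the same internal pressure (blood fills
the false lumen), and the intimal flap transmits no force, so the two
segments must meet with equal tension and tangent continuity — the deformed
shape is a single circle of radius ``rho`` with piecewise-constant stretch.

Per segment the membrane tension (force per unit axial length) is
``T = H_i * W'(lam_i)`` and the in-plane Laplace relation gives
``T = P * rho``.  Eliminating ``rho`` leaves one scalar closure equation in T:

    g(T) = lam_1(T) * L1 + lam_2(T) * L2 - 2*pi*T/P = 0,

with ``lam_i = invert_tension(mat, T / H_i)`` and reference arc lengths
``L1 = 2*alpha_lim*R_fl`` (FL wall, measured at its mid-surface) and
``L2 = (2*pi - 2*alpha_lim)*R`` (intact wall mid-surface).

The total potential energy uses the area enclosed by the *inner* wall
surfaces in both configurations (deformed thicknesses ``h_i = H_i / lam_i``):

    U_II = W(lam1) H1 L1 + W(lam2) H2 L2 - P * DeltaA_in
    DeltaA_in = (pi - a)(rho - h2/2)^2 + a (rho - h1/2)^2
                - (pi - a) R_in^2 - a R_c^2,          a = alpha_lim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .constitutive import MaterialSpec, invert_tension, reduced_energy
from .errors import NoEquilibriumError, SolverError
from .geometry import AortaGeometry

__all__ = [
    "MembraneState",
    "solve_dissected_section",
    "potential_energy_dissected",
    "solve_normal_membrane",
]


@dataclass(frozen=True)
class MembraneState:
    """Converged two-segment membrane solution of the dissected section."""

    geom: AortaGeometry
    mat: MaterialSpec
    p: float
    T: float             # membrane tension per unit axial length
    rho: float           # deformed mid-surface radius
    lam_fl: float        # stretch of the false-lumen wall segment (thickness H1)
    lam_wall: float      # stretch of the intact wall segment (thickness H2)
    W_SE: float
    dA_in: float
    U: float
    closure_residual: float


def arc_lengths(geom: AortaGeometry) -> tuple[float, float]:
    """Reference mid-surface arc lengths (L1 of the FL segment, L2 of the wall)."""
    L1 = 2.0 * geom.alpha_lim * geom.R_fl
    L2 = (2.0 * math.pi - 2.0 * geom.alpha_lim) * geom.R
    return L1, L2


def _energy_terms(
    geom: AortaGeometry, mat: MaterialSpec, p: float, lam1: float, lam2: float, rho: float
) -> tuple[float, float, float]:
    """(W_SE, dA_in, U) for given segment stretches and deformed radius."""
    L1, L2 = arc_lengths(geom)
    W_SE = reduced_energy(mat, lam1) * geom.H1 * L1 + reduced_energy(mat, lam2) * geom.H2 * L2
    a = geom.alpha_lim
    h1 = geom.H1 / lam1
    h2 = geom.H2 / lam2
    A_def = (math.pi - a) * (rho - 0.5 * h2) ** 2 + a * (rho - 0.5 * h1) ** 2
    A_ref = (math.pi - a) * geom.R_in ** 2 + a * geom.R_c ** 2
    dA_in = A_def - A_ref
    return W_SE, dA_in, W_SE - p * dA_in


def solve_dissected_section(geom: AortaGeometry, mat: MaterialSpec, p: float) -> MembraneState:
    """Solve the dissected-section membrane equilibrium at pressure ``p``.

    For ``p = 0`` the reference state is returned directly.

    Raises
    ------
    NoEquilibriumError
        If the closure equation has no positive root — e.g. a uniform
        neo-Hookean membrane at ``P/mu >= H/R`` (inflation limit point).
    """
    if p < 0:
        raise ValueError("pressure must be non-negative")
    if p == 0.0:
        return MembraneState(
            geom, mat, 0.0, 0.0, geom.R, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0
        )

    L1, L2 = arc_lengths(geom)

    def g(T: float) -> float:
        lam1 = invert_tension(mat, T / geom.H1)
        lam2 = invert_tension(mat, T / geom.H2)
        return lam1 * L1 + lam2 * L2 - 2.0 * math.pi * T / p

    # g(0) = L1 + L2 > 0; below the limit point g eventually turns negative.
    lo = 0.0
    hi = 0.01 * mat.mu * geom.H2
    found = False
    for _ in range(80):
        if g(hi) < 0.0:
            found = True
            break
        lo = hi
        hi *= 2.0
    if not found:
        raise NoEquilibriumError(
            f"no equilibrium: pressure P/mu={p / mat.mu:g} above the membrane limit point"
        )
    try:
        T = brentq(g, lo, hi, xtol=1e-15 * mat.mu * geom.R)
    except Exception as exc:  # pragma: no cover
        raise SolverError(f"membrane closure root finding failed on [{lo:g}, {hi:g}]") from exc

    lam_fl = invert_tension(mat, T / geom.H1)
    lam_wall = invert_tension(mat, T / geom.H2)
    rho = T / p
    closure_residual = lam_fl * L1 + lam_wall * L2 - 2.0 * math.pi * rho
    W_SE, dA_in, U = _energy_terms(geom, mat, p, lam_fl, lam_wall, rho)
    return MembraneState(geom, mat, p, T, rho, lam_fl, lam_wall, W_SE, dA_in, U, closure_residual)


def potential_energy_dissected(
    state: MembraneState, geom: AortaGeometry | None = None, p: float | None = None
) -> float:
    """Total potential energy per unit length U_II of a converged membrane state."""
    geom = state.geom if geom is None else geom
    p = state.p if p is None else p
    if geom is state.geom and p == state.p:
        return state.U
    return _energy_terms(geom, state.mat, p, state.lam_fl, state.lam_wall, state.rho)[2]


def solve_normal_membrane(geom: AortaGeometry, mat: MaterialSpec, p: float) -> MembraneState:
    """Uniform-membrane solution of the *normal* (uncracked) section.

    Used by the all-membrane consistency mode (``normal_model='membrane'``):
    the intact ring treated as a thin membrane of thickness H2.  Implemented
    as the two-segment solver with both thicknesses equal, which degenerates
    to the classical uniform inflation solution.
    """
    uniform = geom.with_(H1=geom.H2)
    return solve_dissected_section(uniform, mat, p)
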