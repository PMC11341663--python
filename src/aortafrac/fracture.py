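"""Energy release rates for tear propagation in the dissected aorta.

Longitudinal propagation converts a slice of the normal section into a
dissected one at fixed crack angle, so

    G_long = (U_I - U_II(alpha_lim)) / (R_c * 2 * alpha_lim),

with the crack length measured in the stress-free state at the crack-surface
radius ``R_c = R + H2/2 - H1``.  Circumferential propagation widens the crack
angle; an upwind (forward) difference in the crack angle is used:

    G_circ = (U_II(alpha_lim) - U_II(alpha_lim + d_alpha)) / (R_c * 2 * d_alpha),

with ``d_alpha = 4 degrees`` by default.  Results are reported as the
dimensionless ``G / (mu * R)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .constitutive import MaterialSpec
from .errors import NoEquilibriumError
from .geometry import AortaGeometry
from .membrane import solve_dissected_section, solve_normal_membrane
from .ring import solve_normal_ring

__all__ = [
    "DEFAULT_DELTA_ALPHA",
    "EnergyReleaseResult",
    "energy_release_longitudinal",
    "energy_release_circumferential",
    "crack_angle_profile",
]

DEFAULT_DELTA_ALPHA = math.radians(4.0)


@dataclass(frozen=True)
class EnergyReleaseResult:
    """Direction-tagged dimensionless energy release rate G/(mu*R)."""

    direction: str               # 'longitudinal' or 'circumferential'
    G_norm: float                # G / (mu * R)
    U_I_norm: float | None       # U_I / (mu * R^2), longitudinal only
    U_II_norm: float
    inputs: dict = field(default_factory=dict, repr=False)

    def as_row(self) -> dict:
        """Flat record for CSV serialization."""
        row = {"direction": self.direction, "G_over_muR": self.G_norm,
               "U_I": self.U_I_norm, "U_II": self.U_II_norm}
        row.update(self.inputs)
        return row


def _inputs_record(geom: AortaGeometry, mat: MaterialSpec, p: float, delta_alpha=None) -> dict:
    rec = {
        "P_over_mu": p / mat.mu,
        "H2_over_R": geom.H2 / geom.R,
        "H1_over_H2": geom.H1 / geom.H2,
        "alpha_deg": round(math.degrees(geom.alpha_lim), 10),
        "material": mat.kind,
        "Jm": mat.Jm,
        "K1_over_mu": None if mat.K1 is None else mat.K1 / mat.mu,
        "K2": mat.K2,
        "beta_deg": math.degrees(mat.beta),
    }
    if delta_alpha is not None:
        rec["delta_alpha_deg"] = math.degrees(delta_alpha)
    return rec


def _normal_energy(geom: AortaGeometry, mat: MaterialSpec, p: float, normal_model: str) -> float:
    if normal_model == "thick":
        return solve_normal_ring(geom, mat, p).U
    if normal_model == "membrane":
        return solve_normal_membrane(geom, mat, p).U
    raise ValueError(f"unknown normal_model {normal_model!r}; expected 'thick' or 'membrane'")


def energy_release_longitudinal(
    geom: AortaGeometry, mat: MaterialSpec, p: float, normal_model: str = "thick"
) -> EnergyReleaseResult:
    """G/(mu*R) for longitudinal tear propagation at fixed crack angle.

    The normal-section energy U_I always uses the full wall thickness H2; the
    crack length is the reference arc ``R_c * 2 * alpha_lim``.
    """
    try:
        U_I = _normal_energy(geom, mat, p, normal_model)
    except NoEquilibriumError as exc:
        raise NoEquilibriumError(f"normal section: {exc}") from exc
    try:
        U_II = solve_dissected_section(geom, mat, p).U
    except NoEquilibriumError as exc:
        raise NoEquilibriumError(f"dissected section: {exc}") from exc
    crack_len = geom.R_c * 2.0 * geom.alpha_lim
    G = (U_I - U_II) / crack_len
    norm = mat.mu * geom.R
    return EnergyReleaseResult(
        "longitudinal", G / norm, U_I / (norm * geom.R), U_II / (norm * geom.R),
        _inputs_record(geom, mat, p),
    )


def energy_release_circumferential(
    geom: AortaGeometry,
    mat: MaterialSpec,
    p: float,
    delta_alpha: float = DEFAULT_DELTA_ALPHA,
) -> EnergyReleaseResult:
    """G/(mu*R) for circumferential widening of the tear (upwind scheme)."""
    if not geom.alpha_lim + delta_alpha < math.pi:
        raise ValueError("alpha_lim + delta_alpha must stay below pi")
    try:
        U_a = solve_dissected_section(geom, mat, p).U
        U_b = solve_dissected_section(geom.with_(alpha_lim=geom.alpha_lim + delta_alpha), mat, p).U
    except NoEquilibriumError as exc:
        raise NoEquilibriumError(f"dissected section: {exc}") from exc
    G = (U_a - U_b) / (geom.R_c * 2.0 * delta_alpha)
    norm = mat.mu * geom.R
    return EnergyReleaseResult(
        "circumferential", G / norm, None, U_a / (norm * geom.R),
        _inputs_record(geom, mat, p, delta_alpha),
    )


def crack_angle_profile(
    geom: AortaGeometry,
    mat: MaterialSpec,
    p: float,
    direction: str,
    alpha_grid: Sequence[float],
    delta_alpha: float = DEFAULT_DELTA_ALPHA,
    normal_model: str = "thick",
) -> list[EnergyReleaseResult | Exception]:
    """Evaluate G over a grid of crack half-angles (radians).

    Per-point solver failures are returned in place of the result rather than
    aborting the sweep.
    """
    out: list[EnergyReleaseResult | Exception] = []
    for alpha in alpha_grid:
        g = geom.with_(alpha_lim=alpha)
        try:
            if direction == "longitudinal":
                out.append(energy_release_longitudinal(g, mat, p, normal_model))
            elif direction == "circumferential":
                out.append(energy_release_circumferential(g, mat, p, delta_alpha))
            else:
                raise ValueError(f"unknown direction {direction!r}")
        except (NoEquilibriumError,) as exc:
            out.append(exc)
    return out
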