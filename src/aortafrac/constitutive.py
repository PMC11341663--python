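"""Hyperelastic strain-energy laws in plane-strain incompressible form.

The aortic wall is modeled as an incompressible hyperelastic solid deforming
in plane strain, so the principal stretches reduce to a single circumferential
stretch ``lam``::

    lam_theta = lam,   lam_r = 1/lam,   lam_z = 1

Three constitutive laws are supported:

* ``neo_hookean`` — ideal rubber elasticity, ``W = (mu/2)(lam^2 + lam^-2 - 2)``;
* ``gent`` — strain stiffening through chain inextensibility with strain
  limit ``Jm``: ``W = -(mu*Jm/2) * ln(1 - (lam^2 + lam^-2 - 2)/Jm)``;
* ``hgo`` — Holzapfel–Gasser–Ogden-type elastin matrix plus an exponential
  collagen-fiber term governed by ``K1`` (fiber stiffness), ``K2``
  (strain-stiffening exponent) and the mean fiber angle ``beta`` measured
  from the circumferential direction.  The fiber pseudo-invariant is
  ``I = lam^2 cos^2(beta) + sin^2(beta)``; fibers carry load only in
  tension (``I > 1``).

All energies are per unit reference volume.  The hoop–radial stress
difference needed by the equilibrium solvers is ``lam * dW/dlam``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

__all__ = [
    "MaterialSpec",
    "StrainLimitError",
    "neo_hookean",
    "gent",
    "hgo",
    "reduced_energy",
    "reduced_energy_derivative",
    "invert_tension",
]

_KINDS = ("neo_hookean", "gent", "hgo")


class StrainLimitError(ValueError):
    """Gent strain measure reached or exceeded the chain-extensibility limit Jm."""

    def __init__(self, lam: float, lam_max: float, Jm: float):
        self.lam = lam
        self.lam_max = lam_max
        self.Jm = Jm
        super().__init__(
            f"stretch lam={lam:.12g} at or beyond the Gent strain limit "
            f"lam_max={lam_max:.12g} (Jm={Jm:g})"
        )


@dataclass(frozen=True)
class MaterialSpec:
    """Constitutive law selector with its parameters.

    Parameters
    ----------
    kind
        One of ``neo_hookean``, ``gent``, ``hgo``.
    mu
        Shear modulus (stress units; 1 in dimensionless runs).
    Jm
        Gent strain limit (dimensionless); required iff ``kind == 'gent'``.
    K1
        Fiber stiffness (stress units); required iff ``kind == 'hgo'``.
    K2
        Fiber strain-stiffening exponent (dimensionless); required iff
        ``kind == 'hgo'``.
    beta
        Mean fiber angle from the circumferential direction, radians.
        Defaults to pi/4, for which ``I = lam^2/2 + 1/2``.
    """

    kind: str
    mu: float = 1.0
    Jm: float | None = None
    K1: float | None = None
    K2: float | None = None
    beta: float = math.pi / 4

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown material kind {self.kind!r}; expected one of {_KINDS}")
        if not self.mu > 0:
            raise ValueError("mu must be positive")
        if self.kind == "gent":
            if self.Jm is None or not self.Jm > 0:
                raise ValueError("gent requires Jm > 0")
        if self.kind == "hgo":
            if self.K1 is None or self.K1 < 0:
                raise ValueError("hgo requires K1 >= 0")
            if self.K2 is None or not self.K2 > 0:
                raise ValueError("hgo requires K2 > 0")
        if not 0.0 <= self.beta <= math.pi / 2:
            raise ValueError("beta must lie in [0, pi/2]")

    @property
    def lam_max(self) -> float | None:
        """Upper stretch bound for Gent (where the energy diverges); None otherwise.

        The strain measure is ``lam^2 + lam^-2 - 2 = (lam - 1/lam)^2``, so the
        limit solves ``lam - 1/lam = sqrt(Jm)`` in closed form.
        """
        if self.kind != "gent":
            return None
        s = math.sqrt(self.Jm)
        return 0.5 * (s + math.sqrt(self.Jm + 4.0))


def neo_hookean(mu: float = 1.0) -> MaterialSpec:
    return MaterialSpec("neo_hookean", mu=mu)


def gent(Jm: float, mu: float = 1.0) -> MaterialSpec:
    return MaterialSpec("gent", mu=mu, Jm=Jm)


def hgo(K1: float, K2: float, mu: float = 1.0, beta: float = math.pi / 4) -> MaterialSpec:
    return MaterialSpec("hgo", mu=mu, K1=K1, K2=K2, beta=beta)


def _check_lam(lam: float) -> None:
    if lam < 1.0 - 1e-12:
        raise ValueError(f"stretch lam={lam!r} < 1: the wall is never in circumferential compression here")


def _strain_measure(lam: float) -> float:
    # lam1^2 + lam2^2 - 2 with lam2 = 1/lam; equals (lam - 1/lam)^2 >= 0
    return lam * lam + 1.0 / (lam * lam) - 2.0


def reduced_energy(mat: MaterialSpec, lam: float) -> float:
    """Strain energy density W(lam) per unit reference volume at stretch ``lam >= 1``."""
    _check_lam(lam)
    e = _strain_measure(lam)
    if mat.kind == "neo_hookean":
        return 0.5 * mat.mu * e
    if mat.kind == "gent":
        if e >= mat.Jm:
            raise StrainLimitError(lam, mat.lam_max, mat.Jm)
        return -0.5 * mat.mu * mat.Jm * math.log1p(-e / mat.Jm)
    # hgo: isotropic part (lam3 = 1 so the 3-D form reduces to the same e)
    w = 0.5 * mat.mu * e
    c2 = math.cos(mat.beta) ** 2
    I = lam * lam * c2 + (1.0 - c2)
    if I > 1.0:  # fibers only resist tension
        w += (mat.K1 / mat.K2) * math.expm1(mat.K2 * (I - 1.0) ** 2)
    return w


def reduced_energy_derivative(mat: MaterialSpec, lam: float) -> float:
    """dW/dlam (stress units); the hoop–radial stress difference is lam * dW/dlam."""
    _check_lam(lam)
    base = mat.mu * (lam - lam ** -3)
    if mat.kind == "neo_hookean":
        return base
    if mat.kind == "gent":
        e = _strain_measure(lam)
        if e >= mat.Jm:
            raise StrainLimitError(lam, mat.lam_max, mat.Jm)
        return base / (1.0 - e / mat.Jm)
    c2 = math.cos(mat.beta) ** 2
    I = lam * lam * c2 + (1.0 - c2)
    d = base
    if I > 1.0:
        # dW/dI * dI/dlam with dW/dI = 2 K1 (I-1) exp(K2 (I-1)^2), dI/dlam = 2 lam cos^2(beta)
        d += 4.0 * mat.K1 * (I - 1.0) * math.exp(mat.K2 * (I - 1.0) ** 2) * lam * c2
    return d


def invert_tension(mat: MaterialSpec, target: float, rtol: float = 1e-12) -> float:
    """Unique stretch ``lam >= 1`` with ``reduced_energy_derivative(mat, lam) == target``.

    ``dW/dlam`` is zero at ``lam = 1`` and strictly increasing on the valid
    range for all three laws, so the inverse is well defined.  For Gent the
    derivative diverges at ``lam_max``, so a solution exists for any finite
    non-negative target and always lies below ``lam_max``.
    """
    if target < 0:
        raise ValueError("target stress must be non-negative")
    if target == 0.0:
        return 1.0

    def f(lam: float) -> float:
        try:
            return reduced_energy_derivative(mat, lam) - target
        except OverflowError:
            # hgo fiber term saturates float range during bracket expansion;
            # any such lam is far above the root
            return 1e308

    lo = 1.0
    if mat.kind == "gent":
        # approach the strain limit from below until the residual turns positive
        lam_max = mat.lam_max
        hi = None
        gap = 0.5 * (lam_max - 1.0)
        for _ in range(200):
            cand = lam_max - gap
            if f(cand) > 0.0:
                hi = cand
                break
            lo = cand
            gap *= 0.5
        if hi is None:  # pragma: no cover - derivative diverges, cannot happen
            raise RuntimeError(f"failed to bracket Gent inverse for target={target:g} in (1, {lam_max:g})")
    else:
        hi = 2.0
        for _ in range(200):
            if f(hi) > 0.0:
                break
            lo = hi
            hi *= 2.0
        else:  # pragma: no cover
            raise RuntimeError(f"failed to bracket inverse tension for target={target:g}; last bracket [{lo:g}, {hi:g}]")
    return brentq(f, lo, hi, xtol=1e-15, rtol=max(rtol, 1e-15))
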