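"""Reference (stress-free) cross-section geometry of the aorta.

The normal aorta is an annular ring of mean radius ``R`` and true-lumen wall
thickness (TLWT) ``H2``.  The dissected section carries a tear spanning the
angle ``2 * alpha_lim`` over which only the false-lumen wall remnant of
thickness (FLWT) ``H1`` remains.  The crack surface sits at radius
``R_c = R + H2/2 - H1`` in the stress-free state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class AortaGeometry:
    """Stress-free cross-section description.

    Parameters
    ----------
    R : mean wall radius (1 in dimensionless runs).
    H2 : true-lumen (full) wall thickness.
    H1 : false-lumen wall thickness, ``0 < H1 <= H2``.
    alpha_lim : crack half-angle in radians; the tear spans ``2*alpha_lim``.
    """

    R: float = 1.0
    H2: float = 0.2
    H1: float = 0.1
    alpha_lim: float = math.radians(30.0)

    def __post_init__(self):
        if not (0 < self.H1 <= self.H2):
            raise ValueError("require 0 < H1 <= H2")
        if not self.H2 < 2 * self.R:
            raise ValueError("require H2 < 2R so the inner radius is positive")
        if not (0 < self.alpha_lim < math.pi):
            raise ValueError("require 0 < alpha_lim < pi")

    @property
    def R_in(self) -> float:
        """Inner wall radius of the intact ring."""
        return self.R - 0.5 * self.H2

    @property
    def R_out(self) -> float:
        """Outer wall radius."""
        return self.R + 0.5 * self.H2

    @property
    def R_c(self) -> float:
        """Crack-surface radius: outer radius minus the FL wall thickness."""
        return self.R + 0.5 * self.H2 - self.H1

    @property
    def R_fl(self) -> float:
        """Mid-surface radius of the false-lumen wall segment."""
        return self.R + 0.5 * self.H2 - 0.5 * self.H1

    def with_(self, **changes) -> "AortaGeometry":
        """Return a copy with the given fields replaced."""
        from dataclasses import replace

        return replace(self, **changes)

    @classmethod
    def from_ratios(
        cls,
        h2_over_r: float,
        h1_over_h2: float,
        alpha_deg: float,
        R: float = 1.0,
    ) -> "AortaGeometry":
        """Build from the dimensionless ratios used throughout the studies."""
        h2 = h2_over_r * R
        return cls(R=R, H2=h2, H1=h1_over_h2 * h2, alpha_lim=math.radians(alpha_deg))
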