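"""Parameter studies: trend sweeps, the safety map, and clinical thresholds.

This module orchestrates the solvers into the figure-style studies a user
actually runs: energy-release-rate curves versus pressure for families of
geometries and materials, G-versus-crack-angle profiles, the pressure/tear-
depth safety map, and the normalization of a measured fracture energy
``Gamma`` (J/m^2) into the dimensionless threshold ``Gamma/(mu*R)`` that the
dimensionless ``G/(mu*R)`` is compared against.

Conventions
-----------
* All sweeps run in dimensionless units (mu = 1, R = 1) and are fully
  deterministic — identical configs give bit-identical outputs.
* "Tear depth" increases as ``H1/H2`` decreases: a deeper tear leaves a
  thinner false-lumen wall.
* Angles are degrees at this interface, radians internally; ``alpha`` is the
  crack half-angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .constitutive import MaterialSpec, gent, hgo, neo_hookean
from .errors import NoEquilibriumError
from .fracture import (
    DEFAULT_DELTA_ALPHA,
    EnergyReleaseResult,
    energy_release_circumferential,
    energy_release_longitudinal,
)
from .geometry import AortaGeometry

__all__ = [
    "DEFAULT_PRESSURE_GRID",
    "DEFAULT_DEPTH_GRID",
    "FIGURE_IDS",
    "SweepSpec",
    "SafetyMap",
    "gamma_over_muR",
    "evaluate_G",
    "run_figure_sweep",
    "check_figure_trends",
    "build_safety_map",
    "critical_pressure",
    "plot_sweep",
    "plot_safety_map",
]

# Pressure and depth grids for the safety map; the published axes are not
# printed, so these cover the ranges the trend figures use.
DEFAULT_PRESSURE_GRID = np.round(np.arange(0.01, 0.1501, 0.005), 10)
DEFAULT_DEPTH_GRID = np.round(np.arange(0.30, 0.9001, 0.05), 10)

# operating point of the safety map: Gent Jm = 1, alpha = 30 deg, H2/R = 0.2
OPERATING_POINT = dict(h2_over_r=0.2, alpha_deg=30.0, Jm=1.0)


def gamma_over_muR(gamma: float, mu: float, radius: float) -> float:
    """Dimensionless fracture-energy threshold ``Gamma / (mu * R)``.

    Parameters are dimensional: ``gamma`` in J/m^2, ``mu`` in Pa, ``radius``
    in m.  With the reported abdominal-aorta values (Gamma = 76 and 51 J/m^2
    longitudinal/circumferential, mu = 157 kPa, R = 20 mm) this gives about
    0.024 and 0.016.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    if not (mu > 0 and radius > 0):
        raise ValueError("mu and radius must be positive")
    return gamma / (mu * radius)


def evaluate_G(
    direction: str,
    p_over_mu: float,
    h2_over_r: float = 0.2,
    h1_over_h2: float = 0.5,
    alpha_deg: float = 30.0,
    mat: MaterialSpec | None = None,
    delta_alpha: float = DEFAULT_DELTA_ALPHA,
    normal_model: str = "thick",
) -> EnergyReleaseResult:
    """Single dimensionless G/(mu*R) evaluation from ratio-style inputs."""
    geom = AortaGeometry.from_ratios(h2_over_r, h1_over_h2, alpha_deg)
    mat = mat if mat is not None else neo_hookean()
    if direction == "longitudinal":
        return energy_release_longitudinal(geom, mat, p_over_mu * mat.mu, normal_model)
    if direction == "circumferential":
        return energy_release_circumferential(geom, mat, p_over_mu * mat.mu, delta_alpha)
    raise ValueError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# figure-style sweeps


@dataclass(frozen=True)
class SweepSpec:
    """Recipe for one figure-style sweep.

    ``varying`` names the parameter swept between curves; ``values`` its grid.
    ``fixed`` holds the remaining scalar parameters.  ``x_axis`` is either
    ``'pressure'`` (G vs P/mu curves) or ``'alpha'`` (G vs crack angle).
    """

    figure: str
    direction: str
    material: str
    varying: str
    values: tuple
    fixed: dict = field(default_factory=dict)
    x_axis: str = "pressure"
    trend: str = "decreasing"  # expected ordering of G with the varying parameter
    # top of the default pressure grid; neo-Hookean sweeps must stay below the
    # membrane limit point of their most compliant curve (e.g. P/mu ~ 0.127
    # for H2/R = 0.15, H1/H2 = 0.5)
    p_max: float = 0.15

    def __post_init__(self):
        if len(self.values) == 0:
            raise ValueError("sweep grid must be non-empty")
        if any(b <= a for a, b in zip(self.values, self.values[1:])):
            raise ValueError("sweep grid must be strictly increasing")


_BASE = dict(h2_over_r=0.2, h1_over_h2=0.5, alpha_deg=30.0)

FIGURE_RECIPES: dict[str, SweepSpec] = {
    "3a": SweepSpec("3a", "longitudinal", "neo_hookean", "h2_over_r", (0.15, 0.20, 0.25),
                    {k: v for k, v in _BASE.items() if k != "h2_over_r"}, p_max=0.12),
    "3b": SweepSpec("3b", "longitudinal", "neo_hookean", "h1_over_h2", (0.3, 0.5, 0.7),
                    {k: v for k, v in _BASE.items() if k != "h1_over_h2"}, p_max=0.13),
    "4a": SweepSpec("4a", "longitudinal", "gent", "Jm", (1.0, 10.0, 100.0), dict(_BASE),
                    trend="increasing"),
    "4b": SweepSpec("4b", "longitudinal", "gent", "h2_over_r", (0.15, 0.20, 0.25),
                    {**{k: v for k, v in _BASE.items() if k != "h2_over_r"}, "Jm": 1.0}),
    "4c": SweepSpec("4c", "longitudinal", "gent", "h1_over_h2", (0.3, 0.5, 0.7),
                    {**{k: v for k, v in _BASE.items() if k != "h1_over_h2"}, "Jm": 1.0}),
    # pressures at which the non-monotonic G(alpha) dip sits inside the
    # 10-160 deg window; below P/mu ~ 0.1 the interior minimum migrates to
    # alpha -> 0 and the profile becomes monotone
    "4d": SweepSpec("4d", "longitudinal", "gent", "p_over_mu", (0.10, 0.125, 0.15),
                    {**{k: v for k, v in _BASE.items() if k != "alpha_deg"}, "Jm": 1.0},
                    x_axis="alpha", trend="increasing"),
    "6a": SweepSpec("6a", "longitudinal", "hgo", "K1_over_mu", (0.0, 0.05, 0.5),
                    {**_BASE, "K2": 1.0}),
    "6b": SweepSpec("6b", "longitudinal", "hgo", "K2", (0.1, 1.0, 10.0),
                    {**_BASE, "K1_over_mu": 0.05}),
}
# 5a-5d and 6c/6d mirror their longitudinal counterparts circumferentially
for _src, _dst in [("4a", "5a"), ("4b", "5b"), ("4c", "5c"), ("4d", "5d"),
                   ("6a", "6c"), ("6b", "6d")]:
    _s = FIGURE_RECIPES[_src]
    FIGURE_RECIPES[_dst] = SweepSpec(_dst, "circumferential", _s.material, _s.varying,
                                     _s.values, dict(_s.fixed), _s.x_axis, _s.trend,
                                     _s.p_max)

FIGURE_IDS = tuple(sorted(FIGURE_RECIPES))

DEFAULT_ALPHA_GRID_DEG = tuple(range(10, 161, 10))


def _material_from(kind: str, params: dict) -> MaterialSpec:
    if kind == "neo_hookean":
        return neo_hookean()
    if kind == "gent":
        return gent(params["Jm"])
    if kind == "hgo":
        return hgo(params["K1_over_mu"], params["K2"])
    raise ValueError(f"unknown material kind {kind!r}")


def default_pressure_grid(figure_id: str, step: float = 0.005) -> np.ndarray:
    """Pressure grid for a figure sweep, capped at the recipe's solvable range."""
    recipe = FIGURE_RECIPES[figure_id]
    return np.round(np.arange(0.01, recipe.p_max + 1e-9, step), 10)


def run_figure_sweep(
    figure_id: str,
    pressure_grid: Sequence[float] | None = None,
    alpha_grid_deg: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Run the sweep for one figure id and return a tidy DataFrame.

    Columns include the varying parameter, the x-axis variable and
    ``G_over_muR``; per-point solver failures are recorded as NaN rows.
    """
    if figure_id not in FIGURE_RECIPES:
        raise KeyError(f"unknown figure id {figure_id!r}; known: {FIGURE_IDS}")
    recipe = FIGURE_RECIPES[figure_id]
    pressures = list(default_pressure_grid(figure_id) if pressure_grid is None else pressure_grid)
    alphas = list(DEFAULT_ALPHA_GRID_DEG if alpha_grid_deg is None else alpha_grid_deg)

    rows = []
    for v in recipe.values:
        params = dict(recipe.fixed)
        params[recipe.varying] = v
        mat = _material_from(recipe.material, params)
        xs = alphas if recipe.x_axis == "alpha" else pressures
        for x in xs:
            kw = dict(
                h2_over_r=params["h2_over_r"],
                h1_over_h2=params["h1_over_h2"],
                alpha_deg=x if recipe.x_axis == "alpha" else params["alpha_deg"],
                mat=mat,
            )
            p = params.get("p_over_mu", x) if recipe.x_axis == "alpha" else x
            try:
                res = evaluate_G(recipe.direction, p, **kw)
                row = res.as_row()
            except NoEquilibriumError as exc:
                row = {"direction": recipe.direction, "G_over_muR": np.nan, "error": str(exc)}
            row["figure"] = figure_id
            row[recipe.varying] = v
            row["x"] = x
            rows.append(row)
    return pd.DataFrame(rows)


def check_figure_trends(figure_id: str, df: pd.DataFrame) -> list[str]:
    """Qualitative ordering checks for a sweep; returns a list of violations."""
    recipe = FIGURE_RECIPES[figure_id]
    failures: list[str] = []
    if recipe.x_axis == "pressure":
        # G strictly increases with pressure along each curve
        for v, sub in df.groupby(recipe.varying):
            g = sub.sort_values("x")["G_over_muR"].to_numpy()
            if not np.all(np.diff(g) > 0):
                failures.append(f"{figure_id}: G not increasing in P at {recipe.varying}={v}")
        # ordering across curves at each pressure
        for x, sub in df.groupby("x"):
            g = sub.sort_values(recipe.varying)["G_over_muR"].to_numpy()
            d = np.diff(g)
            ok = np.all(d > 0) if recipe.trend == "increasing" else np.all(d < 0)
            if not ok:
                failures.append(f"{figure_id}: ordering in {recipe.varying} violated at P={x}")
    else:
        for v, sub in df.groupby(recipe.varying):
            g = sub.sort_values("x")["G_over_muR"].to_numpy()
            if recipe.direction == "circumferential":
                if not np.all(np.diff(g) > 0):
                    failures.append(f"{figure_id}: G vs alpha not increasing at P={v}")
            else:
                i = int(np.argmin(g))
                if not (0 < i < len(g) - 1):
                    failures.append(f"{figure_id}: G vs alpha minimum not interior at P={v}")
    return failures


# ---------------------------------------------------------------------------
# safety map and clinical threshold


@dataclass(frozen=True)
class SafetyMap:
    """G/(mu*R) over a (pressure, tear-depth) grid with unsafe-region masks."""

    pressure_grid: np.ndarray        # P/mu, shape (n_p,)
    depth_grid: np.ndarray           # H1/H2, shape (n_d,)
    G: dict                          # direction -> array (n_p, n_d); NaN where unsolvable
    thresholds: dict                 # direction -> Gamma/(mu*R)

    @property
    def unsafe_mask(self) -> dict:
        """direction -> boolean grid where G >= threshold (tear propagation favored)."""
        return {d: self.G[d] >= self.thresholds[d] for d in self.G}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d, grid in self.G.items():
            mask = self.unsafe_mask[d]
            for i, p in enumerate(self.pressure_grid):
                for j, dep in enumerate(self.depth_grid):
                    rows.append({
                        "direction": d, "P_over_mu": p, "H1_over_H2": dep,
                        "G_over_muR": grid[i, j], "unsafe": bool(mask[i, j]),
                    })
        return pd.DataFrame(rows)


def build_safety_map(
    pressure_grid: Sequence[float] | None = None,
    depth_grid: Sequence[float] | None = None,
    h2_over_r: float = 0.2,
    alpha_deg: float = 30.0,
    mat: MaterialSpec | None = None,
    thresholds: dict | None = None,
    directions: Sequence[str] = ("longitudinal", "circumferential"),
) -> SafetyMap:
    """Evaluate G/(mu*R) on a pressure x tear-depth grid (Gent Jm=1 by default).

    Default thresholds are the abdominal-aorta values Gamma/(mu*R) = 0.024
    (longitudinal) and 0.016 (circumferential).  Per-node solver failures are
    recorded as NaN, never fatal.
    """
    p_grid = np.asarray(DEFAULT_PRESSURE_GRID if pressure_grid is None else pressure_grid, float)
    d_grid = np.asarray(DEFAULT_DEPTH_GRID if depth_grid is None else depth_grid, float)
    mat = mat if mat is not None else gent(OPERATING_POINT["Jm"])
    if thresholds is None:
        thresholds = {
            "longitudinal": gamma_over_muR(76.0, 157e3, 0.020),
            "circumferential": gamma_over_muR(51.0, 157e3, 0.020),
        }
    G = {}
    for direction in directions:
        grid = np.full((len(p_grid), len(d_grid)), np.nan)
        for i, p in enumerate(p_grid):
            for j, dep in enumerate(d_grid):
                try:
                    grid[i, j] = evaluate_G(direction, p, h2_over_r, dep, alpha_deg, mat).G_norm
                except NoEquilibriumError:
                    pass
        G[direction] = grid
    return SafetyMap(p_grid, d_grid, G, {d: thresholds[d] for d in directions})


def critical_pressure(
    threshold: float,
    direction: str = "longitudinal",
    depth_grid: Sequence[float] | None = None,
    h2_over_r: float = 0.2,
    alpha_deg: float = 30.0,
    mat: MaterialSpec | None = None,
    scope: str = "onset",
    p_bracket: tuple[float, float] = (1e-3, 1.0),
    tol: float = 1e-3,
) -> float:
    """Minimal P/mu at which G/(mu*R) reaches ``threshold`` over a tear-depth grid.

    ``scope='onset'`` (default) returns the pressure at which the unsafe
    region first appears, i.e. G >= threshold for *at least one* depth in the
    grid — this is where the G = Gamma contour enters the safety map, the
    quantity the published threshold statement refers to.  ``scope='all'``
    instead requires G >= threshold at *every* depth (worst-case tear), which
    is far higher since G vanishes as H1/H2 -> 1.

    Bisection on P to ``tol``; raises NoEquilibriumError ("above solvable
    range") if the threshold is not reached below the bracket top / membrane
    limit point.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if scope not in ("onset", "all"):
        raise ValueError("scope must be 'onset' or 'all'")
    depths = np.asarray(DEFAULT_DEPTH_GRID if depth_grid is None else depth_grid, float)
    mat = mat if mat is not None else gent(OPERATING_POINT["Jm"])
    agg = np.max if scope == "onset" else np.min

    def f(p: float) -> float:
        vals = []
        for dep in depths:
            vals.append(evaluate_G(direction, p, h2_over_r, dep, alpha_deg, mat).G_norm)
        return agg(vals) - threshold

    lo, hi = p_bracket
    if f(lo) >= 0:
        return lo
    try:
        f_hi = f(hi)
    except NoEquilibriumError:
        raise NoEquilibriumError("critical pressure above solvable range (membrane limit point)")
    if f_hi < 0:
        raise NoEquilibriumError("critical pressure above solvable range (bracket top)")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) >= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# plotting (SVG/PNG; headless-safe)


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_sweep(df: pd.DataFrame, figure_id: str, path: str) -> None:
    """Plot a figure-style sweep to ``path`` (format from the extension)."""
    plt = _pyplot()
    recipe = FIGURE_RECIPES[figure_id]
    fig, ax = plt.subplots(figsize=(5, 4))
    for v, sub in df.groupby(recipe.varying):
        sub = sub.sort_values("x")
        ax.plot(sub["x"], sub["G_over_muR"], marker="o", ms=3, label=f"{recipe.varying}={v:g}")
    ax.set_xlabel("crack half-angle [deg]" if recipe.x_axis == "alpha" else r"$P/\mu$")
    ax.set_ylabel(r"$G/(\mu R)$")
    ax.set_title(f"{recipe.direction} tear propagation ({recipe.material})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_safety_map(smap: SafetyMap, path: str) -> None:
    """Contour plot of G/(mu*R) with the unsafe region shaded."""
    plt = _pyplot()
    dirs = list(smap.G)
    fig, axes = plt.subplots(1, len(dirs), figsize=(5 * len(dirs), 4), squeeze=False)
    D, P = np.meshgrid(smap.depth_grid, smap.pressure_grid)
    for ax, d in zip(axes[0], dirs):
        cs = ax.contourf(D, P, smap.G[d], levels=12, cmap="viridis")
        fig.colorbar(cs, ax=ax, label=r"$G/(\mu R)$")
        thr = smap.thresholds[d]
        ax.contourf(D, P, smap.G[d], levels=[thr, np.inf], colors="gray", alpha=0.55)
        ax.contour(D, P, smap.G[d], levels=[thr], colors="k", linewidths=1.5)
        ax.set_xlabel(r"$H_1/H_2$ (deeper tear $\leftarrow$)")
        ax.set_ylabel(r"$P/\mu$")
        ax.set_title(f"{d} (threshold {thr:.3g})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
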