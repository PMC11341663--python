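"""Parameter studies: sweeps, safety map, thresholds, critical pressure."""

import numpy as np
import pytest

from aortafrac.constitutive import gent
from aortafrac.study import (
    FIGURE_IDS,
    build_safety_map,
    check_figure_trends,
    critical_pressure,
    default_pressure_grid,
    gamma_over_muR,
    run_figure_sweep,
)

COARSE_P = (0.04, 0.08, 0.12)  # inside every recipe's solvable pressure range


class TestThresholdArithmetic:
    def test_longitudinal_abdominal_aorta(self):
        # Gamma = 76 J/m^2, mu = 157 kPa, R = 20 mm
        assert gamma_over_muR(76.0, 157e3, 0.020) == pytest.approx(76 / 3140.0)
        assert round(gamma_over_muR(76.0, 157e3, 0.020), 3) == 0.024

    def test_circumferential_abdominal_aorta(self):
        assert round(gamma_over_muR(51.0, 157e3, 0.020), 3) == 0.016

    def test_zero_gamma_and_invalid_inputs(self):
        assert gamma_over_muR(0.0, 157e3, 0.02) == 0.0
        with pytest.raises(ValueError):
            gamma_over_muR(76.0, 0.0, 0.02)
        with pytest.raises(ValueError):
            gamma_over_muR(-1.0, 1.0, 1.0)


class TestFigureSweeps:
    def test_unknown_figure_id(self):
        with pytest.raises(KeyError):
            run_figure_sweep("99x")

    @pytest.mark.parametrize("fid", ["3a", "3b", "4a", "4c", "5c", "6a", "6b"])
    def test_pressure_sweeps_pass_trend_checks(self, fid):
        df = run_figure_sweep(fid, pressure_grid=COARSE_P)
        assert not check_figure_trends(fid, df)

    @pytest.mark.parametrize("fid", ["4d", "5d"])
    def test_angle_sweeps_pass_trend_checks(self, fid):
        df = run_figure_sweep(fid)  # default 10-160 deg grid, 10 deg steps
        assert not check_figure_trends(fid, df)

    def test_default_pressure_grid_respects_limit_points(self):
        # neo-Hookean recipes stay below their membrane limit point
        assert default_pressure_grid("3a").max() <= 0.127
        assert default_pressure_grid("4a").max() == pytest.approx(0.15)

    def test_hgo_without_fibers_coincides_with_neo_hookean(self):
        df6a = run_figure_sweep("6a", pressure_grid=COARSE_P)
        df3 = run_figure_sweep("3b", pressure_grid=COARSE_P)
        k0 = df6a[df6a["K1_over_mu"] == 0.0].sort_values("x")["G_over_muR"].to_numpy()
        nh = df3[df3["h1_over_h2"] == 0.5].sort_values("x")["G_over_muR"].to_numpy()
        np.testing.assert_allclose(k0, nh, rtol=1e-10)


@pytest.fixture(scope="module")
def smap():
    return build_safety_map(
        pressure_grid=np.arange(0.06, 0.151, 0.015),
        depth_grid=np.arange(0.3, 0.91, 0.15),
    )


class TestSafetyMap:

    def test_zero_threshold_marks_everything_unsafe(self, smap):
        from dataclasses import replace

        allbad = replace(smap, thresholds={d: 0.0 for d in smap.thresholds})
        for mask in allbad.unsafe_mask.values():
            assert mask.all()

    def test_unsafe_region_monotone_in_pressure(self, smap):
        for d, mask in smap.unsafe_mask.items():
            # once unsafe at some P, stays unsafe at higher P (per depth column)
            for col in mask.T:
                assert all(b or not a for a, b in zip(col, col[1:]))

    def test_G_grid_monotone_in_depth_and_pressure(self, smap):
        G = smap.G["longitudinal"]
        assert np.all(np.diff(G, axis=0) > 0)      # increasing with P
        assert np.all(np.diff(G, axis=1) < 0)      # decreasing with H1/H2

    def test_boundary_consistent_with_critical_pressure(self, smap):
        # the onset pressure computed independently must split the deepest
        # column of the mask into safe-below / unsafe-above
        thr = smap.thresholds["longitudinal"]
        p_star = critical_pressure(thr, "longitudinal",
                                   depth_grid=smap.depth_grid, tol=1e-3)
        col = smap.unsafe_mask["longitudinal"][:, 0]  # deepest tear column
        for p, unsafe in zip(smap.pressure_grid, col):
            if p < p_star - 1e-3:
                assert not unsafe
            elif p > p_star + 1e-3:
                assert unsafe


class TestCriticalPressure:
    def test_monotone_in_threshold(self):
        depths = (0.3, 0.5)
        p_small = critical_pressure(0.016, depth_grid=depths)
        p_large = critical_pressure(0.024, depth_grid=depths)
        assert p_large > p_small

    def test_tiny_threshold_gives_tiny_pressure(self):
        # mixed thick-wall/membrane fidelity leaves G a small offset near P=0,
        # so the vanishing-threshold limit is ~0.004, not exactly 0
        assert critical_pressure(1e-6, depth_grid=(0.3,), p_bracket=(1e-3, 0.5)) <= 0.01

    def test_scope_all_exceeds_scope_onset(self):
        depths = (0.3, 0.6, 0.9)
        p_any = critical_pressure(0.024, depth_grid=depths, scope="onset")
        p_all = critical_pressure(0.024, depth_grid=depths, scope="all")
        assert p_all > p_any

    def test_unreachable_threshold_reported(self):
        from aortafrac.errors import NoEquilibriumError

        with pytest.raises(NoEquilibriumError, match="above solvable range"):
            critical_pressure(10.0, depth_grid=(0.3,), p_bracket=(1e-3, 0.3))
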