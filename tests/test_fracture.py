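"""Energy release rates for longitudinal and circumferential tear propagation."""

import math

import pytest

from aortafrac.constitutive import gent, hgo, neo_hookean
from aortafrac.fracture import (
    crack_angle_profile,
    energy_release_circumferential,
    energy_release_longitudinal,
)
from aortafrac.geometry import AortaGeometry


def G_long(p, h2r=0.2, depth=0.5, alpha=30.0, mat=None):
    mat = mat or neo_hookean()
    return energy_release_longitudinal(AortaGeometry.from_ratios(h2r, depth, alpha), mat, p).G_norm


def G_circ(p, h2r=0.2, depth=0.5, alpha=30.0, mat=None, **kw):
    mat = mat or neo_hookean()
    return energy_release_circumferential(
        AortaGeometry.from_ratios(h2r, depth, alpha), mat, p, **kw
    ).G_norm


class TestLongitudinal:
    def test_positive_and_increasing_with_pressure(self, gent1):
        Gs = [G_long(p, mat=gent1) for p in (0.05, 0.1, 0.15)]
        assert all(g > 0 for g in Gs)
        assert Gs[0] < Gs[1] < Gs[2]

    def test_decreases_with_wall_thickness(self):
        assert G_long(0.1, h2r=0.15) > G_long(0.1, h2r=0.25)

    def test_deeper_tears_have_higher_G(self):
        assert G_long(0.1, depth=0.3) > G_long(0.1, depth=0.7)

    def test_strain_stiffening_lowers_G(self):
        g1 = G_long(0.1, mat=gent(1.0))
        g10 = G_long(0.1, mat=gent(10.0))
        g100 = G_long(0.1, mat=gent(100.0))
        gnh = G_long(0.1)
        assert g1 < g10 < g100 < gnh

    def test_gent_large_Jm_matches_neo_hookean_G(self):
        assert G_long(0.1, mat=gent(1e6)) == pytest.approx(G_long(0.1), rel=1e-3)


class TestCircumferential:
    def test_widening_crack_raises_G(self, gent1):
        Gs = [G_circ(0.1, alpha=a, mat=gent1) for a in (30.0, 60.0, 90.0)]
        assert Gs[0] < Gs[1] < Gs[2]

    def test_no_thickness_contrast_gives_zero(self, nh):
        # with H1 = H2 the dissected energy is angle-independent
        assert G_circ(0.1, depth=1.0, mat=nh) == pytest.approx(0.0, abs=1e-10)

    def test_upwind_refinement_consistent(self, gent1):
        g4 = G_circ(0.1, mat=gent1, delta_alpha=math.radians(4.0))
        g2 = G_circ(0.1, mat=gent1, delta_alpha=math.radians(2.0))
        g1 = G_circ(0.1, mat=gent1, delta_alpha=math.radians(1.0))
        # first-order scheme: halving the increment halves the deviation
        assert abs(g2 - g1) < abs(g4 - g1)
        assert abs(g4 - g2) == pytest.approx(2 * abs(g2 - g1), rel=0.3)

    def test_increment_must_keep_angle_below_pi(self, gent1):
        with pytest.raises(ValueError):
            G_circ(0.1, alpha=179.0, mat=gent1)


class TestCrackAngleProfiles:
    def test_longitudinal_profile_has_interior_minimum(self, gent1):
        geom = AortaGeometry.from_ratios(0.2, 0.5, 30.0)
        alphas = [math.radians(a) for a in range(10, 161, 10)]
        res = crack_angle_profile(geom, gent1, 0.1, "longitudinal", alphas)
        Gs = [r.G_norm for r in res]
        i = Gs.index(min(Gs))
        assert 0 < i < len(Gs) - 1
        assert Gs[0] > Gs[i] < Gs[-1]

    def test_circumferential_profile_strictly_increasing(self, gent1):
        geom = AortaGeometry.from_ratios(0.2, 0.5, 30.0)
        alphas = [math.radians(a) for a in range(10, 161, 10)]
        res = crack_angle_profile(geom, gent1, 0.1, "circumferential", alphas)
        Gs = [r.G_norm for r in res]
        assert all(b > a for a, b in zip(Gs, Gs[1:]))

    def test_partial_failures_reported_per_point(self, nh):
        # neo-Hookean near its membrane limit point fails, but the sweep survives
        geom = AortaGeometry.from_ratios(0.2, 1.0, 30.0)
        res = crack_angle_profile(geom, nh, 0.25, "circumferential",
                                  [math.radians(30.0), math.radians(60.0)])
        assert all(isinstance(r, Exception) for r in res)


class TestAnisotropy:
    def test_fiber_stiffness_lowers_G(self):
        for direction_G in (G_long, G_circ):
            g0 = direction_G(0.1, mat=hgo(0.0, 1.0))
            g1 = direction_G(0.1, mat=hgo(0.05, 1.0))
            g2 = direction_G(0.1, mat=hgo(0.5, 1.0))
            assert g0 > g1 > g2

    def test_fiber_stiffening_exponent_lowers_G(self):
        gs = [G_long(0.1, mat=hgo(0.05, k2)) for k2 in (0.1, 1.0, 10.0)]
        assert gs[0] > gs[1] > gs[2]

    def test_weak_fibers_approach_neo_hookean(self):
        assert G_long(0.1, mat=hgo(1e-6, 0.1)) == pytest.approx(G_long(0.1), rel=1e-4)


class TestDimensionalInvariance:
    @pytest.mark.parametrize("c,d", [(2.0, 1.0), (1.0, 3.0), (157e3, 0.02)])
    def test_G_over_muR_invariant_under_rescaling(self, c, d):
        # scale stresses (mu, P) by c and lengths (R, H1, H2) by d
        from aortafrac.constitutive import MaterialSpec

        g1 = AortaGeometry.from_ratios(0.2, 0.5, 30.0)
        g2 = AortaGeometry(R=d, H2=0.2 * d, H1=0.1 * d, alpha_lim=g1.alpha_lim)
        m1 = gent(1.0)
        m2 = MaterialSpec("gent", mu=c, Jm=1.0)
        for fn, kw in [
            (energy_release_longitudinal, {}),
            (energy_release_circumferential, {}),
        ]:
            r1 = fn(g1, m1, 0.1, **kw)
            r2 = fn(g2, m2, 0.1 * c, **kw)
            assert r2.G_norm == pytest.approx(r1.G_norm, rel=1e-8)
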