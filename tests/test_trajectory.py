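"""Air-blown sorting kinematics: worked constants, ODE oracle, monotonicity."""

import math

import numpy as np
import pytest

from seggrade.trajectory import (
    AirBlowParams,
    StallWarning,
    blow_force,
    break_even_mass,
    can_displace,
    crossing_kinematics,
    displacement_envelope,
    post_blow_velocity,
    simulate,
)

from conftest import integrate_crossing


class TestBlowForce:
    def test_worked_constants_with_rounded_pi(self):
        S, F = blow_force(P=0.80e6, r=4e-3, pi_const=3.14)
        assert S * 1e6 == pytest.approx(50.24, abs=0.005)
        assert F == pytest.approx(40.19, abs=0.005)

    def test_exact_pi(self):
        S, _ = blow_force(P=0.80e6, r=4e-3, pi_const="exact")
        assert S * 1e6 == pytest.approx(math.pi * 16, rel=1e-12)
        assert S * 1e6 == pytest.approx(50.265, abs=5e-4)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            blow_force(P=1e5, r=0)

    def test_dimensional_consistency(self):
        # Pa * m^2 = N: halving area at double pressure keeps the force
        _, f1 = blow_force(2e5, 1e-2, pi_const="exact")
        _, f2 = blow_force(4e5, 1e-2 / math.sqrt(2), pi_const="exact")
        assert f1 == pytest.approx(f2)


class TestBreakEven:
    def test_worked_break_even_mass(self):
        m_star = break_even_mass(P=0.80e6, r=4e-3, mu=0.10, g=9.80, pi_const=3.14)
        assert m_star == pytest.approx(41.01, abs=0.005)

    def test_average_mushroom_is_displaceable(self):
        assert can_displace(AirBlowParams(m=0.030))

    def test_boundary_is_strict(self):
        m_star = break_even_mass(P=0.80e6, r=4e-3, mu=0.10, g=9.80, pi_const=3.14)
        assert not can_displace(AirBlowParams(m=m_star))


class TestImpulse:
    def test_no_impulse_no_velocity(self):
        assert post_blow_velocity(F=40.19, dt0=0.0, m=0.030, Vy0=0.0) == 0.0

    def test_hand_computed_velocity(self):
        # 40.19 N * 1 ms / 30 g = 1.3397 m/s (N*s/kg = m/s)
        assert post_blow_velocity(F=40.19, dt0=1e-3, m=0.030) == pytest.approx(1.3397, abs=5e-5)

    def test_zero_impulse_preserves_initial_velocity(self):
        assert post_blow_velocity(F=0.0, dt0=1e-3, m=0.030, Vy0=0.7) == 0.7


class TestCrossing:
    def test_hand_computed_friction_decelerates(self):
        p = AirBlowParams(mu=0.10, g=9.80, W=0.20, Vx=0.10)
        a, vy2, dt1, x = crossing_kinematics(p, Vy1=1.3397, mode="friction_decelerates")
        assert a == pytest.approx(0.98)
        assert vy2 == pytest.approx(math.sqrt(1.3397**2 - 2 * 0.98 * 0.10), abs=1e-4)
        assert vy2 == pytest.approx(1.26444, abs=5e-5)
        assert dt1 == pytest.approx(0.07679, abs=5e-5)
        assert x == pytest.approx(7.679e-3, abs=5e-6)

    def test_zero_belt_speed_no_displacement(self):
        p = AirBlowParams(Vx=0.0)
        for mode in ("as_printed", "friction_decelerates"):
            *_, x = crossing_kinematics(p, Vy1=1.0, mode=mode)
            assert x == 0.0

    def test_low_friction_limit_matches_frictionless_form(self):
        p = AirBlowParams(mu=1e-9, g=9.80, W=0.20, Vx=0.10)
        _, vy2, dt1, x = crossing_kinematics(p, Vy1=1.0, mode="friction_decelerates")
        assert vy2 == pytest.approx(1.0, rel=1e-6)
        assert dt1 == pytest.approx(0.1 / 1.0, rel=1e-6)
        assert x == pytest.approx(0.10 * 0.1, rel=1e-6)

    def test_stall_warning_when_too_slow(self):
        p = AirBlowParams(mu=0.5, g=9.80, W=1.0)
        with pytest.warns(StallWarning):
            _, vy2, _, _ = crossing_kinematics(p, Vy1=0.1, mode="friction_decelerates")
        assert vy2 == 0.0

    def test_as_printed_mode_gains_speed(self):
        p = AirBlowParams(mu=0.10, g=9.80, W=0.20)
        _, vy2, dt1, _ = crossing_kinematics(p, Vy1=1.0, mode="as_printed")
        assert vy2 == pytest.approx(math.sqrt(1.0 + 2 * 0.98 * 0.10))
        assert vy2 > 1.0 and dt1 > 0

    @pytest.mark.parametrize("decelerate", [True, False], ids=["decel", "as-printed"])
    def test_agreement_with_numerical_integrator(self, decelerate):
        rng = np.random.default_rng(23)
        mode = "friction_decelerates" if decelerate else "as_printed"
        for _ in range(20):
            mu = rng.uniform(0.05, 0.4)
            W = rng.uniform(0.1, 0.4)
            vy1 = rng.uniform(0.8, 3.0)
            vx = rng.uniform(0.05, 0.3)
            p = AirBlowParams(mu=mu, g=9.80, W=W, Vx=vx)
            a, vy2, dt1, x = crossing_kinematics(p, Vy1=vy1, mode=mode)
            if decelerate and vy1**2 < 2 * a * W / 2:
                continue  # stall: closed form clips, integrator stops early
            vy2_num, t_num = integrate_crossing(vy1, a, W / 2, decelerate)
            assert vy2 == pytest.approx(vy2_num, rel=1e-3)
            assert dt1 == pytest.approx(t_num, rel=1e-3)
            assert x == pytest.approx(t_num * vx, rel=1e-3)

    def test_monotonicity(self):
        base = AirBlowParams(mu=0.10, g=9.80, W=0.20, Vx=0.10)
        _, _, _, x0 = crossing_kinematics(base, Vy1=1.5)
        # faster belt -> larger displacement (linear)
        fast = AirBlowParams(mu=0.10, g=9.80, W=0.20, Vx=0.20)
        _, _, _, x_fast = crossing_kinematics(fast, Vy1=1.5)
        assert x_fast == pytest.approx(2 * x0)
        # stronger blow -> crosses faster -> smaller displacement
        _, _, _, x_strong = crossing_kinematics(base, Vy1=2.5)
        assert x_strong < x0
        # more friction -> slower crossing -> larger displacement
        rough = AirBlowParams(mu=0.30, g=9.80, W=0.20, Vx=0.10)
        _, _, _, x_rough = crossing_kinematics(rough, Vy1=1.5)
        assert x_rough > x0


class TestEnvelope:
    def test_degenerate_interval(self):
        p = AirBlowParams()
        lo, hi = displacement_envelope(p, 0.030, 0.030)
        assert lo == hi

    def test_heavier_mass_gives_smaller_x_under_fixed_impulse(self):
        p = AirBlowParams()
        lo, hi = displacement_envelope(p, 0.020, 0.050)
        x_light = simulate(AirBlowParams(m=0.020)).X
        x_heavy = simulate(AirBlowParams(m=0.050)).X
        assert (lo, hi) == (min(x_light, x_heavy), max(x_light, x_heavy))
        assert x_heavy > x_light  # slower crossing rides the belt longer

    def test_envelope_linear_in_belt_speed(self):
        p1 = AirBlowParams(Vx=0.10)
        p2 = AirBlowParams(Vx=0.20)
        lo1, hi1 = displacement_envelope(p1, 0.02, 0.05)
        lo2, hi2 = displacement_envelope(p2, 0.02, 0.05)
        assert lo2 == pytest.approx(2 * lo1) and hi2 == pytest.approx(2 * hi1)


def test_simulate_full_chain_consistency():
    p = AirBlowParams(m=0.030, dt0=1e-3)
    res = simulate(p)
    assert res.S_tube == pytest.approx(3.14 * (4e-3) ** 2)
    assert res.F == pytest.approx(p.P * res.S_tube)
    assert res.displaceable
    assert res.Vy1 == pytest.approx(res.F * p.dt0 / p.m)
    assert res.X == pytest.approx(res.dt1 * p.Vx)
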