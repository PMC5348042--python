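"""Force-field terms: printed values, thresholds, gradients, symmetries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axonskel import ModelConfig, ForceField, build_axon, build_free_spectrin
from axonskel.forcefield import (
    CAPTURE_FACTOR,
    INFLEXION_FACTOR,
    STERIC_RADII_SIGMA,
    as_attraction,
    confinement,
    expansion_wall,
    fene_angle,
    harmonic_bond,
    repulsive_lj,
)

TWO16 = 2.0 ** (1.0 / 6.0)


class TestHarmonicBond:
    def test_at_rest(self):
        assert harmonic_bond(1.5, 3.56, 1.5) == (0.0, 0.0)

    def test_one_sigma_stretch(self):
        e, f = harmonic_bond(2.0, 3.56, 1.0)
        assert e == pytest.approx(1.78)
        assert f == pytest.approx(-3.56)

    def test_spectrin_spring_in_SI(self):
        u = ModelConfig().units
        assert u.stiffness_red_to_N_per_m(38.0) == pytest.approx(0.26, rel=0.02)


class TestRepulsiveLJ:
    def test_zero_at_and_beyond_cutoff(self):
        assert repulsive_lj(TWO16, 1.0, 1.0) == pytest.approx((0.0, 0.0), abs=1e-12)
        assert repulsive_lj(5.0, 1.0, 1.0) == (0.0, 0.0)

    def test_curvature_matches_spectrin_spring(self):
        # eps1 = eps/16 makes the curvature at the minimum equal k0 = 3.56
        h = 1e-4
        r0 = TWO16
        e = lambda r: repulsive_lj(r, 1.0 / 16.0, 1.0)[0]
        k = (e(r0 - h) - 2 * e(r0 - 2 * h) + e(r0 - 3 * h)) / h**2
        assert k == pytest.approx(3.56, rel=1e-2)

    @given(st.floats(0.5, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_nonnegative_energy_and_outward_force(self, r):
        e, f = repulsive_lj(r, 1.0, 1.0)
        assert e >= 0.0
        assert f >= 0.0


class TestFeneAngle:
    KB = 3500.0 * 0.03  # ring bending parameter in eps

    def test_zero_at_equilibrium(self):
        theta0 = math.radians(170.77)
        assert fene_angle(theta0, self.KB, theta0, 0.3 * theta0) == (0.0, 0.0)

    def test_small_angle_matches_harmonic(self):
        # 0.01 rad deviation, kb = 3500 kT, dtheta_max = 0.894 rad
        theta0 = math.radians(170.77)
        dth = 0.894
        e, _ = fene_angle(theta0 + 0.01, self.KB, theta0, dth)
        e_kT = e / 0.03
        assert e_kT == pytest.approx(0.5 * (3500.0 / dth) * 1e-4, rel=0.01)

    def test_divergence_at_limit(self):
        theta0 = math.radians(170.77)
        dth = 0.3 * theta0
        e_close, _ = fene_angle(theta0 + 0.999 * dth, self.KB, theta0, dth)
        assert e_close > 100.0
        with pytest.raises(FloatingPointError):
            fene_angle(theta0 + dth, self.KB, theta0, dth)


class TestBreakableJunction:
    SIG = 4.0  # 4 sigma junction scale

    def test_equilibrium_energy_is_minus_eps(self):
        r_eq = TWO16 * self.SIG  # ~ 20 nm
        e, f, state = as_attraction(r_eq, 1, self.SIG)
        assert e == pytest.approx(-1.0)
        assert f == pytest.approx(0.0, abs=1e-12)
        assert state == 1
        assert r_eq * 4.45 == pytest.approx(20.0, rel=2e-3)

    def test_inflexion_distance(self):
        r_inf = INFLEXION_FACTOR * self.SIG * 4.45
        assert r_inf == pytest.approx(22.15, abs=0.03)

    def test_threshold_ordering_and_cycle(self):
        r_eq = TWO16 * self.SIG
        r_inf = INFLEXION_FACTOR * self.SIG
        r_capt = CAPTURE_FACTOR * self.SIG
        assert r_eq < r_inf < r_capt
        # documented state sequence while cycling the distance
        state = 1
        _, _, state = as_attraction(r_eq, state, self.SIG)          # stays intact
        assert state == 1
        _, _, state = as_attraction(r_inf * 1.01, state, self.SIG)  # breaks
        assert state == 0
        e, f, state = as_attraction(r_capt * 1.5, state, self.SIG)  # stays broken
        assert state == 0 and e == 0.0 and f == 0.0
        _, _, state = as_attraction(r_capt * 0.99, state, self.SIG)  # recaptures
        assert state == 1

    def test_repulsive_core_active_when_broken(self):
        e, f, state = as_attraction(
            0.8 * TWO16 * self.SIG, 0, self.SIG, allow_recapture=False
        )
        assert state == 0
        assert e > 0 and f > 0


class TestConfinement:
    CFG = ModelConfig()
    R0S = 217.0 / 4.45
    R0K = 232.0 / 4.45
    KC = 0.1 * 3.56

    def test_spectrin_free_inside(self):
        assert confinement(200.0 / 4.45, 1, self.R0S, self.R0K, self.KC) == (0.0, 0.0)

    def test_ankyrin_zero_at_rest(self):
        assert confinement(self.R0K, 2, self.R0S, self.R0K, self.KC) == (0.0, 0.0)

    def test_spectrin_linear_restoring_outside(self):
        _, f = confinement(218.0 / 4.45, 1, self.R0S, self.R0K, self.KC)
        assert f == pytest.approx(-0.356 * (1.0 / 4.45), rel=1e-9)

    def test_ankyrin_two_sided(self):
        _, f_in = confinement(self.R0K - 1.0, 2, self.R0S, self.R0K, self.KC)
        _, f_out = confinement(self.R0K + 1.0, 2, self.R0S, self.R0K, self.KC)
        assert f_in > 0 > f_out


class TestExpansionWall:
    RC = 217.0 / 4.45

    def test_inactive_wall_is_null(self):
        assert expansion_wall(50.0, 1, None) == (0.0, 0.0)

    def test_zero_force_at_cutoffs(self):
        # spectrin: minimum at rc - rS + 2^(1/6) sigma ~ rc + rS
        rs = 2.5 / 4.45
        _, f = expansion_wall(self.RC + rs, 1, self.RC)
        assert f == pytest.approx(0.0, abs=1e-6)
        # actin: 2^(1/6) * 7 sigma ~ 35 nm = 2 rA
        ra = 17.5 / 4.45
        _, f = expansion_wall(self.RC + ra, 0, self.RC)
        assert f == pytest.approx(0.0, abs=2e-2)

    def test_outward_push_inside_cutoff(self):
        _, f = expansion_wall(self.RC, 1, self.RC)
        assert f > 0

    def test_singularity_raises(self):
        with pytest.raises(FloatingPointError):
            expansion_wall(self.RC - 2.0, 1, self.RC)


def test_steric_radii_close_on_printed_scales():
    s = STERIC_RADII_SIGMA
    assert s[1] + s[1] == pytest.approx(1.0)   # S-S: sigma
    assert s[0] + s[0] == pytest.approx(7.0)   # A-A: 35 nm scale
    assert s[1] + s[2] == pytest.approx(3.0)   # S-K: 15 nm scale
    assert s[0] + s[1] == pytest.approx(4.0)   # A-S: 4 sigma junction core


# ---------------------------------------------------------------------------
# assembled engine
# ---------------------------------------------------------------------------


def _fd_check(system, ff, indices, h=1e-6):
    res = ff.compute(system)
    err = 0.0
    for i in indices:
        for d in range(3):
            p0 = system.pos[i, d]
            system.pos[i, d] = p0 + h
            ff.invalidate_neighbors()
            ep = ff.compute(system).potential
            system.pos[i, d] = p0 - h
            ff.invalidate_neighbors()
            em = ff.compute(system).potential
            system.pos[i, d] = p0
            ff.invalidate_neighbors()
            fd = -(ep - em) / (2 * h)
            err = max(err, abs(fd - res.forces[i, d]) / max(1.0, abs(res.forces[i, d])))
    return err


def test_forces_match_energy_gradient_free_chain():
    cfg = ModelConfig()
    system, topo = build_free_spectrin(cfg)
    system.pos += 0.05 * np.random.default_rng(1).standard_normal(system.pos.shape)
    ff = ForceField(cfg, topo, system)
    assert _fd_check(system, ff, [0, 7, 20, 33, 40]) < 1e-6


def test_forces_match_energy_gradient_small_axon_with_wall():
    # all terms at once: bonds, angles, junctions, sterics, confinement,
    # ring coupling, expansion wall
    cfg = ModelConfig(n_rings=2, filaments_per_gap=3)
    system, topo = build_axon(cfg)
    rng = np.random.default_rng(2)
    system.pos += 0.03 * rng.standard_normal(system.pos.shape)
    ff = ForceField(cfg, topo, system)
    ff.set_wall(216.0)
    idx = list(rng.choice(system.n, size=10, replace=False))
    # h = 1e-5 keeps the finite-difference cancellation error (total energy
    # ~1e5 with the wall engaged) well below the 1e-6 relative tolerance
    assert _fd_check(system, ff, idx, h=1e-5) < 1e-6


def test_momentum_conservation_without_external_fields():
    cfg = ModelConfig()
    system, topo = build_free_spectrin(cfg)
    system.pos += 0.05 * np.random.default_rng(3).standard_normal(system.pos.shape)
    ff = ForceField(cfg, topo, system)
    res = ff.compute(system)
    assert np.abs(res.forces.sum(axis=0)).max() < 1e-10


def test_axon_build_is_near_equilibrium_for_actin():
    cfg = ModelConfig(n_rings=3)
    system, topo = build_axon(cfg)
    ff = ForceField(cfg, topo, system)
    res = ff.compute(system)
    n_actin = system.count(0)
    # rings are built exactly at their bond/angle equilibrium
    assert np.abs(res.forces[:n_actin]).max() < 1e-9
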