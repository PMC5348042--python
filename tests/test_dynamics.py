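"""Integrator and thermostat: exactness, conservation, determinism."""

import numpy as np
import pytest

from axonskel import ModelConfig, ForceField, Simulation, build_free_spectrin
from axonskel.dynamics import instantaneous_temperature, maxwell_boltzmann
from axonskel.model import ParticleSystem, Topology


def _empty_topology(n):
    return Topology(
        bonds=np.empty((0, 2), np.int64),
        bond_type=np.empty(0, np.int8),
        bond_k=np.empty(0),
        bond_r0=np.empty(0),
        angles=np.empty((0, 3), np.int64),
        angle_theta0=np.pi,
        ring_of_actin=np.empty(0, np.int64),
        n_rings=0,
        as_pairs=np.empty((0, 2), np.int64),
        as_state=np.empty(0, np.uint8),
        as_recapture_ok=np.empty(0, np.uint8),
    )


def _two_beads(r=1.5, k=3.56, r0=1.1236, clamp_first=False):
    pos = np.zeros((2, 3))
    pos[1, 2] = r
    mobile = np.ones(2, bool)
    if clamp_first:
        mobile[0] = False
    system = ParticleSystem(
        pos=pos,
        vel=np.zeros((2, 3)),
        kind=np.full(2, 1, np.int8),
        mobile=mobile,
    )
    topo = _empty_topology(2)
    topo.bonds = np.array([[0, 1]], np.int64)
    topo.bond_type = np.array([0], np.int8)
    topo.bond_k = np.array([k])
    topo.bond_r0 = np.array([r0])
    return system, topo


def test_free_particle_moves_uniformly():
    system = ParticleSystem(
        pos=np.zeros((1, 3)),
        vel=np.array([[0.1, -0.2, 0.3]]),
        kind=np.full(1, 1, np.int8),
        mobile=np.ones(1, bool),
    )
    topo = _empty_topology(1)
    cfg = ModelConfig()
    ff = ForceField(cfg, topo, system)
    sim = Simulation(system, topo, ff, config=cfg)
    sim.run(1000, thermostat=False)
    assert np.allclose(system.pos[0], np.array([0.1, -0.2, 0.3]) * 1000 * cfg.dt, atol=1e-10)


def test_two_bead_spring_period():
    # reduced-mass oscillator: T = 2 pi sqrt(mu / k), mu = 1/2; rest length
    # beyond the steric cutoff so only the bond acts
    system, topo = _two_beads(r=1.7, r0=1.5)
    cfg = ModelConfig()
    ff = ForceField(cfg, topo, system)
    sim = Simulation(system, topo, ff, config=cfg)
    seps = []
    sim.run(4000, thermostat=False, observers=[(1, lambda s, x: seps.append(
        float(np.linalg.norm(x.system.pos[1] - x.system.pos[0]))))])
    seps = np.asarray(seps)
    # period from zero crossings of (r - mean)
    x = seps - seps.mean()
    crossings = np.flatnonzero(np.diff(np.sign(x)) != 0)
    periods = 2 * np.diff(crossings) * cfg.dt
    T_expected = 2 * np.pi * np.sqrt(0.5 / 3.56)
    assert np.mean(periods) == pytest.approx(T_expected, rel=0.01)


def test_energy_conservation_without_thermostat():
    cfg = ModelConfig()
    system, topo = build_free_spectrin(cfg)
    ff = ForceField(cfg, topo, system)
    sim = Simulation(system, topo, ff, config=cfg, seed=5)
    sim.run(2000, thermostat=True)  # thermalise first
    rec = sim.run(10_000, thermostat=False, record_stride=100)
    e = rec.total_energy()
    drift = np.abs(e - e[0]).max() / abs(e[0])
    assert drift < 1e-3


def test_berendsen_identity_when_on_target():
    system, topo = _two_beads(clamp_first=True)
    cfg = ModelConfig()
    ff = ForceField(cfg, topo, system)
    sim = Simulation(system, topo, ff, config=cfg, seed=1)
    v0 = system.vel.copy()
    sim._berendsen()  # velocities drawn at the target temperature exactly
    assert np.allclose(system.vel, v0, rtol=1e-12)


def test_berendsen_off_in_long_tau_limit():
    system, topo = _two_beads(clamp_first=True)
    cfg = ModelConfig()
    ff = ForceField(cfg, topo, system)
    sim = Simulation(system, topo, ff, config=cfg, seed=1, tau_steps=1e12)
    system.vel *= 3.0  # far from target
    v0 = system.vel.copy()
    sim._berendsen()
    assert np.allclose(system.vel, v0, rtol=1e-9)


def test_berendsen_reseeds_from_zero_temperature():
    system, topo = _two_beads(clamp_first=True)
    cfg = ModelConfig()
    ff = ForceField(cfg, topo, system)
    sim = Simulation(system, topo, ff, config=cfg, seed=1)
    system.vel[:] = 0.0
    sim._berendsen()
    assert instantaneous_temperature(system) == pytest.approx(0.03, rel=1e-9)


def test_equipartition_on_free_chain():
    cfg = ModelConfig()
    system, topo = build_free_spectrin(cfg)
    ff = ForceField(cfg, topo, system)
    sim = Simulation(system, topo, ff, config=cfg, seed=11)
    sim.run(20_000)
    temps = []
    sim.run(
        80_000,
        observers=[(50, lambda s, x: temps.append(
            instantaneous_temperature(x.system, x.free_rotation)))],
    )
    assert np.mean(temps) == pytest.approx(0.030, abs=0.001)


def test_zero_steps_keeps_initial_frame():
    cfg = ModelConfig()
    system, topo = build_free_spectrin(cfg)
    ff = ForceField(cfg, topo, system)
    sim = Simulation(system, topo, ff, config=cfg, seed=0)
    rec = sim.run(0, record_stride=10)
    assert len(rec.frames) == 1
    assert np.array_equal(rec.frames[0], system.pos)


def test_same_seed_same_trajectory():
    def traj(seed):
        cfg = ModelConfig(seed=seed)
        system, topo = build_free_spectrin(cfg)
        ff = ForceField(cfg, topo, system)
        sim = Simulation(system, topo, ff, config=cfg)
        sim.run(3000)
        return system.pos.copy()

    assert np.array_equal(traj(42), traj(42))
    assert not np.array_equal(traj(42), traj(43))


def test_clamped_beads_do_not_move():
    from axonskel import build_free_ring_filament

    cfg = ModelConfig()
    system, topo = build_free_ring_filament(8, clamped=True, config=cfg)
    ff = ForceField(cfg, topo, system)
    sim = Simulation(system, topo, ff, config=cfg, seed=3)
    p0 = system.pos[:2].copy()
    sim.run(5000)
    assert np.array_equal(system.pos[:2], p0)
    assert np.any(system.pos[2:, :2] != 0.0)  # free end fluctuates


def test_maxwell_boltzmann_exact_temperature():
    cfg = ModelConfig()
    system, topo = build_free_spectrin(cfg)
    maxwell_boltzmann(system, 0.03, np.random.default_rng(0), free_rotation=True)
    assert instantaneous_temperature(system, free_rotation=True) == pytest.approx(0.03, rel=1e-12)
    # rigid-body components removed
    assert np.abs(system.vel.mean(axis=0)).max() < 1e-12
    r = system.pos - system.pos.mean(axis=0)
    L = np.sum(np.cross(r, system.vel), axis=0)
    assert np.abs(L).max() < 1e-10
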