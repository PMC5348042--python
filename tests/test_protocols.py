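"""Measurement protocols: fast correctness checks and cross-validations.

The full-scale acceptance measurements live in test_acceptance.py; here the
protocols run on reduced systems/windows to check their mechanics.
"""

import numpy as np
import pytest

from axonskel import ModelConfig, make_preset
from axonskel.protocols import (
    bending_rigidity,
    channel_density,
    free_filament_stats,
    lacerate_and_watch,
    make_simulation,
    prepare_axon,
    radial_expansion,
)


# ---------------------------------------------------------------------------
# channel density (pure geometry)
# ---------------------------------------------------------------------------


def test_channel_density_matches_physiology():
    rho = channel_density(ModelConfig(n_rings=2))
    assert rho == pytest.approx(150.0, rel=0.05)
    assert 110.0 <= rho <= 300.0


def test_channel_density_intensive_in_rings():
    assert channel_density(ModelConfig(n_rings=2)) == pytest.approx(
        channel_density(ModelConfig(n_rings=5)), rel=1e-12
    )


def test_channel_density_zero_filaments():
    assert channel_density(ModelConfig(filaments_per_gap=0)) == 0.0


# ---------------------------------------------------------------------------
# free filament statistics
# ---------------------------------------------------------------------------


def test_free_filament_requires_enough_samples():
    with pytest.raises(ValueError):
        free_filament_stats(production_steps=2000, equil_steps=100, sample_stride=200)


def test_md_sampling_agrees_with_mc_oracle():
    """Dual route: MD end-to-end statistics vs direct Metropolis sampling."""
    from mc_oracle import run_chain_mc

    ree2_mc = run_chain_mc(41, 2500, 400, seed=3)
    md = free_filament_stats(
        production_steps=300_000, equil_steps=100_000, sample_stride=200, seed=4
    )
    assert md.rms_ree_nm == pytest.approx(np.sqrt(ree2_mc), rel=0.15)


# ---------------------------------------------------------------------------
# bending rigidity
# ---------------------------------------------------------------------------


def test_bending_rigidity_stiffness_limit():
    """A 10x stiffer filament fluctuates less; kappa scales accordingly."""
    cfg = ModelConfig()
    soft = bending_rigidity(n_beads=7, production_steps=120_000, seed=1, config=cfg)
    stiff = bending_rigidity(
        n_beads=7,
        production_steps=120_000,
        seed=1,
        config=cfg.replace(kb_kT=10 * cfg.kb_kT),
    )
    assert stiff["du_rms_nm"] < soft["du_rms_nm"]
    assert stiff["kappa_Nm2"] > 3.0 * soft["kappa_Nm2"]


def test_bending_rigidity_against_discrete_rod():
    """Cantilever fluctuations vs kappa = k_theta * a for the bead-rod chain.

    k_theta = kb/dtheta_max is the small-angle bending constant; tolerance
    reflects the modest sample count of a desk-scale run.
    """
    cfg = ModelConfig()
    res = bending_rigidity(n_beads=9, production_steps=500_000, seed=2, config=cfg)
    u = cfg.units
    k_theta_eps = cfg.kb_kT * cfg.kT_over_eps / (0.3 * np.pi)
    kappa_rod = k_theta_eps * u.epsilon_J * (35e-9)
    assert res["kappa_Nm2"] == pytest.approx(kappa_rod, rel=0.35)


# ---------------------------------------------------------------------------
# laceration
# ---------------------------------------------------------------------------


def test_laceration_zero_severed_is_vacuous():
    p = make_preset("axon_2ring")
    sim = make_simulation(p.system, p.topology, p.config, seed=0)
    res = lacerate_and_watch(sim, n_severed=0, watch_steps=2000)
    assert np.all(res.fraction_reconnected == 1.0)


def test_laceration_cumulative_fraction_monotone():
    cfg = ModelConfig(n_rings=2, ring_spacing_nm=110.0)
    sim = prepare_axon(cfg, seed=1, equil_steps=30_000)
    res = lacerate_and_watch(
        sim, n_severed=5, evolve_steps=2000, watch_steps=10_000, checkpoint_stride=500
    )
    assert np.all(np.diff(res.fraction_reconnected) >= 0.0)
    assert 0.0 <= res.fraction_reconnected[-1] <= 1.0
    assert np.all(res.fraction_intact_now <= res.fraction_reconnected + 1e-12)


# ---------------------------------------------------------------------------
# radial expansion mechanics (reduced protocol)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def small_expansion():
    cfg = ModelConfig(n_rings=2)
    sim = prepare_axon(cfg, seed=0, equil_steps=30_000)
    return radial_expansion(
        sim,
        increments=5,
        transition_steps=500,
        equil_steps=500,
        measure_steps=1000,
        settle_steps=4000,
    )


def test_expansion_pressures_positive_and_rising(small_expansion):
    res = small_expansion
    assert np.all(res.p_ring > 0)
    assert np.all(res.p_between > 0)
    assert res.p_between[-1] > res.p_between[0]


def test_expansion_moduli_positive(small_expansion):
    res = small_expansion
    assert res.E_ring_kPa > 0
    assert res.E_between_kPa > 0
    assert res.E_avg_kPa > 0


def test_expansion_average_is_width_weighted_stripe_mean(small_expansion):
    # p_total is the area-weighted stripe mean by construction, so the
    # fitted moduli must close on the same identity
    res = small_expansion
    w_ring = 2 * res.ring_stripe_nm       # 2 rings
    w_between = 1 * res.between_stripe_nm  # 1 gap
    expected = (w_ring * res.E_ring_red + w_between * res.E_between_red) / (
        w_ring + w_between
    )
    assert res.E_avg_red == pytest.approx(expected, rel=0.02)


def test_expansion_requires_built_axon():
    p = make_preset("free_spectrin")
    sim = make_simulation(p.system, p.topology, p.config, seed=0)
    with pytest.raises(ValueError):
        radial_expansion(sim, increments=1)
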