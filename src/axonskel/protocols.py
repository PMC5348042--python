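"""The model's in-silico experiments as reproducible measurements.

* :func:`free_filament_stats` — thermal end-to-end statistics of a free
  spectrin tetramer and the persistence length inferred from them.
* :func:`bending_rigidity` — clamped-cantilever fluctuation measurement of
  the ring-material bending rigidity.
* :func:`radial_expansion` — cylindrical-wall expansion of the axon,
  stripe-resolved pressures, and shell-theory Young's moduli.
* :func:`ankyrin_motion` — thermal trajectories of the ankyrin anchors and
  the order statistics of the attached sodium channels.
* :func:`lacerate_and_watch` — severing of spectrin filaments and the
  kinetics of junction re-association.
* :func:`channel_density` — geometric sodium-channel surface density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import ModelConfig
from .dynamics import Simulation
from .forcefield import ForceField
from .model import (
    ANKYRIN,
    ParticleSystem,
    Topology,
    build_free_ring_filament,
    build_free_spectrin,
)

#: default per-particle force cap (eps/sigma) used while relaxing the
#: artificial built state; measurements always run uncapped.
EQUILIBRATION_CAP = 1.0e3


def make_simulation(
    system: ParticleSystem,
    topology: Topology,
    config: ModelConfig,
    seed: int | None = None,
) -> Simulation:
    ff = ForceField(config, topology, system)
    return Simulation(system, topology, ff, config=config, seed=seed)


def equilibrate(sim: Simulation, n_steps: int = 150_000, cap: float = EQUILIBRATION_CAP) -> None:
    """Thermalise a freshly built system (force-capped; see module note)."""
    sim.run(n_steps, thermostat=True, cap=cap)


def prepare_axon(
    config: ModelConfig,
    seed: int | None = None,
    equil_steps: int = 150_000,
    ramp_steps_per_nm: int = 200,
) -> Simulation:
    """Assemble an axon stress-free and bring it gradually to working length.

    The skeleton is built at the assembly spacing ``2 * junction + contour``
    (240 nm for the defaults), where every spectrin bond sits at its rest
    length and every steric pair at its cutoff, then the inter-ring
    restraint equilibrium is ramped linearly down to the configured ring
    spacing and the system thermalised.  This avoids the force blast of
    building directly at the working spacing and keeps all actin-spectrin
    junctions intact while the filaments develop entropic tension (185 nm)
    or coil up (110 nm).
    """
    from .model import build_axon

    target_nm = config.ring_spacing_nm
    assembly_nm = 2.0 * config.junction_eq_nm + config.contour_length_nm
    build_cfg = config.replace(ring_spacing_nm=assembly_nm)
    system, topo = build_axon(build_cfg)
    ff = ForceField(build_cfg, topo, system)
    sim = Simulation(system, topo, ff, config=config, seed=seed)
    sig = config.units.sigma_nm
    span_nm = assembly_nm - target_nm
    if span_nm > 0:
        n_chunks = max(1, int(span_nm))  # ~1 nm per chunk
        steps_per_chunk = max(1, int(ramp_steps_per_nm * span_nm / n_chunks))
        for c in range(n_chunks):
            d_nm = assembly_nm + (c + 1) / n_chunks * (target_nm - assembly_nm)
            ff.d_eq = d_nm / sig
            ff.dd_max = config.dd_max_frac * ff.d_eq
            sim.run(steps_per_chunk, thermostat=True)
    ff.d_eq = target_nm / sig
    ff.dd_max = config.dd_max_frac * ff.d_eq
    # downstream measurements read geometry (stripe widths, spacing) from
    # ff.config; hand them the working configuration, not the assembly one
    ff.config = config
    sim.run(equil_steps, thermostat=True)
    return sim


def clone_simulation(sim: Simulation, seed: int | None = None) -> Simulation:
    """Independent copy of an equilibrated simulation.

    Positions, velocities, junction states, and force-field state (ring
    spacing, wall) are copied, so several destructive measurements can
    branch from one equilibrated configuration.
    """
    system = sim.system.copy()
    topo = sim.topology.copy()
    ff = ForceField(sim.ff.config, topo, system)
    ff.d_eq = sim.ff.d_eq
    ff.dd_max = sim.ff.dd_max
    ff.wall_rc = sim.ff.wall_rc
    ff.as_recapture_enabled = sim.ff.as_recapture_enabled
    clone = Simulation(
        system, topo, ff, config=sim.ff.config,
        dt=sim.dt, kT=sim.kT, tau_steps=sim.tau_steps,
        seed=sim.ff.config.seed if seed is None else seed,
    )
    return clone


# ---------------------------------------------------------------------------
# free spectrin statistics
# ---------------------------------------------------------------------------


@dataclass
class FreeFilamentStats:
    ree_samples_nm: np.ndarray
    rms_ree_nm: float
    mean_ree_nm: float
    std_ree_nm: float
    lp_nm: float
    contour_length_nm: float


def free_filament_stats(
    production_steps: int = 500_000,
    equil_steps: int = 100_000,
    sample_stride: int = 200,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> FreeFilamentStats:
    """End-to-end statistics of the free 41-bead spectrin chain.

    The chain starts straight, is equilibrated, then sampled during thermal
    fluctuations.  The persistence length follows from the flexible-filament
    relation <r_ee^2> = 2 l_p L_c with L_c the 200 nm contour length.
    """
    config = config or ModelConfig()
    system, topo = build_free_spectrin(config)
    sim = make_simulation(system, topo, config, seed=seed)
    sim.run(equil_steps, thermostat=True)
    samples: list[float] = []

    def grab(step, s):
        samples.append(float(np.linalg.norm(s.system.pos[-1] - s.system.pos[0])))

    sim.run(production_steps, thermostat=True, observers=[(sample_stride, grab)])
    if len(samples) < 100:
        raise ValueError(
            f"only {len(samples)} end-to-end samples; need >= 100 for a fit"
        )
    sig = config.units.sigma_nm
    ree = np.asarray(samples) * sig
    lc = config.contour_length_nm
    rms = float(np.sqrt(np.mean(ree**2)))
    return FreeFilamentStats(
        ree_samples_nm=ree,
        rms_ree_nm=rms,
        mean_ree_nm=float(ree.mean()),
        std_ree_nm=float(ree.std()),
        lp_nm=rms**2 / (2.0 * lc),
        contour_length_nm=lc,
    )


# ---------------------------------------------------------------------------
# bending rigidity of ring material
# ---------------------------------------------------------------------------


def bending_rigidity(
    n_beads: int = 13,
    production_steps: int = 300_000,
    equil_steps: int = 30_000,
    sample_stride: int = 100,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> dict:
    """Bending rigidity of a clamped straight ring-material filament.

    Records transverse end displacements du of the free tip and inverts the
    clamped-cantilever fluctuation relation <du^2> = L^3 kB T / (3 kappa)
    per transverse direction, with L the contour from the clamp (the second
    fixed bead) to the tip.
    """
    config = config or ModelConfig()
    system, topo = build_free_ring_filament(n_beads, clamped=True, config=config)
    sim = make_simulation(system, topo, config, seed=seed)
    sim.run(equil_steps, thermostat=True)
    du: list[tuple[float, float]] = []

    def grab(step, s):
        du.append((float(s.system.pos[-1, 0]), float(s.system.pos[-1, 1])))

    sim.run(production_steps, thermostat=True, observers=[(sample_stride, grab)])
    if len(du) < 100:
        raise ValueError("insufficient samples for the fluctuation estimate")
    d = np.asarray(du)
    var_per_axis = float(np.mean(d**2))  # mean over both transverse axes, about 0
    u = config.units
    a_nm = config.actin_bead_diameter_nm
    L_m = (n_beads - 2) * a_nm * 1e-9
    du2_m2 = var_per_axis * (u.sigma_m**2)
    kappa = L_m**3 * u.kBT_J / (3.0 * du2_m2)
    return {
        "kappa_Nm2": kappa,
        "du_rms_nm": math.sqrt(var_per_axis) * u.sigma_nm,
        "L_nm": (n_beads - 2) * a_nm,
        "n_samples": len(du),
    }


# ---------------------------------------------------------------------------
# radial expansion stiffness
# ---------------------------------------------------------------------------


@dataclass
class StiffnessResult:
    delta_nm: np.ndarray
    p_ring: np.ndarray       # mean pressures per increment, eps/sigma^3
    p_ring_std: np.ndarray
    p_between: np.ndarray
    p_between_std: np.ndarray
    p_total: np.ndarray
    p_total_std: np.ndarray
    E_ring_red: float        # eps/sigma^3
    E_between_red: float
    E_avg_red: float
    E_ring_kPa: float
    E_between_kPa: float
    E_avg_kPa: float
    r2_ring: float
    r2_between: float
    r2_total: float
    broken_fraction: float
    ring_stripe_nm: float = 80.0
    between_stripe_nm: float = 105.0


def _slope_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    yhat = A @ coef
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(coef[0]), r2


def radial_expansion(
    sim: Simulation,
    increments: int = 20,
    dr_nm: float = 0.5,
    transition_steps: int = 1000,
    equil_steps: int = 1000,
    measure_steps: int = 8000,
    settle_steps: int = 2000,
    ring_stripe_nm: float = 80.0,
) -> StiffnessResult:
    """Expand an internal cylindrical wall and measure stripe pressures.

    The wall starts at the spectrin confinement radius (217 nm) and grows by
    ``dr_nm`` per increment, each over ``transition_steps``; after
    ``equil_steps`` of settling, the radial wall force on every particle is
    accumulated every step for ``measure_steps``.  Particles are assigned to
    80 nm stripes centred on the ring planes or to the complementary
    between-ring stripes by their z coordinate.  Mean stripe pressure
    (force / lateral stripe area at the current wall radius) versus radius
    change is fit by ordinary least squares and inverted with thin-shell
    theory E = p R^2 / (delta H), R = 217 nm, H = 10 nm.
    """
    config = sim.ff.config
    sig = config.units.sigma_nm
    topo = sim.topology
    if topo.n_rings < 2:
        raise ValueError("radial expansion requires a built axon")
    r_start_nm = config.spectrin_confine_radius_nm
    spacing_nm = config.ring_spacing_nm
    between_stripe_nm = spacing_nm - ring_stripe_nm
    n_rings = topo.n_rings
    n_gaps = n_rings - 1
    half_ring = 0.5 * ring_stripe_nm / sig

    # wall on, let the skeleton settle onto it (capped: the activation is abrupt)
    sim.ff.set_wall(r_start_nm)
    sim.ff.invalidate_neighbors()
    sim.run(settle_steps, thermostat=True, cap=EQUILIBRATION_CAP)

    n_actin = int(np.sum(sim.system.kind == 0))

    delta, pr, prs, pb, pbs, pt, pts = [], [], [], [], [], [], []
    for k in range(1, increments + 1):
        rc_nm = r_start_nm + k * dr_nm
        # grow the wall linearly over the transition
        for sub in range(transition_steps // 50):
            f = (sub + 1) / (transition_steps // 50)
            sim.ff.set_wall(r_start_nm + (k - 1) * dr_nm + f * dr_nm)
            sim.run(50, thermostat=True)
        sim.run(equil_steps, thermostat=True)

        # stripe membership from the current ring planes
        z_actin = sim.system.pos[:n_actin, 2]
        zring = np.array(
            [z_actin[topo.ring_of_actin == g].mean() for g in range(n_rings)]
        )
        z = sim.system.pos[:, 2]
        in_ring = np.zeros(sim.system.n, bool)
        for zg in zring:
            in_ring |= np.abs(z - zg) < half_ring
        zmin, zmax = zring[0] - half_ring, zring[-1] + half_ring
        in_span = (z >= zmin) & (z <= zmax)
        in_between = in_span & ~in_ring

        rc_red = rc_nm / sig
        area_ring = n_rings * 2.0 * math.pi * rc_red * (ring_stripe_nm / sig)
        area_between = n_gaps * 2.0 * math.pi * rc_red * (between_stripe_nm / sig)
        area_total = area_ring + area_between

        samples_r, samples_b, samples_t = [], [], []

        def grab(step, s):
            w = s.last_result.wall_radial
            fr = float(w[in_ring].sum())
            fb = float(w[in_between].sum())
            samples_r.append(fr / area_ring)
            samples_b.append(fb / area_between)
            samples_t.append((fr + fb) / area_total)

        sim.run(measure_steps, thermostat=True, observers=[(1, grab)])
        delta.append(k * dr_nm)
        pr.append(np.mean(samples_r)), prs.append(np.std(samples_r))
        pb.append(np.mean(samples_b)), pbs.append(np.std(samples_b))
        pt.append(np.mean(samples_t)), pts.append(np.std(samples_t))

    delta = np.asarray(delta)
    pr, pb, pt = np.asarray(pr), np.asarray(pb), np.asarray(pt)
    R_red = r_start_nm / sig
    H_red = 10.0 / sig
    u = config.units

    def invert(p: np.ndarray) -> tuple[float, float]:
        slope, r2 = _slope_r2(delta / sig, p)
        return slope * R_red**2 / H_red, r2

    E_ring, r2_r = invert(pr)
    E_between, r2_b = invert(pb)
    E_avg, r2_t = invert(pt)
    return StiffnessResult(
        delta_nm=delta,
        p_ring=pr, p_ring_std=np.asarray(prs),
        p_between=pb, p_between_std=np.asarray(pbs),
        p_total=pt, p_total_std=np.asarray(pts),
        E_ring_red=E_ring, E_between_red=E_between, E_avg_red=E_avg,
        E_ring_kPa=u.pressure_red_to_kPa(E_ring),
        E_between_kPa=u.pressure_red_to_kPa(E_between),
        E_avg_kPa=u.pressure_red_to_kPa(E_avg),
        r2_ring=r2_r, r2_between=r2_b, r2_total=r2_t,
        broken_fraction=float(1.0 - sim.topology.as_state.mean()),
        ring_stripe_nm=ring_stripe_nm,
        between_stripe_nm=between_stripe_nm,
    )


# ---------------------------------------------------------------------------
# ankyrin thermal motion
# ---------------------------------------------------------------------------


@dataclass
class AnkyrinStats:
    planar_radius_nm: float
    dz_over_lc: np.ndarray
    s: float
    lc_nm: float
    n_samples: int
    per_ankyrin_radius_nm: np.ndarray = field(
        default_factory=lambda: np.empty(0)
    )
    n_excluded: int = 0


def ankyrin_motion(
    sim: Simulation,
    production_steps: int = 1_000_000,
    stride: int = 10_000,
    exclude_detached: bool = True,
) -> AnkyrinStats:
    """Thermal-motion statistics of the ankyrin (Na_v anchor) particles.

    Positions are sampled every ``stride`` steps.  For each ankyrin the
    planar trajectory radius is the RMS deviation from its mean position in
    the local membrane plane (z, circumferential arc); d(z) is the pooled
    z-deviation; L_c is the mean longitudinal spacing between consecutive
    ankyrin mean positions, so s = std(d(z)/L_c) measures the longitudinal
    order of the channel lattice.

    By default anchors riding on detached filaments (a junction broken at
    the end of the run) are excluded: the statistic characterises the
    connected channel lattice, and a free filament's anchor wanders over
    tens of nanometres, swamping the lattice signal.  Set
    ``exclude_detached=False`` for the raw all-anchor statistic.
    """
    if production_steps < 10 * stride:
        raise ValueError("production must cover at least 10 sampling strides")
    system = sim.system
    ank = np.flatnonzero(system.kind == ANKYRIN)
    frames: list[np.ndarray] = []

    def grab(step, s):
        frames.append(s.system.pos[ank].copy())

    sim.run(production_steps, thermostat=True, observers=[(stride, grab)])
    traj = np.stack(frames)  # (n_samples, n_ank, 3)
    config = sim.ff.config
    sig = config.units.sigma_nm
    n_fil = config.filaments_per_gap
    n_gaps = sim.topology.n_rings - 1

    # ankyrin i belongs to filament (gap, f) = divmod(i, n_fil); keep those
    # whose filament has both junctions intact
    keep = np.ones(len(ank), bool)
    if exclude_detached and len(sim.topology.as_pairs):
        topo = sim.topology
        intact_by_fil = np.ones((n_gaps, n_fil), bool)
        for p in range(len(topo.as_pairs)):
            if topo.as_state[p] == 0:
                intact_by_fil[topo.as_gap[p], topo.as_filament[p]] = False
        keep = intact_by_fil.ravel()

    x, y, z = traj[..., 0], traj[..., 1], traj[..., 2]
    r = np.hypot(x, y)
    phi = np.arctan2(y, x)
    phi0 = np.arctan2(np.sin(phi).mean(axis=0), np.cos(phi).mean(axis=0))
    dphi = np.angle(np.exp(1j * (phi - phi0)))
    rbar = r.mean(axis=0)
    arc = rbar * dphi
    dz = z - z.mean(axis=0)
    per_radius = np.sqrt(np.mean(dz**2 + arc**2, axis=0))  # per ankyrin

    # longitudinal spacing from consecutive gaps of the same filament index
    zbar = z.mean(axis=0).reshape(n_gaps, n_fil)
    keep2d = keep.reshape(n_gaps, n_fil)
    if n_gaps >= 2:
        pair_ok = keep2d[:-1] & keep2d[1:]
        diffs = np.diff(zbar, axis=0)[pair_ok]
        lc_red = float(diffs.mean()) if diffs.size else float(
            config.ring_spacing_nm / sig
        )
    else:
        lc_red = float(config.ring_spacing_nm / sig)
    pooled = (dz[:, keep] / lc_red).ravel()
    return AnkyrinStats(
        planar_radius_nm=float(per_radius[keep].mean()) * sig,
        dz_over_lc=pooled,
        s=float(pooled.std()),
        lc_nm=lc_red * sig,
        n_samples=traj.shape[0],
        per_ankyrin_radius_nm=per_radius[keep] * sig,
        n_excluded=int((~keep).sum()),
    )


# ---------------------------------------------------------------------------
# laceration
# ---------------------------------------------------------------------------


@dataclass
class LacerationResult:
    severed_pairs: np.ndarray
    checkpoint_steps: np.ndarray
    fraction_reconnected: np.ndarray  # cumulative, monotone
    fraction_intact_now: np.ndarray


def lacerate_and_watch(
    sim: Simulation,
    n_severed: int = 15,
    gap: int = 0,
    end: int = 1,
    evolve_steps: int = 10_000,
    watch_steps: int = 50_000,
    checkpoint_stride: int = 1000,
) -> LacerationResult:
    """Sever spectrin filaments and watch for re-association.

    ``n_severed`` angularly contiguous filaments of one gap are detached at
    one end (their junction forced broken, recapture suppressed); the system
    evolves for ``evolve_steps``, then recapture at 2.5 x (4 sigma) is
    re-enabled and reconnections to the original junctions are recorded at
    checkpoints.  The headline fraction is cumulative (a pair counts as
    reconnected once it has re-formed its original junction).

    The default severed end (``end=1``, the higher-index ring of the gap)
    puts the open junctions on an interior ring in the 3-ring models: rings
    that keep tethers on both sides stay upright, whereas an end ring that
    loses over a third of its tethers tilts freely (only the mean ring
    plane position is restrained) and carries its junctions away from the
    severed ends.
    """
    topo = sim.topology
    if n_severed == 0:
        steps = np.arange(0, watch_steps + 1, checkpoint_stride)
        ones = np.ones_like(steps, float)
        return LacerationResult(np.empty(0, np.int64), steps, ones, ones)
    pair_idx = np.array(
        [topo.as_pair_index(gap, f, end) for f in range(n_severed)], np.int64
    )
    topo.as_state[pair_idx] = 0
    topo.as_recapture_ok[pair_idx] = 0
    sim.run(evolve_steps, thermostat=True)
    topo.as_recapture_ok[pair_idx] = 1

    steps, frac_cum, frac_now = [0], [0.0], [0.0]
    ever = np.zeros(n_severed, bool)
    for _ in range(watch_steps // checkpoint_stride):
        sim.run(checkpoint_stride, thermostat=True)
        intact = topo.as_state[pair_idx] == 1
        ever |= intact
        steps.append(steps[-1] + checkpoint_stride)
        frac_cum.append(float(ever.mean()))
        frac_now.append(float(intact.mean()))
    return LacerationResult(
        severed_pairs=pair_idx,
        checkpoint_steps=np.asarray(steps),
        fraction_reconnected=np.asarray(frac_cum),
        fraction_intact_now=np.asarray(frac_now),
    )


# ---------------------------------------------------------------------------
# channel density
# ---------------------------------------------------------------------------


def channel_density(config: ModelConfig) -> float:
    """Na_v channels per square micron implied by the geometry.

    One channel rides on each ankyrin (one per spectrin tetramer); the
    reference surface is the cylinder through the ring diameter.
    """
    gaps = config.n_rings - 1
    if config.filaments_per_gap == 0 or gaps <= 0:
        return 0.0
    n_channels = gaps * config.filaments_per_gap
    d_um = 2.0 * config.ring_radius_nm * 1e-3
    length_um = gaps * config.ring_spacing_nm * 1e-3
    return n_channels / (math.pi * d_um * length_um)
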