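"""NVT time integration: Beeman algorithm with Berendsen velocity rescaling.

The equations of motion are integrated with the explicit Beeman scheme
(positions third-order, velocities second-order accurate); the first step
is bootstrapped by setting the previous acceleration equal to the current
one, which reduces the position update to velocity Verlet.  Temperature is
maintained by Berendsen weak coupling with tau_T = 100 dt by default —
gentle enough not to distort the fluctuation statistics the measurement
protocols rely on.  All masses are 1 in reduced units, kB = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .config import ModelConfig
from .forcefield import ForceField
from .model import ParticleSystem, Topology


def remove_rigid_motion(system: ParticleSystem, rotation: bool = False) -> None:
    """Zero the net linear (and optionally angular) momentum.

    In vacuum the internal forces are central, so both momenta are
    conserved; any rigid-body component drawn with the thermal velocities
    would persist forever and — under velocity rescaling — slowly absorb
    the internal fluctuations (the chain would end up spinning rigidly).
    Free filaments therefore start with both momenta removed.
    """
    m = system.mobile
    v = system.vel
    v[m] -= v[m].mean(axis=0)
    if rotation:
        r = system.pos[m] - system.pos[m].mean(axis=0)
        L = np.sum(np.cross(r, v[m]), axis=0)
        r2 = np.sum(r * r)
        inertia = r2 * np.eye(3) - r.T @ r
        # pinv: a collinear chain has no rotation about its own axis to remove
        omega = np.linalg.pinv(inertia, rcond=1e-10) @ L
        v[m] -= np.cross(omega, r)


def remove_axial_rigid_motion(system: ParticleSystem) -> None:
    """Zero net z translation and rigid rotation about the z axis.

    The axon's external restraints (confinement, wall) are symmetric under
    both, so the corresponding momenta are conserved; round-off plus
    velocity rescaling would otherwise let the whole skeleton drift and
    spin about its axis, contaminating trajectory statistics.
    """
    m = system.mobile
    v = system.vel
    v[m, 2] -= v[m, 2].mean()
    x, y = system.pos[m, 0], system.pos[m, 1]
    iz = np.sum(x * x + y * y)
    if iz > 0:
        omega = np.sum(x * v[m, 1] - y * v[m, 0]) / iz
        v[m, 0] += omega * y
        v[m, 1] -= omega * x


def maxwell_boltzmann(
    system: ParticleSystem,
    kT: float,
    rng: np.random.Generator,
    free_rotation: bool = False,
) -> None:
    """Draw velocities at temperature kT, remove rigid motion, exact rescale."""
    v = rng.normal(0.0, np.sqrt(kT), size=system.vel.shape)
    v[~system.mobile] = 0.0
    system.vel[:] = v
    nm = int(system.mobile.sum())
    if nm == system.n and nm > 1:
        remove_rigid_motion(system, rotation=free_rotation)
    ndof = degrees_of_freedom(system, free_rotation)
    if ndof > 0:
        t_inst = np.sum(system.vel[system.mobile] ** 2) / ndof
        if t_inst > 0:
            system.vel[system.mobile] *= np.sqrt(kT / t_inst)


def degrees_of_freedom(system: ParticleSystem, free_rotation: bool = False) -> int:
    nm = int(system.mobile.sum())
    if nm == 0:
        return 0
    if nm < system.n:
        # clamped beads break every rigid-body invariance
        return 3 * nm
    return max(3 * nm - (6 if free_rotation else 3), 0)


def instantaneous_temperature(system: ParticleSystem, free_rotation: bool = False) -> float:
    ndof = degrees_of_freedom(system, free_rotation)
    if ndof == 0:
        return 0.0
    return float(np.sum(system.vel[system.mobile] ** 2) / ndof)


@dataclass
class TrajectoryRecord:
    """Sparse log of a run: sampled steps, temperatures, energies, frames."""

    steps: list[int] = field(default_factory=list)
    temperature: list[float] = field(default_factory=list)
    potential: list[float] = field(default_factory=list)
    kinetic: list[float] = field(default_factory=list)
    frames: list[np.ndarray] = field(default_factory=list)

    def total_energy(self) -> np.ndarray:
        return np.asarray(self.potential) + np.asarray(self.kinetic)


class Simulation:
    """Owns the integrator state for one system + force field.

    Use :meth:`run` for plain propagation; measurement protocols drive
    :meth:`run` in short bursts and read ``last_result`` between them.
    """

    def __init__(
        self,
        system: ParticleSystem,
        topology: Topology,
        forcefield: ForceField,
        config: ModelConfig | None = None,
        dt: float | None = None,
        kT: float | None = None,
        tau_steps: float = 100.0,
        seed: int | None = None,
    ):
        config = config or forcefield.config
        self.system = system
        self.topology = topology
        self.ff = forcefield
        self.dt = config.dt if dt is None else dt
        self.kT = config.kT_over_eps if kT is None else kT
        self.tau_steps = tau_steps
        #: stride for re-zeroing rigid-body motion of free systems; integrator
        #: round-off slowly regenerates angular momentum, which weak-coupling
        #: rescaling would otherwise amplify into rigid rotation
        self.comm_remove_stride = 1000
        self.rng = np.random.default_rng(config.seed if seed is None else seed)
        self.step_count = 0
        # a lone filament in vacuum conserves angular momentum; the built
        # axon interacts with axisymmetric external restraints instead
        self.free_rotation = topology.n_rings == 0
        if not np.any(system.vel):
            maxwell_boltzmann(system, self.kT, self.rng, self.free_rotation)
        # three rotating force buffers: acc_prev, acc, and the next target
        self._buffers = [np.zeros_like(system.pos) for _ in range(3)]
        self._mobile_u8 = system.mobile.astype(np.uint8)
        self._ndof = degrees_of_freedom(system, self.free_rotation)
        res = self.ff.compute(system, out=self._buffers[0])
        self.acc = res.forces  # m = 1
        self.acc_prev = self._buffers[1]
        self.acc_prev[:] = self.acc
        self.last_result = res
        self._next_buf = 2

    # ------------------------------------------------------------------

    def _berendsen(self) -> None:
        if self._ndof == 0:
            return
        from . import _kernels

        t_inst = _kernels.kinetic_sum(self.system.vel, self._mobile_u8) / self._ndof
        if t_inst == 0.0:
            if self.kT > 0:
                maxwell_boltzmann(self.system, self.kT, self.rng, self.free_rotation)
            return
        lam2 = 1.0 + (1.0 / self.tau_steps) * (self.kT / t_inst - 1.0)
        if lam2 < 0.0:
            lam2 = 0.0
        _kernels.scale_velocities(self.system.vel, self._mobile_u8, np.sqrt(lam2))

    def run(
        self,
        n_steps: int,
        thermostat: bool = True,
        cap: float | None = None,
        observers: Sequence[tuple[int, Callable]] = (),
        record_stride: int | None = None,
        raise_on_divergence: bool = True,
    ) -> TrajectoryRecord:
        """Advance ``n_steps``; observers are (stride, fn(step, sim)) pairs.

        With ``record_stride`` set, temperatures/energies/positions are
        logged every that many steps (and at step 0).
        """
        rec = TrajectoryRecord()
        sys_ = self.system
        dt = self.dt
        dt2 = dt * dt

        def log() -> None:
            rec.steps.append(self.step_count)
            rec.temperature.append(instantaneous_temperature(sys_))
            rec.potential.append(self.last_result.potential)
            rec.kinetic.append(0.5 * float(np.sum(sys_.vel[sys_.mobile] ** 2)))
            rec.frames.append(sys_.pos.copy())

        if record_stride is not None:
            log()
        from . import _kernels

        mobile_u8 = self._mobile_u8
        del dt2
        for _ in range(n_steps):
            _kernels.beeman_positions(
                sys_.pos, sys_.vel, self.acc, self.acc_prev, mobile_u8, dt
            )
            res = self.ff.compute(sys_, cap=cap, out=self._buffers[self._next_buf])
            if res.n_diverging and raise_on_divergence and cap is None:
                raise FloatingPointError(
                    f"{res.n_diverging} FENE restraint(s) at their divergence "
                    f"limit at step {self.step_count}"
                )
            acc_new = res.forces
            _kernels.beeman_velocities(
                sys_.vel, acc_new, self.acc, self.acc_prev, mobile_u8, dt
            )
            # rotate buffers: old acc_prev becomes the next compute target
            for bi, buf in enumerate(self._buffers):
                if buf is self.acc_prev:
                    self._next_buf = bi
                    break
            self.acc_prev = self.acc
            self.acc = acc_new
            self.last_result = res
            if thermostat:
                self._berendsen()
            self.step_count += 1
            if self.step_count % self.comm_remove_stride == 0 and sys_.mobile.all():
                if self.free_rotation:
                    remove_rigid_motion(sys_, rotation=True)
                else:
                    remove_axial_rigid_motion(sys_)
            if self.step_count % 200 == 0 and not _kernels.all_finite(sys_.pos):
                raise FloatingPointError(
                    f"non-finite positions at step {self.step_count}"
                )
            for stride, fn in observers:
                if self.step_count % stride == 0:
                    fn(self.step_count, self)
            if record_stride is not None and self.step_count % record_stride == 0:
                log()
        return rec

    # convenience -------------------------------------------------------

    def reseed_velocities(self, seed: int) -> None:
        self.rng = np.random.default_rng(seed)
        maxwell_boltzmann(self.system, self.kT, self.rng, self.free_rotation)
        # restart the integrator history from the new phase-space point
        res = self.ff.compute(self.system, out=self._buffers[0])
        self.acc = self._buffers[0]
        self.acc_prev = self._buffers[1]
        self.acc_prev[:] = self.acc
        self.last_result = res
        self._next_buf = 2


def run_nvt(
    system: ParticleSystem,
    topology: Topology,
    forcefield: ForceField,
    n_steps: int,
    observers: Sequence[tuple[int, Callable]] = (),
    seed: int | None = None,
    thermostat: bool = True,
    cap: float | None = None,
    record_stride: int | None = None,
    spacing_ramp: tuple[float, float, int] | None = None,
) -> TrajectoryRecord:
    """One-shot NVT run, optionally ramping the ring spacing first.

    ``spacing_ramp = (d_from_nm, d_to_nm, ramp_steps)`` linearly moves the
    inter-ring FENE equilibrium spacing before the main run (the gradual
    approach to the working length); the ramp steps are counted separately
    from ``n_steps``.
    """
    sim = Simulation(system, topology, forcefield, seed=seed)
    if spacing_ramp is not None:
        d_from, d_to, ramp_steps = spacing_ramp
        sig = forcefield.config.units.sigma_nm
        chunks = max(1, int(ramp_steps // 50))
        for k in range(chunks):
            f = (k + 1) / chunks
            d_nm = d_from + f * (d_to - d_from)
            forcefield.d_eq = d_nm / sig
            forcefield.dd_max = forcefield.config.dd_max_frac * forcefield.d_eq
            sim.run(ramp_steps // chunks, thermostat=thermostat, cap=cap)
    return sim.run(
        n_steps,
        thermostat=thermostat,
        cap=cap,
        observers=observers,
        record_stride=record_stride,
    )
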