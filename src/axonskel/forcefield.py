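"""Potential-energy terms of the membrane-skeleton model.

Two layers live here:

* scalar reference functions (:func:`harmonic_bond`, :func:`repulsive_lj`,
  :func:`fene_angle`, :func:`as_attraction`, ...) that implement each term
  in its textbook form — used directly by tests and by anyone wanting the
  raw potentials;
* :class:`ForceField`, the assembled engine that evaluates all active terms
  over a :class:`~axonskel.model.ParticleSystem` + Topology with cell-list
  neighbour search, and owns the live state of the breakable actin-spectrin
  junctions and of the cylindrical expansion wall.

Units are reduced (sigma, epsilon) throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .config import ModelConfig
from .model import ACTIN, ANKYRIN, SPECTRIN, ParticleSystem, Topology

TWO16 = 2.0 ** (1.0 / 6.0)
#: inflexion point of the 12-6 potential, in units of its sigma
INFLEXION_FACTOR = (26.0 / 7.0) ** (1.0 / 6.0)
#: capture distance for junction re-formation, in units of its sigma
CAPTURE_FACTOR = 2.5

#: additive per-kind steric radii in sigma; pair scale = s[i] + s[j].
#: These close exactly on the model's printed pair scales: S-S sigma,
#: A-A 7 sigma (35 nm), S-K 3 sigma (15 nm), A-S 4 sigma (20 nm junction).
STERIC_RADII_SIGMA = {ACTIN: 3.5, SPECTRIN: 0.5, ANKYRIN: 2.5}

INTACT, BROKEN = 1, 0


# ---------------------------------------------------------------------------
# scalar reference forms
# ---------------------------------------------------------------------------


def harmonic_bond(r: float, k: float, r_eq: float) -> tuple[float, float]:
    """Energy and signed force magnitude of a harmonic spring.

    Force is the component along the bond on the outer particle; negative
    means restoring (pulling back toward ``r_eq``).
    """
    dr = r - r_eq
    return 0.5 * k * dr * dr, -k * dr


def repulsive_lj(r: float, eps_pair: float, sigma_pair: float) -> tuple[float, float]:
    """Shifted, purely repulsive 12-6 potential cut at its minimum.

    Energy is continuous and non-negative; force is the outward radial
    component (always >= 0).  Returns (0, 0) beyond the cutoff.
    """
    if r <= 0:
        raise ValueError("r must be positive")
    if r >= TWO16 * sigma_pair:
        return 0.0, 0.0
    s6 = (sigma_pair / r) ** 6
    e = 4.0 * eps_pair * (s6 * s6 - s6) + eps_pair
    f = 24.0 * eps_pair * (2.0 * s6 * s6 - s6) / r
    return e, f


def fene_angle(
    theta: float, kb: float, theta0: float, dtheta_max: float
) -> tuple[float, float]:
    """Finitely extensible bending restraint on a three-bead angle.

    U = -1/2 kb dtheta_max ln[1 - ((theta - theta0)/dtheta_max)^2]; harmonic
    with spring constant kb/dtheta_max for small deviations, diverging as
    |theta - theta0| -> dtheta_max.  Returns (energy, dU/dtheta).
    """
    u = (theta - theta0) / dtheta_max
    if abs(u) >= 1.0:
        raise FloatingPointError(
            f"angle deviation {theta - theta0:.4f} rad at or beyond the FENE "
            f"limit {dtheta_max:.4f} rad"
        )
    e = -0.5 * kb * dtheta_max * math.log(1.0 - u * u)
    return e, kb * u / (1.0 - u * u)


def as_attraction(
    r: float, state: int, sigma_as: float, eps: float = 1.0, allow_recapture: bool = True
) -> tuple[float, float, int]:
    """Breakable actin-spectrin junction: full 12-6 while intact.

    The association breaks (attraction zeroed) when an intact pair passes
    the inflexion point ``(26/7)^(1/6) sigma_as`` and re-forms when a broken
    pair comes within the capture distance ``2.5 sigma_as``.  The repulsive
    core below the potential minimum is always active.  Returns
    (energy, outward force, new state).
    """
    r_inf = INFLEXION_FACTOR * sigma_as
    r_capt = CAPTURE_FACTOR * sigma_as
    if state == INTACT:
        if r > r_inf:
            state = BROKEN
    elif allow_recapture and r < r_capt:
        state = INTACT
    if state == INTACT:
        s6 = (sigma_as / r) ** 6
        e = 4.0 * eps * (s6 * s6 - s6)
        f = 24.0 * eps * (2.0 * s6 * s6 - s6) / r
        return e, f, state
    if r < TWO16 * sigma_as:
        e, f = repulsive_lj(r, eps, sigma_as)
        return e, f, state
    return 0.0, 0.0, state


def confinement(
    r: float, kind: int, r0_spectrin: float, r0_ankyrin: float, kc: float
) -> tuple[float, float]:
    """Bilayer confinement on the radial coordinate.

    Spectrin is restrained only when outside ``r0_spectrin`` (the chain
    cannot cross the bilayer but is free to move inward); ankyrin, being
    embedded in the bilayer, is held two-sidedly at ``r0_ankyrin``.
    Returns (energy, radial force; negative = inward).
    """
    if kind == SPECTRIN:
        dr = r - r0_spectrin
        if dr <= 0:
            return 0.0, 0.0
    elif kind == ANKYRIN:
        dr = r - r0_ankyrin
    else:
        raise ValueError("confinement applies to spectrin and ankyrin only")
    return 0.5 * kc * dr * dr, -kc * dr


def expansion_wall(
    r_i: float, kind: int, r_c: float | None, sigma: float = 1.0
) -> tuple[float, float]:
    """Cylindrical expansion repulsion at wall radius ``r_c`` (sigma units).

    Spectrin uses length scale sigma, actin 7 sigma; the potential argument
    is ``r_i - (r_c - r_kind)`` with the physical bead radius ``r_kind``,
    and the cutoff sits at the potential minimum (~``r_c + r_kind``).
    Returns (energy, outward radial force); (0, 0) when the wall is off.
    """
    if r_c is None:
        return 0.0, 0.0
    if kind == SPECTRIN:
        sw, roff = sigma, 2.5 / 4.45
    elif kind == ACTIN:
        sw, roff = 7.0 * sigma, 17.5 / 4.45
    else:
        return 0.0, 0.0
    x = r_i - (r_c - roff)
    if x <= 0:
        raise FloatingPointError("particle at or inside the wall singularity")
    if x >= TWO16 * sw:
        return 0.0, 0.0
    s6 = (sw / x) ** 6
    e = 4.0 * (s6 * s6 - s6) + 1.0
    f = 24.0 * (2.0 * s6 * s6 - s6) / x
    return e, f


# ---------------------------------------------------------------------------
# assembled force field
# ---------------------------------------------------------------------------


@dataclass
class ForceResult:
    forces: np.ndarray       # (N, 3)
    potential: float
    wall_radial: np.ndarray  # (N,) outward wall force magnitudes
    n_capped: int
    n_diverging: int


class ForceField:
    """All interaction terms of the skeleton model over one built system."""

    def __init__(self, config: ModelConfig, topology: Topology, system: ParticleSystem):
        self.config = config
        self.topology = topology
        sig_nm = config.units.sigma_nm
        n = system.n

        # steric pair tables
        radii = STERIC_RADII_SIGMA
        self.sigma_table = np.zeros((3, 3))
        self.eps_table = np.zeros((3, 3))
        for a in (ACTIN, SPECTRIN, ANKYRIN):
            for b in (ACTIN, SPECTRIN, ANKYRIN):
                self.sigma_table[a, b] = radii[a] + radii[b]
                self.eps_table[a, b] = 1.0
        self.eps_table[SPECTRIN, SPECTRIN] = config.eps1

        # junction LJ scale from the configured junction size
        self.sigma_as = (config.junction_eq_nm / sig_nm) / TWO16

        # confinement
        self.r0_s = config.spectrin_confine_radius_nm / sig_nm
        self.r0_k = config.ankyrin_confine_radius_nm / sig_nm
        self.kc = config.kc_frac * config.k0

        # ring bending FENE (kb printed in kB*T)
        self.kb = config.kb_kT * config.kT_over_eps
        self.theta0 = topology.angle_theta0
        self.dtheta_max = config.dtheta_max_frac * self.theta0

        # inter-ring FENE (kmt printed in kB*T/sigma)
        self.kmt = config.kmt_kT_per_sigma * config.kT_over_eps
        self.d_eq = config.ring_spacing_nm / sig_nm
        self.dd_max = config.dd_max_frac * self.d_eq

        # expansion wall: per-kind LJ length scales and physical radii offsets
        self.wall_rc: float | None = None
        self.wall_sig = np.array([7.0, 1.0, 0.0])  # actin, spectrin, ankyrin
        self.wall_off = np.array([17.5 / sig_nm, 2.5 / sig_nm, 0.0])
        self.as_recapture_enabled = True

        # neighbour list state
        self.skin = 1.0
        rc = TWO16 * self.sigma_table + self.skin
        self._rlist2 = rc * rc
        self._cell = float(rc.max())
        excl = np.sort(
            topology.as_pairs.min(axis=1) * n + topology.as_pairs.max(axis=1)
        ).astype(np.int64) if len(topology.as_pairs) else np.empty(0, np.int64)
        self._excl = excl
        self._cap_pairs = max(4096, 32 * n)
        self._pi = np.empty(self._cap_pairs, np.int64)
        self._pj = np.empty(self._cap_pairs, np.int64)
        self._npair = 0
        self._ref_pos = None
        self._wall_rad = np.zeros(n)

    # ------------------------------------------------------------------

    def set_wall(self, rc_nm: float | None) -> None:
        """Activate (or deactivate with ``None``) the cylindrical wall."""
        self.wall_rc = None if rc_nm is None else rc_nm / self.config.units.sigma_nm

    def invalidate_neighbors(self) -> None:
        self._ref_pos = None

    def _maybe_rebuild(self, pos: np.ndarray, kind: np.ndarray) -> None:
        if self._ref_pos is not None:
            if _kernels.max_disp2(pos, self._ref_pos) < (0.5 * self.skin) ** 2:
                return
        while True:
            npair = _kernels.build_pairs(
                pos, kind, self._rlist2, self._cell, self._excl, self._pi, self._pj
            )
            if npair >= 0:
                break
            self._cap_pairs *= 2
            self._pi = np.empty(self._cap_pairs, np.int64)
            self._pj = np.empty(self._cap_pairs, np.int64)
        self._npair = npair
        self._ref_pos = pos.copy()

    # ------------------------------------------------------------------

    def compute(
        self,
        system: ParticleSystem,
        cap: float | None = None,
        out: np.ndarray | None = None,
    ) -> ForceResult:
        """Total forces and potential energy; mutates junction states.

        ``out``, if given, is used as the force accumulator (zeroed first);
        the integrator passes rotating buffers to avoid per-step allocation.
        """
        pos, kind = system.pos, system.kind
        topo = self.topology
        if out is None:
            forces = np.zeros_like(pos)
        else:
            forces = out
            forces[:] = 0.0
        self._maybe_rebuild(pos, kind)

        e = _kernels.steric_forces(
            pos, kind, self._pi, self._pj, self._npair,
            self.sigma_table, self.eps_table, forces,
        )
        e += _kernels.bond_forces(pos, topo.bonds, topo.bond_k, topo.bond_r0, forces)
        nbad = 0
        if len(topo.angles):
            ea, nb = _kernels.angle_forces(
                pos, topo.angles, self.kb, self.theta0, self.dtheta_max, forces
            )
            e += ea
            nbad += nb
        if len(topo.as_pairs):
            e += _kernels.as_forces(
                pos, topo.as_pairs, topo.as_state, topo.as_recapture_ok,
                1 if self.as_recapture_enabled else 0, self.sigma_as, 1.0, forces,
            )
        if topo.n_rings >= 2:
            er, nb = _kernels.ring_coupling_forces(
                pos, topo.ring_of_actin, topo.n_rings,
                self.config.particles_per_ring, self.kmt, self.d_eq, self.dd_max,
                forces,
            )
            e += er
            nbad += nb
            e += _kernels.confinement_forces(
                pos, kind, self.r0_s, self.r0_k, self.kc, forces
            )
        nclip = 0
        if self.wall_rc is not None:
            ew, nclip = _kernels.wall_forces(
                pos, kind, self.wall_rc, self.wall_sig, self.wall_off, 1.0,
                forces, self._wall_rad,
            )
            e += ew
        else:
            self._wall_rad[:] = 0.0
        ncap = nclip
        if cap is not None:
            ncap += _kernels.cap_forces(forces, cap)
        if not system.mobile.all():
            forces[~system.mobile] = 0.0
        return ForceResult(forces, e, self._wall_rad, ncap, nbad)

    def potential_energy(self, system: ParticleSystem) -> float:
        """Total potential without touching junction states."""
        saved = self.topology.as_state.copy()
        res = self.compute(system)
        self.topology.as_state[:] = saved
        return res.potential
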