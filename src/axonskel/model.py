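"""Particle system, topology, and deterministic geometry builders.

Coordinates are in reduced units (sigma) with the axon axis along z and the
actin rings in x-y planes.  Radial distances are measured from the z axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import ModelConfig

# particle kinds
ACTIN, SPECTRIN, ANKYRIN = 0, 1, 2
KIND_NAMES = ("actin", "spectrin", "ankyrin")
KIND_TAGS = ("A", "S", "K")
#: physical bead radii in nm (actin junction, spectrin repeat, ankyrin complex)
KIND_RADII_NM = (17.5, 2.5, 12.5)

# bond types
BOND_SS, BOND_AA, BOND_SK = 0, 1, 2


@dataclass
class ParticleSystem:
    """Positions, velocities, kinds, and mobility flags of all beads."""

    pos: np.ndarray          # (N, 3) float64, sigma units
    vel: np.ndarray          # (N, 3) float64, sigma / t_s
    kind: np.ndarray         # (N,) int8
    mobile: np.ndarray       # (N,) bool

    @property
    def n(self) -> int:
        return self.pos.shape[0]

    def count(self, kind: int) -> int:
        return int(np.sum(self.kind == kind))

    def radial_distance(self) -> np.ndarray:
        return np.hypot(self.pos[:, 0], self.pos[:, 1])

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            self.pos.copy(), self.vel.copy(), self.kind.copy(), self.mobile.copy()
        )


@dataclass
class Topology:
    """Typed bond lists, ring angle triplets, and breakable junction pairs.

    ``as_pairs`` holds the designated actin-spectrin junctions (one actin
    bead per filament end); ``as_state`` is the live bond state (1 intact,
    0 broken) and is mutated by the force field.
    """

    bonds: np.ndarray        # (nb, 2) int64
    bond_type: np.ndarray    # (nb,) int8 (BOND_SS / BOND_AA / BOND_SK)
    bond_k: np.ndarray       # (nb,) float64, eps/sigma^2
    bond_r0: np.ndarray      # (nb,) float64, sigma
    angles: np.ndarray       # (na, 3) int64, consecutive ring/filament triples
    angle_theta0: float      # rad
    ring_of_actin: np.ndarray  # (n_actin,) int64, ring index per actin bead
    n_rings: int
    as_pairs: np.ndarray     # (m, 2) int64: (actin index, spectrin index)
    as_state: np.ndarray     # (m,) uint8
    as_recapture_ok: np.ndarray  # (m,) uint8
    as_gap: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    as_filament: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    as_end: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    def n_bonds_of_type(self, btype: int) -> int:
        return int(np.sum(self.bond_type == btype))

    def as_pair_index(self, gap: int, filament: int, end: int) -> int:
        """Index into ``as_pairs`` for a filament end (end 0 = lower ring)."""
        hits = np.flatnonzero(
            (self.as_gap == gap) & (self.as_filament == filament) & (self.as_end == end)
        )
        if hits.size != 1:
            raise KeyError(f"no unique AS pair for gap={gap}, filament={filament}, end={end}")
        return int(hits[0])

    def copy(self) -> "Topology":
        import dataclasses

        kwargs = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            kwargs[f.name] = v.copy() if isinstance(v, np.ndarray) else v
        return Topology(**kwargs)

    def to_json_dict(self) -> dict:
        return {
            "bonds": self.bonds.tolist(),
            "bond_type": self.bond_type.tolist(),
            "angles": self.angles.tolist(),
            "angle_theta0": self.angle_theta0,
            "ring_of_actin": self.ring_of_actin.tolist(),
            "n_rings": self.n_rings,
            "as_pairs": self.as_pairs.tolist(),
            "as_state": self.as_state.tolist(),
        }


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def particle_counts(config: ModelConfig) -> tuple[int, int, int]:
    """(n_actin, n_spectrin, n_ankyrin) implied by the builder formula."""
    gaps = config.n_rings - 1
    n_actin = config.n_rings * config.particles_per_ring
    n_spectrin = gaps * config.filaments_per_gap * config.beads_per_filament
    n_ankyrin = gaps * config.filaments_per_gap
    return n_actin, n_spectrin, n_ankyrin


def build_axon(config: ModelConfig) -> tuple[ParticleSystem, Topology]:
    """Construct the axon membrane skeleton geometry and topology.

    Rings of ``particles_per_ring`` actin beads lie in x-y planes spaced
    ``ring_spacing_nm`` along z.  Filament f of every gap runs between the
    angularly aligned actin beads f of the bounding rings; its 41 beads are
    equally spaced on the straight segment between the two junction points
    (offset ``junction_eq_nm`` along z from each actin bead centre), which
    leaves the chain under entropic tension once thermalised.  One ankyrin
    bead sits radially outward (at the ankyrin confinement radius) of each
    filament's attachment bead.
    """
    if config.n_rings < 2:
        raise ValueError("build_axon requires n_rings >= 2")
    config.validate()

    sig = config.units.sigma_nm
    n_ring = config.particles_per_ring
    n_fil = config.filaments_per_gap
    n_bead = config.beads_per_filament
    gaps = config.n_rings - 1

    R = config.ring_radius_nm / sig
    spacing = config.ring_spacing_nm / sig
    jeq = config.junction_eq_nm / sig
    r_ank = config.ankyrin_confine_radius_nm / sig

    n_actin, n_spectrin, n_ankyrin = particle_counts(config)
    N = n_actin + n_spectrin + n_ankyrin
    pos = np.zeros((N, 3))
    kind = np.empty(N, np.int8)

    phi = 2.0 * math.pi * np.arange(n_ring) / n_ring
    cphi, sphi = np.cos(phi), np.sin(phi)

    def actin_id(g: int, j: int) -> int:
        return g * n_ring + j

    def spectrin_id(g: int, f: int, b: int) -> int:
        return n_actin + (g * n_fil + f) * n_bead + b

    def ankyrin_id(g: int, f: int) -> int:
        return n_actin + n_spectrin + g * n_fil + f

    # actin rings
    for g in range(config.n_rings):
        sl = slice(g * n_ring, (g + 1) * n_ring)
        pos[sl, 0] = R * cphi
        pos[sl, 1] = R * sphi
        pos[sl, 2] = g * spacing
    kind[:n_actin] = ACTIN

    # spectrin filaments: straight, equally spaced between the junction points
    frac = np.linspace(0.0, 1.0, n_bead)
    for g in range(gaps):
        z0 = g * spacing + jeq
        z1 = (g + 1) * spacing - jeq
        for f in range(n_fil):
            i0 = spectrin_id(g, f, 0)
            pos[i0 : i0 + n_bead, 0] = R * cphi[f % n_ring]
            pos[i0 : i0 + n_bead, 1] = R * sphi[f % n_ring]
            pos[i0 : i0 + n_bead, 2] = z0 + frac * (z1 - z0)
    kind[n_actin : n_actin + n_spectrin] = SPECTRIN

    # ankyrin: radially outward of each filament's attachment bead
    attach = config.ankyrin_attach_bead - 1  # 0-based
    for g in range(gaps):
        for f in range(n_fil):
            i = ankyrin_id(g, f)
            zb = pos[spectrin_id(g, f, attach), 2]
            pos[i] = (r_ank * cphi[f % n_ring], r_ank * sphi[f % n_ring], zb)
    kind[n_actin + n_spectrin :] = ANKYRIN

    # ---- topology ----
    bonds, btype, bk, br0 = [], [], [], []

    bond_ss_r0 = config.spectrin_bond_eq_nm / sig
    bond_aa_r0 = config.actin_bead_diameter_nm / sig
    bond_sk_r0 = config.sk_eq_nm / sig

    for g in range(gaps):
        for f in range(n_fil):
            for b in range(n_bead - 1):
                bonds.append((spectrin_id(g, f, b), spectrin_id(g, f, b + 1)))
                btype.append(BOND_SS)
                bk.append(config.k0)
                br0.append(bond_ss_r0)
    for g in range(config.n_rings):
        for j in range(n_ring):
            bonds.append((actin_id(g, j), actin_id(g, (j + 1) % n_ring)))
            btype.append(BOND_AA)
            bk.append(config.kA)
            br0.append(bond_aa_r0)
    for g in range(gaps):
        for f in range(n_fil):
            bonds.append((ankyrin_id(g, f), spectrin_id(g, f, attach)))
            btype.append(BOND_SK)
            bk.append(config.k_sk)
            br0.append(bond_sk_r0)

    angles = []
    for g in range(config.n_rings):
        for j in range(n_ring):
            angles.append(
                (
                    actin_id(g, (j - 1) % n_ring),
                    actin_id(g, j),
                    actin_id(g, (j + 1) % n_ring),
                )
            )

    as_pairs, as_gap, as_fil, as_end = [], [], [], []
    for g in range(gaps):
        for f in range(n_fil):
            as_pairs.append((actin_id(g, f % n_ring), spectrin_id(g, f, 0)))
            as_gap.append(g), as_fil.append(f), as_end.append(0)
            as_pairs.append((actin_id(g + 1, f % n_ring), spectrin_id(g, f, n_bead - 1)))
            as_gap.append(g), as_fil.append(f), as_end.append(1)

    topo = Topology(
        bonds=np.asarray(bonds, np.int64).reshape(-1, 2),
        bond_type=np.asarray(btype, np.int8),
        bond_k=np.asarray(bk, float),
        bond_r0=np.asarray(br0, float),
        angles=np.asarray(angles, np.int64).reshape(-1, 3),
        angle_theta0=math.radians(config.theta0_deg),
        ring_of_actin=np.repeat(np.arange(config.n_rings), n_ring),
        n_rings=config.n_rings,
        as_pairs=np.asarray(as_pairs, np.int64).reshape(-1, 2),
        as_state=np.ones(len(as_pairs), np.uint8),
        as_recapture_ok=np.ones(len(as_pairs), np.uint8),
        as_gap=np.asarray(as_gap, np.int64),
        as_filament=np.asarray(as_fil, np.int64),
        as_end=np.asarray(as_end, np.int64),
    )
    system = ParticleSystem(
        pos=pos, vel=np.zeros_like(pos), kind=kind, mobile=np.ones(N, bool)
    )
    return system, topo


def build_free_spectrin(config: ModelConfig | None = None) -> tuple[ParticleSystem, Topology]:
    """A single free spectrin tetramer: 41 beads, 40 bonds, no confinement."""
    config = config or ModelConfig()
    n = config.beads_per_filament
    r0 = config.spectrin_bond_eq_nm / config.units.sigma_nm
    pos = np.zeros((n, 3))
    pos[:, 2] = np.arange(n) * r0
    bonds = np.column_stack([np.arange(n - 1), np.arange(1, n)]).astype(np.int64)
    topo = Topology(
        bonds=bonds,
        bond_type=np.full(n - 1, BOND_SS, np.int8),
        bond_k=np.full(n - 1, config.k0),
        bond_r0=np.full(n - 1, r0),
        angles=np.empty((0, 3), np.int64),
        angle_theta0=math.pi,
        ring_of_actin=np.empty(0, np.int64),
        n_rings=0,
        as_pairs=np.empty((0, 2), np.int64),
        as_state=np.empty(0, np.uint8),
        as_recapture_ok=np.empty(0, np.uint8),
    )
    system = ParticleSystem(
        pos=pos,
        vel=np.zeros_like(pos),
        kind=np.full(n, SPECTRIN, np.int8),
        mobile=np.ones(n, bool),
    )
    return system, topo


def build_free_ring_filament(
    n_beads: int, clamped: bool = False, config: ModelConfig | None = None
) -> tuple[ParticleSystem, Topology]:
    """A straight free filament of ring material (actin beads).

    Uses the ring bond (kA) and bending FENE (kb) parameters with the
    straight-filament equilibrium angle theta0 = 180 deg; used for the
    bending-rigidity calibration.  ``clamped`` freezes the first two beads.
    """
    if n_beads < 3:
        raise ValueError("build_free_ring_filament requires n_beads >= 3")
    config = config or ModelConfig()
    a = config.actin_bead_diameter_nm / config.units.sigma_nm
    pos = np.zeros((n_beads, 3))
    pos[:, 2] = np.arange(n_beads) * a
    bonds = np.column_stack([np.arange(n_beads - 1), np.arange(1, n_beads)]).astype(np.int64)
    angles = np.column_stack(
        [np.arange(n_beads - 2), np.arange(1, n_beads - 1), np.arange(2, n_beads)]
    ).astype(np.int64)
    topo = Topology(
        bonds=bonds,
        bond_type=np.full(n_beads - 1, BOND_AA, np.int8),
        bond_k=np.full(n_beads - 1, config.kA),
        bond_r0=np.full(n_beads - 1, a),
        angles=angles,
        angle_theta0=math.pi,
        ring_of_actin=np.empty(0, np.int64),
        n_rings=0,
        as_pairs=np.empty((0, 2), np.int64),
        as_state=np.empty(0, np.uint8),
        as_recapture_ok=np.empty(0, np.uint8),
    )
    mobile = np.ones(n_beads, bool)
    if clamped:
        mobile[:2] = False
    system = ParticleSystem(
        pos=pos,
        vel=np.zeros((n_beads, 3)),
        kind=np.full(n_beads, ACTIN, np.int8),
        mobile=mobile,
    )
    return system, topo
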