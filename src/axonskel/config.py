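"""Model configuration: geometry counts and force-field parameters.

All lengths are stated in nanometres, spring constants in the reduced units
in which they are usually quoted (epsilon/sigma^2 for harmonic springs,
kB*T for the ring bending parameter, kB*T/sigma for the inter-ring FENE
parameter).  The builder and force field convert everything to reduced
units internally through :class:`axonskel.units.UnitSystem`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .units import UnitSystem

#: junction (actin-spectrin equilibrium) sizes considered by the model, nm
STANDARD_JUNCTION_SIZES = (5.0, 10.0, 15.0, 20.0)


@dataclass
class ModelConfig:
    """Geometry and force-field parameters of the axon membrane skeleton.

    Defaults describe the reference configuration: actin rings of 39 beads
    (35 nm diameter each, ring diameter ~434 nm) spaced 185 nm along the
    axon, connected by 39 spectrin tetramers per gap (41 beads, 40 bonds,
    200 nm contour), each anchored to the bilayer through one ankyrin
    particle at its 20th bead.
    """

    # geometry
    n_rings: int = 3
    ring_spacing_nm: float = 185.0
    particles_per_ring: int = 39
    actin_bead_diameter_nm: float = 35.0
    filaments_per_gap: int = 39
    beads_per_filament: int = 41
    spectrin_bond_eq_nm: float = 5.0
    junction_eq_nm: float = 20.0
    ankyrin_attach_bead: int = 20  # 1-based bead index along the filament
    spectrin_confine_radius_nm: float = 217.0
    ankyrin_confine_radius_nm: float = 232.0

    # force field (reduced units unless suffixed)
    k0: float = 3.56            # spectrin bond, eps/sigma^2
    eps1: float = 1.0 / 16.0    # spectrin-spectrin repulsion, eps
    kA: float = 38.0            # actin ring bond, eps/sigma^2
    kb_kT: float = 3500.0       # ring bending FENE parameter, kB*T
    dtheta_max_frac: float = 0.3
    kmt_kT_per_sigma: float = 477.0  # inter-ring FENE parameter, kB*T/sigma
    dd_max_frac: float = 0.3
    kc_frac: float = 0.1        # confinement stiffness as a fraction of k0
    k_sk: float = 3.56          # spectrin-ankyrin bond, eps/sigma^2
    sk_eq_nm: float = 15.0

    # thermodynamics / integration
    kT_over_eps: float = 0.03
    dt: float = 0.01            # in t_s
    seed: int = 0

    allow_nonstandard_junction: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------

    def validate(self) -> None:
        counts = {
            "n_rings": self.n_rings,
            "particles_per_ring": self.particles_per_ring,
            "beads_per_filament": self.beads_per_filament,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if int(self.filaments_per_gap) != self.filaments_per_gap or self.filaments_per_gap < 0:
            raise ValueError("filaments_per_gap must be a non-negative integer")
        positive = {
            "ring_spacing_nm": self.ring_spacing_nm,
            "actin_bead_diameter_nm": self.actin_bead_diameter_nm,
            "spectrin_bond_eq_nm": self.spectrin_bond_eq_nm,
            "junction_eq_nm": self.junction_eq_nm,
            "k0": self.k0,
            "kA": self.kA,
            "kb_kT": self.kb_kT,
            "kmt_kT_per_sigma": self.kmt_kT_per_sigma,
            "dt": self.dt,
            "kT_over_eps": self.kT_over_eps,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value!r}")
        if (
            self.junction_eq_nm not in STANDARD_JUNCTION_SIZES
            and not self.allow_nonstandard_junction
        ):
            raise ValueError(
                f"junction_eq_nm must be one of {STANDARD_JUNCTION_SIZES} "
                "(set allow_nonstandard_junction=True to override)"
            )
        if not 1 <= self.ankyrin_attach_bead <= self.beads_per_filament:
            raise ValueError("ankyrin_attach_bead outside the filament")

    # ------------------------------------------------------------------

    @property
    def units(self) -> UnitSystem:
        return UnitSystem(kT_over_eps=self.kT_over_eps)

    @property
    def ring_radius_nm(self) -> float:
        """Radius of the circle through the actin bead centres.

        39 chords of 35 nm close into a circle of diameter ~434 nm.
        """
        import math

        return (self.actin_bead_diameter_nm / 2.0) / math.sin(
            math.pi / self.particles_per_ring
        )

    @property
    def theta0_deg(self) -> float:
        """Equilibrium ring angle, 180 * (n - 2) / n degrees."""
        n = self.particles_per_ring
        return 180.0 * (n - 2) / n

    @property
    def contour_length_nm(self) -> float:
        return (self.beads_per_filament - 1) * self.spectrin_bond_eq_nm

    @property
    def spectrin_span_nm(self) -> float:
        """Built end-to-end distance of a filament between its junctions."""
        return self.ring_spacing_nm - 2.0 * self.junction_eq_nm

    # ------------------------------------------------------------------

    def replace(self, **kwargs) -> "ModelConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
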