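"""Reduced simulation units and SI conversions.

The model is formulated in Lennard-Jones-style reduced units: length sigma,
energy epsilon, and the spectrin-bead mass m as the mass unit.  The length
unit is fixed by requiring the spectrin bead diameter (the minimum of the
bead-bead repulsion, ``2**(1/6) * sigma``) to equal the 5 nm spectrin repeat
spacing, giving sigma = 4.45 nm.  The energy unit is fixed by the reduced
temperature: kT/epsilon = 0.03 at T = 300 K, i.e. epsilon ~ 0.86 eV, the
actin-spectrin association energy.  The time unit is
``t_s = sqrt(m * sigma**2 / epsilon)``.
"""

from __future__ import annotations

from dataclasses import dataclass

KB = 1.380649e-23  # J/K
EV = 1.602176634e-19  # J

#: quantity kinds accepted by :meth:`UnitSystem.to_SI` / :meth:`UnitSystem.from_SI`
QUANTITY_KINDS = ("length", "energy", "force", "stiffness", "pressure", "time")


@dataclass(frozen=True)
class UnitSystem:
    """Reduced-unit definitions and algebraic SI conversions.

    Parameters
    ----------
    sigma_nm:
        Length unit in nanometres.
    kT_over_eps:
        Reduced temperature; fixes the energy unit via
        ``epsilon = kB * T_kelvin / kT_over_eps``.
    T_kelvin:
        Physical temperature the reduced temperature refers to.
    mass_kg:
        SI mass of one spectrin bead.  The model never needs it (all
        equilibrium statistics are mass independent) so it defaults to
        ``None``; time conversions require an explicit value.
    """

    sigma_nm: float = 4.45
    kT_over_eps: float = 0.03
    T_kelvin: float = 300.0
    mass_kg: float | None = None

    # -- derived scales ----------------------------------------------------

    @property
    def kBT_J(self) -> float:
        return KB * self.T_kelvin

    @property
    def epsilon_J(self) -> float:
        return self.kBT_J / self.kT_over_eps

    @property
    def epsilon_eV(self) -> float:
        return self.epsilon_J / EV

    @property
    def sigma_m(self) -> float:
        return self.sigma_nm * 1e-9

    @property
    def bead_diameter_nm(self) -> float:
        """Equilibrium spacing of the bead-bead repulsion, 2^(1/6) sigma."""
        return 2.0 ** (1.0 / 6.0) * self.sigma_nm

    @property
    def eps_per_sigma2_N_per_m(self) -> float:
        """One reduced spring constant (epsilon/sigma^2) in N/m."""
        return self.epsilon_J / self.sigma_m**2

    @property
    def eps_per_sigma3_Pa(self) -> float:
        """One reduced pressure/modulus (epsilon/sigma^3) in Pa."""
        return self.epsilon_J / self.sigma_m**3

    @property
    def kBT_per_sigma_N(self) -> float:
        """Thermal force scale kB*T/sigma in newtons."""
        return self.kBT_J / self.sigma_m

    @property
    def t_s_seconds(self) -> float:
        if self.mass_kg is None:
            raise ValueError(
                "time conversion requires an explicit bead mass (mass_kg)"
            )
        return (self.mass_kg * self.sigma_m**2 / self.epsilon_J) ** 0.5

    # -- conversions -------------------------------------------------------

    def _si_scale(self, quantity_kind: str) -> float:
        if quantity_kind == "length":
            return self.sigma_m
        if quantity_kind == "energy":
            return self.epsilon_J
        if quantity_kind == "force":
            return self.epsilon_J / self.sigma_m
        if quantity_kind == "stiffness":
            return self.eps_per_sigma2_N_per_m
        if quantity_kind == "pressure":
            return self.eps_per_sigma3_Pa
        if quantity_kind == "time":
            return self.t_s_seconds
        raise ValueError(
            f"unknown quantity_kind {quantity_kind!r}; expected one of {QUANTITY_KINDS}"
        )

    def to_SI(self, value: float, quantity_kind: str) -> float:
        """Convert a reduced-unit value to SI (m, J, N, N/m, Pa, s)."""
        return value * self._si_scale(quantity_kind)

    def from_SI(self, value: float, quantity_kind: str) -> float:
        """Inverse of :meth:`to_SI`."""
        return value / self._si_scale(quantity_kind)

    # -- common shortcuts --------------------------------------------------

    def nm_to_sigma(self, nm: float) -> float:
        return nm / self.sigma_nm

    def sigma_to_nm(self, sigma: float) -> float:
        return sigma * self.sigma_nm

    def pressure_red_to_kPa(self, p_red: float) -> float:
        return p_red * self.eps_per_sigma3_Pa / 1e3

    def stiffness_red_to_N_per_m(self, k_red: float) -> float:
        return k_red * self.eps_per_sigma2_N_per_m

    def kmt_from_longitudinal_modulus(
        self, E_L_kPa: float = 10.0, radius_nm: float = 217.0
    ) -> float:
        """Inter-ring FENE parameter k_mt = 0.3 * E_L * pi * R^2, in kB*T/sigma.

        The inter-ring restraint represents microtubule/neurofilament support
        of the ring spacing; its small-deformation spring constant is matched
        to an axon of longitudinal Young's modulus ``E_L`` and radius ``R``.
        """
        k_mt_N = 0.3 * E_L_kPa * 1e3 * 3.141592653589793 * (radius_nm * 1e-9) ** 2
        return k_mt_N / self.kBT_per_sigma_N
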