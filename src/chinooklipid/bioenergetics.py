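"""Energy accounting for migrating Chinook and their killer-whale predator.

Three pieces of arithmetic connect the lipid survey to predator ecology:

* gonadal investment — the energy a maturing fish moves into its gonads
  as its GSI (gonad mass / somatic mass) rises over the run, at a gonad
  energy density of 7.79 kJ/g;
* whole-body energy — body mass times energy density, the latter an
  affine function of whole-body lipid content (see
  :func:`chinooklipid.survey.fit_ed_conversion`);
* prey requirements — how many average-mass Chinook per year a resident
  killer-whale population needs at a given prey energy density. The
  predator's annual energy demand is back-calculated from a reference
  scenario (245,000 fish/year of 8 kg, 1900 kcal/kg spring-run prey)
  rather than re-deriving the whale energetics model.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import reference
from .survey import EnergyConversion, energy_density

KJ_PER_KCAL = reference.KJ_PER_KCAL
G_PER_KG = 1000.0


@dataclass(frozen=True)
class GonadEnergyParams:
    """Gonad energy density and the mass basis for the GSI arithmetic.

    ``mass_basis="total"`` treats the fish mass given to
    :func:`gonad_energy_change` as total body mass (gonad mass =
    ``m * gsi / (1 + gsi)``); ``"somatic"`` treats it as somatic mass
    (gonad mass = ``m * gsi``).
    """

    gonad_energy_density: float = 7.79   # kJ/g
    mass_basis: str = "total"            # {"total", "somatic"}

    def __post_init__(self) -> None:
        if self.gonad_energy_density <= 0:
            raise ValueError("gonad_energy_density must be positive")
        if self.mass_basis not in ("total", "somatic"):
            raise ValueError(f"unknown mass_basis {self.mass_basis!r}")


def gonad_mass_from_gsi(total_mass: float, gsi: float) -> float:
    """Gonad mass (kg) of a fish of ``total_mass`` kg with the given GSI.

    GSI is gonad over somatic mass, so gonad = total * gsi / (1 + gsi).
    Inverse of :func:`chinooklipid.homogenate.gonadosomatic_index`.
    """
    if total_mass <= 0:
        raise ValueError("total_mass must be positive")
    if gsi < 0:
        raise ValueError("gsi must be nonnegative")
    return total_mass * gsi / (1.0 + gsi)


def gonad_energy_change(
    mass: float,
    gsi_start: float,
    gsi_end: float,
    params: GonadEnergyParams = GonadEnergyParams(),
) -> float:
    """Energy (kJ) invested in gonad growth as GSI moves start→end.

    For the printed worked example — an average 8 kg fall-run fish whose
    GSI rises from 0.1 to 0.2 at 7.79 kJ/g on the total-mass basis — this
    is ~4721 kJ.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    if gsi_start < 0 or gsi_end < 0:
        raise ValueError("GSI values must be nonnegative")
    if params.mass_basis == "total":
        dm = gonad_mass_from_gsi(mass, gsi_end) - gonad_mass_from_gsi(mass, gsi_start)
    else:
        dm = mass * (gsi_end - gsi_start)
    return dm * G_PER_KG * params.gonad_energy_density


def whole_body_energy(mass: float, lipid_pct: float, conv: EnergyConversion) -> float:
    """Total body energy (kJ) of a fish: mass × energy density × 4.184."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    return mass * energy_density(lipid_pct, conv) * conv.kj_per_kcal


def prey_requirement(population_energy: float, prey_mass: float, ed: float) -> float:
    """Fish per year a predator population needs.

    ``population_energy`` is the population's annual demand in kcal/year;
    ``prey_mass`` the average prey mass (kg); ``ed`` the prey energy
    density (kcal/kg).
    """
    if population_energy <= 0 or prey_mass <= 0 or ed <= 0:
        raise ValueError("all inputs must be positive")
    return population_energy / (prey_mass * ed)


def back_calculate_population_energy(prey_count: float, prey_mass: float, ed: float) -> float:
    """Annual population energy demand (kcal/year) implied by a scenario.

    Exact inverse of :func:`prey_requirement`.
    """
    if prey_count <= 0 or prey_mass <= 0 or ed <= 0:
        raise ValueError("all inputs must be positive")
    return prey_count * prey_mass * ed


def reference_population_energy() -> float:
    """SRKW annual energy demand implied by the spring-run reference scenario."""
    return back_calculate_population_energy(
        reference.SPRING5_2_PREY_COUNT,
        reference.PREY_MASS_KG,
        reference.MU_ED_MEANS["Spring5_2"],
    )


@dataclass(frozen=True)
class EnergyScenario:
    """A single-MU-diet prey-requirement scenario."""

    label: str
    prey_mass: float          # kg
    ed: float                 # kcal/kg
    population_energy: float  # kcal/year
    prey_count: float         # fish/year

    @classmethod
    def build(
        cls,
        label: str,
        ed: float,
        population_energy: float | None = None,
        prey_mass: float = reference.PREY_MASS_KG,
    ) -> "EnergyScenario":
        if population_energy is None:
            population_energy = reference_population_energy()
        return cls(
            label=label, prey_mass=prey_mass, ed=ed,
            population_energy=population_energy,
            prey_count=prey_requirement(population_energy, prey_mass, ed),
        )
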