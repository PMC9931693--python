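"""Whole-body composition of homogenized calibration fish.

A calibration fish is processed as two compartments: somatic tissue
(carcase plus viscera) and gonad. Tissue lipid is measured gravimetrically
on dried subsamples (somatic in triplicate, gonad in duplicate), converted
back to a wet-mass fraction using the tissue water fraction, and the two
compartments are combined by mass weighting into whole-body lipid content
(% wet weight). The gonadosomatic index (GSI) is gonad mass over somatic
mass, a dimensionless maturation proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date
from typing import Optional, Sequence

MASS_BALANCE_TOL = 1e-6


def dry_to_wet_lipid(lipid_frac_dry: float, water_frac: float) -> float:
    """Convert a lipid fraction of dry mass to a fraction of wet mass.

    Parameters
    ----------
    lipid_frac_dry : fraction of dry tissue mass that is lipid, in [0, 1].
    water_frac : fraction of wet tissue mass that is water, in [0, 1].

    Returns
    -------
    Lipid as a fraction of wet mass: ``lipid_frac_dry * (1 - water_frac)``.
    """
    if not (0.0 <= lipid_frac_dry <= 1.0):
        raise ValueError(f"lipid_frac_dry must be in [0, 1], got {lipid_frac_dry}")
    if not (0.0 <= water_frac <= 1.0):
        raise ValueError(f"water_frac must be in [0, 1], got {water_frac}")
    return lipid_frac_dry * (1.0 - water_frac)


def whole_body_lipid(
    somatic_mass: float,
    somatic_lipid_wet: float,
    gonad_mass: float,
    gonad_lipid_wet: float,
) -> float:
    """Mass-weighted whole-body lipid content in % wet weight.

    Combines the somatic and gonadal compartments:
    ``100 * (m_s * f_s + m_g * f_g) / (m_s + m_g)``. The result always lies
    between the two tissue percentages (convex combination).
    """
    if somatic_mass < 0 or gonad_mass < 0:
        raise ValueError("tissue masses must be nonnegative")
    if somatic_mass + gonad_mass <= 0:
        raise ValueError("at least one tissue mass must be positive")
    for name, frac in (("somatic_lipid_wet", somatic_lipid_wet),
                       ("gonad_lipid_wet", gonad_lipid_wet)):
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {frac}")
    total = somatic_mass + gonad_mass
    return 100.0 * (somatic_mass * somatic_lipid_wet + gonad_mass * gonad_lipid_wet) / total


def gonadosomatic_index(gonad_mass: float, somatic_mass: float) -> float:
    """GSI = gonad mass / somatic mass (dimensionless ratio)."""
    if somatic_mass <= 0:
        raise ValueError(f"somatic_mass must be positive, got {somatic_mass}")
    if gonad_mass < 0:
        raise ValueError(f"gonad_mass must be nonnegative, got {gonad_mass}")
    return gonad_mass / somatic_mass


@dataclass
class CalibrationSample:
    """One homogenized fish linking fat-meter readings to measured lipid.

    Readings are the three fat-meter positions along the anterior side
    (position 1 most informative). Lipid replicates are fractions of dry
    mass; water fractions are of wet mass. ``whole_body_lipid_pct`` is
    derived (see :meth:`compute_whole_body_lipid`) unless provided.
    """

    fish_id: str
    total_mass: float                      # kg
    somatic_mass: float                    # kg
    gonad_mass: float                      # kg
    readings: Sequence[float]              # meter units, positions 1-3
    somatic_water_frac: float
    somatic_lipid_dry_reps: Sequence[float]
    gonad_lipid_dry_reps: Sequence[float] = ()
    gonad_water_frac: float = 0.0
    source: str = "test_fishery"           # {troll, test_fishery}
    capture_date: Optional[_date] = None
    sex: str = "unknown"                   # {M, F, unknown}
    fork_length: Optional[float] = None    # cm
    whole_body_lipid_pct: Optional[float] = field(default=None)

    def __post_init__(self) -> None:
        if abs(self.somatic_mass + self.gonad_mass - self.total_mass) > max(
            MASS_BALANCE_TOL, MASS_BALANCE_TOL * self.total_mass
        ):
            raise ValueError(
                f"fish {self.fish_id}: somatic + gonad mass "
                f"({self.somatic_mass} + {self.gonad_mass}) != total {self.total_mass}"
            )
        if len(self.readings) != 3:
            raise ValueError(f"fish {self.fish_id}: expected 3 readings")
        if any(r < 0 for r in self.readings):
            raise ValueError(f"fish {self.fish_id}: readings must be >= 0")
        for name, frac in (("somatic_water_frac", self.somatic_water_frac),
                           ("gonad_water_frac", self.gonad_water_frac)):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"fish {self.fish_id}: {name} outside [0, 1]")
        for name, reps in (("somatic_lipid_dry_reps", self.somatic_lipid_dry_reps),
                           ("gonad_lipid_dry_reps", self.gonad_lipid_dry_reps)):
            if any(not (0.0 <= r <= 1.0) for r in reps):
                raise ValueError(f"fish {self.fish_id}: {name} outside [0, 1]")
        if self.whole_body_lipid_pct is None:
            self.whole_body_lipid_pct = self.compute_whole_body_lipid()
        if not (0.0 <= self.whole_body_lipid_pct <= 100.0):
            raise ValueError(f"fish {self.fish_id}: whole_body_lipid_pct outside [0, 100]")

    @property
    def somatic_lipid_wet(self) -> float:
        """Somatic lipid as fraction of wet mass, replicates averaged first."""
        reps = list(self.somatic_lipid_dry_reps)
        if not reps:
            raise ValueError(f"fish {self.fish_id}: no somatic lipid replicates")
        return dry_to_wet_lipid(sum(reps) / len(reps), self.somatic_water_frac)

    @property
    def gonad_lipid_wet(self) -> float:
        """Gonad lipid as fraction of wet mass; 0 when no gonad replicates."""
        reps = list(self.gonad_lipid_dry_reps)
        if not reps:
            return 0.0
        return dry_to_wet_lipid(sum(reps) / len(reps), self.gonad_water_frac)

    def compute_whole_body_lipid(self) -> float:
        """Whole-body lipid (% wet weight) from replicate means."""
        return whole_body_lipid(
            self.somatic_mass, self.somatic_lipid_wet,
            self.gonad_mass, self.gonad_lipid_wet,
        )

    @property
    def gsi(self) -> float:
        return gonadosomatic_index(self.gonad_mass, self.somatic_mass)
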