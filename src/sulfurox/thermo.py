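"""Thermodynamic constants and Gibbs free energies of balanced reactions.

All reaction energies are expressed in kJ per mole of the sulfur substrate
at the biochemical standard state (pH 7, 1 M, 25 degC).  Non-standard
conditions enter only through the reaction quotient term RT ln Q
(``delta_g`` = standard + quotient); the formation energies themselves are
not temperature-corrected.

Conventions
-----------
* Activities are approximated by molar concentrations.
* Elemental sulfur, water and biomass carbon (CH2O) carry activity 1.
* Formation energies are pH-7 biochemical standard values, i.e. H+ is
  already priced at 1e-7 M.  The quotient therefore uses the H+ activity
  *relative to* 1e-7, 10**-(pH-7), so that RT ln Q vanishes exactly at
  pH 7 with all concentrations at 1 M.
* Redox carriers are priced through the reduced-minus-oxidized increment
  (60.99 NADH, 42.65 FADH2, 38.88 Fd_red kJ per mole reduced carrier);
  only the difference is thermodynamically meaningful.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import TYPE_CHECKING, Mapping

import pandas as pd

from .exceptions import InadmissibleParameterError, UnknownSpeciesError
from .species import ACTIVITY_ONE

if TYPE_CHECKING:  # pragma: no cover
    from .stoichiometry import Stoichiometry

logger = logging.getLogger(__name__)

#: gas constant, kJ mol-1 K-1
R_KJ = 8.314462618e-3
#: biochemical standard temperature, K
T_STANDARD = 298.15
PH_STANDARD = 7.0

_CARRIER_COUPLES = {"NADH": "NAD+", "FADH2": "FAD", "Fd_red": "Fd_ox"}


@dataclass(frozen=True)
class Conditions:
    """Reactant concentrations (M), pH and temperature (K) defining Q.

    An empty concentration map means every quotient-active species sits at
    the 1 M standard state.
    """

    concentrations: Mapping[str, float] = field(default_factory=dict)
    pH: float = PH_STANDARD
    temperature: float = T_STANDARD

    def __post_init__(self) -> None:
        for sp, c in self.concentrations.items():
            if not c > 0:
                raise InadmissibleParameterError(
                    f"concentration of {sp} must be positive, got {c}"
                )
        if not 0.0 <= self.pH <= 14.0:
            raise InadmissibleParameterError(f"pH must be in [0, 14], got {self.pH}")
        if not self.temperature > 0:
            raise InadmissibleParameterError(
                f"temperature must be positive, got {self.temperature}"
            )

    @classmethod
    def standard(cls) -> "Conditions":
        """Standard biochemical conditions: 1 M, pH 7, 298.15 K."""
        return cls()

    @classmethod
    def environmental(cls, concentration: float = 1e-3) -> "Conditions":
        """All dissolved reactants at ``concentration`` (default 1 mM), pH 7.

        Carrier pools are left at the standard ratio of 1.
        """
        dissolved = ("H2S", "S2O3", "O2", "SO4", "CO2", "NO3", "N2", "NH4")
        return cls(concentrations={sp: concentration for sp in dissolved})

    def replace(self, **overrides: float) -> "Conditions":
        """A copy with single species concentrations (or pH/temperature) changed."""
        conc = dict(self.concentrations)
        pH = overrides.pop("pH", self.pH)
        temperature = overrides.pop("temperature", self.temperature)
        conc.update(overrides)
        return Conditions(concentrations=conc, pH=pH, temperature=temperature)

    def activity(self, species: str, warn_missing: bool = True) -> float:
        if species in ACTIVITY_ONE:
            return 1.0
        if species == "H+":
            return 10.0 ** -(self.pH - PH_STANDARD)
        try:
            return float(self.concentrations[species])
        except KeyError:
            if self.concentrations and warn_missing:
                logger.warning(
                    "no concentration given for %s; defaulting to 1 M", species
                )
            return 1.0


@dataclass(frozen=True)
class ReactionEnergy:
    """Gibbs free energy split into standard and RT ln Q parts (kJ/mol substrate)."""

    standard: float
    quotient_term: float

    @property
    def total(self) -> float:
        return self.standard + self.quotient_term


@dataclass(frozen=True)
class ThermoTable:
    """Formation free energies and the ATP energy content.

    ``formation_energy`` maps species token -> dGf0' in kJ/mol at the pH-7
    biochemical standard state.  Carrier couples are encoded by pinning the
    oxidized form at 0 and storing the reduction increment on the reduced
    form.
    """

    formation_energy: Mapping[str, float]
    atp_energy: float = 41.0

    @property
    def couple_increments(self) -> dict[str, float]:
        """kJ per mole of reduced carrier (reduced minus oxidized form)."""
        fe = self.formation_energy
        return {red: fe[red] - fe[ox] for red, ox in _CARRIER_COUPLES.items()}

    @classmethod
    def from_file(cls, path, atp_energy: float = 41.0) -> "ThermoTable":
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        df.columns = [c.strip() for c in df.columns]
        species_col, value_col = df.columns[:2]
        table = dict(zip(df[species_col].astype(str), df[value_col].astype(float)))
        return cls(formation_energy=table, atp_energy=atp_energy)

    @classmethod
    def default(cls) -> "ThermoTable":
        global _DEFAULT_TABLE
        if _DEFAULT_TABLE is None:
            with resources.as_file(
                resources.files("sulfurox") / "data" / "thermo_table.tsv"
            ) as path:
                _DEFAULT_TABLE = cls.from_file(path)
        return _DEFAULT_TABLE


_DEFAULT_TABLE: ThermoTable | None = None


def reaction_standard_energy(stoich: "Stoichiometry", table: ThermoTable | None = None) -> float:
    """Sum nu_i * dGf0'_i over the reaction, kJ per mole of sulfur substrate.

    Products carry positive, reactants negative coefficients; the substrate
    is normalized to -1 by the builders, so the result is per mole substrate.
    """
    table = table or ThermoTable.default()
    total = 0.0
    for sp, nu in stoich.coefficients.items():
        try:
            total += nu * table.formation_energy[sp]
        except KeyError:
            raise UnknownSpeciesError(
                f"unknown species {sp!r}: no formation energy in the thermo table"
            ) from None
    return total


def reaction_quotient_term(stoich: "Stoichiometry", cond: Conditions) -> float:
    """RT ln Q in kJ per mole substrate.

    Each species contributes activity**nu; S0, H2O and CH2O have activity 1
    and H+ contributes relative to the pH-7 standard state.
    """
    rt = R_KJ * cond.temperature
    log_q = 0.0
    for sp, nu in stoich.coefficients.items():
        a = cond.activity(sp)
        if a != 1.0:
            log_q += nu * math.log(a)
    return rt * log_q


def delta_g(
    stoich: "Stoichiometry",
    cond: Conditions | None = None,
    table: ThermoTable | None = None,
) -> ReactionEnergy:
    """Gibbs free energy of a reaction: dGr = dGr0 + RT ln Q."""
    cond = cond or Conditions.standard()
    return ReactionEnergy(
        standard=reaction_standard_energy(stoich, table),
        quotient_term=reaction_quotient_term(stoich, cond),
    )
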