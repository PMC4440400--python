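"""Energy-conservation efficiencies of autotrophic sulfur oxidation.

Two definitions are computed, both as ratios of endergonic to exergonic
Gibbs free energies per mole of sulfur substrate:

* traditional: ``eps_I = (1-y) dGr(CO2 red) / (-y dGr(TEA red))`` where
  dGr(CO2 red) is the free energy of the *net* assimilation reaction;
* carrier-resolved: ``eps_II = (1-y) [dGr(RET) + dGr(CO2 fix)] /
  (-y dGr(TEA red))``, which splits CO2 reduction into reverse electron
  transport (RET) and the carbon pathway's own requirement (69.7 kJ/mol CO2
  for the Calvin cycle, 64.3 for the rTCA cycle).

eps_II factorizes into partial efficiencies of ATP generation by sulfur
oxidation (eps_SO), ATP transfer (eps_t), RET (eps_RET) and CO2 fixation
(eps_CO2 — a known constant per pathway).  Only the minima of the unknown
partials are identifiable; ``factorize`` reports them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import InadmissibleParameterError, ThermodynamicError
from .stoichiometry import (
    assimilation_equation,
    energy_equation,
    get_pathway,
    get_substrate,
    get_tea,
    ret_equation,
)
from .thermo import Conditions, ThermoTable, delta_g


@dataclass(frozen=True)
class PathwayEnergetics:
    """ATP-equivalent requirement and efficiency of a CO2 fixation pathway."""

    pathway: str
    dg_co2fix: float  # kJ per mole CO2, thermodynamic requirement
    de_co2fix: float  # kJ per mole CO2, ATP-equivalent requirement

    @property
    def epsilon_co2(self) -> float:
        return self.dg_co2fix / self.de_co2fix


def pathway_energetics(pathway, table: ThermoTable | None = None) -> PathwayEnergetics:
    pw = get_pathway(pathway)
    table = table or ThermoTable.default()
    return PathwayEnergetics(
        pathway=pw.identifier,
        dg_co2fix=pw.dg_fix,
        de_co2fix=pw.atp_per_co2 * table.atp_energy,
    )


@dataclass(frozen=True)
class EfficiencyBreakdown:
    """Both efficiencies plus component energies and identifiable minima.

    All dg_* terms are kJ per mole of sulfur substrate at the evaluated
    conditions; efficiencies are fractions.
    """

    epsilon_I: float
    epsilon_II: float
    dg_energy: float          # dGr of the TEA-reducing (exergonic) reaction
    dg_co2red: float          # dGr of the net assimilation reaction
    dg_ret: float             # dGr of the RET reaction
    dg_fix_total: float       # pathway dG requirement, scaled per mole substrate
    de_fix_total: float       # pathway ATP-equivalent requirement per mole substrate
    alpha: float              # weight of CO2 fixation within total CO2 reduction
    epsilon_co2: float
    epsilon_so_min: float
    epsilon_ret_min: float
    epsilon_t_min: float


def _validate_y(y: float) -> None:
    if y == 0:
        raise InadmissibleParameterError(
            "y = 0 means no energy-generating reaction; efficiency is undefined"
        )
    if not 0.0 < y <= 1.0:
        raise InadmissibleParameterError(f"y must be in (0, 1], got {y}")


def _energy_dg(x, substrate, tea, cond, table) -> float:
    dg = delta_g(energy_equation(substrate, tea, x), cond, table).total
    return dg


def _require_signs(dg_energy: float, dg_demand: float, label: str) -> None:
    if dg_energy >= 0 or dg_demand <= 0:
        raise ThermodynamicError(
            f"efficiency undefined at these conditions: dGr(energy) = "
            f"{dg_energy:.2f} kJ/mol (must be < 0) and dGr({label}) = "
            f"{dg_demand:.2f} kJ/mol (must be > 0)"
        )


def efficiency_traditional(x: float, y: float, substrate, tea,
                           cond: Conditions | None = None,
                           table: ThermoTable | None = None) -> float:
    """Traditional efficiency from the net assimilation and energy reactions."""
    _validate_y(y)
    cond = cond or Conditions.standard()
    dg_energy = _energy_dg(x, substrate, tea, cond, table)
    dg_assim = delta_g(assimilation_equation(substrate, x), cond, table).total
    if y == 1.0:
        return 0.0
    _require_signs(dg_energy, dg_assim, "CO2 red")
    return (1.0 - y) * dg_assim / (-y * dg_energy)


def _fix_terms(x, substrate, pathway, table):
    """Pathway dG and dE requirements per mole of substrate routed to fixation."""
    sub = get_substrate(substrate)
    energetics = pathway_energetics(pathway, table)
    co2_per_substrate = sub.electron_yield(x) / 4.0
    return (co2_per_substrate * energetics.dg_co2fix,
            co2_per_substrate * energetics.de_co2fix,
            energetics)


def efficiency_new(x: float, y: float, substrate, tea, pathway,
                   cond: Conditions | None = None,
                   table: ThermoTable | None = None) -> float:
    """Carrier-resolved efficiency accounting for RET and the fixation pathway."""
    _validate_y(y)
    cond = cond or Conditions.standard()
    dg_energy = _energy_dg(x, substrate, tea, cond, table)
    dg_ret = delta_g(ret_equation(substrate, pathway, x), cond, table).total
    dg_fix, _, _ = _fix_terms(x, substrate, pathway, table)
    if y == 1.0:
        return 0.0
    _require_signs(dg_energy, dg_ret + dg_fix, "RET + CO2 fix")
    return (1.0 - y) * (dg_ret + dg_fix) / (-y * dg_energy)


def factorize(x: float, y: float, substrate, tea, pathway,
              cond: Conditions | None = None,
              table: ThermoTable | None = None) -> EfficiencyBreakdown:
    """Full efficiency breakdown with the identifiable partial-efficiency minima.

    eps_SO,min (= eps_t,min) replaces the pathway's thermodynamic requirement
    with its ATP-equivalent requirement in the eps_II numerator; eps_RET,min
    follows from the factorized product with the other partials at 1.
    """
    _validate_y(y)
    cond = cond or Conditions.standard()
    dg_energy = _energy_dg(x, substrate, tea, cond, table)
    dg_assim = delta_g(assimilation_equation(substrate, x), cond, table).total
    dg_ret = delta_g(ret_equation(substrate, pathway, x), cond, table).total
    dg_fix, de_fix, energetics = _fix_terms(x, substrate, pathway, table)

    if y == 1.0:
        eps_i = eps_ii = eps_so = eps_ret = 0.0
    else:
        _require_signs(dg_energy, dg_ret + dg_fix, "RET + CO2 fix")
        denom = -y * dg_energy
        eps_i = (1.0 - y) * dg_assim / denom
        eps_ii = (1.0 - y) * (dg_ret + dg_fix) / denom
        eps_so = (1.0 - y) * (dg_ret + de_fix) / denom
    alpha = dg_fix / (dg_ret + dg_fix)
    eps_co2 = energetics.epsilon_co2
    if y == 1.0:
        eps_ret = 0.0
    else:
        eps_ret = eps_ii * (1.0 - alpha) * eps_co2 / (eps_co2 - alpha * eps_ii)
    return EfficiencyBreakdown(
        epsilon_I=eps_i,
        epsilon_II=eps_ii,
        dg_energy=dg_energy,
        dg_co2red=dg_assim,
        dg_ret=dg_ret,
        dg_fix_total=dg_fix,
        de_fix_total=de_fix,
        alpha=alpha,
        epsilon_co2=eps_co2,
        epsilon_so_min=eps_so,
        epsilon_ret_min=eps_ret,
        epsilon_t_min=eps_so,
    )


def co2_tea_ratio(x: float, y: float, tea="aerobic") -> float:
    """Moles of CO2 fixed per mole of TEA consumed — the growth-yield proxy.

    nu_CO2 / nu_TEA = (1-y) e(x)/4 / (y e(x)/n_e) = (1-y)/y * n_e/4, which is
    independent of x and of the substrate; for O2 (n_e = 4) it is (1-y)/y.
    """
    if y == 0:
        raise InadmissibleParameterError("y = 0: no TEA is consumed")
    if not 0.0 < y <= 1.0:
        raise InadmissibleParameterError(f"y must be in (0, 1], got {y}")
    process = get_tea(tea)
    return (1.0 - y) / y * process.electrons_per_mole / 4.0
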