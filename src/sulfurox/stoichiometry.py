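"""Balanced reaction builders for chemolithoautotrophic sulfur oxidation.

The framework describes the overall activity of a sulfur oxidizer with two
parameters:

* ``x`` — the fraction of oxidized sulfur atoms ending as zero-valent sulfur
  (S0) rather than sulfate.  ``x`` may be negative when stored S0 is
  co-oxidized together with the dissolved substrate.
* ``y`` — the fraction of the reduced-sulfur pool oxidized for energy
  generation (terminal electron acceptor reduction); the remaining 1-y
  donates its electrons to CO2 fixation.

Four reaction families are built for any substrate / terminal acceptor /
carbon-pathway combination: the energy-generating reaction, the CO2-fixing
(assimilation) reaction, the reverse-electron-transport (RET) reaction that
reduces the carbon pathway's electron carriers, and the overall reaction
(the y : 1-y blend of energy and assimilation).

All coefficients follow the sign convention products positive / reactants
negative, normalized to -1 for the sulfur substrate.  Every builder output
is element- and charge-balanced to 1e-9; ``check_balance`` verifies this for
arbitrary coefficient maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

from .exceptions import InadmissibleParameterError
from .species import COMPOSITIONS, ELEMENTS, display_name

BALANCE_TOL = 1e-9

#: electrons transferred per mole of reduced carrier
CARRIER_ELECTRONS = {"NADH": 2.0, "FADH2": 2.0, "Fd_red": 1.0}
_CARRIER_OXIDIZED = {"NADH": "NAD+", "FADH2": "FAD", "Fd_red": "Fd_ox"}


@dataclass(frozen=True)
class SulfurSubstrate:
    """A reduced sulfur substrate and its electron yield as a function of x."""

    identifier: str
    species: str
    s_atoms: int
    electrons_complete: float  # electrons per mole at x = 0 (full oxidation to SO4)
    electrons_slope: float  # d(electrons)/dx
    x_max: float  # upper x bound (exclusive where the electron yield vanishes)
    x_min: float = -10.0

    def electron_yield(self, x: float) -> float:
        return self.electrons_complete - self.electrons_slope * x

    def s_products(self, x: float) -> dict[str, float]:
        """Coefficients of S0 and SO4 per mole of substrate."""
        n = self.s_atoms
        return {"S0": n * x, "SO4": n * (1.0 - x)}

    def validate_x(self, x: float) -> None:
        if not self.x_min <= x < self.x_max + BALANCE_TOL:
            raise InadmissibleParameterError(
                f"x={x} outside admissible domain [{self.x_min}, {self.x_max}] "
                f"for {self.identifier}"
            )
        if self.electron_yield(x) <= 0:
            raise InadmissibleParameterError(
                f"x={x} leaves no electrons for {self.identifier} "
                f"(bound x < {self.electrons_complete / self.electrons_slope:.4g})"
            )
        if x < -2:
            warnings.warn(
                f"x={x} implies a very large stored-S0 co-oxidation; interpret "
                "with caution",
                stacklevel=2,
            )


@dataclass(frozen=True)
class TerminalAcceptorProcess:
    """A terminal electron acceptor and its reduced nitrogen product, if any."""

    identifier: str
    acceptor: str
    electrons_per_mole: float
    n_product: tuple[str, float] | None  # (species, moles per mole acceptor)


@dataclass(frozen=True)
class CarbonPathway:
    """A CO2 fixation pathway: ATP cost, energy requirement and carrier demand."""

    identifier: str
    dg_fix: float  # kJ per mole CO2 fixed
    atp_per_co2: float
    electron_fractions: Mapping[str, float]  # reduced carrier -> fraction of electrons

    def carrier_coefficients(self, electrons: float) -> dict[str, float]:
        """Moles of each reduced carrier supplying ``electrons`` electrons."""
        return {
            carrier: electrons * frac / CARRIER_ELECTRONS[carrier]
            for carrier, frac in self.electron_fractions.items()
        }


SULFIDE = SulfurSubstrate(
    identifier="sulfide", species="H2S", s_atoms=1,
    electrons_complete=8.0, electrons_slope=6.0, x_max=1.0,
)
# Re-derived generalization: x is the fraction of the two S atoms ending as S0,
# admissible x in [0, 2/3) to keep the electron yield 8 - 12x positive.
THIOSULFATE = SulfurSubstrate(
    identifier="thiosulfate", species="S2O3", s_atoms=2,
    electrons_complete=8.0, electrons_slope=12.0, x_max=Fraction(2, 3) - 1e-12,
)

AEROBIC = TerminalAcceptorProcess("aerobic", "O2", 4.0, None)
DENITRIFICATION = TerminalAcceptorProcess("denitrification", "NO3", 5.0, ("N2", 0.5))
DNRA = TerminalAcceptorProcess("dnra", "NO3", 8.0, ("NH4", 1.0))

CALVIN = CarbonPathway("calvin", dg_fix=69.7, atp_per_co2=3.0,
                       electron_fractions={"NADH": 1.0})
RTCA = CarbonPathway("rtca", dg_fix=64.3, atp_per_co2=float(Fraction(5, 3)),
                     electron_fractions={"NADH": Fraction(6, 12),
                                         "Fd_red": Fraction(4, 12),
                                         "FADH2": Fraction(2, 12)})

_SUBSTRATES = {"sulfide": SULFIDE, "thiosulfate": THIOSULFATE}
_TEAS = {"aerobic": AEROBIC, "denitrification": DENITRIFICATION, "dnra": DNRA}
_PATHWAYS = {"calvin": CALVIN, "rtca": RTCA}


def get_substrate(substrate: str | SulfurSubstrate) -> SulfurSubstrate:
    if isinstance(substrate, SulfurSubstrate):
        return substrate
    try:
        return _SUBSTRATES[substrate]
    except KeyError:
        raise InadmissibleParameterError(
            f"unknown substrate {substrate!r}; choose from {sorted(_SUBSTRATES)}"
        ) from None


def get_tea(tea: str | TerminalAcceptorProcess) -> TerminalAcceptorProcess:
    if isinstance(tea, TerminalAcceptorProcess):
        return tea
    try:
        return _TEAS[tea]
    except KeyError:
        raise InadmissibleParameterError(
            f"unknown terminal acceptor process {tea!r}; choose from {sorted(_TEAS)}"
        ) from None


def get_pathway(pathway: str | CarbonPathway) -> CarbonPathway:
    if isinstance(pathway, CarbonPathway):
        return pathway
    try:
        return _PATHWAYS[pathway]
    except KeyError:
        raise InadmissibleParameterError(
            f"unknown carbon pathway {pathway!r}; choose from {sorted(_PATHWAYS)}"
        ) from None


@dataclass(frozen=True)
class Stoichiometry:
    """One balanced reaction: signed coefficients over species.

    Products are positive, reactants negative; the sulfur substrate is
    normalized to -1.  ``kind`` tags the provenance (energy | assimilation |
    ret | co2fix | overall).
    """

    coefficients: Mapping[str, float]
    substrate: str
    kind: str
    x: float | None = None
    y: float | None = None
    tea: str | None = None
    pathway: str | None = None

    def coefficient(self, species: str) -> float:
        return float(self.coefficients.get(species, 0.0))

    def ratio(self, species_a: str, species_b: str) -> float:
        """|nu_a / nu_b| — the magnitude ratio of two coefficients."""
        return abs(self.coefficient(species_a) / self.coefficient(species_b))

    def combine(self, other: "Stoichiometry", w_self: float, w_other: float,
                **tags) -> "Stoichiometry":
        coeffs: dict[str, float] = {}
        for sp, nu in self.coefficients.items():
            coeffs[sp] = coeffs.get(sp, 0.0) + w_self * nu
        for sp, nu in other.coefficients.items():
            coeffs[sp] = coeffs.get(sp, 0.0) + w_other * nu
        coeffs = {sp: nu for sp, nu in coeffs.items() if abs(nu) > BALANCE_TOL / 10}
        defaults = dict(substrate=self.substrate, kind="combination",
                        x=self.x, tea=self.tea, pathway=self.pathway)
        defaults.update(tags)
        return Stoichiometry(coefficients=coeffs, **defaults)

    def species(self) -> list[str]:
        return list(self.coefficients)

    def to_text(self) -> str:
        """Render as 'A + 2 B -> C + 0.5 D' moving negatives to the left."""
        def side(items):
            parts = []
            for sp, nu in items:
                mag = abs(nu)
                name = display_name(sp)
                parts.append(name if abs(mag - 1) < 1e-12 else f"{mag:g} {name}")
            return " + ".join(parts)

        lhs = [(sp, nu) for sp, nu in self.coefficients.items() if nu < 0]
        rhs = [(sp, nu) for sp, nu in self.coefficients.items() if nu > 0]
        return f"{side(lhs)} -> {side(rhs)}"

    def to_records(self) -> list[tuple[str, float]]:
        return [(sp, float(nu)) for sp, nu in self.coefficients.items()]


@dataclass(frozen=True)
class BalanceReport:
    """Per-element and charge residuals of a reaction."""

    residuals: Mapping[str, float]
    tolerance: float = BALANCE_TOL

    @property
    def ok(self) -> bool:
        return all(abs(r) < self.tolerance for r in self.residuals.values())

    @property
    def max_residual(self) -> float:
        return max((abs(r) for r in self.residuals.values()), default=0.0)


def check_balance(stoich: Stoichiometry) -> BalanceReport:
    """Element and charge residuals; all must vanish for a balanced reaction."""
    residuals = dict.fromkeys(ELEMENTS, 0.0)
    for sp, nu in stoich.coefficients.items():
        comp = COMPOSITIONS[sp]
        for element, count in comp.items():
            residuals[element] += nu * count
    return BalanceReport(residuals=residuals)


def _close_with_water_and_protons(coeffs: dict[str, float]) -> dict[str, float]:
    """Complete a reaction by solving the H2O and H+ coefficients.

    The O balance fixes nu_H2O and the H balance then fixes nu_H+; the
    remaining element and charge balances must already hold and are asserted.
    """
    o_excess = sum(nu * COMPOSITIONS[sp].get("O", 0) for sp, nu in coeffs.items())
    coeffs["H2O"] = coeffs.get("H2O", 0.0) - o_excess
    h_excess = sum(nu * COMPOSITIONS[sp].get("H", 0) for sp, nu in coeffs.items())
    coeffs["H+"] = coeffs.get("H+", 0.0) - h_excess
    coeffs = {sp: nu for sp, nu in coeffs.items() if abs(nu) > BALANCE_TOL / 10}
    charge = sum(nu * COMPOSITIONS[sp].get("charge", 0) for sp, nu in coeffs.items())
    if abs(charge) > BALANCE_TOL:
        raise AssertionError(
            f"internal error: charge residual {charge} after closing the balance"
        )
    return coeffs


def energy_equation(substrate, tea, x: float) -> Stoichiometry:
    """The energy-generating reaction: substrate oxidation coupled to TEA reduction.

    For sulfide/aerobic this reproduces the textbook generalized equation
    H2S + (2-1.5x) O2 -> x S0 + (1-x) SO4^2- + x H2O + (2-2x) H+.
    """
    sub = get_substrate(substrate)
    process = get_tea(tea)
    sub.validate_x(x)
    electrons = sub.electron_yield(x)
    nu_tea = electrons / process.electrons_per_mole
    coeffs: dict[str, float] = {sub.species: -1.0, process.acceptor: -nu_tea}
    coeffs.update(sub.s_products(x))
    if process.n_product is not None:
        product, per_acceptor = process.n_product
        coeffs[product] = nu_tea * per_acceptor
    coeffs = _close_with_water_and_protons(coeffs)
    return Stoichiometry(coefficients=coeffs, substrate=sub.identifier,
                         kind="energy", x=x, tea=process.identifier)


def assimilation_equation(substrate, x: float) -> Stoichiometry:
    """The CO2-fixing reaction: substrate oxidation donating electrons to CO2.

    Four electrons reduce one CO2 to the CH2O level, so nu_CO2 = nu_CH2O =
    electron_yield(x)/4.
    """
    sub = get_substrate(substrate)
    sub.validate_x(x)
    nu_co2 = sub.electron_yield(x) / 4.0
    coeffs: dict[str, float] = {sub.species: -1.0, "CO2": -nu_co2, "CH2O": nu_co2}
    coeffs.update(sub.s_products(x))
    coeffs = _close_with_water_and_protons(coeffs)
    return Stoichiometry(coefficients=coeffs, substrate=sub.identifier,
                         kind="assimilation", x=x)


def ret_equation(substrate, pathway, x: float) -> Stoichiometry:
    """The reverse-electron-transport reaction reducing the pathway's carriers.

    The substrate's electrons are distributed over NADH / Fd_red / FADH2
    according to the carbon pathway's demand per CO2 fixed.
    """
    sub = get_substrate(substrate)
    pw = get_pathway(pathway)
    sub.validate_x(x)
    electrons = sub.electron_yield(x)
    coeffs: dict[str, float] = {sub.species: -1.0}
    coeffs.update(sub.s_products(x))
    for carrier, nu in pw.carrier_coefficients(electrons).items():
        coeffs[carrier] = float(nu)
        coeffs[_CARRIER_OXIDIZED[carrier]] = -float(nu)
    coeffs = _close_with_water_and_protons(coeffs)
    return Stoichiometry(coefficients=coeffs, substrate=sub.identifier,
                         kind="ret", x=x, pathway=pw.identifier)


def overall_equation(substrate, tea, x: float, y: float) -> Stoichiometry:
    """The overall reaction: y * energy + (1-y) * assimilation.

    ``y`` is the fraction of the reduced-sulfur pool used for energy
    generation; the substrate coefficient stays -1.
    """
    if not 0.0 <= y <= 1.0:
        raise InadmissibleParameterError(f"y must be in [0, 1], got {y}")
    energy = energy_equation(substrate, tea, x)
    assim = assimilation_equation(substrate, x)
    return energy.combine(assim, y, 1.0 - y, kind="overall", y=y, tea=energy.tea)


@dataclass(frozen=True)
class RateSet:
    """Measured consumption/production rates or ready-made coefficient ratios.

    ``rates`` maps species to consumption rates in any one consistent unit;
    consumption is positive, net production negative (only ratios enter the
    mathematics).  ``ratios`` maps "A:B" strings to |nu_A/nu_B| values.
    """

    rates: Mapping[str, float] = field(default_factory=dict)
    ratios: Mapping[str, float] = field(default_factory=dict)

    def ratio(self, species_a: str, species_b: str) -> float:
        key = f"{species_a}:{species_b}"
        if key in self.ratios:
            return float(self.ratios[key])
        try:
            return self.rates[species_a] / self.rates[species_b]
        except KeyError as err:
            raise InadmissibleParameterError(
                f"rate set resolves neither ratio {key!r} nor both rates"
            ) from err


def solve_xy(rateset: RateSet, substrate, tea) -> tuple[float, float, Stoichiometry]:
    """Recover (x, y) from the TEA:substrate and CO2:substrate rate ratios.

    The generalized coefficients give nu_TEA = y*e(x)/n_e and nu_CO2 =
    (1-y)*e(x)/4 per mole substrate, so e(x) = n_e*r_TEA + 4*r_CO2 is linear
    in x and y follows in closed form.  Negative x is reported (with a
    warning) as stored-S0 co-oxidation, not an error.
    """
    sub = get_substrate(substrate)
    process = get_tea(tea)
    r_tea = rateset.ratio(process.acceptor, sub.species)
    r_co2 = rateset.ratio("CO2", sub.species)
    total = process.electrons_per_mole * r_tea + 4.0 * r_co2
    if total <= 0:
        raise InadmissibleParameterError(
            f"TEA and CO2 rate ratios sum to {total} electrons; nothing to solve"
        )
    x = (sub.electrons_complete - total) / sub.electrons_slope
    y = process.electrons_per_mole * r_tea / total
    if y > 1.0 + 1e-9:
        raise InadmissibleParameterError(
            f"solved y={y:.4f} > 1: the rate ratios are inconsistent with the "
            "framework (more TEA reduced than electrons available)"
        )
    y = min(y, 1.0)
    if not 0.0 <= x <= 1.0:
        warnings.warn(
            f"solved x={x:.4f} outside [0, 1]"
            + (": interpreted as net co-oxidation of stored S0" if x < 0 else ""),
            stacklevel=2,
        )
    return x, y, overall_equation(sub, process, x, y)


def adjust_for_host(whole_rates: RateSet, host_o2_fraction: float,
                    respiratory_quotient: float = 1.0) -> RateSet:
    """Correct whole-symbiosis rates for host respiration.

    The symbionts see (1 - f) of the measured O2 consumption, while the CO2
    respired by the host (RQ * f * O2) adds to the symbiont-available CO2
    pool.  Rates are consumption-positive.
    """
    if not 0.0 <= host_o2_fraction < 1.0:
        raise InadmissibleParameterError(
            f"host O2 fraction must be in [0, 1), got {host_o2_fraction}"
        )
    rates = dict(whole_rates.rates)
    if "O2" not in rates or "CO2" not in rates:
        raise InadmissibleParameterError("O2 and CO2 rates are both required")
    o2 = rates["O2"]
    rates["O2"] = o2 * (1.0 - host_o2_fraction)
    rates["CO2"] = rates["CO2"] + respiratory_quotient * host_o2_fraction * o2
    return RateSet(rates=rates, ratios=dict(whole_rates.ratios))
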