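"""Sensitivity of the efficiencies to reactant concentrations, pH and temperature.

Concentrations enter the Gibbs energies only through RT ln Q with fixed-sign
coefficients, so the response of any efficiency to a single concentration is
monotone.  ``scan`` sweeps one variable with the stoichiometry (x, y) held
fixed; ``equalizing_shift`` finds the fold-change (or pH) at which two
organisms' efficiencies coincide — a measure of how robustly the efficiency
ranking survives concentration uncertainty.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .efficiency import efficiency_new, efficiency_traditional, factorize
from .exceptions import (InadmissibleParameterError, NoSolutionError,
                         ThermodynamicError)
from .stoichiometry import (
    assimilation_equation,
    energy_equation,
    get_pathway,
    get_substrate,
    get_tea,
    ret_equation,
)
from .thermo import Conditions, ThermoTable

TARGETS = ("epsilon_I", "epsilon_II", "epsilon_so_min")

_LOG10_FOLD_BOUNDS = (-30.0, 30.0)


def _strain_fields(strain) -> tuple[float, float, object, object, object]:
    """Accept a StrainRecord, mapping or tuple-like with the needed fields."""
    if hasattr(strain, "x"):
        return strain.x, strain.y, strain.substrate, strain.tea, strain.pathway
    return (strain["x"], strain["y"], strain["substrate"], strain["tea"],
            strain["pathway"])


def _target_value(target: str, x, y, substrate, tea, pathway, cond, table) -> float:
    if target == "epsilon_I":
        return efficiency_traditional(x, y, substrate, tea, cond, table)
    if target == "epsilon_II":
        return efficiency_new(x, y, substrate, tea, pathway, cond, table)
    if target == "epsilon_so_min":
        return factorize(x, y, substrate, tea, pathway, cond, table).epsilon_so_min
    raise InadmissibleParameterError(
        f"unknown target {target!r}; choose from {TARGETS}"
    )


def _reaction_species(x, substrate, tea, pathway) -> set[str]:
    species: set[str] = set()
    species.update(energy_equation(substrate, tea, x).species())
    species.update(assimilation_equation(substrate, x).species())
    species.update(ret_equation(substrate, pathway, x).species())
    return species


def _check_variable(variable: str, x, substrate, tea, pathway) -> None:
    if variable in ("pH", "temperature"):
        return
    if variable not in _reaction_species(x, substrate, tea, pathway):
        raise InadmissibleParameterError(
            f"species {variable!r} does not appear in the reactions of this strain"
        )


def scan(strain, variable: str, values: Sequence[float], target: str = "epsilon_I",
         cond: Conditions | None = None,
         table: ThermoTable | None = None) -> list[tuple[float, float]]:
    """Efficiency as one variable (a species concentration, pH or temperature)
    sweeps ``values`` with everything else at standard conditions.

    Returns (value, efficiency) pairs; the stoichiometry is held fixed.
    """
    x, y, substrate, tea, pathway = _strain_fields(strain)
    substrate, tea, pathway = (get_substrate(substrate), get_tea(tea),
                               get_pathway(pathway))
    _check_variable(variable, x, substrate, tea, pathway)
    base = cond or Conditions.standard()
    out = []
    for v in values:
        c = base.replace(**{variable: float(v)})
        out.append((float(v), _target_value(target, x, y, substrate, tea,
                                            pathway, c, table)))
    return out


def relative_change(strain, variable: str, value: float, target: str = "epsilon_I",
                    table: ThermoTable | None = None) -> float:
    """|eps(variable=value) - eps(standard)| / eps(standard).

    The paper-style "changes by ~N %" summary for a single condition shift.
    """
    x, y, substrate, tea, pathway = _strain_fields(strain)
    ref = _target_value(target, x, y, substrate, tea, pathway,
                        Conditions.standard(), table)
    moved = scan(strain, variable, [value], target, table=table)[0][1]
    return abs(moved - ref) / ref


def equalizing_shift(strain_a, strain_b, variable: str,
                     target: str = "epsilon_I",
                     table: ThermoTable | None = None) -> float:
    """Concentration fold-change (applied to strain_a) — or pH — equalizing the
    two strains' efficiencies.

    Root-found to 1e-6 in log10 fold space; ``variable='pH'`` searches pH in
    [0, 14] instead and returns the pH value.
    """
    xa, ya, sub_a, tea_a, pw_a = _strain_fields(strain_a)
    xb, yb, sub_b, tea_b, pw_b = _strain_fields(strain_b)
    _check_variable(variable, xa, get_substrate(sub_a), get_tea(tea_a),
                    get_pathway(pw_a))
    std = Conditions.standard()
    eps_b = _target_value(target, xb, yb, sub_b, tea_b, pw_b, std, table)
    eps_a0 = _target_value(target, xa, ya, sub_a, tea_a, pw_a, std, table)
    if eps_a0 == eps_b:
        return 7.0 if variable == "pH" else 1.0

    def safe_residual(setting: float, is_ph: bool) -> float:
        c = std.replace(pH=setting) if is_ph else std.replace(
            **{variable: 10.0 ** setting})
        try:
            return _target_value(target, xa, ya, sub_a, tea_a, pw_a, c, table) - eps_b
        except ThermodynamicError:
            return np.nan  # efficiency undefined at this extreme

    is_ph = variable == "pH"
    lo, hi = (0.0, 14.0) if is_ph else _LOG10_FOLD_BOUNDS
    grid = np.linspace(lo, hi, 121)
    values = np.array([safe_residual(v, is_ph) for v in grid])
    for a, b, fa, fb in zip(grid[:-1], grid[1:], values[:-1], values[1:]):
        if np.isnan(fa) or np.isnan(fb):
            continue
        if fa == 0.0:
            return float(a) if is_ph else float(10.0 ** a)
        if fa * fb < 0:
            root = brentq(lambda v: safe_residual(v, is_ph), a, b, xtol=1e-6)
            return float(root) if is_ph else float(10.0 ** root)
    raise NoSolutionError(
        f"not equalizable: no crossing of {variable} within "
        f"{'pH 0..14' if is_ph else f'10^{lo:g}..10^{hi:g}-fold'}"
    )


def scan_summary(strain, table: ThermoTable | None = None) -> dict[str, float]:
    """Relative responses (fractions) to canonical three-orders-of-magnitude
    dilutions of TEA, CO2 and NAD+, mirroring the standard robustness checks."""
    _, _, _, tea, _ = _strain_fields(strain)
    acceptor = get_tea(tea).acceptor
    return {
        f"{acceptor}_3_orders_epsilon_I": relative_change(
            strain, acceptor, 1e-3, "epsilon_I", table),
        "CO2_3_orders_epsilon_I": relative_change(
            strain, "CO2", 1e-3, "epsilon_I", table),
        "NAD+_3_orders_epsilon_so_min": relative_change(
            strain, "NAD+", 1e-3, "epsilon_so_min", table),
    }


def monotone_scan(values: Sequence[float], efficiencies: Sequence[float]) -> bool:
    """True if the scanned efficiency is monotone in the scanned variable."""
    eff = np.asarray(efficiencies, dtype=float)
    diffs = np.diff(eff[np.argsort(np.asarray(values, dtype=float))])
    return bool(np.all(diffs >= -1e-12) or np.all(diffs <= 1e-12))
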