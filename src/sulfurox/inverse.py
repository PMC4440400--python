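"""Predict full stoichiometry from one rate ratio plus an activity constraint.

A single measured TEA:substrate ratio fixes one relation between x and y
(y * e(x) / n_e = ratio).  The second relation comes from an assumption about
the organism: its carrier-resolved efficiency eps_II is constant in x (or
varies linearly), or its CO2:TEA yield is constant.  Eliminating y leaves a
one-dimensional root problem in x, solved by a bracketed scalar search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .efficiency import co2_tea_ratio, efficiency_new
from .exceptions import InadmissibleParameterError, NoSolutionError
from .stoichiometry import Stoichiometry, get_substrate, get_tea, overall_equation
from .thermo import Conditions, ThermoTable

#: number of pre-scan subintervals used to bracket sign changes in x
N_PRESCAN = 64
X_TOL = 1e-10


@dataclass(frozen=True)
class Constraint:
    """The assumed dependency of eps_II or CO2:TEA on the S0 partition x.

    kinds: ``constant_efficiency`` (eps_II(x) = reference), ``constant_co2_tea``
    (CO2:TEA = reference) and ``linear_efficiency`` (eps_II(x) interpolates
    from ``reference_value`` at x = 0 to ``terminal_value`` at x = 1).
    """

    kind: str
    reference_value: float
    terminal_value: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in {"constant_efficiency", "constant_co2_tea",
                             "linear_efficiency"}:
            raise InadmissibleParameterError(f"unknown constraint kind {self.kind!r}")
        if not self.reference_value > 0:
            raise InadmissibleParameterError(
                f"constraint reference value must be positive, got "
                f"{self.reference_value}"
            )

    def efficiency_at(self, x: float) -> float:
        if self.kind == "constant_efficiency":
            return self.reference_value
        if self.kind == "linear_efficiency":
            return self.reference_value * (1.0 - x) + self.terminal_value * x
        raise InadmissibleParameterError(
            "constraint kind constant_co2_tea does not define an efficiency curve"
        )


def _parse_ratio_name(name: str, substrate, tea) -> None:
    sub = get_substrate(substrate)
    process = get_tea(tea)
    expected = f"{process.acceptor}:{sub.species}"
    if name.replace(" ", "") != expected:
        raise InadmissibleParameterError(
            f"measured ratio {name!r} not resolvable; expected {expected!r} "
            f"for {sub.identifier}/{process.identifier}"
        )


def solve_constrained(measured_ratio_name: str, measured_ratio_value: float,
                      constraint: Constraint, substrate, tea, pathway=None,
                      cond: Conditions | None = None,
                      table: ThermoTable | None = None,
                      x_bounds: tuple[float, float] | None = None,
                      ) -> tuple[float, float, Stoichiometry]:
    """Solve the (ratio relation, constraint) system for (x, y).

    y is eliminated analytically through y(x) = ratio * n_e / e(x); the
    residual in x is bracketed on N_PRESCAN subintervals and each sign change
    refined by Brent's method.  With several roots the smallest x is returned
    with a warning.
    """
    sub = get_substrate(substrate)
    process = get_tea(tea)
    _parse_ratio_name(measured_ratio_name, sub, process)
    if measured_ratio_value <= 0:
        raise InadmissibleParameterError("measured ratio must be positive")
    cond = cond or Conditions.standard()

    def y_of_x(x: float) -> float:
        return measured_ratio_value * process.electrons_per_mole / sub.electron_yield(x)

    if constraint.kind == "constant_co2_tea":
        # closed form: CO2:TEA = (1-y)/y * n_e/4 fixes y, then x from the ratio
        y = 1.0 / (1.0 + 4.0 * constraint.reference_value / process.electrons_per_mole)
        e_needed = measured_ratio_value * process.electrons_per_mole / y
        x = (sub.electrons_complete - e_needed) / sub.electrons_slope
        sub.validate_x(x)
        return x, y, overall_equation(sub, process, x, y)

    if x_bounds is None:
        x_bounds = (0.0, min(sub.x_max, 1.0) - 1e-9)
    x_lo, x_hi = x_bounds

    def residual(x: float) -> float:
        y = y_of_x(x)
        if not 0.0 < y <= 1.0:
            return np.inf  # outside the physical branch
        eps = efficiency_new(x, y, sub, process, pathway, cond, table)
        return eps - constraint.efficiency_at(x)

    grid = np.linspace(x_lo, x_hi, N_PRESCAN + 1)
    values = [residual(x) for x in grid]
    roots: list[float] = []
    for a, b, fa, fb in zip(grid[:-1], grid[1:], values[:-1], values[1:]):
        if not (np.isfinite(fa) and np.isfinite(fb)):
            continue
        if fa == 0.0:
            roots.append(float(a))
        elif fa * fb < 0:
            roots.append(float(brentq(residual, a, b, xtol=X_TOL)))
    if np.isfinite(values[-1]) and values[-1] == 0.0:
        roots.append(float(grid[-1]))
    if not roots:
        finite = [v for v in values if np.isfinite(v)]
        raise NoSolutionError(
            "no solution in admissible domain "
            f"[{x_lo:.4g}, {x_hi:.4g}]: endpoint residuals "
            f"{finite[0] if finite else np.nan:.4g} .. "
            f"{finite[-1] if finite else np.nan:.4g}"
        )
    if len(roots) > 1 and max(roots) - min(roots) > 100 * X_TOL:
        warnings.warn(
            f"multiple solutions found at x = {sorted(roots)}; returning the "
            "smallest",
            stacklevel=2,
        )
    x = min(roots)
    y = y_of_x(x)
    return x, y, overall_equation(sub, process, x, y)


def co2_tea_curve(x_grid, constraint: Constraint, substrate, tea, pathway,
                  cond: Conditions | None = None,
                  table: ThermoTable | None = None) -> np.ndarray:
    """CO2:TEA yield over a grid of S0 partition values x.

    For each x, y follows in closed form from the efficiency constraint
    ((1-y)/y = eps(x) * |dG_energy| / dG_demand) and the CO2:TEA ratio is
    reported.  Returns an array of (x, co2_tea) rows.
    """
    if constraint.kind not in {"constant_efficiency", "linear_efficiency"}:
        raise InadmissibleParameterError(
            "curve requires an efficiency-type constraint"
        )
    cond = cond or Conditions.standard()
    sub = get_substrate(substrate)
    process = get_tea(tea)
    rows = []
    for x in np.asarray(x_grid, dtype=float):
        eps_target = constraint.efficiency_at(x)
        if eps_target == 0.0:
            rows.append((x, 0.0))  # eps = 0 means y = 1: no carbon fixed
            continue
        # any valid y gives the same (1-y)/y scaling; evaluate at y = 1/2
        eps_unit = efficiency_new(x, 0.5, sub, process, pathway, cond, table)
        odds = eps_target / eps_unit  # (1-y)/y
        rows.append((x, odds * process.electrons_per_mole / 4.0))
    return np.array(rows)


def niche_band(ratio_low: float, ratio_high: float, substrate, tea, pathway,
               cond: Conditions | None = None,
               table: ThermoTable | None = None) -> list[dict]:
    """Efficiency range spanned by an environmental TEA:substrate flux band.

    The low ratio is matched by fully incomplete oxidation (x = 1) and the
    high ratio by complete oxidation (x = 0); y follows from
    ratio = y * e(x) / n_e at each end.  Returns the two endpoints with
    their (x, y, eps_II).
    """
    sub = get_substrate(substrate)
    process = get_tea(tea)
    if not 0 < ratio_low <= ratio_high:
        raise InadmissibleParameterError(
            f"need 0 < ratio_low <= ratio_high, got ({ratio_low}, {ratio_high})"
        )
    cond = cond or Conditions.standard()
    x_incomplete = min(1.0, sub.x_max - 1e-9)
    if ratio_low == ratio_high:
        # degenerate band: the organism never switches products; single point
        # at complete oxidation (x = 0)
        pairs = ((0.0, ratio_high), (0.0, ratio_high))
    else:
        pairs = ((x_incomplete, ratio_low), (0.0, ratio_high))
    endpoints = []
    for x, ratio in pairs:
        y = ratio * process.electrons_per_mole / sub.electron_yield(x)
        if y > 1.0 + 1e-12:
            raise InadmissibleParameterError(
                f"ratio {ratio} exceeds the maximum coefficient "
                f"{sub.electron_yield(x) / process.electrons_per_mole:.4g} at x={x}"
            )
        if y > 1.0 - 1e-12:
            warnings.warn(
                f"ratio {ratio} forces y = 1 at x = {x}: no carbon fixation, "
                "eps_II = 0",
                stacklevel=2,
            )
            y = 1.0
        eps = efficiency_new(x, y, sub, process, pathway, cond, table)
        endpoints.append({"x": x, "y": y, "epsilon_II": eps})
    return endpoints
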