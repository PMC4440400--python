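"""Reporting and synthetic-data utilities: the strain-table regeneration
report and a noisy rate generator for round-trip validation."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .efficiency import co2_tea_ratio, factorize
from .exceptions import InadmissibleParameterError
from .stoichiometry import RateSet, get_substrate, get_tea, overall_equation
from .strains import StrainRecord, load_printed_values, load_strain_table
from .thermo import Conditions, ThermoTable


def reproduce_table1(strains: list[StrainRecord] | None = None,
                     cond: Conditions | None = None,
                     table: ThermoTable | None = None,
                     printed: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute the efficiency compilation per strain.

    Columns: x, y, eps_I/eps_II/eps_so_min in percent (2 decimals carried at
    full precision; round for display) and the CO2:TEA yield.  When published
    values are available the absolute deviations are appended.
    """
    if strains is None:
        strains = load_strain_table()
        if printed is None:
            printed = load_printed_values()
    cond = cond or Conditions.standard()
    rows = []
    for strain in strains:
        breakdown = factorize(strain.x, strain.y, strain.substrate, strain.tea,
                              strain.pathway, cond, table)
        rows.append({
            "id": strain.id,
            "name": strain.name,
            "group": strain.group,
            "x": strain.x,
            "y": strain.y,
            "eps_I_pct": 100.0 * breakdown.epsilon_I,
            "eps_II_pct": 100.0 * breakdown.epsilon_II,
            "eps_so_min_pct": 100.0 * breakdown.epsilon_so_min,
            "co2_tea": co2_tea_ratio(strain.x, strain.y, strain.tea),
        })
    columns = ["id", "name", "group", "x", "y", "eps_I_pct", "eps_II_pct",
               "eps_so_min_pct", "co2_tea"]
    report = pd.DataFrame(rows, columns=columns).set_index("id")
    if printed is not None:
        for col in ("eps_I_pct", "eps_II_pct", "eps_so_min_pct", "co2_tea"):
            report[f"dev_{col}"] = (report[col] - printed[col]).abs()
    return report


def generate_synthetic_rates(x: float, y: float, substrate, tea,
                             total_sulfur_rate: float = 1.0,
                             noise_cv: float = 0.0,
                             seed: int | np.random.Generator | None = None,
                             ) -> RateSet:
    """Consumption/production rates implied by (x, y), with multiplicative noise.

    Rates are the overall-equation coefficients scaled by the substrate
    consumption rate, each multiplied by mean-one lognormal noise with the
    given coefficient of variation.  Deterministic under a fixed seed.
    """
    if noise_cv < 0:
        raise InadmissibleParameterError(f"noise_cv must be >= 0, got {noise_cv}")
    sub = get_substrate(substrate)
    process = get_tea(tea)
    stoich = overall_equation(sub, process, x, y)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    sigma = float(np.sqrt(np.log1p(noise_cv ** 2)))
    rates = {}
    for sp, nu in stoich.coefficients.items():
        noise = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma) if sigma else 1.0
        # consumption-positive convention: reactants (nu < 0) have positive rates
        rates[sp] = -nu * total_sulfur_rate * noise
    return RateSet(rates=rates)
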