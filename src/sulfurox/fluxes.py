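"""Interpretation of net O2:sulfide flux ratios in mixed communities.

In a microbial mat the sulfide oxidation zone hosts both the sulfur oxidizer
and heterotrophs respiring its biomass.  Under steady state the oxidizer
produces sulfate only (x = 0), consuming 2y O2 per sulfide, so any observed
O2:sulfide ratio above 2y reflects heterotrophic respiration.  An observed
ratio of exactly 2 means the biomass built by the oxidizer is completely
recycled within the zone — independent of y.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import InadmissibleParameterError

COMPLETE_RECYCLING = "complete internal recycling"
CARBON_EXPORT = "organic carbon export"
REDUCTANT_IMPORT = "external reductant import"

_TOL = 1e-12


@dataclass(frozen=True)
class FluxInterpretation:
    recycled_fraction: float
    classification: str
    heterotrophic_o2_share: float  # moles O2 per mole sulfide beyond SOB demand


def interpret_o2_h2s(y: float, observed_ratio: float) -> FluxInterpretation:
    """Partition an observed net O2:sulfide consumption ratio.

    ``recycled_fraction`` is the fraction of the oxidizer's biomass production
    that is respired back to CO2 within the zone: (observed - 2y) / (2(1-y)).
    Values of 1 (observed = 2) indicate complete internal recycling, below 1
    export of organic carbon, above 1 import of external reductant.
    """
    if not 0.0 < y <= 1.0:
        raise InadmissibleParameterError(f"y must be in (0, 1], got {y}")
    if observed_ratio < 0:
        raise InadmissibleParameterError("observed ratio must be non-negative")
    sob_share = 2.0 * y
    hetero = observed_ratio - sob_share
    if hetero < -_TOL:
        raise InadmissibleParameterError(
            f"observed ratio {observed_ratio} is below the oxidizer's own demand "
            f"2y = {sob_share}: negative heterotrophy; re-estimate y"
        )
    if abs(observed_ratio - 2.0) < _TOL:
        # exact closed form: (2 - 2y) / (2(1-y)) = 1 for every y
        return FluxInterpretation(1.0, COMPLETE_RECYCLING, max(hetero, 0.0))
    if y == 1.0:
        raise InadmissibleParameterError(
            "y = 1: the oxidizer fixes no carbon, recycling is undefined unless "
            "the observed ratio is exactly 2"
        )
    recycled = hetero / (2.0 * (1.0 - y))
    classification = CARBON_EXPORT if recycled < 1.0 else REDUCTANT_IMPORT
    return FluxInterpretation(recycled, classification, max(hetero, 0.0))
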