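"""Chemical species bookkeeping: compositions, charges and activity conventions.

Species are identified by short ASCII tokens ("H2S", "SO4", "NAD+", ...).
Compositions list atoms per mole plus the formal charge; the redox carriers
(NAD+/NADH, FAD/FADH2, Fd_ox/Fd_red) are tracked with a pseudo-element for
their organic core so that only the hydrogen and charge transferred on
reduction enter the element/charge balance.
"""

from __future__ import annotations

# element counts per species; "charge" is the formal charge
COMPOSITIONS: dict[str, dict[str, float]] = {
    "H2S": {"H": 2, "S": 1},
    "S0": {"S": 1},
    "SO4": {"S": 1, "O": 4, "charge": -2},
    "S2O3": {"S": 2, "O": 3, "charge": -2},
    "O2": {"O": 2},
    "H2O": {"H": 2, "O": 1},
    "H+": {"H": 1, "charge": 1},
    "CO2": {"C": 1, "O": 2},
    "CH2O": {"C": 1, "H": 2, "O": 1},
    "NO3": {"N": 1, "O": 3, "charge": -1},
    "N2": {"N": 2},
    "NH4": {"N": 1, "H": 4, "charge": 1},
    # carriers: NADH = NAD+ + H+ + 2e-, FADH2 = FAD + 2H+ + 2e-, Fd_red = Fd_ox + e-
    "NAD+": {"NAD": 1, "charge": 1},
    "NADH": {"NAD": 1, "H": 1},
    "FAD": {"FAD": 1},
    "FADH2": {"FAD": 1, "H": 2},
    "Fd_ox": {"Fd": 1},
    "Fd_red": {"Fd": 1, "charge": -1},
}

ELEMENTS = ("S", "O", "H", "C", "N", "NAD", "FAD", "Fd", "charge")

#: species whose activity is fixed at 1 in reaction quotients: elemental sulfur
#: (pure solid), water (solvent) and generic biomass carbon.
ACTIVITY_ONE = frozenset({"S0", "H2O", "CH2O"})

#: display names used when rendering equations as text
DISPLAY = {
    "SO4": "SO4^2-",
    "S2O3": "S2O3^2-",
    "NO3": "NO3^-",
    "NH4": "NH4^+",
}


def display_name(species: str) -> str:
    return DISPLAY.get(species, species)
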