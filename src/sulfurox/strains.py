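"""Strain records and the packaged strain compilation fixture."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .exceptions import InadmissibleParameterError
from .stoichiometry import get_pathway, get_substrate, get_tea


@dataclass(frozen=True)
class StrainRecord:
    """One organism's stoichiometric characterization.

    (x, y) must be admissible for the substrate; pathway is the CO2 fixation
    cycle (calvin or rtca).
    """

    id: str
    name: str
    substrate: str
    tea: str
    pathway: str
    x: float
    y: float
    group: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        get_substrate(self.substrate).validate_x(self.x)
        get_tea(self.tea)
        get_pathway(self.pathway)
        if not 0.0 <= self.y <= 1.0:
            raise InadmissibleParameterError(
                f"y must be in [0, 1], got {self.y} for strain {self.id}"
            )


def _records_from_frame(df: pd.DataFrame) -> list[StrainRecord]:
    return [
        StrainRecord(
            id=str(row["id"]), name=str(row["name"]),
            substrate=str(row["substrate"]), tea=str(row["tea"]),
            pathway=str(row["pathway"]), x=float(row["x"]), y=float(row["y"]),
            group=str(row.get("group", "")), source=str(row.get("source", "")),
        )
        for _, row in df.iterrows()
    ]


def load_strain_table(path=None) -> list[StrainRecord]:
    """Load a strain table (delimited text, header required).

    With no path the packaged compilation of literature-derived strains is
    returned.
    """
    if path is None:
        with resources.as_file(
            resources.files("sulfurox") / "data" / "strains.tsv"
        ) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    return _records_from_frame(df)


def load_printed_values() -> pd.DataFrame:
    """Published efficiency values for the packaged compilation (for deviation
    reporting); indexed by strain id."""
    with resources.as_file(
        resources.files("sulfurox") / "data" / "table1_printed.tsv"
    ) as p:
        return pd.read_csv(p, sep="\t", comment="#").set_index("id")


def get_strain(strain_id: str, strains: list[StrainRecord] | None = None) -> StrainRecord:
    strains = strains if strains is not None else load_strain_table()
    for record in strains:
        if record.id == strain_id:
            return record
    raise InadmissibleParameterError(f"no strain with id {strain_id!r}")
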