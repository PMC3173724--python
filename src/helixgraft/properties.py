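"""Amino-acid property tables.

A :class:`PropertyTable` maps each of the 20 canonical residues to one real
number (a hydrophobicity scale value, a residue mass in Da, ...). Tables ship
as editable two-column whitespace-delimited text files and can be replaced by
the user; the bundled defaults are the Kyte-Doolittle hydropathy scale and
average residue masses. Chou-Fasman conformational propensities (three values
per residue) back the built-in secondary-structure predictor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

from .errors import AlphabetError, FormatError

#: The 20 canonical one-letter amino-acid codes, alphabetical.
CANONICAL_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)


def validate_sequence_alphabet(seq: str, *, context: str = "sequence") -> str:
    """Return ``seq`` uppercased, raising :class:`AlphabetError` on any
    non-canonical residue (B, Z, X, U, gaps, ...)."""
    seq = seq.upper()
    bad = sorted(set(seq) - _CANONICAL_SET)
    if bad:
        raise AlphabetError(
            f"{context} contains non-canonical residue(s) {bad!r}; "
            f"allowed alphabet is {CANONICAL_RESIDUES}"
        )
    return seq


@dataclass(frozen=True)
class PropertyTable:
    """One real value per canonical residue.

    Parameters
    ----------
    name:
        Free-text label ("kyte_doolittle", "average_mass", ...).
    values:
        Mapping with exactly the 20 canonical residues as keys and finite
        floats as values.
    """

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        keys = set(self.values)
        if keys != _CANONICAL_SET:
            missing = sorted(_CANONICAL_SET - keys)
            extra = sorted(keys - _CANONICAL_SET)
            raise FormatError(
                f"property table {self.name!r} must cover exactly the 20 "
                f"canonical residues (missing {missing}, extra {extra})"
            )
        for res, val in self.values.items():
            if not math.isfinite(val):
                raise FormatError(
                    f"property table {self.name!r}: non-finite value for {res}"
                )

    def __getitem__(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise AlphabetError(
                f"residue {residue!r} not in property table {self.name!r}"
            ) from None

    @property
    def min(self) -> float:
        return min(self.values.values())

    @property
    def max(self) -> float:
        return max(self.values.values())


def _parse_rows(text: str, path: str) -> list[list[str]]:
    rows = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields[0]) != 1:
            raise FormatError(f"{path}:{lineno}: expected one-letter residue code")
        rows.append(fields)
    return rows


def load_property_table(path: str | Path, name: str | None = None) -> PropertyTable:
    """Load a two-column (residue, value) whitespace-delimited table."""
    path = Path(path)
    rows = _parse_rows(path.read_text(), str(path))
    values: dict[str, float] = {}
    for fields in rows:
        if len(fields) != 2:
            raise FormatError(f"{path}: expected two columns, got {fields!r}")
        res = fields[0].upper()
        if res in values:
            raise FormatError(f"{path}: duplicate residue {res}")
        values[res] = float(fields[1])
    return PropertyTable(name or path.stem, values)


@dataclass(frozen=True)
class PropensityTable:
    """Chou-Fasman style conformational propensities: per residue one value
    for each of helix (H), sheet (E) and turn/loop (C)."""

    name: str
    helix: Mapping[str, float] = field(repr=False)
    sheet: Mapping[str, float] = field(repr=False)
    turn: Mapping[str, float] = field(repr=False)

    def __post_init__(self) -> None:
        for label, mapping in (("helix", self.helix), ("sheet", self.sheet),
                               ("turn", self.turn)):
            if set(mapping) != _CANONICAL_SET:
                raise FormatError(
                    f"propensity table {self.name!r}: {label} column must "
                    "cover exactly the 20 canonical residues"
                )


def load_propensity_table(path: str | Path, name: str | None = None) -> PropensityTable:
    """Load a four-column (residue, P_helix, P_sheet, P_turn) text table."""
    path = Path(path)
    rows = _parse_rows(path.read_text(), str(path))
    helix: dict[str, float] = {}
    sheet: dict[str, float] = {}
    turn: dict[str, float] = {}
    for fields in rows:
        if len(fields) != 4:
            raise FormatError(f"{path}: expected four columns, got {fields!r}")
        res = fields[0].upper()
        if res in helix:
            raise FormatError(f"{path}: duplicate residue {res}")
        helix[res], sheet[res], turn[res] = map(float, fields[1:])
    return PropensityTable(name or path.stem, helix, sheet, turn)


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("helixgraft").joinpath("data", filename)))


def kyte_doolittle() -> PropertyTable:
    """The bundled Kyte-Doolittle hydropathy scale."""
    return load_property_table(_data_path("kyte_doolittle.tsv"), "kyte_doolittle")


def average_mass() -> PropertyTable:
    """The bundled average residue masses (Da)."""
    return load_property_table(_data_path("residue_mass_average.tsv"), "average_mass")


def chou_fasman() -> PropensityTable:
    """The bundled Chou-Fasman conformational propensities."""
    return load_propensity_table(
        _data_path("chou_fasman_propensities.tsv"), "chou_fasman"
    )
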