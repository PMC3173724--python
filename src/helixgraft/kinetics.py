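"""Protein-DNA association criterion and relative rate arithmetic.

The reaction criterion used to score Brownian-dynamics trajectories: polar
atom pairs between the two molecules that sit closer than 4.5 Angstrom in
the bound complex define the reaction pairs, and a diffusional encounter
counts as an association event when three or more of those pairs are
simultaneously closer than 5.5 Angstrom. Distance comparisons are strict
(<). This module identifies pairs, tests frames, computes success fractions,
and turns externally computed k_on values into rates relative to a reference
complex. The Brownian propagator and the Northrup-Allison-McCammon rate
formula themselves are out of scope: k_on values are consumed, not produced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import AtomLookupError, ParameterError

#: Elements treated as polar by default (hydrogen-bond donors/acceptors).
DEFAULT_POLAR_ELEMENTS = frozenset({"N", "O"})

DEFINE_CUTOFF = 4.5  # Angstrom, bound-complex pair definition
FIRE_CUTOFF = 5.5  # Angstrom, per-frame association test
MIN_PAIRS = 3  # simultaneous pairs required for association


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the protein-DNA complex."""

    serial: int
    atom_name: str
    element: str
    residue_id: int
    molecule_tag: str  # "protein" | "dna"
    coord: tuple[float, float, float]
    polar_flag: bool | None = None

    def __post_init__(self) -> None:
        if self.molecule_tag not in ("protein", "dna"):
            raise ParameterError(
                f"molecule_tag must be 'protein' or 'dna', got {self.molecule_tag!r}"
            )
        if not np.isfinite(self.coord).all():
            raise ParameterError(f"atom {self.serial}: non-finite coordinates")
        if self.polar_flag is None:
            object.__setattr__(
                self, "polar_flag", self.element.upper() in DEFAULT_POLAR_ELEMENTS
            )


@dataclass(frozen=True)
class ReactionPairSet:
    """Cross-molecule polar atom pairs with the association thresholds."""

    pairs: frozenset[tuple[int, int]]  # (protein serial, dna serial)
    define_cutoff: float = DEFINE_CUTOFF
    fire_cutoff: float = FIRE_CUTOFF
    min_pairs: int = MIN_PAIRS

    def __post_init__(self) -> None:
        if not self.define_cutoff < self.fire_cutoff:
            raise ParameterError("define_cutoff must be below fire_cutoff")
        if self.min_pairs < 1:
            raise ParameterError("min_pairs must be >= 1")

    def __len__(self) -> int:
        return len(self.pairs)


def define_reaction_pairs(
    complex_atoms: Sequence[AtomRecord],
    cutoff: float = DEFINE_CUTOFF,
    fire_cutoff: float = FIRE_CUTOFF,
    min_pairs: int = MIN_PAIRS,
    polar_elements: Iterable[str] | None = None,
) -> ReactionPairSet:
    """All protein-DNA polar atom pairs at distance < ``cutoff`` in the
    bound complex.

    ``polar_elements`` overrides the default N/O polarity convention; atoms
    constructed with an explicit ``polar_flag`` keep it regardless.
    """
    tags = {a.molecule_tag for a in complex_atoms}
    if tags != {"protein", "dna"}:
        raise ParameterError(
            f"complex must contain both protein and dna atoms, got {sorted(tags)}"
        )
    if polar_elements is None:
        prot = [a for a in complex_atoms if a.molecule_tag == "protein" and a.polar_flag]
        dna = [a for a in complex_atoms if a.molecule_tag == "dna" and a.polar_flag]
    else:
        polar = {e.upper() for e in polar_elements}
        prot = [
            a for a in complex_atoms
            if a.molecule_tag == "protein" and a.element.upper() in polar
        ]
        dna = [
            a for a in complex_atoms
            if a.molecule_tag == "dna" and a.element.upper() in polar
        ]
    if not prot or not dna:
        warnings.warn(
            "no polar atoms on one side of the complex; empty reaction-pair set",
            RuntimeWarning,
            stacklevel=2,
        )
        return ReactionPairSet(frozenset(), cutoff, fire_cutoff, min_pairs)
    ptree = cKDTree(np.array([a.coord for a in prot]))
    dtree = cKDTree(np.array([a.coord for a in dna]))
    pairs = set()
    for pi, hits in enumerate(ptree.query_ball_tree(dtree, r=cutoff)):
        pxyz = np.array(prot[pi].coord)
        for di in hits:
            # KD-tree uses <=; the criterion is strictly '<'
            if np.linalg.norm(pxyz - np.array(dna[di].coord)) < cutoff:
                pairs.add((prot[pi].serial, dna[di].serial))
    return ReactionPairSet(frozenset(pairs), cutoff, fire_cutoff, min_pairs)


def _coord_lookup(frame: Sequence[AtomRecord]) -> dict[int, np.ndarray]:
    return {a.serial: np.asarray(a.coord, dtype=float) for a in frame}


def association_test(frame: Sequence[AtomRecord], pairs: ReactionPairSet) -> bool:
    """True iff at least ``min_pairs`` reaction pairs are at distance
    < ``fire_cutoff`` in this frame."""
    coords = _coord_lookup(frame)
    close = 0
    for p_serial, d_serial in pairs.pairs:
        for serial in (p_serial, d_serial):
            if serial not in coords:
                raise AtomLookupError(f"atom serial {serial} missing from frame")
        if np.linalg.norm(coords[p_serial] - coords[d_serial]) < pairs.fire_cutoff:
            close += 1
            if close >= pairs.min_pairs:
                return True
    return False


def association_fraction(
    frames: Sequence[Sequence[AtomRecord]], pairs: ReactionPairSet
) -> float:
    """Fraction of frames (or trajectory endpoints) that satisfy the
    association criterion."""
    if len(frames) == 0:
        raise ParameterError("need at least one frame")
    fired = sum(association_test(frame, pairs) for frame in frames)
    return fired / len(frames)


def _round3(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class RateTable:
    """Per-model association rates relative to a reference complex."""

    rows: pd.DataFrame = field(repr=False)
    reference_label: str = ""

    def rel_kon(self, label: str) -> float:
        hit = self.rows.loc[self.rows["model"] == label, "rel_kon"]
        if hit.empty:
            raise ParameterError(f"no model labelled {label!r}")
        return float(hit.iloc[0])


def relative_kon(
    table: Sequence[tuple[str, float]] | pd.DataFrame,
    reference_label: str,
    net_charges: dict[str, int] | None = None,
) -> RateTable:
    """Relative association rates: rel_kon = k_on / k_on(reference), rounded
    half-even to 3 decimals (reference row = 1.000, zero k_on = 0.000)."""
    if isinstance(table, pd.DataFrame):
        rows = list(zip(table["model"], table["k_on"]))
    else:
        rows = list(table)
    kon = dict(rows)
    if reference_label not in kon:
        raise ParameterError(f"reference {reference_label!r} not in table")
    ref = float(kon[reference_label])
    if ref <= 0:
        raise ParameterError("reference k_on must be positive")
    records = []
    for label, value in rows:
        value = float(value)
        if value < 0:
            raise ParameterError(f"negative k_on for {label!r}")
        rec = {"model": label, "k_on": value, "rel_kon": _round3(value / ref)}
        if net_charges is not None:
            rec["net_charge"] = net_charges.get(label)
        records.append(rec)
    cols = ["model", "k_on"] + (["net_charge"] if net_charges else []) + ["rel_kon"]
    df = pd.DataFrame.from_records(records)[cols]
    return RateTable(rows=df, reference_label=reference_label)


def read_rate_table(path: str | Path) -> pd.DataFrame:
    """Read a (model, k_on[, net_charge]) tab-separated table; lines starting
    with '#' are comments."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "model" not in df.columns or "k_on" not in df.columns:
        raise ParameterError(f"{path}: need 'model' and 'k_on' columns")
    return df


def write_rate_table(table: RateTable, path: str | Path) -> None:
    table.rows.to_csv(path, sep="\t", index=False)
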