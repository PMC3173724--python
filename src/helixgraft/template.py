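"""Constrained fusion-design templates.

The design problem: graft a donor segment (here, the DNA-binding helix of
MyoD bHLH) into a scaffold (the three-helix Z domain derived from
staphylococcal protein A), keep the functionally essential residues of both
binding sites fixed, and let a genetic algorithm mutate everything else.

All user-facing residue indices are 1-based and ranges are closed, matching
standard residue numbering. Internal arrays are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple

from .errors import CoordinateError, ParameterError
from .properties import validate_sequence_alphabet

SS_ALPHABET = frozenset("HEC")


class FitnessVector(NamedTuple):
    """The three-component objective vector, oriented so that greater is
    better in every component (differences enter negated)."""

    ss_score: float
    neg_hydro_diff: float
    neg_mw_diff: float


@dataclass(frozen=True)
class DesignTemplate:
    """Seed sequence plus the constraints and targets the objectives use.

    Parameters
    ----------
    seed:
        The fusion seed sequence (canonical residues).
    fixed_positions:
        1-based positions that must never mutate (the binding-site residues).
    target_ss:
        Secondary-structure string over {H, E, C} the query predictions are
        aligned against; same length as ``seed``. ``None`` until completed.
    target_hydro_integral, target_mw_integral:
        Stored spline integrals of the target hydropathy / mass profiles
        (scale*residue and Da*residue units). ``None`` until completed.
    """

    seed: str
    fixed_positions: frozenset[int]
    target_ss: str | None = None
    target_hydro_integral: float | None = None
    target_mw_integral: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "seed", validate_sequence_alphabet(self.seed, context="seed")
        )
        object.__setattr__(self, "fixed_positions", frozenset(self.fixed_positions))
        n = len(self.seed)
        if n == 0:
            raise ParameterError("seed sequence must be non-empty")
        for pos in self.fixed_positions:
            if not 1 <= pos <= n:
                raise CoordinateError(
                    f"fixed position {pos} outside fusion coordinates 1..{n}"
                )
        if self.target_ss is not None:
            if len(self.target_ss) != n:
                raise ParameterError(
                    f"target_ss length {len(self.target_ss)} != seed length {n}"
                )
            bad = set(self.target_ss) - SS_ALPHABET
            if bad:
                raise ParameterError(f"target_ss contains states {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seed)

    @property
    def free_positions(self) -> tuple[int, ...]:
        """1-based positions the GA may mutate, ascending."""
        return tuple(
            i for i in range(1, len(self.seed) + 1) if i not in self.fixed_positions
        )

    @property
    def is_complete(self) -> bool:
        """True once target structure string and both integrals are set."""
        return (
            self.target_ss is not None
            and self.target_hydro_integral is not None
            and self.target_mw_integral is not None
        )

    def with_targets(
        self, target_ss: str, target_hydro_integral: float, target_mw_integral: float
    ) -> "DesignTemplate":
        return replace(
            self,
            target_ss=target_ss,
            target_hydro_integral=target_hydro_integral,
            target_mw_integral=target_mw_integral,
        )


@dataclass
class Individual:
    """One candidate sequence in the population."""

    sequence: str
    fitness: FitnessVector | None = None
    pareto_rank: int | None = None


def _check_closed_range(rng: tuple[int, int], n: int, system: str) -> None:
    lo, hi = rng
    if not (1 <= lo <= hi <= n):
        raise CoordinateError(
            f"range {lo}-{hi} invalid in {system} coordinates 1..{n}"
        )


def build_fusion_template(
    scaffold_seq: str,
    scaffold_keep: tuple[int, int],
    graft_seq: str,
    graft_range: tuple[int, int],
    conserved_scaffold: Iterable[int] = (),
    conserved_graft: Iterable[int] = (),
) -> DesignTemplate:
    """Concatenate a kept scaffold range with a donor graft segment.

    ``scaffold_keep`` and ``graft_range`` are 1-based closed ranges in the
    scaffold's and the donor's own numbering. Conserved positions, given in
    their native numbering, are remapped onto fusion coordinates and become
    the template's fixed positions. For the published design this is the Z
    domain with helix 3 (residues 42-57) replaced by the MyoD basic helix
    (donor residues 110-125), conserving the Fc contacts (5, 9-11, 13, 14,
    28, 31) and the DNA contacts (110, 111, 114, 115, 117-119, 121).

    The returned template carries no objective targets yet; see
    :func:`helixgraft.fitness.complete_template`.
    """
    scaffold_seq = validate_sequence_alphabet(scaffold_seq, context="scaffold")
    graft_seq = validate_sequence_alphabet(graft_seq, context="graft donor")
    _check_closed_range(scaffold_keep, len(scaffold_seq), "scaffold")
    _check_closed_range(graft_range, len(graft_seq), "graft donor")

    keep_lo, keep_hi = scaffold_keep
    graft_lo, graft_hi = graft_range
    scaffold_part = scaffold_seq[keep_lo - 1 : keep_hi]
    graft_part = graft_seq[graft_lo - 1 : graft_hi]
    seed = scaffold_part + graft_part

    fixed: set[int] = set()
    for pos in conserved_scaffold:
        if not keep_lo <= pos <= keep_hi:
            raise CoordinateError(
                f"conserved scaffold position {pos} outside kept range "
                f"{keep_lo}-{keep_hi} (scaffold coordinates)"
            )
        fixed.add(pos - keep_lo + 1)
    offset = len(scaffold_part)
    for pos in conserved_graft:
        if not graft_lo <= pos <= graft_hi:
            raise CoordinateError(
                f"conserved graft position {pos} outside grafted range "
                f"{graft_lo}-{graft_hi} (donor coordinates)"
            )
        fixed.add(offset + pos - graft_lo + 1)

    return DesignTemplate(seed=seed, fixed_positions=frozenset(fixed))


def validate_sequence(seq: str, template: DesignTemplate) -> bool:
    """True iff ``seq`` has the template's length and agrees with the seed
    at every fixed position. Pure predicate; never raises."""
    if len(seq) != len(template.seed):
        return False
    seed = template.seed
    return all(seq[i - 1] == seed[i - 1] for i in template.fixed_positions)
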