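"""The three design objectives.

A candidate sequence is scored against the design template by

1. a Smith-Waterman local alignment of its predicted secondary-structure
   string (alphabet H/E/C) against the template's target structure string;
2. the absolute difference of the hydropathy-profile spline integrals,
   |integral f_query - integral f_target|, with profiles built by a
   sliding-window mean (window 7) over a hydrophobicity scale;
3. the same integral difference computed on residue molecular weights.

The integrals, rather than pointwise differences, are used so that
neighbouring residues can neutralise each other's contributions. The two
difference objectives enter the fitness vector negated so that every
component is maximised and Pareto dominance applies uniformly.

Secondary structure prediction is a pluggable contract (sequence -> state
string); the default is a deterministic sliding-window Chou-Fasman propensity
predictor, and any external predictor can be wired in via a shell command.
"""

from __future__ import annotations

import functools
import shlex
import subprocess
from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
from Bio import Align
from scipy.interpolate import CubicSpline

from .errors import ParameterError, PredictionError
from .properties import (
    CANONICAL_RESIDUES,
    PropensityTable,
    PropertyTable,
    chou_fasman,
    validate_sequence_alphabet,
)
from .template import DesignTemplate, FitnessVector, Individual, validate_sequence

DEFAULT_WINDOW = 7

_RESIDUE_INDEX = {res: i for i, res in enumerate(CANONICAL_RESIDUES)}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_RESIDUE_INDEX[r] for r in seq), dtype=np.intp, count=len(seq))


@dataclass(frozen=True)
class SSPrediction:
    """A per-residue secondary-structure string over {H, E, C}."""

    states: str

    def __post_init__(self) -> None:
        bad = set(self.states) - set("HEC")
        if bad:
            raise PredictionError(
                f"secondary-structure states must be H/E/C, got {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.states)


class SSPredictor(Protocol):
    """Contract for secondary-structure predictors."""

    def __call__(self, seq: str) -> str: ...


class PropensityPredictor:
    """Deterministic Chou-Fasman-style baseline predictor.

    For each residue the helix/sheet/turn propensities are averaged over a
    sliding window (truncated at the termini) and the state with the largest
    mean wins; ties break in the order H > E > C.
    """

    def __init__(self, table: PropensityTable | None = None, window: int = DEFAULT_WINDOW):
        if window < 1 or window % 2 == 0:
            raise ParameterError(f"propensity window must be odd and >= 1, got {window}")
        table = table or chou_fasman()
        self.table = table
        self.window = window
        # rows: H, E, C propensity per residue ordinal
        self._prop = np.array(
            [
                [table.helix[r] for r in CANONICAL_RESIDUES],
                [table.sheet[r] for r in CANONICAL_RESIDUES],
                [table.turn[r] for r in CANONICAL_RESIDUES],
            ]
        )

    def __call__(self, seq: str) -> str:
        idx = _encode(seq)
        tracks = self._prop[:, idx]  # (3, n)
        w = min(self.window, len(seq))
        if w % 2 == 0:  # keep the window odd (and centred) for short sequences
            w -= 1
        kernel = np.ones(w)
        counts = np.convolve(np.ones(len(seq)), kernel, mode="same")
        means = np.stack(
            [np.convolve(t, kernel, mode="same") / counts for t in tracks]
        )
        # argmax picks the first maximum -> tie order H > E > C
        winner = np.argmax(means, axis=0)
        return "".join("HEC"[k] for k in winner)


class ConstantPredictor:
    """Test stub: every residue gets the same state."""

    def __init__(self, state: str):
        if state not in "HEC" or len(state) != 1:
            raise ParameterError(f"constant predictor state must be H, E or C, got {state!r}")
        self.state = state

    def __call__(self, seq: str) -> str:
        return self.state * len(seq)


class ExternalPredictor:
    """Shell out to any program that reads FASTA on stdin and writes the
    state string to stdout."""

    def __init__(self, command: str):
        self.command = command

    def __call__(self, seq: str) -> str:
        proc = subprocess.run(
            shlex.split(self.command),
            input=f">query\n{seq}\n",
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            raise PredictionError(
                f"external predictor {self.command!r} failed: {proc.stderr.strip()}"
            )
        return proc.stdout.strip()


def predictor_from_spec(spec: str) -> SSPredictor:
    """Build a predictor from a config key: ``propensity``, ``constant:<X>``
    or ``external:<command>``."""
    if spec == "propensity":
        return PropensityPredictor()
    if spec.startswith("constant:"):
        return ConstantPredictor(spec.split(":", 1)[1])
    if spec.startswith("external:"):
        return ExternalPredictor(spec.split(":", 1)[1])
    raise ParameterError(f"unknown predictor spec {spec!r}")


def predict_ss(seq: str, predictor: SSPredictor) -> SSPrediction:
    """Run a predictor and validate its output (one H/E/C state per residue)."""
    seq = validate_sequence_alphabet(seq)
    if not seq:
        raise ParameterError("cannot predict secondary structure of an empty sequence")
    try:
        states = predictor(seq)
    except PredictionError:
        raise
    except Exception as exc:  # pragma: no cover - defensive wrap
        raise PredictionError(f"predictor raised {exc!r}") from exc
    if len(states) != len(seq):
        raise PredictionError(
            f"predictor returned {len(states)} states for {len(seq)} residues"
        )
    return SSPrediction(states)


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring for the 3-letter local alignment: match reward, mismatch and
    linear gap penalties."""

    match: float = 2.0
    mismatch: float = -1.0
    gap: float = -2.0

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ParameterError("match reward must be positive")
        if self.mismatch > 0 or self.gap > 0:
            raise ParameterError("mismatch and gap penalties must be <= 0")


@functools.lru_cache(maxsize=8)
def _aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def ss_alignment_score(
    query_ss: SSPrediction | str,
    target_ss: SSPrediction | str,
    params: AlignmentParams = AlignmentParams(),
) -> float:
    """Optimal Smith-Waterman local-alignment score of two H/E/C strings.

    Non-negative by the local-alignment convention (the empty alignment
    scores 0) and symmetric in its arguments.
    """
    q = query_ss.states if isinstance(query_ss, SSPrediction) else query_ss
    t = target_ss.states if isinstance(target_ss, SSPrediction) else target_ss
    if not q or not t:
        raise ParameterError("both structure strings must be non-empty")
    score = _aligner(params.match, params.mismatch, params.gap).score(q, t)
    return max(0.0, float(score))


@dataclass(frozen=True)
class HydroProfile:
    """Windowed-mean property profile: one value per residue position."""

    values: np.ndarray
    table_name: str = ""

    @property
    def n(self) -> int:
        return len(self.values)


def windowed_profile(
    seq: str, table: PropertyTable, window: int = DEFAULT_WINDOW
) -> HydroProfile:
    """Sliding-window mean of a property scale along the sequence.

    The value at position i is the mean table value over the window centred
    at i; at the termini the window is truncated so the profile has exactly
    one value per residue.
    """
    seq = validate_sequence_alphabet(seq)
    n = len(seq)
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be odd and positive, got {window}")
    if window > n:
        raise ParameterError(f"window {window} larger than sequence length {n}")
    vals = np.array([table[r] for r in seq], dtype=float)
    if window == 1:
        return HydroProfile(vals, table.name)
    kernel = np.ones(window)
    counts = np.convolve(np.ones(n), kernel, mode="same")
    return HydroProfile(np.convolve(vals, kernel, mode="same") / counts, table.name)


def profile_integral(profile: HydroProfile | np.ndarray) -> float:
    """Definite integral over the profile support [1, n] of the natural cubic
    spline interpolating the points (i, value_i)."""
    values = profile.values if isinstance(profile, HydroProfile) else np.asarray(profile, float)
    n = len(values)
    if n < 2:
        raise ParameterError(f"profile needs at least 2 points, got {n}")
    x = np.arange(1, n + 1, dtype=float)
    if n == 2:  # a single straight segment
        return float(0.5 * (values[0] + values[1]))
    spline = CubicSpline(x, values, bc_type="natural")
    return float(spline.integrate(1.0, float(n)))


def integral_difference_score(
    query_seq: str,
    template: DesignTemplate,
    table: PropertyTable,
    window: int = DEFAULT_WINDOW,
    kind: str = "hydro",
) -> float:
    """|integral of the query profile - stored target integral|.

    ``kind`` selects which stored target integral to compare against
    ("hydro" or "mw"). Zero when the query reproduces the target profile.
    """
    if kind == "hydro":
        target = template.target_hydro_integral
    elif kind == "mw":
        target = template.target_mw_integral
    else:
        raise ParameterError(f"kind must be 'hydro' or 'mw', got {kind!r}")
    if target is None:
        raise ParameterError(
            "template has no stored target integral; complete it first"
        )
    return abs(profile_integral(windowed_profile(query_seq, table, window)) - target)


def complete_template(
    template: DesignTemplate,
    predictor: SSPredictor,
    hydro_table: PropertyTable,
    mw_table: PropertyTable,
    window: int = DEFAULT_WINDOW,
) -> DesignTemplate:
    """Fill in the template's objective targets from its own seed: the
    predicted structure string and the two profile integrals."""
    target_ss = predict_ss(template.seed, predictor).states
    hydro = profile_integral(windowed_profile(template.seed, hydro_table, window))
    mw = profile_integral(windowed_profile(template.seed, mw_table, window))
    return template.with_targets(target_ss, hydro, mw)


def evaluate_fitness(
    ind: Individual | str,
    template: DesignTemplate,
    predictor: SSPredictor,
    params: AlignmentParams,
    hydro_table: PropertyTable,
    mw_table: PropertyTable,
    window: int = DEFAULT_WINDOW,
) -> FitnessVector:
    """Evaluate the three objectives for one candidate.

    Returns (ss_score, -hydro_difference, -mw_difference) so that greater is
    uniformly better.
    """
    seq = ind.sequence if isinstance(ind, Individual) else ind
    if not validate_sequence(seq, template):
        raise ParameterError(
            "candidate sequence violates the template (length or fixed positions)"
        )
    if not template.is_complete:
        raise ParameterError("template targets not set; call complete_template first")
    ss = predict_ss(seq, predictor)
    score = ss_alignment_score(ss, template.target_ss, params)
    hydro = integral_difference_score(seq, template, hydro_table, window, kind="hydro")
    mw = integral_difference_score(seq, template, mw_table, window, kind="mw")
    return FitnessVector(score, -hydro, -mw)


def make_fitness_function(
    template: DesignTemplate,
    predictor: SSPredictor,
    params: AlignmentParams,
    hydro_table: PropertyTable,
    mw_table: PropertyTable,
    window: int = DEFAULT_WINDOW,
) -> Callable[[str], FitnessVector]:
    """Bind the objective configuration into a sequence -> FitnessVector
    closure for the genetic algorithm."""

    def fitness(seq: str) -> FitnessVector:
        return evaluate_fitness(
            seq, template, predictor, params, hydro_table, mw_table, window
        )

    return fitness
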