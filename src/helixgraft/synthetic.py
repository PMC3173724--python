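"""Synthetic inputs with planted ground truth.

Every analysis stage can be exercised without any external data: random
constrained design templates, ideal-helix C-alpha traces with planted rigid
transforms and per-residue fluctuation amplitudes, and protein-DNA frame sets
in which the number of frames satisfying the association criterion is
planted exactly. All generators are bit-reproducible from ``rng_seed``.

The generators emulate the SHAPE of the study's inputs (a 56-residue fusion
seed with 16 fixed binding-site positions, multi-frame C-alpha trajectories,
polar-contact complexes); they carry none of the real Z-domain or MyoD
sequences or coordinates, which users supply themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .fitness import (
    DEFAULT_WINDOW,
    PropensityPredictor,
    complete_template,
)
from .kinetics import AtomRecord, ReactionPairSet, define_reaction_pairs
from .properties import CANONICAL_RESIDUES, average_mass, kyte_doolittle
from .structure import CaStructure, CaTrajectory
from .template import DesignTemplate


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs for the generators; unused fields are ignored by each one.

    Defaults mirror the study conditions: a 56-residue fusion sequence with
    16 conserved binding-site positions.
    """

    rng_seed: int = 0
    seq_length: int = 56
    n_fixed: int = 16
    n_residues: int = 15
    n_frames: int = 100
    planted_rotation: np.ndarray | None = field(default=None, repr=False)
    planted_translation: np.ndarray | None = field(default=None, repr=False)
    planted_rmsf: float | np.ndarray = 0.0
    n_defined_pairs: int = 5
    planted_firing_frames: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


def make_template(spec: FixtureSpec, window: int = DEFAULT_WINDOW) -> DesignTemplate:
    """Random canonical seed with randomly chosen fixed positions; the
    objective targets are computed from the seed itself (built-in propensity
    predictor, bundled hydropathy and mass tables), so the seed scores
    (perfect alignment, 0, 0)."""
    if spec.n_fixed > spec.seq_length:
        raise ParameterError(
            f"n_fixed {spec.n_fixed} exceeds seq_length {spec.seq_length}"
        )
    rng = spec.rng()
    seed = "".join(rng.choice(list(CANONICAL_RESIDUES), size=spec.seq_length))
    fixed = rng.choice(spec.seq_length, size=spec.n_fixed, replace=False) + 1
    template = DesignTemplate(seed=seed, fixed_positions=frozenset(int(i) for i in fixed))
    return complete_template(
        template, PropensityPredictor(), kyte_doolittle(), average_mass(), window
    )


def ideal_helix(n_residues: int, residue_start: int = 1) -> CaStructure:
    """C-alpha trace of an ideal alpha-helix: 2.3 A radius, 1.5 A rise and
    100 degrees of turn per residue."""
    i = np.arange(n_residues)
    theta = np.deg2rad(100.0) * i
    coords = np.stack(
        [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i], axis=1
    )
    return CaStructure(np.arange(residue_start, residue_start + n_residues), coords)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniformly random proper rotation matrix (QR with sign fix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_trajectory(spec: FixtureSpec) -> CaTrajectory:
    """Helix-like trajectory with planted per-residue fluctuations.

    Each frame is the ideal helix plus isotropic Gaussian jitter whose
    per-residue amplitude equals ``planted_rmsf`` in expectation (the
    per-axis standard deviation is amplitude / sqrt(3)). If a planted
    transform is set, every frame is rigidly moved by it.
    """
    rng = spec.rng()
    base = ideal_helix(spec.n_residues)
    amp = np.broadcast_to(
        np.asarray(spec.planted_rmsf, dtype=float), (spec.n_residues,)
    )
    sigma = amp / np.sqrt(3.0)
    jitter = rng.normal(size=(spec.n_frames, spec.n_residues, 3)) * sigma[None, :, None]
    frames = base.coords[None, :, :] + jitter
    if spec.planted_rotation is not None or spec.planted_translation is not None:
        R = spec.planted_rotation if spec.planted_rotation is not None else np.eye(3)
        t = (
            spec.planted_translation
            if spec.planted_translation is not None
            else np.zeros(3)
        )
        frames = frames @ np.asarray(R).T + np.asarray(t)
    return CaTrajectory(
        base.residue_ids, frames, np.arange(spec.n_frames, dtype=float)
    )


def _bound_complex(spec: FixtureSpec) -> list[AtomRecord]:
    """Bound complex: matched polar N/O atoms 3.0 A apart per pair, pairs
    spread 20 A apart so only the matched partners fall inside the 4.5 A
    definition cutoff."""
    atoms: list[AtomRecord] = []
    for k in range(spec.n_defined_pairs):
        x = 20.0 * k
        atoms.append(
            AtomRecord(
                serial=2 * k + 1, atom_name="N", element="N", residue_id=k + 1,
                molecule_tag="protein", coord=(x, 0.0, 0.0),
            )
        )
        atoms.append(
            AtomRecord(
                serial=2 * k + 2, atom_name="O", element="O", residue_id=k + 1,
                molecule_tag="dna", coord=(x, 3.0, 0.0),
            )
        )
    return atoms


def make_complex_frames(
    spec: FixtureSpec,
) -> tuple[list[list[AtomRecord]], ReactionPairSet, np.ndarray]:
    """Frames with an exactly planted number of associating frames.

    Firing frames keep the bound geometry (all pairs ~3 A, jitter < 0.2 A);
    non-firing frames translate the protein 50 A away. Returns the frames,
    the pair set defined from the bound complex, and the boolean firing mask.
    """
    if spec.planted_firing_frames > spec.n_frames:
        raise ParameterError(
            f"cannot plant {spec.planted_firing_frames} firing frames "
            f"in {spec.n_frames} frames"
        )
    if spec.n_defined_pairs < 3:
        raise ParameterError(
            "need at least 3 defined pairs for the association criterion"
        )
    rng = spec.rng()
    bound = _bound_complex(spec)
    pairs = define_reaction_pairs(bound)
    firing = np.zeros(spec.n_frames, dtype=bool)
    firing[rng.choice(spec.n_frames, size=spec.planted_firing_frames, replace=False)] = True
    frames: list[list[AtomRecord]] = []
    for fire in firing:
        frame = []
        for atom in bound:
            xyz = np.asarray(atom.coord) + rng.uniform(-0.1, 0.1, size=3)
            if not fire and atom.molecule_tag == "protein":
                xyz = xyz + np.array([0.0, -50.0, 0.0])
            frame.append(
                AtomRecord(
                    serial=atom.serial, atom_name=atom.atom_name,
                    element=atom.element, residue_id=atom.residue_id,
                    molecule_tag=atom.molecule_tag, coord=tuple(xyz),
                )
            )
        frames.append(frame)
    return frames, pairs, firing
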