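"""Post-simulation geometry on C-alpha traces.

Covers the analysis protocol applied to the designed fusion models: rigid
superposition onto a reference on a stated fit region (helices 1 and 2 of the
Z domain, residues 6-17 and 22-33 by default), C-alpha RMSD over a region of
interest (the grafted helix, residues 39-53 by default), per-residue RMSF
across trajectory frames, and spline smoothing of RMSD-versus-time curves.
All residue ranges are user parameters; the defaults document the protocol
used for the Z-domain fusion designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio.PDB import PDBParser
from scipy.interpolate import UnivariateSpline

from .errors import FormatError, ParameterError


@dataclass(frozen=True)
class CaStructure:
    """Ordered C-alpha trace: residue numbers and one (x, y, z) in Angstrom
    per residue."""

    residue_ids: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        rid = np.asarray(self.residue_ids, dtype=int)
        xyz = np.asarray(self.coords, dtype=float)
        if rid.ndim != 1 or xyz.shape != (len(rid), 3):
            raise ParameterError("residue_ids must be (n,), coords (n, 3)")
        if len(rid) and not (np.diff(rid) > 0).all():
            raise ParameterError("residue_ids must be strictly increasing")
        if not np.isfinite(xyz).all():
            raise ParameterError("coordinates must be finite")
        object.__setattr__(self, "residue_ids", rid)
        object.__setattr__(self, "coords", xyz)

    def __len__(self) -> int:
        return len(self.residue_ids)

    def index_of(self, residues: Iterable[int]) -> np.ndarray:
        """0-based array positions of the given residue numbers."""
        wanted = sorted(set(residues))
        lookup = {int(r): i for i, r in enumerate(self.residue_ids)}
        missing = [r for r in wanted if r not in lookup]
        if missing:
            raise ParameterError(f"residues {missing} absent from structure")
        return np.array([lookup[r] for r in wanted], dtype=int)


@dataclass(frozen=True)
class CaTrajectory:
    """Frames sharing one residue numbering; times in ps, strictly
    increasing."""

    residue_ids: np.ndarray
    coords: np.ndarray  # (n_frames, n_residues, 3)
    times: np.ndarray

    def __post_init__(self) -> None:
        rid = np.asarray(self.residue_ids, dtype=int)
        xyz = np.asarray(self.coords, dtype=float)
        t = np.asarray(self.times, dtype=float)
        if xyz.ndim != 3 or xyz.shape[1] != len(rid) or xyz.shape[2] != 3:
            raise ParameterError("coords must be (n_frames, n_residues, 3)")
        if len(t) != len(xyz):
            raise ParameterError("one time per frame required")
        if len(t) > 1 and not (np.diff(t) > 0).all():
            raise ParameterError("times must be strictly increasing")
        object.__setattr__(self, "residue_ids", rid)
        object.__setattr__(self, "coords", xyz)
        object.__setattr__(self, "times", t)

    @property
    def n_frames(self) -> int:
        return len(self.coords)

    def frame(self, i: int) -> CaStructure:
        return CaStructure(self.residue_ids, self.coords[i])


def read_ca_pdb(
    path: str | Path, chain: str | None = None
) -> CaStructure | CaTrajectory:
    """Parse CA atoms from a PDB file (first chain, or a named chain).

    A single-MODEL file yields a :class:`CaStructure`; MODEL/ENDMDL-delimited
    files yield a :class:`CaTrajectory` with frame index as the time axis.
    """
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    frames = []
    residue_ids = None
    for model in structure:
        if chain is None:
            chains = list(model)
            if not chains:
                continue
            target = chains[0]
        else:
            if chain not in model:
                raise FormatError(f"{path}: chain {chain!r} not found")
            target = model[chain]
        rids, xyz = [], []
        for residue in target:
            if "CA" in residue:
                rids.append(residue.id[1])
                xyz.append(residue["CA"].coord)
        if not rids:
            raise FormatError(f"{path}: no CA atoms in chain {target.id!r}")
        if residue_ids is None:
            residue_ids = rids
        elif rids != residue_ids:
            raise FormatError(f"{path}: models carry different residue sets")
        frames.append(np.array(xyz, dtype=float))
    if not frames:
        raise FormatError(f"{path}: no models with CA atoms")
    if len(frames) == 1:
        return CaStructure(np.array(residue_ids), frames[0])
    return CaTrajectory(
        np.array(residue_ids),
        np.stack(frames),
        np.arange(len(frames), dtype=float),
    )


def write_ca_pdb(obj: CaStructure | CaTrajectory, path: str | Path) -> None:
    """Write a CA-only PDB file (fixed columns; MODEL records per frame)."""

    def atom_lines(struct: CaStructure) -> list[str]:
        lines = []
        for serial, (rid, (x, y, z)) in enumerate(
            zip(struct.residue_ids, struct.coords), 1
        ):
            lines.append(
                f"ATOM  {serial:5d}  CA  ALA A{rid:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
        return lines

    out: list[str] = []
    if isinstance(obj, CaTrajectory):
        for i in range(obj.n_frames):
            out.append(f"MODEL     {i + 1:4d}")
            out.extend(atom_lines(obj.frame(i)))
            out.append("ENDMDL")
    else:
        out.extend(atom_lines(obj))
    out.append("END")
    Path(path).write_text("\n".join(out) + "\n")


def kabsch_superpose(
    mobile: CaStructure, reference: CaStructure, fit_residues: Iterable[int]
) -> tuple[np.ndarray, np.ndarray, CaStructure]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    The optimal proper rotation over ``fit_residues`` is found by SVD of the
    covariance matrix with the usual determinant correction, so a reflection
    is never returned. The transform is applied to ALL mobile residues.

    Returns (rotation (3,3), translation (3,), transformed structure) with
    transformed = mobile @ R.T + t.
    """
    fit = list(fit_residues)
    if len(fit) < 3:
        raise ParameterError("superposition needs at least 3 fit residues")
    mi = mobile.index_of(fit)
    ri = reference.index_of(fit)
    P = mobile.coords[mi]
    Q = reference.coords[ri]
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    # conditioning check: (near-)collinear fit sets leave a rotation axis free
    sv = np.linalg.svd(P0, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        warnings.warn(
            "fit residues are (near-)collinear; superposition is ill-conditioned",
            RuntimeWarning,
            stacklevel=2,
        )
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    transformed = CaStructure(mobile.residue_ids, mobile.coords @ R.T + t)
    return R, t, transformed


def region_rmsd(a: CaStructure, b: CaStructure, region: Iterable[int]) -> float:
    """Root-mean-square deviation of paired CA positions over ``region``
    (Angstrom). Symmetric; zero iff the region coordinates coincide."""
    region = list(region)
    if not region:
        raise ParameterError("RMSD region must be non-empty")
    pa = a.coords[a.index_of(region)]
    pb = b.coords[b.index_of(region)]
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


def rmsf(
    traj: CaTrajectory, region: Iterable[int] | None = None
) -> dict[int, float]:
    """Per-residue root-mean-square fluctuation about the mean position
    across frames (frames are assumed pre-superposed)."""
    if traj.n_frames < 2:
        raise ParameterError("RMSF needs at least 2 frames")
    if region is None:
        idx = np.arange(len(traj.residue_ids))
    else:
        idx = traj.frame(0).index_of(region)
    xyz = traj.coords[:, idx, :]
    mean = xyz.mean(axis=0)
    flucts = np.sqrt(np.mean(np.sum((xyz - mean) ** 2, axis=2), axis=0))
    return {int(traj.residue_ids[i]): float(f) for i, f in zip(idx, flucts)}


def superposed_trajectory(
    traj: CaTrajectory, reference: CaStructure, fit_residues: Iterable[int]
) -> CaTrajectory:
    """Superpose every frame onto ``reference`` over ``fit_residues``."""
    fit = list(fit_residues)
    frames = [
        kabsch_superpose(traj.frame(i), reference, fit)[2].coords
        for i in range(traj.n_frames)
    ]
    return CaTrajectory(traj.residue_ids, np.stack(frames), traj.times)


def smooth_curve(
    times: np.ndarray,
    values: np.ndarray,
    degree: int = 3,
    smoothing: float | None = None,
) -> tuple[UnivariateSpline, np.ndarray]:
    """Cubic smoothing spline through (time, value), sampled back on the
    input grid.

    ``smoothing`` is the residual budget of the smoothing spline; the default
    (scipy's heuristic) reproduces noiseless linear data exactly, since a
    straight line has zero roughness and zero residual.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.ndim != 1 or times.shape != values.shape:
        raise ParameterError("times and values must be equal-length 1-D arrays")
    if len(times) < 4:
        raise ParameterError("smoothing needs at least 4 points")
    if not (np.diff(times) > 0).all():
        raise ParameterError("times must be strictly increasing")
    spline = UnivariateSpline(times, values, k=degree, s=smoothing)
    return spline, spline(times)
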