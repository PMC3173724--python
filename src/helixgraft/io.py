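"""File formats and run configuration.

FASTA via Biopython, residue-position range lists ("5,9-11,13"), and a YAML
run configuration that round-trips losslessly so every run directory can
reproduce itself.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ParameterError
from .properties import validate_sequence_alphabet


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) records; wrapped lines allowed, lowercase input
    is uppercased with a warning, non-canonical residues are rejected."""
    path = Path(path)
    records = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:
        raise FormatError(f"{path}: not parseable as FASTA ({exc})") from exc
    for rec in parsed:
        seq = str(rec.seq)
        if seq != seq.upper():
            warnings.warn(
                f"{path}: record {rec.id!r} contains lowercase residues; uppercasing",
                stacklevel=2,
            )
        try:
            seq = validate_sequence_alphabet(seq, context=f"record {rec.id!r}")
        except Exception as exc:
            raise FormatError(f"{path}: {exc}") from exc
        records.append((rec.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def parse_range_list(text: str) -> list[int]:
    """Parse "5,9-11,13" into sorted unique 1-based positions."""
    positions: set[int] = set()
    for token in text.split(","):
        token = token.strip()
        if not token:
            continue
        if "-" in token:
            lo_s, hi_s = token.split("-", 1)
            lo, hi = int(lo_s), int(hi_s)
            if lo > hi:
                raise ParameterError(f"bad range {token!r}: start exceeds end")
            positions.update(range(lo, hi + 1))
        else:
            positions.add(int(token))
    if not positions:
        raise ParameterError(f"no positions in range list {text!r}")
    return sorted(positions)


def format_range_list(positions) -> str:
    """Inverse of :func:`parse_range_list`: compact "5,9-11,13" form."""
    pos = sorted(set(int(p) for p in positions))
    if not pos:
        return ""
    chunks: list[str] = []
    start = prev = pos[0]
    for p in pos[1:] + [None]:
        if p is not None and p == prev + 1:
            prev = p
            continue
        chunks.append(str(start) if start == prev else f"{start}-{prev}")
        if p is not None:
            start = prev = p
    return ",".join(chunks)


@dataclass
class RunConfig:
    """Every tunable of the design pipeline, YAML round-trippable."""

    # GA
    population_size: int = 600
    generations: int = 1000
    mutation_rate: float = 0.01
    init_mutation_rate: float = 0.05
    offspring_per_generation: int | None = None
    rng_seed: int = 0
    # fitness
    window: int = 7
    match: float = 2.0
    mismatch: float = -1.0
    gap: float = -2.0
    ss_predictor: str = "propensity"
    hydro_table: str | None = None  # path; None = bundled Kyte-Doolittle
    mw_table: str | None = None  # path; None = bundled average masses
    # analysis defaults (published protocol)
    fit_residues: str = "6-17,22-33"
    rmsd_region: str = "39-53"
    # bookkeeping
    seed_fasta: str | None = None
    fixed_positions: str | None = None
    out_dir: str | None = None
    verbosity: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)


def write_history_tsv(history, path: str | Path) -> None:
    """Per-generation GA history as TSV with one commented header line."""
    lines = ["# generation\tfrontier_size\tbest_ss\tbest_neg_hydro\tbest_neg_mw"]
    for rec in history:
        best = "\t".join(f"{v:.6g}" for v in rec.best_components)
        lines.append(f"{rec.generation}\t{rec.frontier_size}\t{best}")
    Path(path).write_text("\n".join(lines) + "\n")
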