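"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's code paths: explicit loops, recursion
over the alignment definition, and two-pass statistics.
"""

from __future__ import annotations

import functools

import numpy as np


def oracle_dominates(x, y) -> bool:
    """Pairwise dominance written with explicit loops."""
    assert len(x) == len(y)
    some_greater = False
    for a, b in zip(x, y):
        if a < b:
            return False
        if a > b:
            some_greater = True
    return some_greater


def oracle_pareto_ranks(vectors) -> list[int]:
    """O(n^2 d) frontier peeling with explicit scans."""
    n = len(vectors)
    ranks = [0] * n
    remaining = set(range(n))
    rank = 0
    while remaining:
        rank += 1
        front = [
            i
            for i in remaining
            if not any(
                oracle_dominates(vectors[j], vectors[i])
                for j in remaining
                if j != i
            )
        ]
        assert front, "dominance must be acyclic"
        for i in front:
            ranks[i] = rank
        remaining -= set(front)
    return ranks


def best_local_alignment(query: str, target: str, match: float,
                         mismatch: float, gap: float) -> float:
    """Best Smith-Waterman local score by exhausting all substring pairs and
    recursing over the global-alignment definition for each pair.

    Exponential in principle; memoisation on suffix pairs keeps short inputs
    tractable without changing the recursion.
    """

    @functools.lru_cache(maxsize=None)
    def global_score(a: str, b: str) -> float:
        if not a and not b:
            return 0.0
        options = []
        if a and b:
            s = match if a[0] == b[0] else mismatch
            options.append(s + global_score(a[1:], b[1:]))
        if a:
            options.append(gap + global_score(a[1:], b))
        if b:
            options.append(gap + global_score(a, b[1:]))
        return max(options)

    best = 0.0
    for i0 in range(len(query)):
        for i1 in range(i0, len(query)):
            for j0 in range(len(target)):
                for j1 in range(j0, len(target)):
                    best = max(
                        best,
                        global_score(query[i0 : i1 + 1], target[j0 : j1 + 1]),
                    )
    return best


def oracle_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Sum-of-squares RMSD with an explicit loop."""
    total = 0.0
    for pa, pb in zip(a, b):
        for ca, cb in zip(pa, pb):
            total += (ca - cb) ** 2
    return (total / len(a)) ** 0.5


def oracle_rmsf(coords: np.ndarray) -> np.ndarray:
    """Two-pass per-residue fluctuation: mean first, then deviations."""
    n_frames, n_res, _ = coords.shape
    out = np.zeros(n_res)
    for r in range(n_res):
        mean = coords[:, r, :].sum(axis=0) / n_frames
        acc = 0.0
        for f in range(n_frames):
            d = coords[f, r, :] - mean
            acc += float(d @ d)
        out[r] = (acc / n_frames) ** 0.5
    return out


def oracle_pair_scan(protein_atoms, dna_atoms, cutoff: float):
    """O(n^2) cross-molecule polar pair scan."""
    pairs = set()
    for p in protein_atoms:
        if not p.polar_flag:
            continue
        for d in dna_atoms:
            if not d.polar_flag:
                continue
            dist = sum((a - b) ** 2 for a, b in zip(p.coord, d.coord)) ** 0.5
            if dist < cutoff:
                pairs.add((p.serial, d.serial))
    return pairs
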