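# Methods

## Design model

`helixgraft` treats fusion-protein design as multiobjective sequence
optimisation under positional constraints. A design template holds the fusion
seed (scaffold residues up to the graft point, followed by the donor
segment), the set of fixed 1-based positions (binding-site residues of both
parents, remapped into fusion coordinates), and the target values the
objectives compare against. Every candidate sequence has the template's
length and agrees with the seed at every fixed position; the mutation
operator enforces this by construction, so conservation of both binding
sites holds in every generation, not merely at the end.

All user-facing residue indices are 1-based with closed ranges, matching
conventional residue numbering. The fused length is always derived from the
inputs (kept scaffold range + grafted donor range), never assumed.

## Objectives

1. **Secondary-structure alignment.** The candidate's predicted H/E/C string
   is locally aligned (Smith–Waterman) against the template's target string.
   Defaults: match +2, mismatch −1, linear gap −2. These are package
   defaults, configurable; the 3-letter alphabet makes the score insensitive
   to the exact penalties as long as mismatch and gap are penalised. The
   empty alignment floors the score at 0. The DP is delegated to
   Biopython's `PairwiseAligner` (C implementation); tests check it against
   an independent exhaustive enumerator on short strings.
2. **Hydropathy-integral difference.** Per-residue Kyte–Doolittle values are
   averaged over a sliding window of 7; the profile is interpolated by a
   natural cubic spline and integrated in closed form over the profile
   support [1, n]. The objective is −|I_query − I_target|. The integral, as
   opposed to a pointwise distance, lets neighbouring residues neutralise
   each other — a deliberately coarse surrogate for hydrophobic-core
   compatibility.
3. **Molecular-weight-integral difference.** Identical machinery on average
   residue masses (Da), a surrogate for steric compatibility.

Both differences enter the fitness vector negated so that "greater is
better" holds uniformly and Pareto dominance needs no per-component
direction flags.

Windows at the termini are truncated (shrinking) so the profile has exactly
one value per residue — the integral's support then always matches the
sequence length. With fewer than 3 profile points the "spline" degenerates to
the straight segment. Non-canonical residues (B, Z, X, U) are rejected, not
imputed: the property tables have no entries for them.

### Secondary-structure predictor

The predictor is a contract: any callable from sequence to state string. The
built-in baseline averages Chou–Fasman helix/sheet/turn propensities over a
sliding window (7, truncated at termini; shrunk to the sequence length, kept
odd, for very short inputs) and assigns the arg-max state, ties breaking
H > E > C. It is deterministic, fast, and adequate for driving the GA and
its tests; it is *not* a modern predictor, and nothing in the pipeline
depends on its accuracy — any external predictor can be substituted via
`external:<command>`. A `constant:<X>` stub exists for tests.

## Genetic algorithm

- **Dominance and ranking.** x dominates y iff x ≥ y componentwise with at
  least one strict inequality. Frontier peeling assigns rank 1 to the
  nondominated set, removes it, and repeats. The implementation precomputes
  the pairwise dominance matrix (O(n²d), vectorised); an O(n²d) looped
  oracle backs the tests.
- **Selection.** The wording "lower rank is more likely selected" admits many
  schemes; the package samples two distinct parents with weight 1/rank — the
  simplest strictly rank-monotone choice. With all ranks equal it reduces to
  uniform sampling.
- **Variation.** 1-point crossover at a uniform cut in 1..L−1 (both parents
  satisfy the constraints, hence so does any child), then independent
  per-free-position substitution with probability equal to the mutation
  rate, drawing uniformly among the 19 other residues. The default rate
  0.01 reconciles "mutated at a random position" with a stated rate: at
  ~40 free positions it yields ≈0.4 substitutions per offspring.
- **Replacement.** Offspring count defaults to the population size; the 2N
  pool is ranked and truncated to N by (rank, then higher first objective,
  then stable input order). Elitist truncation implies no frontier
  regression: no rank-1 vector of generation g may dominate a rank-1 vector
  of generation g+1, which the tests audit generation by generation.
- **Initial population.** Seed copies mutated at free positions with
  probability 0.05 — diverse but seed-centred. Duplicates are allowed
  throughout; frontier sizes count individuals, not unique sequences.
- **Reproducibility.** All randomness flows from one integer seed through a
  single `numpy` generator; runs are bitwise reproducible. Fitness values
  are cached per sequence string (the objectives are deterministic), which
  collapses the cost of duplicated individuals.

"Sequences analysed" follows the population × generations accounting
(600 × 2000 = 1.2 million at full scale).

## Structural analysis

Kabsch superposition (SVD of the covariance with the determinant correction,
so a reflection is never returned) is computed on a user-stated fit region
and applied to all residues; Cα RMSD is then taken over a separate region of
interest. The documented defaults — fit on 6–17 and 22–33, RMSD over 39–53 —
are carried as *parameters* of the Z-domain fusion protocol; the package
makes no attempt to reconcile that RMSD window with the graft's scaffold
numbering (42–57), which the protocol leaves unexplained. Near-collinear fit sets
trigger a conditioning warning (a rotation axis is unconstrained).

RMSF is the per-residue RMS deviation from the mean position across frames,
computed on frames assumed pre-superposed; the CLI superposes every frame on
the reference fit region first. RMSD-versus-time curves are smoothed with a
cubic smoothing spline (`scipy` `UnivariateSpline`); the smoothing budget is
user-settable and the default heuristic reproduces noiseless linear series
exactly (a line has zero roughness and zero residual). Only Cα-based
analysis is implemented; all-atom RMSD would require full-atom trajectories
from external MD engines.

PDB I/O is fixed-column, CA-only, with MODEL/ENDMDL frames; reading goes
through Biopython's parser. Coordinates survive a write/read round trip to
the format's 3-decimal precision.

## Kinetics

Reaction pairs are cross-molecule polar–polar atom pairs at distance
< 4.5 Å in the bound complex; "polar" defaults to elements N and O
(user-overridable list, or explicit per-atom flags). A frame associates when
≥ 3 defined pairs are simultaneously < 5.5 Å. Both comparisons are strict
(<), following the criterion's wording. Pair search uses a KD-tree with an
explicit strict-inequality re-check (the tree query is ≤); an O(n²) scan
backs the tests.

Relative rates are `k_on / k_on(reference)`, rounded half-even to 3
decimals; a zero rate maps to 0.000 and the reference to 1.000. One known
rounding-provenance subtlety: from inputs already rounded to 3 significant
figures, 4.56e8 / 4.66e8 = 0.97854… rounds to 0.979, whereas a table
computed upstream from the unrounded rates can legitimately show 0.978. The
package always reports what its own inputs imply. The Brownian propagator and the Northrup–Allison–McCammon
rate formula are deliberately out of scope: this module consumes externally
computed rate constants and synthetic trajectory fixtures.

## Synthetic data

The fixture generators emulate the *shape* of the study's inputs, not their
content:

- **Templates**: random canonical 56-mers with 16 random fixed positions
  (both configurable); targets are computed from the seed itself, so the
  seed scores the perfect vector — a useful self-consistency anchor.
- **Trajectories**: ideal α-helix Cα traces (2.3 Å radius, 1.5 Å rise,
  100°/residue) with isotropic Gaussian jitter whose per-residue expected
  RMSF equals the planted amplitude (per-axis σ = amplitude/√3), optionally
  rigidly transformed by a planted rotation+translation.
- **Complexes**: matched polar atom pairs 3 Å apart, 20 Å between pairs, so
  the defined pair set is exactly the matched pairs; firing frames keep the
  bound geometry (±0.1 Å jitter), non-firing frames displace the protein
  50 Å, and the number of firing frames is planted exactly.

Because the generators carry no real sequences or coordinates, passing tests
demonstrate the *machinery* (constraint handling, convergence behaviour,
recovery of planted ground truth), not biological validity of any designed
sequence: real design runs require the user's own scaffold/donor sequences,
an external structure predictor of adequate quality, and downstream
modelling.

## Problem sizes and checks

The test suite runs the full population size (600) for 100 generations with
the built-in predictor — enough to audit conservation, determinism and
frontier monotonicity at scale — and uses reduced sizes elsewhere. The
single-objective toy check (maximise alanine count at free positions) runs
on a 16-free-position template at mutation rate 0.05, a configuration where
the optimum is reliably reachable within 50 individuals × 100 generations;
at the design default of 0.01 the expected tail time to fix the last few
positions exceeds that budget. Exhaustive oracle comparisons cover all
ordered populations of size ≤ 3 over the {0,1,2}³ fitness grid and all
H/E/C string pairs of length ≤ 3, with seeded random sampling beyond
(populations to size 12, strings to length 6), since full enumeration at
the larger sizes is combinatorially infeasible.

## Known limitations

- The propensity baseline is a 1970s-style predictor; frontier compositions
  and sizes depend strongly on the predictor driving the run, so frontier
  sizes obtained with other (e.g. neural-network) predictors are qualitative
  context only and are not targeted by any check here.
- Free-energy ranking (ERIS), MD engines and Brownian-dynamics propagation
  are integration points, not components: the package prepares their inputs
  and analyses their outputs.
- Only linear gap penalties and the 3-letter alphabet are supported in the
  structure alignment; no affine gaps or substitution matrices.
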