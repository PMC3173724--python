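# helixgraft

Multiobjective genetic-algorithm design of constrained fusion proteins, with
Pareto ranking and structural/kinetic post-analysis.

## The problem

Grafting a functional motif from one protein into another — here, the
DNA-binding basic helix of the MyoD bHLH domain into helix 3 of the Z domain,
a 58-residue three-helix IgG Fc-binding scaffold derived from staphylococcal
protein A — produces a fusion sequence that must keep two binding sites
intact while the rest of the sequence is re-optimised so the chimera still
folds like its scaffold. Physics-based screening (free-energy modelling,
molecular dynamics) is far too slow to search a sequence space of this size,
so `helixgraft` optimises cheap sequence-level surrogates instead and leaves
structure- and simulation-based refinement to downstream tools, for which it
provides the standard post-analyses.

## The method

Each candidate sequence `x` is scored by a fitness **vector**
`{f1(x), f2(x), f3(x)}`:

- `f1`: Smith–Waterman local-alignment score of the predicted
  secondary-structure string (alphabet H/E/C) against the target structure
  string (default scoring: match +2, mismatch −1, linear gap −2);
- `f2 = −|∫ h_query − ∫ h_target|`: negated absolute difference of the
  hydropathy-profile spline integrals, where the profile is a sliding-window
  mean (window 7) of the Kyte–Doolittle scale and the integral is taken over
  the natural cubic spline through the profile points;
- `f3`: the same construction on residue molecular weights.

Vectors are compared by Pareto dominance (`x` dominates `y` iff `x_i ≥ y_i`
everywhere and `x_i > y_i` somewhere); peeling nondominated frontiers yields
Pareto ranks. The GA keeps a fixed population (default 600), selects parents
with probability ∝ 1/rank, applies 1-point crossover and per-free-position
mutation (default rate 0.01), and truncates parents+offspring elitistically.
Binding-site residues are fixed positions that can never mutate, so every
individual in every generation conserves both sites by construction.

Post-analysis mirrors the standard protocol for the resulting models:
Kabsch superposition on a stated fit region (defaults: residues 6–17 and
22–33, helices 1–2), Cα RMSD over the grafted helix (default 39–53), RMSF
per residue, smoothing-spline RMSD curves, and the protein–DNA association
criterion (polar atom pairs defined at < 4.5 Å in the bound complex; a frame
associates when ≥ 3 pairs are < 5.5 Å) plus relative association rates
`rel k_on = k_on / k_on(reference)` from externally computed rate constants.

Secondary structure prediction is pluggable (`propensity` built-in baseline,
`constant:<X>` stub, `external:<command>` for any program reading FASTA on
stdin); the built-in predictor is a deterministic sliding-window
Chou–Fasman propensity classifier.

## Worked example

Generate a synthetic 56-residue design template (16 fixed positions) and run
a small design:

```sh
$ helixgraft gen-fixtures --kind template --seed 11 --out fixtures
wrote fixtures/seed.fasta
$ cat fixtures/fixed_positions.txt
1,5-6,9,14,17,22,24,33,36-37,42-43,47,50,55
$ helixgraft design --seed-fasta fixtures/seed.fasta \
    --fixed "$(cat fixtures/fixed_positions.txt)" \
    --pop 60 --gens 30 --rng-seed 11 --out run
final frontier: 60 individuals (written to run/frontier.fasta)
$ head -2 run/frontier.fasta
>design_0000 rank=1 ss=112 hydro_diff=0 mw_diff=0
DDSLNPRALDKWMCMDSWYPVIDMKQYGVDHSFQLMWTTMYYDFHNTLYIWNRFNT
$ head -4 run/history.tsv
# generation	frontier_size	best_ss	best_neg_hydro	best_neg_mw
0	8	112	-0	-0
1	24	112	-0	-0
2	51	112	-0	-0
```

`ss=112` is the perfect local-alignment score for a 56-residue target at
match +2; `hydro_diff=0` and `mw_diff=0` mean the frontier member reproduces
the target profile integrals exactly. The history shows the first Pareto
frontier growing as the population converges onto the trade-off surface.
Scoring the seed against its own template returns the perfect vector:

```sh
$ helixgraft score --query-fasta fixtures/seed.fasta \
    --seed-fasta fixtures/seed.fasta --fixed "$(cat fixtures/fixed_positions.txt)"
# id	ss_score	hydro_diff	mw_diff
synthetic_seed	112	0	0
```

Relative association rates from a table of measured `k_on` values:

```sh
$ helixgraft analyze-kinetics rates --table rates.tsv --reference WT
model	k_on	net_charge	rel_kon
WT	466000000.0	5	1.0
JW70	456000000.0	5	0.979
```

See also `helixgraft rank`, `helixgraft analyze-structure` (superposition,
region RMSD, RMSF, smoothed RMSD curves) and `helixgraft gen-fixtures
--kind trajectory|complex`.

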