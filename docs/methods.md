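# Methods

## Data model

A dataset is n samples × L SNPs of genotype codes (0 homozygous major,
1 heterozygous, 2 homozygous minor) with binary labels (1 = case). The
on-disk dialect is the GAMETES tab-delimited layout (header of SNP names
plus a final `Class` column), so files produced by GAMETES itself load
unchanged. Missing genotypes are deliberately unsupported: any token
outside {0,1,2} is a parse error, never an imputation.

## Fitness

The association of a pair {r_p, r_q} with disease is Pearson's χ² on the
2 × 9 table of status against joint genotypes. Columns with zero total
are dropped before expecteds are formed, which keeps the statistic
finite without pseudo-counts or a continuity correction; the degrees of
freedom for reported p-values are (occupied columns − 1), overridable by
the caller. The raw χ² (not the p-value) is the search fitness: at fixed
sample size the two orderings agree, and the statistic avoids p-value
underflow at strong signals. χ² = 0 exactly when the case and control
rows are proportional over occupied columns.

## Search operators and their free choices

Several operator details are underdetermined by the verbal description;
the choices made here, and why:

- **Index range.** Valid SNP indices are [1, L]. The initialization map
  ⌈u·L⌉ with u ~ U(0,1) produces exactly this range (the measure-zero
  u = 0 maps to 1).
- **Mutation offset rounding.** DBM's step is ⌈range · δ⌉, rounding
  *up*, so the smallest non-zero δ (2⁻¹⁵) still moves one index. This
  preserves the designed granularity of the δ distribution — under
  round-to-nearest more than half of all non-zero draws would collapse
  to a null move, and in our power study that collapse measurably starved
  exploration.
- **Out-of-range mutants.** A mutant with either coordinate outside
  [1, L] is reinitialized wholesale: both coordinates redrawn uniformly.
  This is the search's only unconditional global restart and matters for
  escaping a wrong basin once the population has contracted.
- **Per-coordinate draws.** Sign and δ are drawn independently per
  coordinate; a `shared_mutation_offset` switch applies one draw to both
  coordinates for users who prefer the coupled reading.
- **Degenerate pairs.** Any operator that produces r_p = r_q redraws the
  second coordinate uniformly — a self-pair has no 9-column joint
  distribution.
- **Local search body.** SLS is gated hill-climbing: up to
  `max_ls_steps` (default 10) DBM proposals, moving on fitness ties or
  gains. "Improved" for the p_z update means a strict fitness increase
  of the returned point over the point that entered local search;
  counting plateau moves as improvement would pin p_z at 1.
- **Best-pair timing.** x_best is recomputed after each generation's
  selection, so all individuals of a generation cross against the same
  best. Ties in the best scan break lexicographically for determinism.
- **Termination.** A fixed generation budget only; no convergence-based
  early stop. Elitist selection makes the best-fitness history
  non-decreasing by construction.

All randomness flows from a single seeded numpy Generator per run; pair
fitness is memoized, so duplicated proposals (frequent once the
population contracts around x_best) cost a dictionary lookup, and the
number of χ² computations per run is bounded by the number of distinct
pairs visited, itself at most L(L−1)/2.

## Penetrance models

The twelve built-in tables (three architectures × MAF 0.05/0.10/0.20/
0.50) are stored to the three printed decimals. Two identities validate
the transcription analytically under HWE at both loci with independent
loci:

- prevalence K = Σ P(g_A)P(g_B) f(g_A,g_B) = 0.1 within 5e-4;
- heritability h² = Σ P(g_A)P(g_B)(f − K)² / (K(1−K)) equal to the
  design value (0.005 for the multiplicative model, 0.02 for the
  threshold and interaction models) within 5e-4.

The residual up to 5e-4 is exactly the 3-decimal rounding of the stored
entries. The variance-explained h² is the definition GAMETES uses, and
it reproduces the printed design values, which is the evidence that this
is the right identity for these tables.

## Simulator

Disease status is generated forward from the model: functional genotypes
~ HWE at the model MAF, status ~ Bernoulli(f(g_A, g_B)), rejection
sampling until exactly n_d cases and n_u controls are kept (in draw
order). Noise SNPs are independent of status, each with its own MAF
drawn once per dataset from U(0.05, 0.5) and genotypes under HWE. The
causal pair is placed at seeded-random columns by default so positional
bias cannot leak into the search; ground truth travels in a JSON sidecar
and an in-memory attribute, never in the genotype file itself.

Default sample size is n_d = n_u = 1000 — the conventional benchmark
size in this literature, and the scale at which the easy MAF 0.5
settings sit in their near-1 power regime. Replicate seeds derive from
the master seed through numpy's SeedSequence, kept below 2³¹.

What the simulator does *not* emulate: linkage disequilibrium between
SNPs, population stratification, genotyping error or missingness, and
main-effect-free pure epistasis beyond what the built-in tables encode.
Power measured here is therefore an idealised upper bound relative to
real cohorts, where LD both helps (proxy hits) and hurts (diluted
contrast), and confounding can inflate the null.

## Study sizes

The shipped validation study is a desk-scale replica chosen so the whole
suite runs in minutes on one core: oracle-agreement uses 20 replicates
at L = 25 (where the brute-force argmax is cheap to compute and the
search must match it in ≥ 19), and the power study uses the easy
threshold/interaction settings at MAF 0.5 with L = 200, n = 2000,
M = 500, 50 generations and #G = 20 replicates, asserting power ≥ 0.9.
The full-scale design (#G = 100, L = 2000, 500 generations) is the same
code via the CLI flags and is left as a documented long-running preset.

## Known limitations

- Pairs only; no higher-order (k > 2) interaction search.
- No main-effect adjustment: a pair containing one strong marginal SNP
  scores high χ² without genuine epistasis, and at small MAF the causal
  pair's contrast competes with the extreme order statistics of ~L²/2
  null pairs, which is where detection power genuinely drops.
- The index-space mutation treats adjacent SNP columns as neighbours;
  on simulated data column order is arbitrary, so local moves are a
  diversification device rather than an exploitation of genomic
  structure.
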