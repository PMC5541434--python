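# Methods

## Model

Let Y be the m x n matrix of drug responses (m drugs, n cell lines;
natural-log IC50 in uM, where lower means more sensitive, or activity
area, where higher means more sensitive), observed only at the entries
marked by the binary mask W. SRMF maps drugs and cell lines into a shared
K-dimensional latent space (K << min(m, n)) and estimates the factor pair
U (m x K), V (n x K) by minimizing

    f(U, V) = || W ∘ (Y − U Vᵀ) ||²_F
            + λ_l (||U||²_F + ||V||²_F)
            + λ_d || S_d − U Uᵀ ||²_F
            + λ_c || S_c − V Vᵀ ||²_F .

The first term is a weighted low-rank approximation that ignores missing
entries; the λ_l term is ordinary Tikhonov shrinkage; the last two terms
pull latent inner products toward precomputed similarities — S_d, the
Jaccard coefficient between binary chemical-fingerprint bit sets of drug
pairs, and S_c, the Pearson correlation between gene-expression profiles
of cell-line pairs. Before fitting, Y is divided by its maximum absolute
observed value so responses lie in [−1, 1], commensurate with the
similarity entries; predictions U Vᵀ are mapped back by the stored
divisor. The model assumes the response matrix is approximately low rank
and that structurally similar drugs (and transcriptionally similar cell
lines) have similar latent coordinates; it does not model mutation data,
dose-response curve shape, or batch structure.

## Solver

f is non-convex jointly in (U, V) but, with the quartic similarity terms
linearized, each factor has a closed-form row-wise update. One sweep:

1. For each drug row u_i, solve the K x K regularized normal equations
   assembled from (a) the observed entries of row i against V, (b) the
   λ_l ridge, and (c) the similarity term with the second occurrence of U
   frozen at the previous sweep:
   (Vᵀ diag(w_i) V + λ_l I + 2 λ_d ŪᵀŪ) u_iᵀ = Vᵀ(w_i ∘ y_i) + 2 λ_d Ūᵀ s_d,i.
2. Symmetrically for each cell-line row v_j.

Because the linearization does not by itself guarantee descent of the
exact quartic objective, each proposed sweep passes through a
backtracking line search (step halved up to 30 times, falling back to
the previous iterate), so the recorded objective sequence is
non-increasing unconditionally. The sweep touching the shorter matrix
side runs first; together with the initialization sign convention below
this makes the solver exactly equivariant under transposing the problem
(swap drugs with cell lines, S_d with S_c, λ_d with λ_c).

Initialization is deterministic: the top-K singular triplets of the
mean-imputed scaled Y, with U = U_K √Σ_K and V = V_K √Σ_K, and the sign
of each component fixed by making the largest-magnitude entry of the
concatenated singular-vector pair positive. A seeded random-normal
initialization (sd 1/√K) is available as `init="random"`. Iteration
stops when the relative objective change falls below `tol` (default
1e-4) or after `max_iter` sweeps (default 500).

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| K | latent dimensionality | 45 | the GDSC-scale setting; 12 suits a CCLE-scale panel; must satisfy K ≤ min(m, n) |
| λ_l | L2 shrinkage | 0.125 | smallest value of the search grid {2⁻³ … 2²} |
| λ_d | drug-similarity weight | 0 | on GDSC-style IC50 panels the optimum is 0 (structure adds nothing); grid {2⁻⁵ … 2¹, 0} |
| λ_c | cell-similarity weight | 0.125 | grid {2⁻⁵ … 2¹, 0} |
| tol | relative objective-change stop | 1e-4 | unitless |
| max_iter | sweep cap | 500 | |

The full printed search grid is 6 x 8 x 8 = 384 points
(`evaluation.default_lambda_grid`). `grid_search` scores each point by
internal cross-validation on the training data it is given (nested
selection — no test leakage); running it on the full matrix instead
reproduces the optimistic non-nested reading, which the caller can do
explicitly but is not the default.

## Evaluation protocol

Metrics are always per drug, then averaged over drugs: Pearson
correlation (PCC) and RMSE = √(Σ_C (R(D,C) − R̂(D,C))² / n) over the n
cells with known response for drug D. PCC_S/R and RMSE_S/R restrict the
same computation to the drug's sensitive and resistant cell lines: the
first and fourth quartiles of its observed responses, with Q1/Q3 from
the linear-interpolation quantile convention and boundary values
included in the extreme groups; which quartile is "sensitive" follows
the response direction. Drugs need at least 8 observed cells for the
split and 3 non-constant values for a PCC; drugs with undefined metrics
are excluded from the average and counted, never imputed as zero.
S/R membership is determined from the observed values of the full
matrix, not per training fold (the per-fold alternative would make
membership depend on the fold split).

Cross-validation is entry-wise: the observed matrix cells are shuffled
(seeded) and dealt into k folds whose sizes differ by at most one. Each
fold is masked from training — the response rescaling constant is then
recomputed from the training entries only — the model refitted, and the
pooled held-out predictions scored in one pass.

## Synthetic data

`simulation.simulate_instance` draws U* (m x k_true) and V* (n x k_true)
with independent standard-normal entries, sets the clean target
Y* = U* V*ᵀ, adds independent Gaussian noise with standard deviation
`noise_level · sd(Y*)`, computes S_d and S_c as Pearson correlations of
the clean target's drug rows and cell columns, and masks
`missing_fraction` of entries uniformly at random. Defaults are m = 100,
n = 150, k_true = 10, missing_fraction = 0.1, 200 repeats, with noise
swept over [0, 0.5]; the package's own benchmark runs use 20 repeats
(tests) and 10 (acceptance script) at the same dimensions to keep a
single-CPU run in minutes, with correspondingly wider stochastic
tolerances. Sweep scoring is against the noise-free target Y*, i.e. the
task is estimation of the true response surface, not of the noisy
observations; per-repeat seeds derive from (base seed, noise level,
repeat index) so sweep results are independent of iteration order.

What the generator emulates: low-rank signal, missingness, response-
derived similarity structure, homoscedastic noise. What it does not:
heavy-tailed IC50 distributions, drug-specific dynamic ranges, tissue
block structure in expression, informative (non-random) missingness,
and similarity matrices computed from independent data rather than from
the target. Passing tests therefore demonstrate correctness of the
machinery and recoverability under the stated generative model, not
expected accuracy on laboratory panels.

## Rank tests

Within/between-group similarity contrasts and genotype-sensitivity
associations use the one-sided Mann-Whitney U test. For combined sample
size ≤ 16 the null distribution is enumerated over all C(n, n1) group
assignments of the pooled midranks (exact, tie-safe); for tie-free
samples up to n = 50 the exact distribution comes from the standard
counting recursion; beyond that a tie-corrected normal approximation is
used. Full enumeration with ties is combinatorially infeasible much
beyond n ≈ 16, which is why the tie-safe exact branch stops there.
Genotype tests orient responses so that "mutated lines are more
sensitive" always means a right-shifted sensitivity score, regardless of
whether the measurement is IC50 or activity area; sidedness is a
required argument, never guessed. No multiple-testing correction is
applied by default (single-gene comparisons); a Benjamini-Hochberg
option exists for panel scans.

## Numerical choices and degenerate inputs

- Backtracking slack: a sweep is accepted only if it does not increase
  the exact objective; the monotonicity test allows 1e-8 relative noise.
- Similarity matrices are validated symmetric to 1e-12 with unit
  diagonal and used as given — no positive-semidefinite correction of
  negative Pearson entries, since the objective does not require one.
- All-zero fingerprints (Jaccard undefined), zero-variance expression
  profiles (Pearson undefined), all-zero observed responses (scaling
  undefined) and empty input files are hard errors naming the offender,
  not silent repairs.
- Grid-search ties break to the first point in grid order; fold
  assignment, initialization and per-repeat seeds are all deterministic
  functions of the configured seed.

## Limitations

- The alternating updates are a linearization of the quartic similarity
  terms; the guarantee is monotone descent to a local minimum, not the
  specific stationary point another update scheme might reach.
- K, λ defaults are panel-scale heuristics; small or very sparse
  matrices need smaller K and a fresh grid search.
- The synthetic benchmark shares its similarity matrices with the data-
  generating process, which is the easiest case for the regularizers;
  real similarity matrices are noisier and help less.
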