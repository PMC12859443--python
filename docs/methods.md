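# Methods

## Data model

A cognate dataset is the triple (L, C, M) of languages, concepts, and the
assignment `M : L × C → finite sets of cognate-class labels`.  ν = |M(l, c)|
counts the classes a language attests for a concept; ν = 0 is missing data
throughout (no mechanistic distinction is made between unelicited and lost
words).  Class labels are scoped per concept: identical labels under
different concepts are unrelated classes.  Per concept, the inventory
V_c is the union of assigned classes over all languages, ordered
lexicographically; κ = |V_c|.

Two character encodings are derived from M:

* **Binary** `A^b`: one column per (concept, class); entry 1/0 for
  presence/absence, and all κ columns of a concept are `-` when ν = 0.
* **Bit-vector** `A^v`: one column per concept of a fixed κ.  A non-empty
  state maps to the index ∫(b) − 1, where the bit for the *first* class in
  lexicographic order is the *most significant* of the length-κ string b.
  The convention is arbitrary but deterministic and documented; it makes
  encodings stable under row reordering.  The default 64-symbol alphabet is
  digits, upper case, lower case, then `!` and `*`; it is configurable, and
  caps κ at 6 (2^κ − 1 ≤ 64).  κ = 1 concepts are constant columns with no
  topological signal and are excluded from κ-subsets.

## Substitution models

All models are reversible CTMCs specified as `q(i, j) = x(i, j) · π_j` with a
symmetric exchangeability matrix x, which guarantees detailed balance
π_i q(i, j) = π_j q(j, i) identically (a symmetric *rate* matrix combined
with unequal frequencies would not be reversible; the exchangeability
parameterization preserves the intended symmetry classes).  Generators are
rescaled to unit expected rate at stationarity, Σ_i π_i (−q_ii) = 1, so
branch lengths are expected substitutions per column; the overall rate scale
is therefore not a free parameter and is pinned during optimization.

For COG and COGs the frequency of a state with popcount ν is π_ν, normalized
over the binomial multiplicities: Σ_ν C(κ, ν) π_ν = 1.  COGs has two rate
classes (λ⁺ for single-bit differences, λ₀ for the rest); COG refines λ⁺
into λ_1 … λ_{κ−1} indexed by the smaller state's size and pins λ₀ to exactly
zero — the structural zeros are exact in the generator, not epsilons.

AIC uses the published counting convention verbatim (BIN 1, MK 0, GTR
2^κ(2^κ−1)/2 + 2^κ, COGs κ + 1, COG 2κ) even where constraint subtraction is
debatable; `free_parameter_count(..., identifiable=True)` exposes a count
that subtracts the simplex and rate-scale constraints but is never the
default.  AIC comparisons are restricted to fits on the same representation:
BIN (binary matrices) is never tabulated against bit-vector models.

## Likelihood and optimization

Felsenstein pruning with per-node rescaling and pattern compression; missing
tip entries contribute all-ones conditionals, so an all-missing column adds
exactly zero log-likelihood.  Transition matrices come from the symmetrized
eigendecomposition of the generator (exact for reversible chains; tiny
negative round-off entries are clipped and rows renormalized).

Branch lengths are optimized coordinate-wise with bounded Brent **in log
length** over [1e−6, 100]: the likelihood optimum typically sits orders of
magnitude below the upper bound, and on the raw scale a bounded
golden-section probe lands on the saturation plateau and misses the dip.
Each sweep optimizes all branches against one shared snapshot of directional
partials (one single-branch evaluation then costs a single matrix product);
a sweep that fails to improve the exact likelihood is repeated with partials
refreshed after every branch.  Convergence: 1e−6 log units per sweep.

Model parameters are optimized by L-BFGS-B on unconstrained transforms
(log-ratio frequencies with the first class pinned, log rates with the first
rate pinned) with bounds ±12, convergence at ~1e−6 log units; the fitted
model is never returned with a likelihood below its starting point.  MK has
nothing to optimize and is returned unchanged.

Tree search mirrors a 10-random + 10-parsimony multi-start design: uniform
random topologies (sequential random edge insertion, which is exactly
uniform over unrooted binary topologies) and randomized stepwise-addition
Fitch parsimony trees (missing data as full state sets), each refined by
alternating branch-length/model optimization with steepest-ascent NNI.  NNI
candidates are scored after re-optimizing only their central edge (lazy
evaluation); accepted moves trigger a full branch-length pass.  Ties between
equally likely starts are broken by start index; one master seed spawns
independent per-start and per-fold substreams, so every result is
reproducible bit for bit.  Only NNI moves are implemented — sufficient for
the dataset sizes this package targets and easy to audit — not SPR.

## Cross-validation

`crossval` samples ⌊0.6 · ncols⌋ columns without replacement as training
data (the remainder is the test set), fits tree + parameters by full search
on the training matrix, and evaluates the test matrix on the fitted tree and
parameters with **no** re-optimization.  Log-likelihoods are normalized by
their matrix's column count and the relative error is
e = (llh_test_rel − llh_train_rel) / llh_train_rel; folds (default 10)
use disjoint sub-seeds and the mean over folds is reported.  Matrices with
fewer than 10 columns are rejected as too small to split meaningfully.
Large positive e indicates overparameterization; e near 0 indicates a
stable fit.  The same operation applies unchanged to a full binary matrix
under BIN.

## Entropy and diagnostics

Column entropy is Shannon entropy (base 2 by default) of the empirical
distribution over non-missing symbols; missing entries are excluded from the
distribution and an all-missing column contributes 0.  The dataset
diagnostics report the ν-distribution over all language-concept pairs,
κ-subset sizes, per-κ concepts-over-languages ratios, and per-κ symbol
occurrence counts.

## Synthetic data

The simulator draws a uniform random unrooted topology with i.i.d.
exponential branch lengths (default mean 0.25 expected substitutions per
column — moderate divergence; deeper histories are modelled by raising it),
evolves each column from a stationary root draw through P(t) along every
branch, and masks each tip entry to missing independently with probability
0.1 by default.  Default κ-subset sizes shrink with κ ({2: 40, 3: 25, 4: 12,
5: 8, 6: 5}) and the default COG/COGs parameters set π_ν ∝ 4^−(ν−1), so the
simulated ν-distribution is heavily skewed towards single-class states —
the shape observed in real cognate collections.

What the simulator does **not** emulate: borrowing/contact (columns are
independent), rate heterogeneity across concepts, any mechanistic
missing-data process (masking is exogenous), or dialect chains.  Passing
tests on synthetic data therefore demonstrate correctness of the machinery
and recoverability under the model's own assumptions, not robustness to
their violation on real wordlists.

A subtlety worth knowing: a simulated "κ = 3" concept only remains in the
κ = 3 subset if all three classes are attested among the sampled languages.
On shallow trees the languages are strongly correlated and classes are
easily lost, so the realized κ-subset is smaller than the configured concept
count — the same ascertainment effect that shapes real datasets.

## Verification sizes

The test suite verifies pruning against brute-force ancestral-state
enumeration (200 random instances, ≤ 5 taxa, ≤ 7 states, 1e−10), a two-taxon
closed form for the 3-state equal-rates chain, detailed balance and unit
mean rate on 1000 random models (1e−12), optimized-likelihood nesting
L*(GTR) ≥ L*(COGs) ≥ L*(MK) on 20 simulated matrices (8 taxa, 100 columns,
κ = 3, tolerance 1e−4, with warm starts along the nesting chain), recovery
of λ1/λ2 = 2 within 10% from a 16-taxon, 5000-column COG simulation, and the
monotone decrease of the mean MK cross-validation error over {20, 100, 500}
columns (6 taxa, 10 seeds, 10 folds, one random + one parsimony start per
fold).  These sizes were chosen as the smallest at which the corresponding
statistical signals are unambiguous.

## Known limitations

* No ascertainment-bias correction for the binary encoding, no Gamma rate
  heterogeneity, no non-reversible models, no Bayesian sampling, no SPR or
  ratchet searches, no bootstrap support values.
* The GTR parameter count used for AIC follows the published 2^κ-state
  convention rather than the 2^κ − 1 realizable symbols.
* The average-coverage definition (mean over languages of the fraction of
  concepts with at least one word) is a stated assumption; published sources
  cite it without reproducing a formula.
* The 64-symbol alphabet is a compatible stand-in for the one used by
  external inference tools, whose exact symbol order is not published;
  PHYLIP files written with a different alphabet must be read with the same
  one.
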