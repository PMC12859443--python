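# cogvec

Phylogenetic inference on cognate-coded wordlists with a bit-vector character
encoding and substitution models tailored to it.

## The problem

Historical linguists code a wordlist as a map `M : (language, concept) → set
of cognate classes`: for language *l* and meaning slot *c* ("hand", "water",
…), `M(l, c)` is the set of etymological classes the attested words belong
to.  Its size ν is usually 1, occasionally larger (synonyms), and ν = 0 means
no word is recorded (missing data).  The classic way to feed such data to a
phylogenetic tree program is a **binary expansion** `A^b`: one 0/1 column per
(concept, class) pair.  That representation breaks the independence
assumption of the likelihood — the κ columns of one concept evolve jointly.

`cogvec` implements the alternative **bit-vector encoding** `A^v`: one
multistate column per concept.  The presence/absence pattern over the κ
classes of a concept is a non-zero bit string *b* of length κ, mapped to the
symbol `Σm[∫(b) − 1]`, where ∫(b) is the integer with binary representation
*b* and Σm is an ordered 64-symbol alphabet.  The all-zero vector encodes
missing data and gets no symbol, so a concept needs 2^κ − 1 symbols and κ ≤ 6.
Columns with the same κ share a state space, so datasets are partitioned into
**κ-subsets** before inference.

## Models

For the 2^κ − 1 bit-vector states the package builds time-reversible
continuous-time Markov models `q(i, j) = x(i, j) · π_j` with symmetric
exchangeabilities *x*, normalized to one expected substitution per unit
branch length:

| model | exchangeabilities | frequencies | free parameters k |
|-------|-------------------|-------------|---------------------|
| BIN   | shared (binary data) | one free frequency | 1 |
| MK    | all equal | uniform | 0 |
| GTR   | all free  | all free | 2^κ(2^κ−1)/2 + 2^κ |
| COGs  | λ⁺ for one-bit differences, λ₀ otherwise | π_ν by state size | κ + 1 |
| COG   | λ_ν by smaller-state size for one-bit differences, **0** otherwise | π_ν | 2κ |

COG and COGs encode linguistic assumptions: a state's stationary probability
depends only on how many classes it contains (π_ν, decreasing in ν), and at
most one word appears or disappears per instant (COG forbids multi-bit jumps
outright).

Likelihoods are computed by Felsenstein pruning with pattern compression and
rescaling; trees are fitted by maximum likelihood (per-branch Brent in log
length, L-BFGS-B on transformed model parameters, NNI hill climbing from
random and randomized stepwise-addition parsimony starts — 10 + 10 by
default).  Models on the same κ-subset are compared by AIC = 2k − 2·llh, and
overparameterization is quantified by cross-validation: fit on a random 60%
of columns, score the held-out 40% with the fitted tree and parameters, and
report the relative error e = (llh_test_rel − llh_train_rel) / llh_train_rel
of the per-column-normalized log-likelihoods, averaged over 10 random splits.
A forward simulator generates trees, matrices, and full wordlists with the
empirical shape of published cognate data (ν skewed to 1, shrinking
κ-subsets, exogenous missingness), so every stage is testable end to end.

## Worked example

```python
from cogvec import (build_inventory, encode_bitvector, compare_models,
                    crossval, matrix_entropy, simulate_cognate_dataset)
from cogvec.simulate import SimulationConfig

config = SimulationConfig(seed=7, n_taxa=8, branch_mean=1.0,
                          concepts_per_kappa={3: 60}, model_kind="COG",
                          missing_prob=0.1)
dataset, true_tree = simulate_cognate_dataset(config)
inv = build_inventory(dataset)
mat = encode_bitvector(dataset, inv, 3)          # the kappa=3 subset
cmp = compare_models(mat, ["MK", "COGs", "COG"], seed=1,
                     n_random=2, n_parsimony=2)
print(cmp.table)
cv = crossval(mat, "COG", seed=1, folds=5, n_random=1, n_parsimony=1)
print("mean relative error e:", round(cv.mean_error, 4))
print("total entropy (bits):", round(matrix_entropy(mat).total, 2))
```

Output:

```
model      loglik  k        aic
   MK -499.437048  0 998.874095
 COGs -442.237924  4 892.475848
  COG -441.294447  6 894.588894
mean relative error e: 0.0445
total entropy (bits): 67.03
```

Of the 60 simulated concepts, 41 retain all three classes across the 8
languages and form the κ=3 subset.  Both structured models fit far better
than MK (Δllh ≈ 57); COGs edges out COG on AIC here because its smaller k
offsets the slightly lower likelihood.  The cross-validation error of ~0.04
says the held-out columns score about 4% worse per column than the training
columns — mild overfitting at 41 columns.

The same pipeline is scriptable from the shell:

```bash
cogvec simulate --taxa 8 --kappa 3 --concepts 60 --model COG \
    --branch-mean 1.0 --seed 7 --out sim.tsv --tree-out sim.nwk
cogvec subsets --in sim.tsv --kappa 3 --out k3.phy
cogvec fit --in k3.phy --model COG --kappa 3 --seed 42 --out fit.json
cogvec crossval --in k3.phy --model COG --kappa 3 --seed 1 --out cv.tsv
```

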