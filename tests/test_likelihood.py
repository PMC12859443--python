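import itertools

import numpy as np
import pytest

from cogvec import (
    BitVectorMatrix,
    LikelihoodWorkspace,
    PhyloTree,
    TaxaMismatchError,
    build_model,
    log_likelihood,
    optimize_branch_lengths,
    optimize_model,
    random_tree,
    simulate_matrix,
)


def brute_force_loglik(tree, matrix, model):
    """Sum over all ancestral state assignments; exponential-time oracle."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    taxrow = {t: i for i, t in enumerate(matrix.taxa)}
    pmats = {id(n): model.transition_matrix(n.length) for n in nodes if n.parent}
    total = 0.0
    for col in range(matrix.n_columns):
        like = 0.0
        for assign in itertools.product(range(model.n_states), repeat=len(internals)):
            amap = dict(zip((id(n) for n in internals), assign))
            prob = model.freqs[amap[id(tree.root)]]
            for n in nodes:
                if n.parent is None:
                    continue
                ps = amap[id(n.parent)]
                if n.is_leaf:
                    obs = matrix.data[taxrow[n.name], col]
                    prob *= 1.0 if obs == -1 else pmats[id(n)][ps, obs]
                else:
                    prob *= pmats[id(n)][ps, amap[id(n)]]
            like += prob
        total += np.log(like)
    return total


@pytest.mark.parametrize("seed", range(6))
def test_pruning_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n_taxa = int(rng.integers(3, 6))
    kappa = int(rng.integers(2, 4))  # up to 7 states
    tree = random_tree(n_taxa, 0.4, seed=seed)
    model = build_model(
        "COG",
        kappa,
        {"pi": rng.uniform(0.1, 1.0, kappa), "lambda": rng.uniform(0.2, 2.0, kappa - 1)},
    )
    matrix = simulate_matrix(tree, model, 5, 0.2, seed=seed + 100)
    assert log_likelihood(tree, matrix, model) == pytest.approx(
        brute_force_loglik(tree, matrix, model), abs=1e-10
    )


def test_two_taxon_identical_state_zero_branches():
    model = build_model("MK", 2)
    tree = PhyloTree.from_newick("(A:0,B:0);")
    mat = BitVectorMatrix(["A", "B"], ["c1"], 2, np.array([[1], [1]]))
    assert np.exp(log_likelihood(tree, mat, model)) == pytest.approx(model.freqs[1])


def test_two_taxon_mk_closed_form():
    model = build_model("MK", 2)
    tree = PhyloTree.from_newick("(A:0.4,B:0.6);")
    mat = BitVectorMatrix(["A", "B"], ["c1"], 2, np.array([[0], [0]]))
    expected = (1 / 3) * (1 / 3 + (2 / 3) * np.exp(-1.5))
    assert np.exp(log_likelihood(tree, mat, model)) == pytest.approx(expected, abs=1e-10)


def test_all_missing_column_contributes_zero():
    model = build_model("MK", 3)
    tree = random_tree(5, 0.3, seed=3)
    mat = simulate_matrix(tree, model, 10, 0.0, seed=4)
    with_missing = BitVectorMatrix(
        mat.taxa,
        mat.concepts + ["empty"],
        3,
        np.hstack([mat.data, np.full((5, 1), -1, dtype=np.int16)]),
    )
    assert log_likelihood(tree, with_missing, model) == pytest.approx(
        log_likelihood(tree, mat, model), abs=1e-12
    )


def test_likelihood_invariant_under_rerooting_and_column_order():
    model = build_model("COG", 2, {"pi": [0.4, 0.1], "lambda": [1.5]})
    a = PhyloTree.from_newick("(A:0.1,(B:0.2,C:0.3):0.05,D:0.4);")
    b = PhyloTree.from_newick("(B:0.2,(D:0.4,A:0.1):0.05,C:0.3);")
    assert a.topology_key() == b.topology_key()
    mat = simulate_matrix(a, model, 30, 0.1, seed=10)
    assert log_likelihood(a, mat, model) == pytest.approx(
        log_likelihood(b, mat, model), abs=1e-9
    )
    perm = np.random.default_rng(0).permutation(mat.n_columns)
    shuffled = mat.subset_columns(list(perm))
    assert log_likelihood(a, shuffled, model) == pytest.approx(
        log_likelihood(a, mat, model), abs=1e-9
    )


def test_pattern_compression_matches_duplication():
    """Duplicating every column doubles the log-likelihood exactly."""
    model = build_model("MK", 3)
    tree = random_tree(5, 0.3, seed=21)
    mat = simulate_matrix(tree, model, 20, 0.1, seed=22)
    doubled = mat.subset_columns(list(range(mat.n_columns)) * 2)
    assert log_likelihood(tree, doubled, model) == pytest.approx(
        2 * log_likelihood(tree, mat, model), abs=1e-10
    )


def test_taxa_mismatch_raises():
    model = build_model("MK", 2)
    tree = PhyloTree.from_newick("(X:0.1,Y:0.1,Z:0.1);")
    mat = BitVectorMatrix(["A", "B", "C"], ["c1"], 2, np.array([[0], [1], [2]]))
    with pytest.raises(TaxaMismatchError):
        log_likelihood(tree, mat, model)


def test_optimize_model_mk_is_identity(mk3_matrix):
    tree = random_tree(6, 0.3, seed=11)
    model = build_model("MK", 3)
    fitted, llh = optimize_model(tree, mk3_matrix, model)
    assert fitted is model
    assert llh == pytest.approx(log_likelihood(tree, mk3_matrix, model))


def test_optimize_model_recovers_rate_ratio():
    true = build_model("COG", 3, {"pi": [0.7, 0.2, 0.1], "lambda": [2.0, 1.0]})
    tree = random_tree(10, 0.3, seed=31)
    mat = simulate_matrix(tree, true, 3000, 0.0, seed=32)
    fitted, llh = optimize_model(tree, mat, build_model("COG", 3))
    lam = fitted.params["lambda"]
    assert lam[0] / lam[1] == pytest.approx(2.0, rel=0.15)
    assert llh >= log_likelihood(tree, mat, build_model("COG", 3))


def test_optimize_model_single_column_converges():
    model = build_model("COGs", 2)
    tree = random_tree(4, 0.3, seed=41)
    mat = simulate_matrix(tree, model, 1, 0.0, seed=42)
    fitted, llh = optimize_model(tree, mat, model)
    assert np.isfinite(llh)


def test_branch_length_lower_bound_for_identical_taxa():
    model = build_model("MK", 2)
    tree = PhyloTree.from_newick("(A:0.3,B:0.3);")
    mat = BitVectorMatrix(
        ["A", "B"], [f"c{i}" for i in range(30)], 2,
        np.tile(np.array([[1], [1]]), (1, 30)),
    )
    opt = optimize_branch_lengths(tree, mat, model)
    assert sum(e.length for e in opt.edges()) <= 3e-6


def test_branch_length_matches_analytic_inversion():
    """MK 3-state: observed mismatch fraction p gives t = -ln(1-1.5p)/1.5."""
    model = build_model("MK", 2)
    n, diff = 400, 80
    data = np.zeros((2, n), dtype=np.int16)
    data[1, :diff] = 1
    mat = BitVectorMatrix(["A", "B"], [f"c{i}" for i in range(n)], 2, data)
    opt = optimize_branch_lengths(PhyloTree.from_newick("(A:0.1,B:0.1);"), mat, model)
    total = sum(e.length for e in opt.edges())
    p = diff / n
    assert total == pytest.approx(-np.log(1 - 1.5 * p) / 1.5, rel=1e-3)


def test_branch_length_optimization_is_monotone(mk3_matrix):
    model = build_model("MK", 3)
    tree = random_tree(6, 0.3, seed=77)
    ws = LikelihoodWorkspace(mk3_matrix, model)
    before = ws.log_likelihood(tree, model)
    opt, after = ws.optimize_branch_lengths(tree, model)
    assert after >= before
    # at the fixed point another pass changes nothing measurable
    _, again = ws.optimize_branch_lengths(opt, model)
    assert again - after < 1e-4


def test_optimized_likelihood_nesting_small():
    gen = build_model("COGs", 3, {"pi": [0.5, 0.2, 0.1], "lambda_plus": 1.0, "lambda_0": 0.3})
    tree = random_tree(6, 0.25, seed=51)
    mat = simulate_matrix(tree, gen, 80, 0.05, seed=52)
    mk = build_model("MK", 3)
    ws = LikelihoodWorkspace(mat, mk)
    tree_opt, llh_mk = ws.optimize_branch_lengths(tree, mk)
    _, llh_cogs = optimize_model(tree_opt, mat, build_model("COGs", 3))
    assert llh_cogs >= llh_mk - 1e-4
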