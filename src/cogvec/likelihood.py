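"""Phylogenetic likelihood, parameter optimization, and tree search.

The likelihood of a character matrix on a tree is computed with Felsenstein's
pruning algorithm: conditional likelihood vectors are propagated from the tips
to an arbitrary storage root through transition matrices P(t) = exp(Gt).
Missing entries contribute all-ones conditionals, identical columns are
pattern-compressed, and per-node rescaling guards against underflow.  Because
every model is time reversible the result is independent of the storage root.

Model parameters are optimized by bounded quasi-Newton iteration on
unconstrained transforms (log-ratio frequencies, log rates, with the global
rate scale pinned since it is absorbed by the branch lengths).  Branch
lengths are optimized one at a time by Brent search, using cached directional
partials so a single-branch evaluation costs one matrix product.  Tree search
alternates branch-length optimization, model optimization, and
nearest-neighbour-interchange hill climbing from random and randomized
stepwise-addition parsimony starting trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit, logit

from .encoding import MISSING_CODE, BinaryMatrix, BitVectorMatrix
from .errors import CogvecError, TaxaMismatchError
from .models import SubstitutionModel, build_model
from .tree import (
    MAX_BRANCH_LENGTH,
    MIN_BRANCH_LENGTH,
    Node,
    PhyloTree,
    nni_neighbors,
)

#: convergence threshold (log-likelihood units) for parameter optimization
PARAM_TOL = 1e-6
#: convergence threshold for a full branch-length sweep
BRANCH_TOL = 1e-6
#: convergence threshold for the outer search alternation
SEARCH_TOL = 1e-5

Matrix = BinaryMatrix | BitVectorMatrix


def _check_compatible(matrix: Matrix, model: SubstitutionModel) -> None:
    if isinstance(matrix, BinaryMatrix):
        if model.kind != "BIN":
            raise CogvecError(f"{model.kind} cannot run on a binary matrix")
    else:
        if model.kind == "BIN":
            raise CogvecError("BIN runs on binary matrices only")
        if model.kappa != matrix.kappa:
            raise CogvecError(
                f"model kappa={model.kappa} does not match matrix kappa={matrix.kappa}"
            )
    if matrix.n_states != model.n_states:
        raise CogvecError("matrix state space does not match the model")


class LikelihoodWorkspace:
    """Pattern-compressed data plus cached tip conditionals for one matrix."""

    def __init__(self, matrix: Matrix, model: SubstitutionModel):
        _check_compatible(matrix, model)
        self.n_states = model.n_states
        states = np.asarray(matrix.data, dtype=np.int64)
        patterns, weights = np.unique(states, axis=1, return_counts=True)
        self.patterns = patterns
        self.weights = weights.astype(float)
        self.n_patterns = patterns.shape[1]
        self.taxon_row = {taxon: i for i, taxon in enumerate(matrix.taxa)}
        self._pcache: dict[tuple[int, float], np.ndarray] = {}
        self._tip: dict[str, np.ndarray] = {}
        for taxon, row in zip(matrix.taxa, patterns):
            arr = np.zeros((self.n_states, self.n_patterns))
            missing = row == MISSING_CODE
            arr[:, missing] = 1.0
            cols = np.nonzero(~missing)[0]
            arr[row[cols], cols] = 1.0
            self._tip[taxon] = arr

    def _P(self, model: SubstitutionModel, t: float) -> np.ndarray:
        # the tree passes re-evaluate the same branch lengths many times per
        # sweep; memoize P(t) (Brent line searches bypass this cache)
        key = (model.serial, t)
        p = self._pcache.get(key)
        if p is None:
            if len(self._pcache) > 4096:
                self._pcache.clear()
            p = model.transition_matrix(t)
            self._pcache[key] = p
        return p

    def check_tree(self, tree: PhyloTree) -> None:
        if set(tree.taxa) != set(self.taxon_row):
            raise TaxaMismatchError(
                f"tree taxa {sorted(tree.taxa)} != matrix taxa {sorted(self.taxon_row)}"
            )

    # -- pruning -----------------------------------------------------------

    def _down_pass(
        self, tree: PhyloTree, model: SubstitutionModel
    ) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray]]:
        """Conditional likelihoods of each subtree given the state at its root."""
        down: dict[int, np.ndarray] = {}
        scale: dict[int, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_leaf:
                down[id(node)] = self._tip[node.name]
                scale[id(node)] = np.zeros(self.n_patterns)
                continue
            arr = np.ones((self.n_states, self.n_patterns))
            logs = np.zeros(self.n_patterns)
            for child in node.children:
                p = self._P(model, child.length)
                arr *= p @ down[id(child)]
                logs += scale[id(child)]
            m = arr.max(axis=0)
            nz = m > 0
            arr[:, nz] /= m[nz]
            with np.errstate(divide="ignore"):
                logs += np.where(nz, np.log(np.maximum(m, 1e-300)), -np.inf)
            down[id(node)] = arr
            scale[id(node)] = logs
        return down, scale

    def log_likelihood(self, tree: PhyloTree, model: SubstitutionModel) -> float:
        self.check_tree(tree)
        down, scale = self._down_pass(tree, model)
        root = tree.root
        site = model.freqs @ down[id(root)]
        with np.errstate(divide="ignore"):
            loglik = np.log(site) + scale[id(root)]
        return float(self.weights @ loglik)

    # -- branch lengths ----------------------------------------------------

    def _edge_context(
        self,
        tree: PhyloTree,
        model: SubstitutionModel,
        down: dict[int, np.ndarray],
        dscale: dict[int, np.ndarray],
    ) -> dict[int, tuple[np.ndarray, np.ndarray]]:
        """For each edge (by child node id): the outside partial at the parent.

        ``R_v[i]`` is proportional to P(data outside the subtree of v, parent
        state = i); the edge likelihood is then L(t) = Σ_ij R_v[i] P(t)[i, j]
        D_v[j] per pattern, so a Brent evaluation costs one matrix product.
        """
        out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        above: dict[int, tuple[np.ndarray, np.ndarray]] = {
            id(tree.root): (
                np.tile(model.freqs[:, None], (1, self.n_patterns)),
                np.zeros(self.n_patterns),
            )
        }
        for node in tree.preorder():
            if node.is_leaf:
                continue
            o_node, o_scale = above[id(node)]
            messages = []
            for child in node.children:
                p = self._P(model, child.length)
                messages.append(p @ down[id(child)])
            for idx, child in enumerate(node.children):
                r = o_node.copy()
                r_scale = o_scale.copy()
                for jdx, sibling in enumerate(node.children):
                    if jdx != idx:
                        r *= messages[jdx]
                        r_scale = r_scale + dscale[id(sibling)]
                m = r.max(axis=0)
                nz = m > 0
                r[:, nz] /= m[nz]
                with np.errstate(divide="ignore"):
                    r_scale += np.where(nz, np.log(np.maximum(m, 1e-300)), -np.inf)
                out[id(child)] = (r, r_scale)
                if not child.is_leaf:
                    p = self._P(model, child.length)
                    above[id(child)] = (p.T @ r, r_scale)
        return out

    def _edge_objective(self, r, r_scale, d, d_scale, model):
        base = r_scale + d_scale

        def negloglik(t: float) -> float:
            p = model.transition_matrix(t)
            site = ((p.T @ r) * d).sum(axis=0)
            # site is strictly positive for any reachable pattern; the floor
            # only guards pathological all-zero conditionals
            return -float(self.weights @ (np.log(np.maximum(site, 1e-300)) + base))

        return negloglik

    @staticmethod
    def _brent_edge(f) -> tuple[float, float]:
        """Minimize f over the branch-length box, searching in log length.

        The likelihood dip typically sits orders of magnitude below the upper
        bound; on the raw scale a bounded golden-section probe lands on the
        saturation plateau and misses it.
        """
        res = minimize_scalar(
            lambda u: f(math.exp(u)),
            bounds=(math.log(MIN_BRANCH_LENGTH), math.log(MAX_BRANCH_LENGTH)),
            method="bounded",
            options={"xatol": 1e-3},
        )
        return float(math.exp(res.x)), float(res.fun)

    def optimize_single_edge(
        self, tree: PhyloTree, model: SubstitutionModel, edge: Node
    ) -> float:
        """Brent-optimize one branch length in place; returns the new llh."""
        down, dscale = self._down_pass(tree, model)
        context = self._edge_context(tree, model, down, dscale)
        r, r_scale = context[id(edge)]
        f = self._edge_objective(r, r_scale, down[id(edge)], dscale[id(edge)], model)
        best_t, best_f = self._brent_edge(f)
        if -best_f > -f(edge.length):
            edge.length = best_t
            return float(-best_f)
        return float(-f(edge.length))

    def optimize_branch_lengths(
        self, tree: PhyloTree, model: SubstitutionModel, tol: float = BRANCH_TOL,
        max_rounds: int = 30,
    ) -> tuple[PhyloTree, float]:
        """Iterated per-branch Brent optimization; returns (new tree, llh).

        Each round optimizes every branch against one shared snapshot of the
        directional partials (Jacobi-style); a round that fails to improve
        the exact likelihood falls back to one exact per-branch sweep that
        refreshes the partials after every update.
        """
        self.check_tree(tree)
        tree = tree.copy()
        tree.clamp_lengths()
        current = self.log_likelihood(tree, model)
        for _ in range(max_rounds):
            saved = [e.length for e in tree.edges()]
            down, dscale = self._down_pass(tree, model)
            context = self._edge_context(tree, model, down, dscale)
            for edge in tree.edges():
                r, r_scale = context[id(edge)]
                f = self._edge_objective(
                    r, r_scale, down[id(edge)], dscale[id(edge)], model
                )
                best_t, best_f = self._brent_edge(f)
                if best_f < f(edge.length):
                    edge.length = best_t
            new = self.log_likelihood(tree, model)
            if new < current:
                for e, s in zip(tree.edges(), saved):
                    e.length = s
                new = current
                for edge in tree.edges():
                    new = self.optimize_single_edge(tree, model, edge)
            if new - current < tol:
                current = max(new, current)
                break
            current = new
        return tree, current


def log_likelihood(tree: PhyloTree, matrix: Matrix, model: SubstitutionModel) -> float:
    """Pruning log-likelihood of ``matrix`` on ``tree`` under ``model``."""
    return LikelihoodWorkspace(matrix, model).log_likelihood(tree, model)


def optimize_branch_lengths(
    tree: PhyloTree, matrix: Matrix, model: SubstitutionModel, tol: float = BRANCH_TOL
) -> PhyloTree:
    """Optimize every branch length; topology is unchanged."""
    new_tree, _ = LikelihoodWorkspace(matrix, model).optimize_branch_lengths(
        tree, model, tol
    )
    return new_tree


# -- model parameter optimization -----------------------------------------


def _pack(model: SubstitutionModel) -> np.ndarray:
    """Map model parameters to an unconstrained vector (scale pinned)."""
    kind, kappa, p = model.kind, model.kappa, model.params
    if kind == "BIN":
        return np.array([logit(np.clip(p["pi_1"], 1e-9, 1 - 1e-9))])
    if kind == "MK":
        return np.zeros(0)
    if kind == "GTR":
        freqs = np.asarray(p["freqs"])
        rates = np.asarray(p["rates"])
        return np.concatenate(
            [np.log(freqs[1:] / freqs[0]), np.log(rates[1:] / rates[0])]
        )
    pi = np.asarray(p["pi"])
    if kind == "COGs":
        lam0 = max(p["lambda_0"], 1e-9)
        return np.concatenate(
            [np.log(pi[1:] / pi[0]), [math.log(lam0 / p["lambda_plus"])]]
        )
    lam = np.asarray(p["lambda"])  # COG: λ_1 pinned to 1
    return np.concatenate([np.log(pi[1:] / pi[0]), np.log(lam[1:] / lam[0])])


def _unpack(theta: np.ndarray, kind: str, kappa: int | None) -> dict[str, Any]:
    if kind == "BIN":
        return {"pi_1": float(expit(theta[0]))}
    if kind == "MK":
        return {}
    if kind == "GTR":
        s = 2**kappa - 1
        nf = s - 1
        freqs = np.exp(np.concatenate([[0.0], theta[:nf]]))
        rates = np.exp(np.concatenate([[0.0], theta[nf:]]))
        return {"freqs": freqs / freqs.sum(), "rates": rates}
    nf = kappa - 1
    pi = np.exp(np.concatenate([[0.0], theta[:nf]]))
    if kind == "COGs":
        return {"pi": pi, "lambda_plus": 1.0, "lambda_0": float(np.exp(theta[nf]))}
    lam = np.exp(np.concatenate([[0.0], theta[nf:]]))
    return {"pi": pi, "lambda": lam}


def optimize_model(
    tree: PhyloTree,
    matrix: Matrix,
    model: SubstitutionModel,
    tol: float = PARAM_TOL,
    workspace: LikelihoodWorkspace | None = None,
) -> tuple[SubstitutionModel, float]:
    """ML estimation of the model's free parameters on a fixed tree.

    The returned log-likelihood is never below the input model's.  MK has no
    free parameters and is returned unchanged.
    """
    ws = workspace or LikelihoodWorkspace(matrix, model)
    start_llh = ws.log_likelihood(tree, model)
    if not math.isfinite(start_llh):
        raise CogvecError("non-finite likelihood at the starting parameters")
    if model.kind == "MK":
        return model, start_llh

    kind, kappa = model.kind, model.kappa

    def negloglik(theta: np.ndarray) -> float:
        try:
            cand = build_model(kind, kappa, _unpack(theta, kind, kappa))
        except CogvecError:
            return 1e10
        val = ws.log_likelihood(tree, cand)
        return -val if math.isfinite(val) else 1e10

    x0 = np.clip(_pack(model), -12, 12)
    res = minimize(
        negloglik,
        x0,
        method="L-BFGS-B",
        bounds=[(-12.0, 12.0)] * len(x0),
        options={"maxiter": 300, "ftol": 1e-10, "gtol": 1e-7},
    )
    if -res.fun > start_llh:
        fitted = build_model(kind, kappa, _unpack(res.x, kind, kappa))
        return fitted, float(-res.fun)
    return model, start_llh


# -- starting trees --------------------------------------------------------


def random_topology(taxa: list[str], rng: np.random.Generator) -> PhyloTree:
    """Uniformly random unrooted binary topology via random edge insertion."""
    if len(taxa) < 3:
        raise CogvecError("need at least 3 taxa for an unrooted topology")
    order = list(taxa)
    rng.shuffle(order)
    root = Node()
    for name in order[:3]:
        root.add_child(Node(name, 0.1))
    tree = PhyloTree(root)
    for name in order[3:]:
        edges = tree.edges()
        target = edges[rng.integers(len(edges))]
        _insert_leaf(target, name)
    return tree


def _insert_leaf(edge_child: Node, name: str) -> None:
    """Split the edge above ``edge_child`` and attach a new leaf."""
    parent = edge_child.parent
    mid = Node(length=edge_child.length / 2)
    parent.children[parent.children.index(edge_child)] = mid
    mid.parent = parent
    edge_child.length /= 2
    mid.add_child(edge_child)
    mid.add_child(Node(name, 0.1))


def _fitch_sets(tree: PhyloTree, tip_masks: dict[str, np.ndarray]) -> int:
    """Fitch parsimony score over all patterns (weights applied by caller)."""
    masks: dict[int, np.ndarray] = {}
    cost = None
    for node in tree.postorder():
        if node.is_leaf:
            masks[id(node)] = tip_masks[node.name]
            continue
        acc = None
        for child in node.children:
            m = masks[id(child)]
            if acc is None:
                acc, costs = m, np.zeros(m.shape, dtype=np.int64)
                continue
            inter = acc & m
            empty = inter == 0
            acc = np.where(empty, acc | m, inter)
            costs = costs + empty
        masks[id(node)] = acc
        cost = costs if cost is None else cost + costs
    return cost


def parsimony_score(tree: PhyloTree, workspace: LikelihoodWorkspace) -> float:
    masks = _tip_masks(workspace)
    cost = _fitch_sets(tree, masks)
    return float(workspace.weights @ cost)


def _tip_masks(workspace: LikelihoodWorkspace) -> dict[str, np.ndarray]:
    full = (1 << workspace.n_states) - 1
    masks = {}
    for taxon, row_idx in workspace.taxon_row.items():
        row = workspace.patterns[row_idx]
        mask = np.where(row == MISSING_CODE, full, 1 << np.maximum(row, 0))
        masks[taxon] = mask.astype(np.int64)
    return masks


def parsimony_topology(
    taxa: list[str], workspace: LikelihoodWorkspace, rng: np.random.Generator
) -> PhyloTree:
    """Greedy stepwise addition under Fitch parsimony, randomized order."""
    order = list(taxa)
    rng.shuffle(order)
    masks = _tip_masks(workspace)
    root = Node()
    for name in order[:3]:
        root.add_child(Node(name, 0.1))
    tree = PhyloTree(root)
    for name in order[3:]:
        best_tree, best_score = None, np.inf
        for idx in range(len(tree.edges())):
            cand = tree.copy()
            _insert_leaf(cand.edges()[idx], name)
            score = float(workspace.weights @ _fitch_sets(cand, masks))
            if score < best_score:
                best_tree, best_score = cand, score
        tree = best_tree
    return tree


# -- tree search -----------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood tree search."""

    tree: PhyloTree
    model: SubstitutionModel
    loglik: float
    aic: float
    seed: int | None = None
    start_logliks: list[float] = field(default_factory=list)
    best_start: int = 0

    def to_json_dict(self) -> dict[str, Any]:
        import json

        return {
            "tree": self.tree.to_newick(),
            "model": json.loads(self.model.to_json()),
            "loglik": self.loglik,
            "aic": self.aic,
            "seed": self.seed,
            "start_logliks": self.start_logliks,
            "best_start": self.best_start,
        }


def _refine_start(
    tree: PhyloTree,
    model: SubstitutionModel,
    ws: LikelihoodWorkspace,
    max_outer: int = 25,
) -> tuple[PhyloTree, SubstitutionModel, float]:
    """Alternate branch-length / model optimization with NNI hill climbing."""
    tree, llh = ws.optimize_branch_lengths(tree, model)
    model, llh = optimize_model(tree, None, model, workspace=ws)  # type: ignore[arg-type]
    for _ in range(max_outer):
        improved_round = llh
        # NNI: steepest ascent; candidates are scored after re-optimizing
        # their central edge length (lazy rearrangement evaluation)
        while True:
            best_cand, best_llh = None, llh
            for edge in tree.internal_edges():
                for cand, central in nni_neighbors(tree, edge, return_edges=True):
                    cand_llh = ws.optimize_single_edge(cand, model, central)
                    if cand_llh > best_llh + 1e-9:
                        best_cand, best_llh = cand, cand_llh
            if best_cand is None:
                break
            tree, llh = ws.optimize_branch_lengths(best_cand, model)
        tree, llh = ws.optimize_branch_lengths(tree, model)
        model, llh = optimize_model(tree, None, model, workspace=ws)  # type: ignore[arg-type]
        if llh - improved_round < SEARCH_TOL:
            break
    return tree, model, llh


def run_search(
    matrix: Matrix,
    model: SubstitutionModel,
    n_random: int = 10,
    n_parsimony: int = 10,
    seed: int | None = None,
) -> FitResult:
    """Maximum-likelihood tree search from multiple starting trees.

    Runs ``n_random`` searches from uniformly random topologies and
    ``n_parsimony`` from randomized stepwise-addition parsimony trees, refines
    each by alternating optimization and NNI, and returns the start with the
    best final log-likelihood (ties broken by start index).  Deterministic for
    a given seed.
    """
    ws = LikelihoodWorkspace(matrix, model)
    taxa = sorted(ws.taxon_row)
    if len(taxa) < 4:
        raise CogvecError("tree search needs at least 4 taxa")
    seq = np.random.SeedSequence(seed if seed is not None else 0)
    children = seq.spawn(n_random + n_parsimony)
    best: tuple[float, int, PhyloTree, SubstitutionModel] | None = None
    start_logliks: list[float] = []
    for idx in range(n_random + n_parsimony):
        rng = np.random.default_rng(children[idx])
        if idx < n_random:
            start = random_topology(taxa, rng)
        else:
            start = parsimony_topology(taxa, ws, rng)
        tree, fitted, llh = _refine_start(start, model, ws)
        start_logliks.append(llh)
        if best is None or llh > best[0] + 1e-12:
            best = (llh, idx, tree, fitted)
    llh, best_idx, tree, fitted = best
    return FitResult(
        tree=tree,
        model=fitted,
        loglik=llh,
        aic=2 * fitted.k - 2 * llh,
        seed=seed,
        start_logliks=start_logliks,
        best_start=best_idx,
    )
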