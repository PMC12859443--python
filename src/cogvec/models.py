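"""Time-reversible substitution models for cognate character matrices.

Five model kinds are provided.  ``BIN`` acts on binary presence/absence
columns (two states, one free base frequency).  The remaining kinds act on the
bit-vector representation of a κ-subset, whose state space is the 2^κ − 1
non-zero bit vectors of length κ:

``MK``
    all rates and frequencies equal; no free parameters.
``GTR``
    every exchangeability and frequency free.
``COGs``
    base frequency of a state depends only on its size ν = popcount(b)
    (π_ν); one exchangeability λ+ for state pairs whose bit vectors differ
    in exactly one position, another (λ0) for all remaining pairs.
``COG``
    as COGs, but multi-bit exchangeabilities are structurally zero
    (λ0 ≡ 0, never optimised) and the single-bit rate depends on the size of
    the smaller state: λ_ν with ν = min(popcount(b_i), popcount(b_j)).

All models are reversible by construction: the instantaneous rate is
q(i, j) = x(i, j) · Q[j] with a symmetric exchangeability x, so detailed
balance Q[i] q(i, j) = Q[j] q(j, i) holds identically.  The generator is
rescaled to unit expected substitution rate at stationarity, so branch
lengths are expected substitutions per column.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import count
from typing import Any, ClassVar

import numpy as np

from .errors import CogvecError

MODEL_KINDS = ("BIN", "MK", "GTR", "COGs", "COG")
MULTISTATE_KINDS = ("MK", "GTR", "COGs", "COG")


def popcount(bits: str | int) -> int:
    """Number of 1s in a bit string or in the binary representation of an int."""
    if isinstance(bits, str):
        if not bits or set(bits) - {"0", "1"}:
            raise CogvecError(f"not a bit string: {bits!r}")
        return bits.count("1")
    if bits < 0:
        raise CogvecError("popcount of a negative integer is undefined")
    return int(bits).bit_count()


def state_bits(index: int, kappa: int) -> int:
    """Bit-vector integer (in [1, 2^κ − 1]) for a 0-based symbol index."""
    value = index + 1
    if not 1 <= value <= 2**kappa - 1:
        raise CogvecError(f"state index {index} out of range for kappa={kappa}")
    return value


def rate_class(i: int, j: int, kind: str, kappa: int | None = None) -> str:
    """Symmetry class of the exchangeability between states i and j.

    Returns "shared" (MK), "x<i>_<j>" (GTR, unique per unordered pair),
    "lambda+"/"lambda0" (COGs), or "lambda<ν>"/"zero" (COG).
    """
    if i == j:
        raise CogvecError("the diagonal does not belong to a rate class")
    if kind == "MK":
        return "shared"
    if kind == "GTR":
        a, b = sorted((i, j))
        return f"x{a}_{b}"
    if kind in ("COGs", "COG"):
        if kappa is None:
            raise CogvecError(f"{kind} needs kappa")
        bi, bj = state_bits(i, kappa), state_bits(j, kappa)
        single_bit = popcount(bi ^ bj) == 1
        if kind == "COGs":
            return "lambda+" if single_bit else "lambda0"
        if single_bit:
            return f"lambda{min(popcount(bi), popcount(bj))}"
        return "zero"
    raise CogvecError(f"unknown model kind {kind!r}")


def free_parameter_count(kind: str, kappa: int | None = None, identifiable: bool = False) -> int:
    """Free-parameter count k used in AIC.

    The default follows the published counting convention: BIN → 1, MK → 0,
    GTR → 2^κ(2^κ − 1)/2 + 2^κ, COGs → κ + 1, COG → 2κ.  With
    ``identifiable=True`` an alternative count is returned that subtracts the
    simplex constraint and the global rate scale; it is never used by default.
    """
    if kind == "BIN":
        return 1
    if kind == "MK":
        return 0
    if kappa is None:
        raise CogvecError(f"{kind} needs kappa")
    if not 2 <= kappa <= 6:
        raise CogvecError(f"kappa={kappa} outside [2, 6]")
    if kind == "GTR":
        if identifiable:
            s = 2**kappa - 1
            return (s - 1) + (s * (s - 1) // 2 - 1)
        n = 2**kappa
        return n * (n - 1) // 2 + n
    if kind == "COGs":
        return kappa if identifiable else kappa + 1
    if kind == "COG":
        return 2 * kappa - 3 if identifiable else 2 * kappa
    raise CogvecError(f"unknown model kind {kind!r}")


@dataclass
class SubstitutionModel:
    """A built model: state space, frequencies Q, generator, and AIC count k."""

    kind: str
    kappa: int | None
    freqs: np.ndarray
    exchangeabilities: np.ndarray
    params: dict[str, Any]
    normalize: bool = True
    rate_matrix: np.ndarray = field(init=False)
    scale: float = field(init=False)
    _eig: tuple[np.ndarray, np.ndarray, np.ndarray] | None = field(
        init=False, default=None, repr=False
    )
    #: process-unique identity for external caches (object ids are recycled)
    serial: int = field(init=False, repr=False)
    _counter: ClassVar[count] = count()

    def __post_init__(self) -> None:
        q = np.asarray(self.freqs, dtype=float)
        x = np.asarray(self.exchangeabilities, dtype=float)
        s = len(q)
        if x.shape != (s, s) or not np.allclose(x, x.T):
            raise CogvecError("exchangeability matrix must be square and symmetric")
        if np.any(q <= 0) or not math.isclose(q.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
            raise CogvecError("frequencies must be positive and sum to 1")
        if np.any(x < 0):
            raise CogvecError("exchangeabilities must be non-negative")
        g = x * q[np.newaxis, :]
        np.fill_diagonal(g, 0.0)
        np.fill_diagonal(g, -g.sum(axis=1))
        mu = float(-(q * np.diag(g)).sum())
        if self.normalize:
            if mu <= 0:
                raise CogvecError("degenerate model: zero expected substitution rate")
            g = g / mu
        self.freqs = q
        self.exchangeabilities = x
        self.rate_matrix = g
        self.scale = mu
        self.serial = next(SubstitutionModel._counter)

    @property
    def n_states(self) -> int:
        return len(self.freqs)

    @property
    def k(self) -> int:
        return free_parameter_count(self.kind, self.kappa)

    def _eigendecomposition(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        # reversible generators are symmetrizable: D^{1/2} G D^{-1/2} is
        # symmetric for D = diag(Q), so a real eigh suffices
        if self._eig is None:
            d = np.sqrt(self.freqs)
            sym = self.rate_matrix * (d[:, None] / d[None, :])
            sym = 0.5 * (sym + sym.T)
            w, u = np.linalg.eigh(sym)
            self._eig = (w, u / d[:, None], np.ascontiguousarray((u * d[:, None]).T))
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(G t); rows sum to one, entries clipped at zero."""
        if t < 0:
            raise CogvecError("branch length must be non-negative")
        w, left, right_t = self._eigendecomposition()
        p = (left * np.exp(w * t)) @ right_t
        np.maximum(p, 0.0, out=p)
        p /= p.sum(axis=1)[:, None]
        return p

    def to_json(self) -> str:
        payload = {
            "kind": self.kind,
            "kappa": self.kappa,
            "k": self.k,
            "params": {
                key: (list(np.asarray(v, dtype=float)) if np.ndim(v) else float(v))
                for key, v in self.params.items()
            },
            "normalization_constant": self.scale,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SubstitutionModel":
        payload = json.loads(text)
        return build_model(payload["kind"], payload["kappa"], payload["params"])


def _binomial_normalize(pi: np.ndarray, kappa: int) -> np.ndarray:
    """Scale the π_ν vector so that Σ_ν C(κ, ν) π_ν = 1."""
    weights = np.array([math.comb(kappa, nu) for nu in range(1, kappa + 1)], dtype=float)
    total = float(weights @ pi)
    if total <= 0:
        raise CogvecError("frequencies are not normalizable")
    return pi / total

def default_params(kind: str, kappa: int | None = None) -> dict[str, Any]:
    """Neutral starting parameters (uniform frequencies, unit rates)."""
    if kind == "BIN":
        return {"pi_1": 0.5}
    if kind == "MK":
        return {}
    if kappa is None:
        raise CogvecError(f"{kind} needs kappa")
    s = 2**kappa - 1
    if kind == "GTR":
        return {"freqs": [1.0 / s] * s, "rates": [1.0] * (s * (s - 1) // 2)}
    if kind == "COGs":
        return {"pi": [1.0 / s] * kappa, "lambda_plus": 1.0, "lambda_0": 1.0}
    if kind == "COG":
        return {"pi": [1.0 / s] * kappa, "lambda": [1.0] * (kappa - 1)}
    raise CogvecError(f"unknown model kind {kind!r}")


def build_model(
    kind: str,
    kappa: int | None = None,
    params: dict[str, Any] | None = None,
    normalize: bool = True,
) -> SubstitutionModel:
    """Construct a substitution model from its free parameters.

    Frequency-type parameters may be given unnormalized; they are rescaled to
    the appropriate simplex (for COG/COGs the π_ν simplex weighted by the
    binomial state multiplicities C(κ, ν)).  Rates must be non-negative and
    strictly positive where the model requires them; COG's λ0 is pinned to
    exactly zero.
    """
    if kind not in MODEL_KINDS:
        raise CogvecError(f"unknown model kind {kind!r}")
    if params is None:
        params = default_params(kind, kappa)
    if kind == "BIN":
        p1 = float(params["pi_1"])
        if not 0 < p1 < 1:
            raise CogvecError("BIN frequency pi_1 must lie strictly in (0, 1)")
        freqs = np.array([1.0 - p1, p1])
        x = np.array([[0.0, 1.0], [1.0, 0.0]])
        return SubstitutionModel("BIN", None, freqs, x, {"pi_1": p1}, normalize)

    if kappa is None or not 2 <= kappa <= 6:
        raise CogvecError(f"{kind} needs kappa in [2, 6], got {kappa}")
    s = 2**kappa - 1

    if kind == "MK":
        freqs = np.full(s, 1.0 / s)
        x = np.ones((s, s))
        np.fill_diagonal(x, 0.0)
        return SubstitutionModel("MK", kappa, freqs, x, {}, normalize)

    if kind == "GTR":
        freqs = np.asarray(params["freqs"], dtype=float)
        rates = np.asarray(params["rates"], dtype=float)
        if freqs.shape != (s,) or np.any(freqs <= 0):
            raise CogvecError(f"GTR needs {s} positive frequencies")
        if rates.shape != (s * (s - 1) // 2,) or np.any(rates < 0):
            raise CogvecError(f"GTR needs {s * (s - 1) // 2} non-negative rates")
        freqs = freqs / freqs.sum()
        x = np.zeros((s, s))
        idx = 0
        for i in range(s):
            for j in range(i + 1, s):
                x[i, j] = x[j, i] = rates[idx]
                idx += 1
        return SubstitutionModel(
            "GTR", kappa, freqs, x,
            {"freqs": freqs.tolist(), "rates": rates.tolist()}, normalize,
        )

    pi = np.asarray(params["pi"], dtype=float)
    if pi.shape != (kappa,) or np.any(pi <= 0):
        raise CogvecError(f"{kind} needs {kappa} positive size-class frequencies π_ν")
    pi = _binomial_normalize(pi, kappa)
    nu = np.array([popcount(state_bits(i, kappa)) for i in range(s)])
    freqs = pi[nu - 1]

    x = np.zeros((s, s))
    if kind == "COGs":
        lam_plus = float(params["lambda_plus"])
        lam_0 = float(params["lambda_0"])
        if lam_plus <= 0 or lam_0 < 0:
            raise CogvecError("COGs needs lambda_plus > 0 and lambda_0 >= 0")
        for i in range(s):
            for j in range(i + 1, s):
                label = rate_class(i, j, "COGs", kappa)
                x[i, j] = x[j, i] = lam_plus if label == "lambda+" else lam_0
        built_params = {"pi": pi.tolist(), "lambda_plus": lam_plus, "lambda_0": lam_0}
        return SubstitutionModel("COGs", kappa, freqs, x, built_params, normalize)

    # COG: single-bit rates by smaller-state size; multi-bit rates exactly 0
    lam = np.asarray(params["lambda"], dtype=float)
    if lam.shape != (kappa - 1,) or np.any(lam <= 0):
        raise CogvecError(f"COG needs {kappa - 1} positive rates λ_1..λ_{kappa - 1}")
    for i in range(s):
        for j in range(i + 1, s):
            label = rate_class(i, j, "COG", kappa)
            if label != "zero":
                x[i, j] = x[j, i] = lam[int(label.removeprefix("lambda")) - 1]
    built_params = {"pi": pi.tolist(), "lambda": lam.tolist(), "lambda_0": 0.0}
    return SubstitutionModel("COG", kappa, freqs, x, built_params, normalize)
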