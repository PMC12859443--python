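import numpy as np
import pytest

from cogvec import (
    CogvecError,
    SubstitutionModel,
    build_model,
    free_parameter_count,
    popcount,
    rate_class,
)
from cogvec.models import state_bits


def random_model(rng: np.random.Generator) -> SubstitutionModel:
    kind = rng.choice(["BIN", "MK", "GTR", "COGs", "COG"])
    kappa = int(rng.integers(2, 7))
    if kind == "BIN":
        return build_model("BIN", params={"pi_1": float(rng.uniform(0.05, 0.95))})
    s = 2**kappa - 1
    if kind == "MK":
        return build_model("MK", kappa)
    if kind == "GTR":
        return build_model(
            "GTR",
            kappa,
            {
                "freqs": rng.uniform(0.05, 1.0, s),
                "rates": rng.uniform(0.05, 2.0, s * (s - 1) // 2),
            },
        )
    pi = rng.uniform(0.05, 1.0, kappa)
    if kind == "COGs":
        return build_model(
            "COGs",
            kappa,
            {
                "pi": pi,
                "lambda_plus": float(rng.uniform(0.1, 3.0)),
                "lambda_0": float(rng.uniform(0.0, 3.0)),
            },
        )
    return build_model(
        "COG", kappa, {"pi": pi, "lambda": rng.uniform(0.1, 3.0, kappa - 1)}
    )


def test_popcount():
    assert popcount("101") == 2
    assert popcount("000") == 0
    assert popcount("111111") == 6
    assert popcount(0b1011) == 3


@pytest.mark.parametrize(
    "kind, kappa, expected",
    [
        ("BIN", None, 1),
        ("MK", 3, 0),
        ("GTR", 2, 10),
        ("GTR", 3, 36),
        ("GTR", 5, 528),
        ("COGs", 2, 3),
        ("COGs", 6, 7),
        ("COG", 2, 4),
        ("COG", 3, 6),
        ("COG", 6, 12),
    ],
)
def test_free_parameter_count(kind, kappa, expected):
    assert free_parameter_count(kind, kappa) == expected


def test_rate_class_cog_and_cogs():
    # κ=3 symbol indices: value = index + 1; 001 -> 0, 011 -> 2, 110 -> 5
    assert rate_class(0, 2, "COG", 3) == "lambda1"
    assert rate_class(0, 5, "COG", 3) == "zero"
    # κ=2: 01 -> 0, 10 -> 1 differ in both bits
    assert rate_class(0, 1, "COGs", 2) == "lambda0"
    assert rate_class(0, 2, "COGs", 2) == "lambda+"
    assert rate_class(3, 5, "MK", 3) == "shared"
    with pytest.raises(CogvecError):
        rate_class(1, 1, "MK", 3)


@pytest.mark.parametrize("seed", range(8))
def test_reversibility_stationarity_normalization(seed):
    rng = np.random.default_rng(seed)
    for _ in range(10):
        m = random_model(rng)
        q, g = m.freqs, m.rate_matrix
        flux = q[:, None] * g
        assert np.abs(flux - flux.T).max() < 1e-12
        assert np.abs(q @ g).max() < 1e-10
        assert abs(-(q * np.diag(g)).sum() - 1.0) < 1e-12
        assert abs(q.sum() - 1.0) < 1e-9


def test_cog_structural_zeros_are_exact():
    rng = np.random.default_rng(7)
    for _ in range(20):
        kappa = int(rng.integers(2, 7))
        m = build_model(
            "COG",
            kappa,
            {"pi": rng.uniform(0.1, 1.0, kappa), "lambda": rng.uniform(0.1, 3.0, kappa - 1)},
        )
        s = m.n_states
        for i in range(s):
            for j in range(s):
                if i != j and popcount(state_bits(i, kappa) ^ state_bits(j, kappa)) > 1:
                    assert m.rate_matrix[i, j] == 0.0


def test_cogs_with_equal_rates_is_mk():
    cogs = build_model(
        "COGs", 2, {"pi": [1 / 3, 1 / 3], "lambda_plus": 1.0, "lambda_0": 1.0}
    )
    mk = build_model("MK", 2)
    assert np.allclose(cogs.rate_matrix, mk.rate_matrix, atol=1e-14)
    assert np.allclose(cogs.freqs, mk.freqs)


def test_cog_equal_lambdas_matches_mk_on_single_bit_support():
    """Raw (unnormalized) generators agree on 1-bit pairs; COG is 0 elsewhere."""
    cog = build_model(
        "COG", 3, {"pi": [1 / 7] * 3, "lambda": [1.0, 1.0]}, normalize=False
    )
    mk = build_model("MK", 3, normalize=False)
    s = 7
    for i in range(s):
        for j in range(s):
            if i == j:
                continue
            single = popcount(state_bits(i, 3) ^ state_bits(j, 3)) == 1
            if single:
                assert cog.rate_matrix[i, j] == pytest.approx(mk.rate_matrix[i, j])
            else:
                assert cog.rate_matrix[i, j] == 0.0


def test_gtr_nests_cogs_exactly():
    cogs = build_model(
        "COGs", 3, {"pi": [0.5, 0.2, 0.1], "lambda_plus": 1.3, "lambda_0": 0.4}
    )
    s = cogs.n_states
    rates = [cogs.exchangeabilities[i, j] for i in range(s) for j in range(i + 1, s)]
    gtr = build_model("GTR", 3, {"freqs": cogs.freqs, "rates": rates})
    assert np.allclose(gtr.rate_matrix, cogs.rate_matrix, atol=1e-14)


def test_frequency_symmetry_layout_kappa3():
    m = build_model("COG", 3, {"pi": [0.5, 0.2, 0.1], "lambda": [2.0, 1.0]})
    by_popcount = {}
    for i in range(7):
        by_popcount.setdefault(popcount(state_bits(i, 3)), set()).add(m.freqs[i])
    # exactly one frequency value per state size ν
    assert all(len(v) == 1 for v in by_popcount.values())
    assert len({next(iter(v)) for v in by_popcount.values()}) == 3
    # COGs rates collapse to at most two distinct off-diagonal exchangeabilities
    ms = build_model(
        "COGs", 3, {"pi": [0.5, 0.2, 0.1], "lambda_plus": 1.3, "lambda_0": 0.4}
    )
    x = ms.exchangeabilities
    off = {round(x[i, j], 12) for i in range(7) for j in range(7) if i != j}
    assert len(off) <= 2


def test_transition_matrix_properties():
    m = build_model("COG", 3, {"pi": [0.5, 0.2, 0.1], "lambda": [2.0, 1.0]})
    assert np.allclose(m.transition_matrix(0.0), np.eye(7), atol=1e-12)
    p = m.transition_matrix(0.7)
    assert np.all(p >= 0)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)
    # ergodic limit: every row approaches the stationary frequencies
    p_inf = m.transition_matrix(500.0)
    assert np.abs(p_inf - m.freqs[None, :]).max() < 1e-8


def test_mk_transition_closed_form():
    m = build_model("MK", 2)  # 3 states, unit-rate normalization
    for t in (0.1, 0.5, 1.0, 3.0):
        p = m.transition_matrix(t)
        same = 1 / 3 + (2 / 3) * np.exp(-1.5 * t)
        diff = (1 - same) / 2
        assert p[0, 0] == pytest.approx(same, abs=1e-12)
        assert p[0, 1] == pytest.approx(diff, abs=1e-12)


def test_invalid_parameters_rejected():
    with pytest.raises(CogvecError):
        build_model("COG", 3, {"pi": [0.5, -0.1, 0.1], "lambda": [1.0, 1.0]})
    with pytest.raises(CogvecError):
        build_model("COG", 7)
    with pytest.raises(CogvecError):
        build_model("COGs", 3, {"pi": [0.5, 0.2, 0.1], "lambda_plus": -1.0, "lambda_0": 0.0})
    with pytest.raises(CogvecError):
        build_model("XYZ", 3)


def test_model_json_round_trip():
    m = build_model("COG", 3, {"pi": [0.5, 0.2, 0.1], "lambda": [2.0, 1.0]})
    back = SubstitutionModel.from_json(m.to_json())
    assert back.kind == "COG" and back.kappa == 3
    assert np.allclose(back.rate_matrix, m.rate_matrix)
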